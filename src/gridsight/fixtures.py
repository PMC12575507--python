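"""Tiny deterministic fixture bundle used by the test suite and docs.

``make_fixtures`` writes three stereo scenes (grid facing the camera at
40/60/90 cm) with images, labels and ground truth, a 2x2 toy grid scene,
and a deliberately corrupted label file for negative tests; everything is
derived from one seed and is byte-stable across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

from .camera import default_rig
from .grid import GridSpec
from .render import RenderSettings, render_stereo
from .scenes import MeasurementLayout, make_measurement_scenes, save_frame
from ._seeding import derive_seed

__all__ = ["make_fixtures"]

_DEPTHS = (0.40, 0.60, 0.90)


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the fixture bundle under ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rig = default_rig()
    manifest: dict = {"seed": seed, "scenes": [], "toy_scene": None,
                      "corrupted_labels": None}

    layout = MeasurementLayout(depths=_DEPTHS, n_lateral=1)
    scenes = make_measurement_scenes(layout)
    for scene in scenes:
        settings = RenderSettings(seed=derive_seed(seed, "fixture", scene.position_id))
        left, right = render_stereo(rig, scene.state, settings)
        entry = {"position_id": scene.position_id, "depth_m": scene.depth, "files": {}}
        for side, frame in (("left", left), ("right", right)):
            stem = f"{scene.position_id}_{side}"
            save_frame(out / f"{stem}.png", out / f"{stem}.txt", frame)
            entry["files"][side] = {"image": f"{stem}.png", "label": f"{stem}.txt"}
        truth_name = f"{scene.position_id}_truth.csv"
        scene.state.to_csv(out / truth_name)
        entry["files"]["truth"] = truth_name
        manifest["scenes"].append(entry)

    # 2x2 toy grid (4 electrodes + 4 tails = 8 keypoints)
    toy_spec = GridSpec(rows=2, cols=2)
    toy = make_measurement_scenes(MeasurementLayout(depths=(0.40,), n_lateral=1),
                                  spec=toy_spec)[0]
    left, _right = render_stereo(rig, toy.state,
                                 RenderSettings(seed=derive_seed(seed, "fixture", "toy")))
    save_frame(out / "toy_left.png", out / "toy_left.txt", left)
    manifest["toy_scene"] = {"image": "toy_left.png", "label": "toy_left.txt",
                             "n_keypoints": toy_spec.n_points}

    # corrupted label file: line 2 is truncated mid-record
    good = (out / "toy_left.txt").read_text().strip()
    corrupted = good + "\n" + " ".join(good.split()[:17]) + "\n"
    (out / "corrupted_labels.txt").write_text(corrupted)
    manifest["corrupted_labels"] = "corrupted_labels.txt"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
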