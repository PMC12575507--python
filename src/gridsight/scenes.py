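"""Dataset factories: super-resolution training corpora and the
measurement-grid scenes of the evaluation protocol.

Corpus images follow the paper-scale recipe at any size: base renders of
the grid at random pose/deformation/appearance, sized 80-260 px, each
written together with its downscaled versions (75%, 50%, 33% by default),
so a corpus of ``n_base`` bases holds exactly ``n_base * len(scales)``
image/label pairs, the smallest 26 px wide.

Label files use the single-stage-detector keypoint convention: one line
per object — class index, normalized bbox center x/y and width/height,
then ``(x, y, visibility)`` triplets for the 68 keypoints, normalized by
the image size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._errors import EmptySceneError, InvalidInputError, LabelFormatError
from ._seeding import derive_seed, substream
from .camera import CameraIntrinsics, DistortionCoeffs, RigidPose
from .grid import DeformationParams, GridSpec, GridState, canonical_grid, deform
from .render import LabeledFrame, RenderSettings, downscale_with_labels, render_mono

__all__ = [
    "CorpusManifest",
    "MeasurementLayout",
    "MeasurementScene",
    "corpus_size",
    "make_sr_corpus",
    "make_measurement_scenes",
    "write_label_file",
    "parse_label_file",
    "save_frame",
]

DEFAULT_SCALES = (1.0, 0.75, 0.5, 0.33)


# --------------------------------------------------------------------------
# label file I/O


def write_label_file(path, frame: LabeledFrame, class_index: int = 0) -> None:
    """Write one frame's labels in the normalized keypoint-label format.

    Coordinates use the continuous image frame (pixel centers at integers),
    normalized so that x_norm = (x + 0.5) / width maps the image to [0, 1].
    """
    h, w = frame.image.shape
    x, y, bw, bh = frame.bbox
    cx = (x + bw / 2.0 + 0.5) / w
    cy = (y + bh / 2.0 + 0.5) / h
    parts = [str(class_index), f"{cx:.8f}", f"{cy:.8f}", f"{bw / w:.8f}", f"{bh / h:.8f}"]
    for (kx, ky), v in zip(frame.keypoints, frame.visible):
        if v:
            parts += [f"{(kx + 0.5) / w:.8f}", f"{(ky + 0.5) / h:.8f}", "2"]
        else:
            parts += ["0", "0", "0"]
    Path(path).write_text(" ".join(parts) + "\n")


def parse_label_file(path, n_keypoints: int = 68) -> list[dict]:
    """Parse a label file; raises :class:`LabelFormatError` with the
    offending line number on malformed input."""
    objects = []
    n_fields = 5 + 3 * n_keypoints
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != n_fields:
            raise LabelFormatError(
                f"expected {n_fields} fields, found {len(tokens)}", line=lineno
            )
        try:
            cls = int(tokens[0])
            vals = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise LabelFormatError(f"non-numeric field: {exc}", line=lineno) from None
        box = vals[:4]
        trip = np.array(vals[4:]).reshape(n_keypoints, 3)
        if np.any((trip[:, 2] > 0) & ((trip[:, :2] < 0) | (trip[:, :2] > 1)).any(axis=1)):
            raise LabelFormatError("visible keypoint outside [0, 1]", line=lineno)
        objects.append(
            {
                "class": cls,
                "bbox_norm": tuple(box),
                "keypoints_norm": trip[:, :2],
                "visibility": trip[:, 2],
            }
        )
    return objects


def save_frame(image_path, label_path, frame: LabeledFrame) -> None:
    """Write an 8-bit grayscale PNG and its label file."""
    img8 = np.clip(np.round(frame.image * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(image_path), img8)
    write_label_file(label_path, frame)


# --------------------------------------------------------------------------
# super-resolution training corpus


@dataclass
class CorpusManifest:
    entries: list[dict]
    counts_per_scale: dict[str, int]
    seed: int
    n_base: int
    scales: tuple[float, ...]

    @property
    def total(self) -> int:
        return len(self.entries)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "n_base": self.n_base,
            "scales": list(self.scales),
            "total": self.total,
            "counts_per_scale": self.counts_per_scale,
            "entries": self.entries,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def corpus_size(n_base: int, scales) -> int:
    """Exact corpus arithmetic: one image per (base render, scale)."""
    return int(n_base) * len(tuple(scales))


def _random_base_scene(spec: GridSpec, rng: np.random.Generator) -> GridState:
    """A deformed grid in a random pose in front of a corpus camera at 0.5 m."""
    tilt = rng.uniform(0.0, 0.7)
    tilt_dir = rng.uniform(0.0, 2 * np.pi)
    roll = rng.uniform(0.0, 2 * np.pi)

    def rot(axis, ang):
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)

    # rot_x(pi) faces the sheet toward the camera; then tilt and roll it
    R = rot([0, 0, 1], roll) @ rot(
        [np.cos(tilt_dir), np.sin(tilt_dir), 0], tilt
    ) @ rot([1, 0, 0], np.pi)

    center = np.array(
        [((spec.cols - 1) / 2.0) * spec.pitch, ((spec.rows - 1) / 2.0) * spec.pitch, 0.0]
    )
    target = np.array([0.0, 0.0, 0.5]) + rng.uniform(-0.01, 0.01, 3) * np.array([1, 1, 2])
    pose = RigidPose(R, target - R @ center)
    state = canonical_grid(spec, pose)
    params = DeformationParams(
        curvature=rng.uniform(-12.0, 12.0),
        bend_axis_angle=rng.uniform(0.0, np.pi),
        random_amplitude=rng.uniform(0.0, 0.0015),
    )
    return deform(state, params, seed=int(rng.integers(2**31)))


def _randomized_settings(seed: int, rng: np.random.Generator) -> RenderSettings:
    return RenderSettings(
        background_mode=("flat", "gradient", "textured-noise")[int(rng.integers(3))],
        blur_sigma=float(rng.uniform(0.3, 1.0)),
        noise_sigma=float(rng.uniform(0.005, 0.02)),
        seed=seed,
    )


def make_sr_corpus(
    n_base: int,
    scales=DEFAULT_SCALES,
    sink=None,
    seed: int = 0,
    spec: GridSpec | None = None,
    size_range: tuple[int, int] = (80, 260),
) -> CorpusManifest:
    """Generate a multi-scale training corpus.

    Writes ``n_base`` object-centered base renders (square, side sampled
    uniformly in ``size_range``) and one image+label per (base, scale)
    under ``sink`` (``images/`` + ``labels/``); returns the manifest.
    """
    if n_base < 1:
        raise InvalidInputError("n_base must be >= 1")
    scales = tuple(scales)
    if not scales:
        raise InvalidInputError("scales must be non-empty")
    if sink is None:
        raise InvalidInputError("sink directory is required")
    sink = Path(sink)
    try:
        (sink / "images").mkdir(parents=True, exist_ok=True)
        (sink / "labels").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create corpus sink {sink}: {exc}") from exc

    spec = spec or GridSpec()
    entries = []
    counts = {f"{s:g}": 0 for s in scales}
    for i in range(n_base):
        rng = substream(seed, "corpus", i)
        side = int(rng.integers(size_range[0], size_range[1] + 1))
        extent = max(
            (spec.cols - 1) * spec.pitch, (spec.rows - 1) * spec.pitch
        ) + 2 * spec.disk_diameter + 0.01
        f_px = 0.72 * side * 0.5 / extent
        intr = CameraIntrinsics(f_px, f_px, (side - 1) / 2.0, (side - 1) / 2.0, side, side)
        render_seed = derive_seed(seed, "corpus-render", i)
        for attempt in range(5):
            try:
                state = _random_base_scene(spec, rng)
                settings = _randomized_settings(derive_seed(render_seed, attempt), rng)
                base = render_mono(intr, DistortionCoeffs(), RigidPose.identity(),
                                   state, settings)
                break
            except EmptySceneError:
                continue
        else:  # pragma: no cover - ranges keep the grid in frame
            raise EmptySceneError(f"base render {i} repeatedly out of frame")
        for s in scales:
            frame = downscale_with_labels(base, s)
            stem = f"b{i:06d}_s{s:g}"
            save_frame(sink / "images" / f"{stem}.png", sink / "labels" / f"{stem}.txt",
                       frame)
            entries.append(
                {
                    "image": f"images/{stem}.png",
                    "label": f"labels/{stem}.txt",
                    "scale": s,
                    "base": i,
                    "size": list(frame.image.shape[::-1]),
                }
            )
            counts[f"{s:g}"] += 1

    manifest = CorpusManifest(
        entries=entries, counts_per_scale=counts, seed=seed,
        n_base=n_base, scales=scales,
    )
    manifest.to_json(sink / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# measurement-grid scenes


@dataclass(frozen=True)
class MeasurementLayout:
    """The evaluation measurement grid: positions spanning 40-90 cm depth
    over a 32 cm-wide lateral band (working area 32x50 cm), the grid at
    each position rotated to face the left camera directly.

    ``lateral_center`` shifts the band onto the stereo overlap (half the
    baseline for the default rig)."""

    depths: tuple[float, ...] = (0.40, 0.50, 0.60, 0.70, 0.80, 0.90)
    n_lateral: int = 5
    lateral_extent: float = 0.32
    lateral_center: float = 0.049
    height: float = 0.0

    def __post_init__(self):
        if min(self.depths) <= 0:
            raise InvalidInputError("depths must be positive")
        if self.n_lateral < 1 or self.lateral_extent < 0:
            raise InvalidInputError("invalid lateral layout")

    @property
    def n_positions(self) -> int:
        return len(self.depths) * self.n_lateral


@dataclass(frozen=True)
class MeasurementScene:
    position_id: str
    depth: float
    lateral: float
    state: GridState
    is_reference: bool


def _facing_pose(position: np.ndarray, spec: GridSpec) -> RigidPose:
    """Grid pose with the electrode-array center at ``position`` and the
    sheet normal aimed exactly at the left camera (world origin)."""
    z_axis = -position / np.linalg.norm(position)  # grid +z toward the camera
    x_axis = np.cross(z_axis, np.array([0.0, 1.0, 0.0]))
    x_axis = x_axis / np.linalg.norm(x_axis)
    y_axis = np.cross(z_axis, x_axis)
    R = np.stack([x_axis, y_axis, z_axis], axis=1)
    if np.linalg.det(R) < 0:
        y_axis = -y_axis
        R = np.stack([x_axis, y_axis, z_axis], axis=1)
    center = np.array(
        [((spec.cols - 1) / 2.0) * spec.pitch, ((spec.rows - 1) / 2.0) * spec.pitch, 0.0]
    )
    return RigidPose(R, position - R @ center)


def make_measurement_scenes(
    layout: MeasurementLayout | None = None, spec: GridSpec | None = None
) -> list[MeasurementScene]:
    """Build the flat, camera-facing grid states of the measurement grid.

    The reference is the closest central position (40 cm for the default
    layout); scenes are ordered by (depth, lateral)."""
    layout = layout or MeasurementLayout()
    spec = spec or GridSpec()
    if layout.n_lateral == 1:
        laterals = np.array([layout.lateral_center])
    else:
        laterals = layout.lateral_center + np.linspace(
            -layout.lateral_extent / 2.0, layout.lateral_extent / 2.0, layout.n_lateral
        )
    ref_depth = min(layout.depths)
    ref_lat_idx = int(np.argmin(np.abs(laterals - layout.lateral_center)))
    scenes = []
    for d_idx, depth in enumerate(sorted(layout.depths)):
        for l_idx, lat in enumerate(laterals):
            position = np.array([lat, layout.height, depth])
            pose = _facing_pose(position, spec)
            state = canonical_grid(spec, pose)
            scenes.append(
                MeasurementScene(
                    position_id=f"z{int(round(depth * 100)):03d}_x{l_idx}",
                    depth=depth,
                    lateral=float(lat),
                    state=state,
                    is_reference=(depth == ref_depth and l_idx == ref_lat_idx),
                )
            )
    return scenes
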