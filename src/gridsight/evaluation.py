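"""Stereo evaluation: grid triangulation, outlier filtering, the
relative-pose error protocol, and the scaled-down experiment harness.

The accuracy statistic mirrors the optical-tracker protocol: the grid is
placed at predefined positions spanning 40-90 cm depth; the closest
central position is the reference; for every electrode the *relative*
displacement (Euclidean distance between its position at the reference
and at another position) measured by the pipeline is compared with the
same displacement in the simulator's ground truth, and the absolute
difference is the error.  Outliers are removed by the 10 cm-from-median
rule before statistics; the false-positive rate counts those removals
over the frames that passed the single-bbox stereo acceptance rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import (
    AmbiguityError,
    ContractError,
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    InvalidInputError,
)
from ._seeding import derive_seed, substream
from .camera import StereoRig, rectify_points, triangulate, undistort_rectify
from .detection import (
    ClassicalDetector,
    OracleDetector,
    accept_stereo,
    crop,
    detect_grid,
)
from .grid import GridSpec
from .pose import (
    KeypointSet,
    assign_indices,
    detect_keypoint_candidates,
    to_full_frame,
    upscale,
)
from .render import LabeledFrame, RenderSettings, render_stereo
from .scenes import MeasurementLayout, MeasurementScene, make_measurement_scenes

__all__ = [
    "GridMeasurement",
    "ErrorReport",
    "ExperimentSpec",
    "triangulate_grid",
    "median_outlier_filter",
    "false_positive_rate",
    "relative_pose_error",
    "electrode_heatmap",
    "run_experiment",
    "process_stereo_frame",
    "OraclePoseEstimator",
    "ClassicalPoseEstimator",
]


@dataclass
class GridMeasurement:
    """Triangulated 3D keypoints of one stereo frame (world = left
    rectified camera frame, meters)."""

    points3d: np.ndarray
    valid: np.ndarray
    position_id: str = ""
    frame_index: int = 0
    run_index: int = 0

    def center(self) -> np.ndarray:
        """Mean of the valid triangulated points."""
        if not self.valid.any():
            raise InvalidInputError("measurement has no valid points")
        return self.points3d[self.valid].mean(axis=0)


def triangulate_grid(
    rect_rig: StereoRig, left: KeypointSet, right: KeypointSet, min_points: int = 4
) -> GridMeasurement:
    """Triangulate the mutually visible keypoints of a stereo pair.

    Both keypoint sets must be in full-frame rectified coordinates; an
    index invisible in either view (or with non-positive disparity) is
    invalid in the result."""
    if left.frame != "full" or right.frame != "full":
        raise ContractError("keypoint sets must be in the full rectified frame")
    n = len(left.points)
    if len(right.points) != n:
        raise ContractError("keypoint sets differ in length")
    mutual = left.visible & right.visible
    if mutual.sum() < min_points:
        raise InsufficientCorrespondencesError(
            f"only {int(mutual.sum())} mutually visible points (< {min_points})"
        )
    pts = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in np.nonzero(mutual)[0]:
        try:
            pts[i] = triangulate(rect_rig, left.points[i], right.points[i])
            valid[i] = True
        except DegenerateGeometryError:
            continue
    if valid.sum() < min_points:
        raise InsufficientCorrespondencesError(
            f"only {int(valid.sum())} triangulable points (< {min_points})"
        )
    return GridMeasurement(points3d=pts, valid=valid)


def median_outlier_filter(
    measurements: list[GridMeasurement], threshold: float = 0.10
):
    """Reject measurements whose center strays more than ``threshold``
    meters from the component-wise median center (strictly greater-than
    rejects; exactly at the threshold is kept)."""
    if not measurements:
        raise InvalidInputError("need at least one measurement")
    centers = np.stack([m.center() for m in measurements])
    median = np.median(centers, axis=0)
    dist = np.linalg.norm(centers - median, axis=1)
    kept = [m for m, d in zip(measurements, dist) if d <= threshold]
    rejected = [m for m, d in zip(measurements, dist) if d > threshold]
    return kept, rejected


def false_positive_rate(considered: int, rejected: int) -> float:
    """rejected / considered; the empty case 0/0 is defined as 0.0 (with a
    warning)."""
    if rejected > considered or rejected < 0:
        raise ContractError(f"rejected ({rejected}) exceeds considered ({considered})")
    if considered == 0:
        warnings.warn("false_positive_rate of 0 considered frames is undefined; returning 0",
                      stacklevel=2)
        return 0.0
    return rejected / considered


def relative_pose_error(
    ref_meas: GridMeasurement,
    pos_meas: GridMeasurement,
    ref_truth: GridMeasurement,
    pos_truth: GridMeasurement,
    n_electrodes: int = 64,
):
    """Per-electrode relative-pose errors (meters).

    ``error_i = | ||m_i(pos) - m_i(ref)|| - ||t_i(pos) - t_i(ref)|| |``
    where m is the pipeline measurement and t the ground truth.  Validity
    masks of measurement and truth must agree per position; the returned
    mask marks electrodes valid at both positions."""
    for m, t in ((ref_meas, ref_truth), (pos_meas, pos_truth)):
        if not np.array_equal(m.valid[:n_electrodes], t.valid[:n_electrodes]):
            raise ContractError("measurement and truth validity masks differ")
    mask = (ref_meas.valid & pos_meas.valid)[:n_electrodes]
    d_meas = np.linalg.norm(
        pos_meas.points3d[:n_electrodes] - ref_meas.points3d[:n_electrodes], axis=1
    )
    d_truth = np.linalg.norm(
        pos_truth.points3d[:n_electrodes] - ref_truth.points3d[:n_electrodes], axis=1
    )
    errors = np.abs(d_meas - d_truth)
    errors[~mask] = np.nan
    return errors, mask


def electrode_heatmap(error_sums: np.ndarray, rows: int = 8, cols: int = 8):
    """Normalize per-electrode error sums by the single worst electrode;
    returns ``(rows x cols map in [0, 1], all_zero_flag)``."""
    sums = np.asarray(error_sums, dtype=float)
    if sums.shape != (rows * cols,):
        raise InvalidInputError(f"expected {rows * cols} electrode sums, got {sums.shape}")
    peak = np.nanmax(sums)
    if not np.isfinite(peak) or peak <= 0:
        return np.zeros((rows, cols)), True
    return (sums / peak).reshape(rows, cols), False


# --------------------------------------------------------------------------
# pose plugins


@dataclass
class OraclePoseEstimator:
    """Returns the ground-truth rectified keypoints, optionally perturbed
    by isotropic pixel noise (per frame, deterministic via the seed)."""

    noise_px: float = 0.0
    seed: int = 0

    def estimate(self, frame: LabeledFrame, rect_points: np.ndarray,
                 stream: tuple = ()) -> KeypointSet:
        pts = rect_points.copy()
        if self.noise_px > 0:
            rng = substream(self.seed, "oracle-pose", *stream)
            pts = pts + rng.normal(0.0, self.noise_px, pts.shape)
        return KeypointSet(points=pts, visible=frame.visible.copy(), frame="full")


@dataclass
class ClassicalPoseEstimator:
    """The classical pose path: bicubic x4 upscale, LoG disk candidates,
    tail-disambiguated index assignment, bookkeeping back to full frame."""

    factor: int = 4
    seed: int = 0
    upscaler: object = "bicubic"
    inlier_tol: float = 2.0

    def estimate_from_crop(self, rec, spec: GridSpec, stream: tuple = ()) -> KeypointSet:
        up = upscale(rec.crop, self.factor, method=self.upscaler)
        cands = detect_keypoint_candidates(up)
        kps = assign_indices(
            cands, spec, seed=derive_seed(self.seed, "assign", *stream),
            inlier_tol=self.inlier_tol,
        )
        return to_full_frame(kps, rec, self.factor)


# --------------------------------------------------------------------------
# per-frame pipeline


@dataclass
class FrameFailure:
    stage: str
    reason: str


def process_stereo_frame(
    rig: StereoRig,
    frames: tuple[LabeledFrame, LabeledFrame],
    detector,
    pose,
    grid_spec: GridSpec,
    stream: tuple = (),
):
    """Run undistort/rectify -> detect -> accept -> crop -> pose ->
    triangulate on one stereo frame.  Returns a GridMeasurement or a
    FrameFailure naming the stage that rejected the frame."""
    frame_l, frame_r = frames
    (img_l, img_r), rect_rig, _rec = undistort_rectify(rig, (frame_l.image, frame_r.image))
    rect_pts = [
        rectify_points(rect_rig, f.keypoints, side)
        for f, side in ((frame_l, "left"), (frame_r, "right"))
    ]

    dets_l = detect_grid(img_l, detector, frame_l)
    dets_r = detect_grid(img_r, detector, frame_r)
    acc = accept_stereo(dets_l, dets_r)
    if not acc.accepted:
        return FrameFailure("acceptance", acc.reason)

    kps = []
    try:
        for side, img, det, frame, rpts in (
            ("left", img_l, dets_l[0], frame_l, rect_pts[0]),
            ("right", img_r, dets_r[0], frame_r, rect_pts[1]),
        ):
            if isinstance(pose, OraclePoseEstimator):
                kps.append(pose.estimate(frame, rpts, stream=(*stream, side)))
            else:
                rec = crop(img, det)
                kps.append(pose.estimate_from_crop(rec, grid_spec, stream=(*stream, side)))
        return triangulate_grid(rect_rig, kps[0], kps[1])
    except (AmbiguityError, InsufficientCorrespondencesError,
            DegenerateGeometryError, InvalidInputError) as exc:
        return FrameFailure("pose", f"{type(exc).__name__}: {exc}")


# --------------------------------------------------------------------------
# the experiment harness


@dataclass
class ExperimentSpec:
    """Scaled-down replication of the measurement-grid experiment."""

    layout: MeasurementLayout = field(default_factory=MeasurementLayout)
    grid_spec: GridSpec = field(default_factory=GridSpec)
    rig: StereoRig | None = None
    render: RenderSettings = field(default_factory=RenderSettings)
    detector: str = "classical"  # classical | oracle
    detector_jitter_px: float = 0.0
    pose: str = "classical"  # classical | oracle
    pose_noise_px: float = 0.0
    upscale_factor: int = 4
    n_frames: int = 30
    n_runs: int = 1
    outlier_threshold_m: float = 0.10


@dataclass
class ErrorReport:
    """Relative-pose statistics of one experiment."""

    positions: pd.DataFrame
    per_electrode_sums: np.ndarray
    heatmap: np.ndarray
    heatmap_degenerate: bool
    fp_by_depth: pd.DataFrame
    totals: dict

    def to_csv(self, positions_path, heatmap_path=None) -> None:
        self.positions.to_csv(positions_path, index=False)
        if heatmap_path is not None:
            pd.DataFrame(self.heatmap).to_csv(heatmap_path, index=False, header=False)

    def to_json(self, path) -> None:
        payload = {
            "totals": self.totals,
            "positions": self.positions.to_dict(orient="records"),
            "fp_by_depth": self.fp_by_depth.to_dict(orient="records"),
            "heatmap": self.heatmap.tolist(),
            "heatmap_degenerate": self.heatmap_degenerate,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def _truth_measurement(scene: MeasurementScene, valid_mask: np.ndarray) -> GridMeasurement:
    return GridMeasurement(
        points3d=scene.state.points3d.copy(),
        valid=valid_mask.copy(),
        position_id=scene.position_id,
    )


def _build_plugins(spec: ExperimentSpec, seed: int):
    if spec.detector == "oracle":
        detector = OracleDetector(jitter_px=spec.detector_jitter_px,
                                  seed=derive_seed(seed, "det"))
    elif spec.detector == "classical":
        detector = ClassicalDetector()
    else:
        raise InvalidInputError(f"unknown detector kind {spec.detector!r}")
    if spec.pose == "oracle":
        pose = OraclePoseEstimator(noise_px=spec.pose_noise_px,
                                   seed=derive_seed(seed, "pose"))
    elif spec.pose == "classical":
        pose = ClassicalPoseEstimator(factor=spec.upscale_factor,
                                      seed=derive_seed(seed, "pose"))
    else:
        raise InvalidInputError(f"unknown pose kind {spec.pose!r}")
    return detector, pose


def run_experiment(spec: ExperimentSpec | None = None, seed: int = 0) -> ErrorReport:
    """Render every scene, run the full pipeline per frame, filter
    outliers, and compute the relative-pose statistics against the
    simulator truth.  Fully reproducible from ``seed``; per-frame stage
    errors are tallied as rejections, never aborts."""
    from .camera import default_rig  # local import keeps dataclass defaults lazy

    spec = spec or ExperimentSpec()
    rig = spec.rig or default_rig()
    scenes = make_measurement_scenes(spec.layout, spec.grid_spec)
    ref_scene = next(s for s in scenes if s.is_reference)
    detector, pose = _build_plugins(spec, seed)

    # measurements[(run, position_id)] = dict(kept=[], outliers=n, failures=n, ...)
    stats: dict[tuple[int, str], dict] = {}
    for run in range(spec.n_runs):
        for scene in scenes:
            rec = {"considered": 0, "accepted": 0, "rejected_acceptance": 0,
                   "stage_failures": 0, "measurements": []}
            for f in range(spec.n_frames):
                frame_seed = derive_seed(seed, "frame", run, scene.position_id, f)
                settings = RenderSettings(
                    **{**spec.render.__dict__, "seed": frame_seed}
                )
                frames = render_stereo(rig, scene.state, settings)
                rec["considered"] += 1
                result = process_stereo_frame(
                    rig, frames, detector, pose, spec.grid_spec,
                    stream=(run, scene.position_id, f),
                )
                if isinstance(result, FrameFailure):
                    if result.stage == "acceptance":
                        rec["rejected_acceptance"] += 1
                    else:
                        rec["accepted"] += 1
                        rec["stage_failures"] += 1
                    continue
                rec["accepted"] += 1
                result.position_id = scene.position_id
                result.frame_index = f
                result.run_index = run
                rec["measurements"].append(result)
            if rec["measurements"]:
                kept, rejected = median_outlier_filter(
                    rec["measurements"], spec.outlier_threshold_m
                )
            else:
                kept, rejected = [], []
            rec["kept"] = kept
            rec["outliers"] = len(rejected)
            stats[(run, scene.position_id)] = rec

    # reference estimate per run: per-electrode mean over kept frames
    ref_by_run: dict[int, GridMeasurement | None] = {}
    for run in range(spec.n_runs):
        kept = stats[(run, ref_scene.position_id)]["kept"]
        if not kept:
            ref_by_run[run] = None
            continue
        n_pts = ref_scene.state.spec.n_points
        acc = np.zeros((n_pts, 3))
        cnt = np.zeros(n_pts)
        for m in kept:
            acc[m.valid] += m.points3d[m.valid]
            cnt[m.valid] += 1
        valid = cnt > 0
        pts = np.full((n_pts, 3), np.nan)
        pts[valid] = acc[valid] / cnt[valid, None]
        ref_by_run[run] = GridMeasurement(points3d=pts, valid=valid,
                                          position_id=ref_scene.position_id)

    n_elec = spec.grid_spec.n_electrodes
    elec_sums = np.zeros(n_elec)
    rows = []
    for scene in scenes:
        frame_means: list[float] = []
        per_elec = np.full(n_elec, np.nan)
        per_elec_acc = np.zeros(n_elec)
        per_elec_cnt = np.zeros(n_elec)
        considered = accepted = rej_acc = outliers = failures = kept_n = 0
        for run in range(spec.n_runs):
            rec = stats[(run, scene.position_id)]
            considered += rec["considered"]
            accepted += rec["accepted"]
            rej_acc += rec["rejected_acceptance"]
            outliers += rec["outliers"]
            failures += rec["stage_failures"]
            kept_n += len(rec["kept"])
            if scene.is_reference:
                # the protocol defines the reference's self-error as zero
                continue
            ref = ref_by_run[run]
            if ref is None:
                continue
            for m in rec["kept"]:
                ref_truth = _truth_measurement(ref_scene, ref.valid)
                pos_truth = _truth_measurement(scene, m.valid)
                errors, mask = relative_pose_error(ref, m, ref_truth, pos_truth,
                                                   n_electrodes=n_elec)
                if mask.any():
                    frame_means.append(float(np.nanmean(errors)))
                    per_elec_acc[mask] += errors[mask]
                    per_elec_cnt[mask] += 1
        has = per_elec_cnt > 0
        per_elec[has] = per_elec_acc[has] / per_elec_cnt[has]
        if not scene.is_reference and has.any():
            elec_sums[has] += per_elec[has]
        rows.append(
            {
                "position_id": scene.position_id,
                "depth_m": scene.depth,
                "lateral_m": scene.lateral,
                "is_reference": scene.is_reference,
                "mean_error_m": 0.0 if scene.is_reference
                else (float(np.mean(frame_means)) if frame_means else np.nan),
                "std_over_frames_m": 0.0 if scene.is_reference
                else (float(np.std(frame_means)) if frame_means else np.nan),
                "std_over_electrodes_m": 0.0 if scene.is_reference
                else (float(np.nanstd(per_elec)) if has.any() else np.nan),
                "n_considered": considered,
                "n_accepted": accepted,
                "n_rejected_acceptance": rej_acc,
                "n_kept": kept_n,
                "n_outliers": outliers,
                "n_stage_failures": failures,
            }
        )
    positions = pd.DataFrame(rows)

    fp_rows = []
    for depth, grp in positions.groupby("depth_m"):
        cons = int(grp["n_accepted"].sum())
        rej = int(grp["n_outliers"].sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rate = false_positive_rate(cons, rej)
        fp_rows.append({"depth_m": depth, "n_considered": cons, "n_outliers": rej,
                        "n_stage_failures": int(grp["n_stage_failures"].sum()),
                        "fp_rate": rate})
    fp_by_depth = pd.DataFrame(fp_rows)

    if spec.grid_spec.rows * spec.grid_spec.cols == n_elec:
        heatmap, degenerate = electrode_heatmap(
            elec_sums, spec.grid_spec.rows, spec.grid_spec.cols
        )
    else:  # pragma: no cover
        heatmap, degenerate = np.zeros((1, n_elec)), True

    nonref = positions[~positions["is_reference"]]
    totals = {
        "seed": seed,
        "n_positions": len(scenes),
        "n_runs": spec.n_runs,
        "frames_per_position": spec.n_frames,
        "frames_considered": int(positions["n_considered"].sum()),
        "frames_accepted": int(positions["n_accepted"].sum()),
        "frames_rejected_acceptance": int(positions["n_rejected_acceptance"].sum()),
        "frames_kept": int(positions["n_kept"].sum()),
        "outliers": int(positions["n_outliers"].sum()),
        "stage_failures": int(positions["n_stage_failures"].sum()),
        "mean_error_nonref_m": float(np.nanmean(nonref["mean_error_m"])),
    }
    return ErrorReport(
        positions=positions,
        per_electrode_sums=elec_sums,
        heatmap=heatmap,
        heatmap_degenerate=degenerate,
        fp_by_depth=fp_by_depth,
        totals=totals,
    )
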