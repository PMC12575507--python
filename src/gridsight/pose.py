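"""Crop upscaling, disk-center extraction, and electrode index assignment.

This is the 2D pose stage: a low-resolution grid crop is upscaled by a
fixed factor (default 4), disk centers are detected as bright blobs
(Laplacian-of-Gaussian extrema refined to subpixel by local intensity
centroid), cable endpoints are found as thin protrusions of the sheet
silhouette, and the unordered candidates are turned into the 68 ordered
keypoints by fitting a plane-to-image homography, resolving the square
grid's 4-fold rotational ambiguity with the cable ("tail") evidence, and
matching candidates to predicted electrode sites one-to-one at minimum
total distance.

A learned upscaler or pose network can be plugged in anywhere along this
path; the contracts are purely geometric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint
from skimage.feature import blob_log

from ._errors import (
    AmbiguityError,
    ContractError,
    InvalidInputError,
    InvalidParameterError,
)
from ._seeding import substream
from .detection import CropRecord
from .grid import GridSpec

__all__ = [
    "KeypointSet",
    "CandidateSet",
    "upscale",
    "detect_keypoint_candidates",
    "assign_indices",
    "to_full_frame",
    "match_one_to_one",
]


@dataclass(frozen=True)
class KeypointSet:
    """68 ordered subpixel keypoints (electrodes row-major, then tails)
    in the pixel frame named by ``frame``."""

    points: np.ndarray
    visible: np.ndarray
    frame: str  # crop | upscaled-crop | full

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        vis = np.asarray(self.visible, dtype=bool)
        if pts.ndim != 2 or pts.shape[1] != 2 or vis.shape != (pts.shape[0],):
            raise InvalidInputError("keypoints must be (n, 2) with (n,) visibility")
        if vis.any() and not np.all(np.isfinite(pts[vis])):
            raise InvalidInputError("visible keypoints must be finite")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "visible", vis)


@dataclass(frozen=True)
class CandidateSet:
    """Unordered detection candidates: (x, y, strength) rows."""

    disk_candidates: np.ndarray
    tail_candidates: np.ndarray

    def __post_init__(self):
        for name in ("disk_candidates", "tail_candidates"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 3)
            if len(arr) and np.any(arr[:, 2] <= 0):
                raise InvalidInputError("candidate strengths must be positive")
            object.__setattr__(self, name, arr)


# --------------------------------------------------------------------------
# upscaling


def upscale(crop: np.ndarray, factor: int, method: str | Callable = "bicubic") -> np.ndarray:
    """Upscale a crop so output size = factor * input size exactly.

    The default is deterministic bicubic resampling with the corner-anchored
    convention: output pixel ``i`` samples the input at ``i / factor``, so a
    feature at crop coordinate ``x`` lands at ``factor * x``.  ``method``
    may be any callable honoring the same size-and-coordinate contract
    (e.g. a learned super-resolution model)."""
    if int(factor) != factor or factor < 1:
        raise InvalidParameterError(f"upscale factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    img = np.asarray(crop, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("upscale expects a grayscale image")
    if callable(method):
        out = np.asarray(method(img, factor), dtype=float)
        if out.shape != (img.shape[0] * factor, img.shape[1] * factor):
            raise ContractError(
                f"external upscaler returned {out.shape}, expected "
                f"{(img.shape[0] * factor, img.shape[1] * factor)}"
            )
        return out
    if method != "bicubic":
        raise InvalidParameterError(f"unknown upscale method {method!r}")
    if factor == 1:
        return img.copy()
    rows = np.arange(img.shape[0] * factor, dtype=float) / factor
    cols = np.arange(img.shape[1] * factor, dtype=float) / factor
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(img, [rr, cc], order=3, mode="nearest")


# --------------------------------------------------------------------------
# candidate extraction


def _refine_centroid(img: np.ndarray, x: float, y: float, radius: float) -> tuple[float, float]:
    """Subpixel refinement: intensity-weighted centroid above the local
    floor inside a window, iterated twice."""
    h, w = img.shape
    for _ in range(2):
        r = int(np.ceil(radius))
        x0, x1 = max(0, int(round(x)) - r), min(w, int(round(x)) + r + 1)
        y0, y1 = max(0, int(round(y)) - r), min(h, int(round(y)) + r + 1)
        win = img[y0:y1, x0:x1]
        if win.size == 0:
            break
        wts = np.clip(win - win.min(), 0.0, None)
        total = wts.sum()
        if total <= 0:
            break
        ys, xs = np.mgrid[y0:y1, x0:x1]
        x, y = float((wts * xs).sum() / total), float((wts * ys).sum() / total)
    return x, y


def detect_keypoint_candidates(
    upscaled: np.ndarray,
    min_sigma: float = 2.0,
    max_sigma: float = 12.0,
    blob_threshold: float = 0.02,
) -> CandidateSet:
    """Extract disk-center and tail-endpoint candidates from an upscaled crop.

    Disks: bright Laplacian-of-Gaussian extrema, detected in two passes —
    a coarse scale sweep estimates the dominant disk scale from the
    strongest responses, then a narrow sweep around that scale finds every
    disk (a single wide sweep lets large-scale blobs swallow the corner
    disks via overlap pruning); centers are refined to subpixel by local
    intensity centroid.  Tails: thin protrusions of the thresholded sheet
    silhouette that survive as residuals of a morphological opening; each
    contributes its outermost point.  Deterministic.
    """
    img = np.asarray(upscaled, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("expected a grayscale image")
    if img.size == 0 or np.ptp(img) < 1e-9:
        return CandidateSet(np.empty((0, 3)), np.empty((0, 3)))

    coarse = blob_log(img, min_sigma=min_sigma, max_sigma=max_sigma, num_sigma=4,
                      threshold=blob_threshold)
    if len(coarse) == 0:
        return CandidateSet(np.empty((0, 3)), np.empty((0, 3)))
    strengths = np.array([
        img[int(np.clip(round(y), 0, img.shape[0] - 1)),
            int(np.clip(round(x), 0, img.shape[1] - 1))]
        for y, x, _s in coarse
    ])
    top = np.argsort(-strengths)[: max(4, len(coarse) // 2)]
    sigma_hat = float(np.median(coarse[top, 2]))
    blobs = blob_log(
        img,
        min_sigma=max(min_sigma * 0.75, 0.65 * sigma_hat),
        max_sigma=1.5 * sigma_hat,
        num_sigma=6,
        threshold=blob_threshold,
    )
    disks = []
    for by, bx, sigma in blobs:
        r = sigma * np.sqrt(2.0)
        x, y = _refine_centroid(img, bx, by, max(1.5, 1.2 * r))
        yi = int(np.clip(round(by), 0, img.shape[0] - 1))
        xi = int(np.clip(round(bx), 0, img.shape[1] - 1))
        disks.append((x, y, max(float(img[yi, xi]), 1e-6)))
    disk_arr = np.array(disks).reshape(-1, 3)

    tails = _tail_candidates(img, blobs, disk_arr)
    return CandidateSet(disk_arr, tails)


def _tail_candidates(img: np.ndarray, blobs: np.ndarray, disk_arr: np.ndarray) -> np.ndarray:
    if len(blobs) == 0:
        return np.empty((0, 3))
    # disk scale from the strongest blobs (weak spurious blobs skew the median)
    order = np.argsort(-disk_arr[:, 2])[: max(8, len(disk_arr) * 2 // 3)]
    r_disk = float(np.median(blobs[order, 2])) * np.sqrt(2.0)
    r_open = max(2, int(round(1.3 * r_disk)))
    # sheet mask: the crop is mostly sheet, so threshold between the border
    # background level and the sheet level (the crop median) rather than
    # Otsu (which would split disks from sheet); cables share the sheet
    # intensity, and blur at far range leaves them barely above background
    border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    bg = float(np.median(border))
    med = float(np.median(img))
    level = med if med > bg + 0.03 else float(np.percentile(img, 98))
    thr = bg + 0.35 * (level - bg)
    mask = img > thr
    # disk-structured opening via two distance transforms (much faster than
    # binary_opening with a large footprint)
    eroded = ndimage.distance_transform_edt(mask) > r_open
    if not eroded.any():
        return np.empty((0, 3))
    opened = ndimage.distance_transform_edt(~eroded) <= r_open
    if not opened.any():
        return np.empty((0, 3))
    residual = mask & ~ndimage.binary_dilation(opened, iterations=1)
    dist_from_body = ndimage.distance_transform_edt(~opened)
    labels, n = ndimage.label(residual)
    out = []
    h, w = img.shape
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < r_open:
            continue
        reach = dist_from_body[ys, xs]
        touches_border = bool(
            (ys.min() == 0) or (xs.min() == 0)
            or (ys.max() == h - 1) or (xs.max() == w - 1)
        )
        # cables clipped by the crop edge protrude less; relax their reach
        if reach.max() < (0.8 if touches_border else 1.5) * r_open:
            continue  # boundary sliver, not a protruding cable
        k = int(np.argmax(reach))
        out.append((float(xs[k]), float(ys[k]), float(len(ys))))
    return np.array(out).reshape(-1, 3)


# --------------------------------------------------------------------------
# homography fitting helpers


def _homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray | None:
    """Least-squares DLT homography src -> dst with Hartley normalization."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 4:
        return None

    def normalizer(pts):
        c = pts.mean(axis=0)
        s = np.sqrt(2.0) / max(np.linalg.norm(pts - c, axis=1).mean(), 1e-12)
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        return T

    Ts, Td = normalizer(src), normalizer(dst)
    sh = np.concatenate([src, np.ones((len(src), 1))], axis=1) @ Ts.T
    dh = np.concatenate([dst, np.ones((len(dst), 1))], axis=1) @ Td.T
    A = []
    for (x, y, _), (u, v, _) in zip(sh, dh):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.array(A)
    try:
        _, s, vt = np.linalg.svd(A)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    H = vt[-1].reshape(3, 3)
    if abs(H[2, 2]) < 1e-12 and np.abs(H).max() < 1e-12:
        return None
    H = np.linalg.inv(Td) @ H @ Ts
    if abs(H[2, 2]) < 1e-12:
        return None
    return H / H[2, 2]


def _apply_h(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    ph = np.concatenate([pts, np.ones((len(pts), 1))], axis=1) @ H.T
    with np.errstate(divide="ignore", invalid="ignore"):
        return ph[:, :2] / ph[:, 2:3]


def _plane_corners(spec: GridSpec) -> np.ndarray:
    w = (spec.cols - 1) * spec.pitch
    h = (spec.rows - 1) * spec.pitch
    return np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])


def _rotate_plane(pts: np.ndarray, spec: GridSpec, k: int) -> np.ndarray:
    """Rotate plane coordinates by k*90 degrees about the electrode-array
    center (a lattice symmetry for square grids)."""
    c = np.array([(spec.cols - 1) / 2.0, (spec.rows - 1) / 2.0]) * spec.pitch
    rel = pts - c
    for _ in range(k % 4):
        rel = np.stack([-rel[:, 1], rel[:, 0]], axis=-1)
    return rel + c


def match_one_to_one(
    predicted: np.ndarray, candidates: np.ndarray, gate: float | None = None
):
    """Minimum-total-distance one-to-one assignment of candidates to
    predicted sites (Hungarian algorithm; deterministic, ties resolved by
    electrode index order).  Returns (pairs, total_cost) where pairs is a
    list of (site_index, candidate_index); pairs beyond ``gate`` distance
    are dropped from the result but not from the optimization."""
    if len(predicted) == 0 or len(candidates) == 0:
        return [], 0.0
    cost = np.linalg.norm(predicted[:, None, :] - candidates[None, :, :], axis=-1)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    total = 0.0
    for r, c in zip(rows, cols):
        total += cost[r, c]
        if gate is None or cost[r, c] <= gate:
            pairs.append((int(r), int(c)))
    return pairs, float(total)


def _score_hypothesis(H, elec_plane, tree, tol):
    pred = _apply_h(H, elec_plane)
    if not np.all(np.isfinite(pred)):
        return -1, np.inf
    d, _ = tree.query(pred)
    inliers = int((d < tol).sum())
    return inliers, float(d[d < tol].mean()) if inliers else np.inf


def assign_indices(
    cands: CandidateSet,
    spec: GridSpec | None = None,
    seed: int = 0,
    inlier_tol: float = 2.0,
    n_random: int = 150,
    min_matched: int | None = None,
    frame: str = "upscaled-crop",
) -> KeypointSet:
    """Order unlabeled candidates into the 68 physical keypoints.

    Robust plane fit: 4-point homography hypotheses (deterministic seeds
    from the candidates' minimum rotated rectangle, then randomly sampled
    quadruples under a fixed budget and seed) scored by inlier count at
    ``inlier_tol`` px; the best is refined by least squares.  The square
    grid's rotational ambiguity is resolved by the hypothesis whose
    predicted tail edge lies nearest the observed tail candidates; without
    tail evidence the orientation is undecidable and an
    :class:`AmbiguityError` is raised.
    """
    spec = spec or GridSpec()
    disks = cands.disk_candidates[:, :2]
    if len(disks) < 4:
        raise InvalidInputError(f"need >= 4 disk candidates, got {len(disks)}")

    elec_plane = spec.plane_points()[: spec.n_electrodes]
    corners = _plane_corners(spec)
    tree = cKDTree(disks)

    # hypothesis seeds come from the strongest candidates: disks outshine
    # spurious sheet-edge/cable blobs, so the top-n_electrodes set hugs the
    # electrode array and its minimum rotated rectangle approximates the
    # array corners
    n_core = min(len(disks), spec.n_electrodes)
    core = disks[np.argsort(-cands.disk_candidates[:, 2])[:n_core]]

    def _pitch_px(H) -> float:
        c = elec_plane.mean(axis=0, keepdims=True)
        return float(
            np.linalg.norm(_apply_h(H, c + [spec.pitch, 0.0]) - _apply_h(H, c))
        )

    def _front_facing(H) -> bool:
        # the camera sees the sheet's front face, which fixes the
        # orientation of the plane->image mapping (grid +z toward the
        # camera, image y down => orientation-reversing); mirror-image
        # hypotheses would silently transpose the electrode numbering
        c = elec_plane.mean(axis=0)
        eps = spec.pitch * 1e-3
        p0 = _apply_h(H, c[None])[0]
        if not np.all(np.isfinite(p0)):
            return False
        jx = (_apply_h(H, (c + [eps, 0.0])[None])[0] - p0) / eps
        jy = (_apply_h(H, (c + [0.0, eps])[None])[0] - p0) / eps
        det = jx[0] * jy[1] - jx[1] * jy[0]
        return bool(np.isfinite(det) and det < 0)

    hypotheses: list[np.ndarray] = []
    rect = MultiPoint([tuple(p) for p in core]).minimum_rotated_rectangle
    if rect.geom_type == "Polygon":
        rc = np.array(rect.exterior.coords)[:4]
        for direction in (rc, rc[::-1]):
            for shift in range(4):
                H = _homography(corners, np.roll(direction, -shift, axis=0))
                if H is not None:
                    hypotheses.append(H)
    rng = substream(seed, "assign")
    for _ in range(n_random):
        idx = rng.choice(len(core), size=4, replace=False)
        H = _homography(corners, core[idx])
        if H is not None:
            hypotheses.append(H)

    best, best_key = None, (-1, np.inf)
    for H in hypotheses:
        if not _front_facing(H):
            continue
        tol = max(inlier_tol, 0.25 * _pitch_px(H))
        inl, mean_d = _score_hypothesis(H, elec_plane, tree, tol)
        if (inl, -mean_d) > (best_key[0], -best_key[1]):
            best, best_key = H, (inl, mean_d)
    if best is None or best_key[0] < 4:
        raise AmbiguityError("no homography hypothesis explains the disk candidates")

    # least-squares refinement on gated one-to-one correspondences
    H = best
    for _ in range(4):
        pred = _apply_h(H, elec_plane)
        gate = max(inlier_tol, 0.35 * _pitch_px(H))
        pairs, _ = match_one_to_one(pred, disks, gate=gate)
        if len(pairs) >= 4:
            ridx = [p[0] for p in pairs]
            cidx = [p[1] for p in pairs]
            H_new = _homography(elec_plane[ridx], disks[cidx])
            if H_new is not None:
                H = H_new

    # rotational disambiguation from the tails
    n_rot = 4 if spec.rows == spec.cols else 2
    if len(cands.tail_candidates) == 0:
        raise AmbiguityError(
            "no tail candidates: the grid's rotational symmetry cannot be resolved"
        )
    tails_obs = cands.tail_candidates[:, :2]
    scores = []
    for k in range(n_rot):
        k_eff = k if n_rot == 4 else 2 * k
        pred_tails = _apply_h(H, _rotate_plane(spec.tail_offsets, spec, k_eff))
        d = np.array([np.linalg.norm(pred_tails - t, axis=1).min() for t in tails_obs])
        scores.append(float(d.mean()))
    k_best = int(np.argmin(scores))
    k_eff = k_best if n_rot == 4 else 2 * k_best

    # final assignment under the chosen orientation
    plane_rot = _rotate_plane(spec.plane_points(), spec, k_eff)
    pred_all = _apply_h(H, plane_rot)
    pitch_px = float(np.linalg.norm(
        _apply_h(H, _rotate_plane(elec_plane[:1] + [spec.pitch, 0.0], spec, k_eff))
        - pred_all[:1]
    ))
    gate = max(2.0 * inlier_tol, 0.45 * pitch_px)
    pairs, _ = match_one_to_one(pred_all[: spec.n_electrodes], disks, gate=gate)

    # quality gate: a fit that explains only a fraction of the lattice is a
    # mis-registration (missing/merged blobs), not a measurement — refuse
    # rather than emit wrongly numbered electrodes
    floor = max(4, spec.n_electrodes // 2) if min_matched is None else min_matched
    if len(pairs) < floor:
        raise AmbiguityError(
            f"plane fit explains only {len(pairs)}/{spec.n_electrodes} "
            "electrodes; refusing an unreliable assignment"
        )

    points = pred_all.copy()
    visible = np.zeros(spec.n_points, dtype=bool)
    for site, cand in pairs:
        points[site] = disks[cand]
        visible[site] = True
    # tails: homography prediction, visible when corroborated by a candidate
    for j in range(spec.n_tails):
        i = spec.n_electrodes + j
        d = np.linalg.norm(tails_obs - pred_all[i], axis=1).min()
        visible[i] = bool(d <= max(2.0 * gate, 1.5 * pitch_px))
    return KeypointSet(points=points, visible=visible, frame=frame)


def to_full_frame(kps: KeypointSet, rec: CropRecord, factor: int) -> KeypointSet:
    """Map upscaled-crop keypoints back to full-frame coordinates:
    ``x_full = x_up / factor + offset_x``.  Invisible points are left
    untransformed."""
    if kps.frame != "upscaled-crop":
        raise ContractError(f"expected frame 'upscaled-crop', got {kps.frame!r}")
    if factor < 1:
        raise InvalidParameterError("factor must be >= 1")
    pts = kps.points.copy()
    off = np.array(rec.offset, dtype=float)
    pts[kps.visible] = pts[kps.visible] / factor + off
    return KeypointSet(points=pts, visible=kps.visible.copy(), frame="full")
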