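"""Calibrated pinhole stereo model: projection, distortion, rectification,
and disparity triangulation.

Conventions (used everywhere in the package):

* pixels are 0-based, ``(0, 0)`` is the **center** of the top-left pixel,
  +x right, +y down;
* the world frame is the left (rectified) camera frame, right-handed,
  +z forward;
* lengths are meters, image coordinates are pixels.

The distortion model is the dominant radial (k1, k2, k3) + tangential
(p1, p2) polynomial applied in normalized image coordinates; undistortion
inverts it by fixed-point iteration.  Rectification rotates both views onto
a common image plane whose x-axis is the baseline, so corresponding points
share a row and depth follows the closed form ``z = f * b / disparity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._errors import (
    DegenerateGeometryError,
    InvalidInputError,
    ShapeError,
)

__all__ = [
    "CameraIntrinsics",
    "DistortionCoeffs",
    "RigidPose",
    "RectifiedModel",
    "StereoRig",
    "default_rig",
    "project",
    "distort_pixels",
    "undistort_pixels",
    "rectify_rig",
    "rectify_points",
    "undistort_rectify",
    "triangulate",
]


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = 640
    height: int = 480

    def __post_init__(self):
        if not np.all(np.isfinite([self.fx, self.fy, self.cx, self.cy])):
            raise InvalidInputError("intrinsics must be finite")
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidInputError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise InvalidInputError("principal point must lie inside the sensor")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class DistortionCoeffs:
    """Radial (k1,k2,k3) + tangential (p1,p2) lens distortion; all-zero = ideal pinhole."""

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.as_array())):
            raise InvalidInputError("distortion coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2])

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.as_array() == 0.0))


@dataclass(frozen=True)
class RigidPose:
    """Rigid transform mapping local-frame points into the parent frame."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ShapeError("rotation must be 3x3")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise InvalidInputError("pose entries must be finite")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise InvalidInputError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise InvalidInputError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidPose":
        return RigidPose(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidPose":
        return RigidPose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidPose") -> "RigidPose":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class RectifiedModel:
    """Shared intrinsics + rotations of the rectified stereo pair.

    ``rot_left``/``rot_right`` map original-camera-frame rays into the
    rectified frame (whose x-axis is the baseline).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    baseline: float
    rot_left: np.ndarray
    rot_right: np.ndarray

    @property
    def intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics(self.fx, self.fy, self.cx, self.cy, self.width, self.height)


@dataclass(frozen=True)
class StereoRig:
    """Calibrated stereo pair; ``right_in_left`` is the right camera's pose
    expressed in the left camera frame (its translation is the baseline)."""

    left: CameraIntrinsics
    right: CameraIntrinsics
    dist_left: DistortionCoeffs = field(default_factory=DistortionCoeffs)
    dist_right: DistortionCoeffs = field(default_factory=DistortionCoeffs)
    right_in_left: RigidPose = None  # type: ignore[assignment]
    rectified: RectifiedModel | None = None

    def __post_init__(self):
        if self.right_in_left is None:
            object.__setattr__(
                self, "right_in_left", RigidPose(np.eye(3), np.array([0.098, 0.0, 0.0]))
            )
        if np.linalg.norm(self.right_in_left.translation) <= 0:
            raise InvalidInputError("stereo baseline must have positive length")

    @property
    def baseline(self) -> float:
        return float(np.linalg.norm(self.right_in_left.translation))

    @property
    def is_ideal_rectified(self) -> bool:
        """True when the raw rig is already an ideal rectified pair
        (zero distortion, parallel identical cameras, baseline along +x)."""
        t = self.right_in_left.translation
        return (
            self.dist_left.is_zero
            and self.dist_right.is_zero
            and np.abs(self.right_in_left.rotation - np.eye(3)).max() < 1e-12
            and abs(t[1]) < 1e-12
            and abs(t[2]) < 1e-12
            and t[0] > 0
            and self.left == self.right
        )


def default_rig(
    width: int = 640,
    height: int = 480,
    focal_px: float = 550.0,
    baseline_m: float = 0.098,
    dist_left: DistortionCoeffs | None = None,
    dist_right: DistortionCoeffs | None = None,
) -> StereoRig:
    """The default virtual head-mounted stereo rig.

    640x480 grayscale sensors, 9.8 cm baseline, fronto-parallel.  The 550 px
    focal length is chosen so a 32 cm-wide working area just fits the stereo
    overlap at 40 cm, which also places grid crops in the 22-60 px width band
    over 40-90 cm working distances.
    """
    intr = CameraIntrinsics(focal_px, focal_px, (width - 1) / 2.0, (height - 1) / 2.0,
                            width, height)
    return StereoRig(
        left=intr,
        right=intr,
        dist_left=dist_left or DistortionCoeffs(),
        dist_right=dist_right or DistortionCoeffs(),
        right_in_left=RigidPose(np.eye(3), np.array([baseline_m, 0.0, 0.0])),
    )


# --------------------------------------------------------------------------
# distortion in normalized coordinates


def _distort_normalized(pts: np.ndarray, dist: DistortionCoeffs) -> np.ndarray:
    x, y = pts[..., 0], pts[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (dist.k1 + r2 * (dist.k2 + r2 * dist.k3))
    xd = x * radial + 2.0 * dist.p1 * x * y + dist.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + dist.p1 * (r2 + 2.0 * y * y) + 2.0 * dist.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def _undistort_normalized(
    pts: np.ndarray, dist: DistortionCoeffs, max_iter: int = 20, tol: float = 1e-10
) -> np.ndarray:
    """Invert the distortion polynomial by fixed-point iteration."""
    if dist.is_zero:
        return np.array(pts, dtype=float, copy=True)
    und = np.array(pts, dtype=float, copy=True)
    for _ in range(max_iter):
        delta = _distort_normalized(und, dist) - und
        new = pts - delta
        if np.abs(new - und).max() < tol:
            und = new
            break
        und = new
    return und


def distort_pixels(
    intr: CameraIntrinsics, dist: DistortionCoeffs, pixels: np.ndarray
) -> np.ndarray:
    """Map ideal-pinhole pixels to distorted (observed) pixels."""
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    xn = (px[:, 0] - intr.cx) / intr.fx
    yn = (px[:, 1] - intr.cy) / intr.fy
    d = _distort_normalized(np.stack([xn, yn], axis=-1), dist)
    out = np.stack([d[:, 0] * intr.fx + intr.cx, d[:, 1] * intr.fy + intr.cy], axis=-1)
    return out[0] if np.asarray(pixels).ndim == 1 else out


def undistort_pixels(
    intr: CameraIntrinsics, dist: DistortionCoeffs, pixels: np.ndarray
) -> np.ndarray:
    """Map distorted (observed) pixels to ideal-pinhole pixels."""
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    xn = (px[:, 0] - intr.cx) / intr.fx
    yn = (px[:, 1] - intr.cy) / intr.fy
    u = _undistort_normalized(np.stack([xn, yn], axis=-1), dist)
    out = np.stack([u[:, 0] * intr.fx + intr.cx, u[:, 1] * intr.fy + intr.cy], axis=-1)
    return out[0] if np.asarray(pixels).ndim == 1 else out


# --------------------------------------------------------------------------
# projection


def project(
    intr: CameraIntrinsics,
    dist: DistortionCoeffs,
    cam_pose: RigidPose,
    points: np.ndarray,
):
    """Project world points through a distorted pinhole camera.

    ``cam_pose`` is the camera's pose in the world (camera-to-world).
    Returns ``(pixels, visible)`` where a point is visible iff it lies in
    front of the camera (z > 0) and its distorted pixel falls inside the
    image bounds ``[-0.5, size - 0.5)``.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ShapeError("points must be 3-vectors")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("points must be finite")

    cam_pts = cam_pose.inverse().apply(pts)
    z = cam_pts[:, 2]
    in_front = z > 0
    safe_z = np.where(in_front, z, 1.0)
    norm = np.stack([cam_pts[:, 0] / safe_z, cam_pts[:, 1] / safe_z], axis=-1)
    d = _distort_normalized(norm, dist)
    pix = np.stack([d[:, 0] * intr.fx + intr.cx, d[:, 1] * intr.fy + intr.cy], axis=-1)
    inside = (
        (pix[:, 0] >= -0.5)
        & (pix[:, 0] < intr.width - 0.5)
        & (pix[:, 1] >= -0.5)
        & (pix[:, 1] < intr.height - 0.5)
    )
    visible = in_front & inside
    pix = np.where(in_front[:, None], pix, np.nan)
    if single:
        return pix[0], bool(visible[0])
    return pix, visible


# --------------------------------------------------------------------------
# rectification


def rectify_rig(rig: StereoRig) -> StereoRig:
    """Compute the rectified model for a rig (Fusiello-style).

    The rectified frame shares the left camera center; its x-axis is the
    baseline, its y-axis is chosen perpendicular to the old left optical
    axis so the new image plane stays as close as possible to the old one.
    """
    t = rig.right_in_left.translation
    b = float(np.linalg.norm(t))
    r1 = t / b
    z_old = np.array([0.0, 0.0, 1.0])
    r2 = np.cross(z_old, r1)
    n2 = np.linalg.norm(r2)
    if n2 < 1e-12:
        raise DegenerateGeometryError("baseline parallel to the optical axis")
    r2 /= n2
    r3 = np.cross(r1, r2)
    rot_left = np.stack([r1, r2, r3])  # rows: rectified axes in left-cam coords
    rot_right = rot_left @ rig.right_in_left.rotation

    fx = (rig.left.fx + rig.left.fy + rig.right.fx + rig.right.fy) / 4.0
    cx = (rig.left.cx + rig.right.cx) / 2.0
    cy = (rig.left.cy + rig.right.cy) / 2.0
    model = RectifiedModel(
        fx=fx, fy=fx, cx=cx, cy=cy,
        width=rig.left.width, height=rig.left.height,
        baseline=b, rot_left=rot_left, rot_right=rot_right,
    )
    return replace(rig, rectified=model)


def rectify_points(rig: StereoRig, pixels: np.ndarray, side: str) -> np.ndarray:
    """Map observed (distorted, original) pixels into the rectified frame."""
    if rig.rectified is None:
        raise InvalidInputError("rig has no rectified model; call rectify_rig first")
    intr = rig.left if side == "left" else rig.right
    dist = rig.dist_left if side == "left" else rig.dist_right
    rot = rig.rectified.rot_left if side == "left" else rig.rectified.rot_right
    px = np.atleast_2d(np.asarray(pixels, dtype=float))
    xn = (px[:, 0] - intr.cx) / intr.fx
    yn = (px[:, 1] - intr.cy) / intr.fy
    und = _undistort_normalized(np.stack([xn, yn], axis=-1), dist)
    rays = np.concatenate([und, np.ones((len(und), 1))], axis=1) @ rot.T
    m = rig.rectified
    out = np.stack(
        [m.fx * rays[:, 0] / rays[:, 2] + m.cx, m.fy * rays[:, 1] / rays[:, 2] + m.cy],
        axis=-1,
    )
    return out[0] if np.asarray(pixels).ndim == 1 else out


def _rectify_maps(rig: StereoRig, side: str) -> np.ndarray:
    """Source sampling coordinates (2, H, W) in the original distorted image
    for every pixel of the rectified image."""
    m = rig.rectified
    intr = rig.left if side == "left" else rig.right
    dist = rig.dist_left if side == "left" else rig.dist_right
    rot = m.rot_left if side == "left" else m.rot_right
    u, v = np.meshgrid(np.arange(m.width, dtype=float), np.arange(m.height, dtype=float))
    xn = (u - m.cx) / m.fx
    yn = (v - m.cy) / m.fy
    rays = np.stack([xn, yn, np.ones_like(xn)], axis=-1) @ rot  # rot.T.T == rot
    und = np.stack([rays[..., 0] / rays[..., 2], rays[..., 1] / rays[..., 2]], axis=-1)
    d = _distort_normalized(und, dist)
    src_x = d[..., 0] * intr.fx + intr.cx
    src_y = d[..., 1] * intr.fy + intr.cy
    return np.stack([src_y, src_x])


@dataclass(frozen=True)
class RemapRecord:
    """Pixel remapping used for rectification, kept so labels can be mapped
    identically to the images (``None`` when the remap was the identity)."""

    map_left: np.ndarray | None
    map_right: np.ndarray | None


def undistort_rectify(rig: StereoRig, frame_pair):
    """Undistort + rectify a stereo image pair.

    Returns ``(rect_pair, rect_rig, remap_record)``.  When the rig is
    already an ideal rectified pair the images pass through untouched (no
    resampling loss).
    """
    img_l, img_r = frame_pair
    img_l = np.asarray(img_l)
    img_r = np.asarray(img_r)
    for img, intr in ((img_l, rig.left), (img_r, rig.right)):
        if img.shape != (intr.height, intr.width):
            raise ShapeError(
                f"image shape {img.shape} does not match rig size "
                f"({intr.height}, {intr.width})"
            )
    rect_rig = rig if rig.rectified is not None else rectify_rig(rig)
    if rig.is_ideal_rectified:
        return (img_l.copy(), img_r.copy()), rect_rig, RemapRecord(None, None)
    map_l = _rectify_maps(rect_rig, "left")
    map_r = _rectify_maps(rect_rig, "right")
    out_l = ndimage.map_coordinates(img_l.astype(float), map_l, order=1, mode="nearest")
    out_r = ndimage.map_coordinates(img_r.astype(float), map_r, order=1, mode="nearest")
    return (out_l, out_r), rect_rig, RemapRecord(map_l, map_r)


# --------------------------------------------------------------------------
# triangulation


def triangulate(rect_rig: StereoRig, pix_left, pix_right) -> np.ndarray:
    """Closed-form disparity triangulation in the left rectified frame.

    ``z = f * b / (x_left - x_right)``; the row coordinate is averaged over
    the two views.  Raises :class:`DegenerateGeometryError` when the
    disparity is not positive.
    """
    if rect_rig.rectified is None:
        raise InvalidInputError("triangulate requires a rectified rig")
    m = rect_rig.rectified
    pl = np.asarray(pix_left, dtype=float)
    pr = np.asarray(pix_right, dtype=float)
    if not (np.all(np.isfinite(pl)) and np.all(np.isfinite(pr))):
        raise InvalidInputError("pixel coordinates must be finite")
    disparity = pl[0] - pr[0]
    if disparity <= 0:
        raise DegenerateGeometryError(
            f"non-positive disparity {disparity:.6g}: point at or behind infinity"
        )
    z = m.fx * m.baseline / disparity
    x = (pl[0] - m.cx) * z / m.fx
    y = ((pl[1] + pr[1]) / 2.0 - m.cy) * z / m.fy
    return np.array([x, y, z])
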