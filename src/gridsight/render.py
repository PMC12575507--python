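"""Programmatic stereo renderer for electrode-grid scenes.

Produces the low-resolution grayscale appearance that matters to the
localization method — a pale silicone sheet, brighter metallic disks, and
four cables leaving one edge — without a 3D render engine: the projected
sheet silhouette, per-electrode disks and cable segments are rasterized
with 4x supersampled anti-aliasing, shaded by a single directional light
plus ambient, then Gaussian-blurred with additive Gaussian noise.

Keypoint labels are the exact projections of the grid's 3D points, never
read back from pixels, so rendered datasets carry perfect ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint

from ._errors import EmptySceneError, InvalidInputError, TooSmallError
from ._seeding import substream
from .camera import CameraIntrinsics, DistortionCoeffs, RigidPose, StereoRig, project
from .grid import GridState

__all__ = [
    "RenderSettings",
    "LabeledFrame",
    "render_stereo",
    "render_mono",
    "downscale_with_labels",
]

_SS = 4  # supersampling factor for anti-aliasing


@dataclass(frozen=True)
class RenderSettings:
    """Appearance randomization ranges; intensities are in [0, 1]."""

    background_mode: str = "flat"  # flat | gradient | textured-noise
    background_range: tuple[float, float] = (0.05, 0.25)
    light_azimuth_range: tuple[float, float] = (0.0, 6.283185307179586)
    light_elevation_range: tuple[float, float] = (0.7, 1.4)
    ambient: float = 0.7
    disk_intensity: float = 0.85
    disk_sigma: float = 0.04
    sheet_intensity: float = 0.50
    sheet_sigma: float = 0.04
    blur_sigma: float = 0.6
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.background_mode not in ("flat", "gradient", "textured-noise"):
            raise InvalidInputError(f"unknown background mode {self.background_mode!r}")
        lo, hi = self.background_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidInputError("background_range must be within [0, 1]")
        for name in ("disk_intensity", "sheet_intensity", "ambient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1]")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise InvalidInputError("blur_sigma and noise_sigma must be >= 0")


@dataclass
class LabeledFrame:
    """One grayscale view with its ground-truth labels.

    ``image``: float array in [0, 1]; ``bbox``: (x_min, y_min, w, h) in
    pixels, half-open; ``keypoints``: (n, 2) ordered electrode-row-major
    then tails, in this image's pixel frame; ``visible``: (n,) bools.
    """

    image: np.ndarray
    bbox: tuple[float, float, float, float]
    keypoints: np.ndarray
    visible: np.ndarray
    truth: dict[str, Any] = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass(frozen=True)
class _Appearance:
    light_dir: np.ndarray
    sheet_val: float
    disk_val: float


def _sample_appearance(settings: RenderSettings, rng: np.random.Generator) -> _Appearance:
    az = rng.uniform(*settings.light_azimuth_range)
    el = rng.uniform(*settings.light_elevation_range)
    # light direction pointing *from* the light toward the scene (world frame)
    light = -np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    sheet = np.clip(settings.sheet_intensity + settings.sheet_sigma * rng.standard_normal(),
                    0.0, 1.0)
    disk = np.clip(settings.disk_intensity + settings.disk_sigma * rng.standard_normal(),
                   0.0, 1.0)
    return _Appearance(light_dir=light, sheet_val=float(sheet), disk_val=float(disk))


def _background(settings: RenderSettings, shape, rng: np.random.Generator) -> np.ndarray:
    lo, hi = settings.background_range
    h, w = shape
    if settings.background_mode == "flat":
        return np.full(shape, rng.uniform(lo, hi))
    if settings.background_mode == "gradient":
        a, b = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0, 2 * np.pi)
        u, v = np.meshgrid(np.linspace(0, 1, w), np.linspace(0, 1, h))
        ramp = u * np.cos(theta) + v * np.sin(theta)
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-12)
        return a + (b - a) * ramp
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, 12.0)
    smooth = (smooth - smooth.min()) / max(np.ptp(smooth), 1e-12)
    return lo + (hi - lo) * smooth


def _sheet_normal(state: GridState, cam_center: np.ndarray) -> np.ndarray:
    pts = state.electrodes3d
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    n = vt[-1]
    if np.dot(n, cam_center - pts.mean(axis=0)) < 0:
        n = -n
    return n


def _cable_segments(state: GridState, cam_pose: RigidPose):
    """3D cable segments (start, end) and their keypoint fraction along
    the segment, one per tail.  Cables run from just inside the sheet edge
    through the tail keypoint and a little beyond."""
    spec = state.spec
    elec = state.electrodes3d
    segs = []
    for tail in state.tails3d:
        j = int(np.argmin(np.linalg.norm(elec - tail, axis=1)))
        v = tail - elec[j]
        segs.append((elec[j] + 0.45 * v, elec[j] + 2.3 * v))
    return segs


def _render_view(
    intr: CameraIntrinsics,
    dist: DistortionCoeffs,
    cam_pose: RigidPose,
    state: GridState,
    settings: RenderSettings,
    appearance: _Appearance,
    rng: np.random.Generator,
) -> LabeledFrame:
    spec = state.spec
    pix, vis = project(intr, dist, cam_pose, state.points3d)
    if not vis.any():
        raise EmptySceneError("grid entirely outside the camera frustum")

    cam_pts = cam_pose.inverse().apply(state.points3d)
    z = cam_pts[:, 2]
    in_front = z > 0
    r_px = np.where(in_front, (spec.disk_diameter / 2.0) * intr.fx / np.maximum(z, 1e-9), 0.0)

    # shading: Lambertian-ish factor from the sheet normal and the light
    normal = _sheet_normal(state, cam_pose.translation)
    lam = max(0.0, float(np.dot(normal, -appearance.light_dir)))
    shade = settings.ambient + (1.0 - settings.ambient) * lam
    sheet_val = appearance.sheet_val * shade
    disk_val = appearance.disk_val * shade

    elec_pix = pix[: spec.n_electrodes]
    elec_ok = in_front[: spec.n_electrodes]
    hull = MultiPoint([tuple(p) for p in elec_pix[elec_ok]]).convex_hull
    margin_px = 1.5 * float(np.median(r_px[: spec.n_electrodes][elec_ok]))
    sheet_poly = hull.buffer(max(margin_px, 1.0))

    segs3d = _cable_segments(state, cam_pose)
    segs2d = []
    for a3, b3 in segs3d:
        (pa, _va), (pb, _vb) = (
            project(intr, dist, cam_pose, a3),
            project(intr, dist, cam_pose, b3),
        )
        if np.all(np.isfinite(pa)) and np.all(np.isfinite(pb)):
            segs2d.append((pa, pb))
    cable_hw = 0.35 * margin_px / 1.5 if margin_px > 0 else 1.0

    # raster window: everything drawable, clipped to the image
    minx, miny, maxx, maxy = sheet_poly.bounds
    for pa, pb in segs2d:
        minx = min(minx, pa[0], pb[0]); maxx = max(maxx, pa[0], pb[0])
        miny = min(miny, pa[1], pb[1]); maxy = max(maxy, pa[1], pb[1])
    pad = 2.0 + 2.0 * settings.blur_sigma + cable_hw
    x0 = max(0, int(np.floor(minx - pad)))
    y0 = max(0, int(np.floor(miny - pad)))
    x1 = min(intr.width, int(np.ceil(maxx + pad)) + 1)
    y1 = min(intr.height, int(np.ceil(maxy + pad)) + 1)

    img = _background(settings, (intr.height, intr.width), rng)

    if x1 > x0 and y1 > y0:
        ww, wh = x1 - x0, y1 - y0
        xs = x0 - 0.5 + (np.arange(ww * _SS) + 0.5) / _SS
        ys = y0 - 0.5 + (np.arange(wh * _SS) + 0.5) / _SS
        X, Y = np.meshgrid(xs, ys)
        buf = img[y0:y1, x0:x1].repeat(_SS, axis=0).repeat(_SS, axis=1).astype(float)

        inside = shapely.contains_xy(sheet_poly, X.ravel(), Y.ravel()).reshape(X.shape)
        buf[inside] = sheet_val

        for pa, pb in segs2d:
            d = pb - pa
            L2 = float(d @ d)
            lo_x = max(0, int((min(pa[0], pb[0]) - cable_hw - x0 + 0.5) * _SS) - 2)
            hi_x = min(ww * _SS, int((max(pa[0], pb[0]) + cable_hw - x0 + 0.5) * _SS) + 3)
            lo_y = max(0, int((min(pa[1], pb[1]) - cable_hw - y0 + 0.5) * _SS) - 2)
            hi_y = min(wh * _SS, int((max(pa[1], pb[1]) + cable_hw - y0 + 0.5) * _SS) + 3)
            if hi_x <= lo_x or hi_y <= lo_y:
                continue
            Xs, Ys = X[lo_y:hi_y, lo_x:hi_x], Y[lo_y:hi_y, lo_x:hi_x]
            if L2 > 0:
                t = np.clip(((Xs - pa[0]) * d[0] + (Ys - pa[1]) * d[1]) / L2, 0.0, 1.0)
            else:
                t = np.zeros_like(Xs)
            dx = Xs - (pa[0] + t * d[0])
            dy = Ys - (pa[1] + t * d[1])
            mask = dx * dx + dy * dy <= cable_hw * cable_hw
            buf[lo_y:hi_y, lo_x:hi_x][mask] = sheet_val

        for i in range(spec.n_electrodes):
            if not elec_ok[i] or r_px[i] <= 0:
                continue
            cx_, cy_ = elec_pix[i]
            r = r_px[i]
            lo_x = max(0, int((cx_ - r - x0 + 0.5) * _SS) - 2)
            hi_x = min(ww * _SS, int((cx_ + r - x0 + 0.5) * _SS) + 3)
            lo_y = max(0, int((cy_ - r - y0 + 0.5) * _SS) - 2)
            hi_y = min(wh * _SS, int((cy_ + r - y0 + 0.5) * _SS) + 3)
            if hi_x <= lo_x or hi_y <= lo_y:
                continue
            Xs, Ys = X[lo_y:hi_y, lo_x:hi_x], Y[lo_y:hi_y, lo_x:hi_x]
            mask = (Xs - cx_) ** 2 + (Ys - cy_) ** 2 <= r * r
            buf[lo_y:hi_y, lo_x:hi_x][mask] = disk_val

        img[y0:y1, x0:x1] = buf.reshape(wh, _SS, ww, _SS).mean(axis=(1, 3))

    if settings.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, settings.blur_sigma)
    if settings.noise_sigma > 0:
        img = img + rng.normal(0.0, settings.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    # bbox from the visible keypoints, expanded by each point's drawn extent
    margins = np.where(
        np.arange(spec.n_points) < spec.n_electrodes, r_px, cable_hw
    )
    vp, vm = pix[vis], margins[vis]
    bx0 = max(float((vp[:, 0] - vm).min()), -0.5)
    by0 = max(float((vp[:, 1] - vm).min()), -0.5)
    bx1 = min(float((vp[:, 0] + vm).max()), intr.width - 0.5)
    by1 = min(float((vp[:, 1] + vm).max()), intr.height - 0.5)
    bbox = (bx0, by0, bx1 - bx0, by1 - by0)

    return LabeledFrame(
        image=img,
        bbox=bbox,
        keypoints=pix,
        visible=vis,
        truth={"state": state, "intrinsics": intr, "cam_pose": cam_pose},
    )


def render_stereo(
    rig: StereoRig, state: GridState, settings: RenderSettings
) -> tuple[LabeledFrame, LabeledFrame]:
    """Render both views of a rig; appearance (light, intensities) is shared
    across the pair, background texture and sensor noise are per-view.
    Deterministic given ``settings.seed``."""
    rng_shared = substream(settings.seed, "appearance")
    appearance = _sample_appearance(settings, rng_shared)
    frames = []
    errors = 0
    for side, intr, dist, pose in (
        ("left", rig.left, rig.dist_left, RigidPose.identity()),
        ("right", rig.right, rig.dist_right, rig.right_in_left),
    ):
        rng = substream(settings.seed, "view", side)
        try:
            frames.append(_render_view(intr, dist, pose, state, settings, appearance, rng))
        except EmptySceneError:
            frames.append(None)
            errors += 1
    if errors:
        raise EmptySceneError("grid outside the stereo frusta")
    return frames[0], frames[1]


def render_mono(
    intr: CameraIntrinsics,
    dist: DistortionCoeffs,
    cam_pose: RigidPose,
    state: GridState,
    settings: RenderSettings,
) -> LabeledFrame:
    """Render a single view (used for training-corpus base renders)."""
    rng_shared = substream(settings.seed, "appearance")
    appearance = _sample_appearance(settings, rng_shared)
    rng = substream(settings.seed, "view", "mono")
    return _render_view(intr, dist, cam_pose, state, settings, appearance, rng)


# --------------------------------------------------------------------------
# exact area-average downscaling with label bookkeeping


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix of pixel-interval overlaps."""
    w = np.zeros((n_out, n_in))
    step = n_in / n_out
    for i in range(n_out):
        a, b = i * step, (i + 1) * step
        j0, j1 = int(np.floor(a)), min(int(np.ceil(b)), n_in)
        for j in range(j0, j1):
            w[i, j] = max(0.0, min(b, j + 1) - max(a, j))
    return w / step


def downscale_with_labels(frame: LabeledFrame, scale: float) -> LabeledFrame:
    """Downscale an image by area averaging and its labels by the realized
    per-axis size ratio (floor rounding: 80 px at scale 0.33 -> 26 px, and
    labels scale by 26/80)."""
    if not 0.0 < scale <= 1.0:
        raise InvalidInputError(f"scale must be in (0, 1], got {scale}")
    h, w = frame.image.shape
    if scale == 1.0:
        return replace(frame)
    out_w = int(np.floor(scale * w))
    out_h = int(np.floor(scale * h))
    if out_w < 8 or out_h < 8:
        raise TooSmallError(f"downscaled size {out_w}x{out_h} below the 8 px minimum")
    rx, ry = out_w / w, out_h / h
    img = _area_weights(h, out_h) @ frame.image @ _area_weights(w, out_w).T
    kps = frame.keypoints * np.array([rx, ry])
    x, y, bw, bh = frame.bbox
    return LabeledFrame(
        image=img,
        bbox=(x * rx, y * ry, bw * rx, bh * ry),
        keypoints=kps,
        visible=frame.visible.copy(),
        truth={**frame.truth, "scale": frame.truth.get("scale", 1.0) * scale},
    )
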