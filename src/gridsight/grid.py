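"""Geometry of the 64-electrode ECoG grid with four cable tails.

The grid is an ``rows x cols`` array of conductive disks embedded in a
flexible silicone sheet (defaults: 8x8, 5 mm pitch, 4 mm disks).  Four
cables ("tails") leave one edge of the sheet; their keypoints break the
square grid's 4-fold rotational symmetry, which is what makes electrode
numbering recoverable from images.

Electrode indexing convention: row-major, electrode 1 at the grid-frame
origin (the corner diagonally opposite the tail edge), electrode ``(r, c)``
(0-based) at ``(c * pitch, r * pitch, 0)``; the tails attach beyond the
last row (adjacent to electrodes 57-64 in the default spec).

The deformation model is a cylindrical bend (an exact isometry) plus a
low-order random smooth height field whose in-plane stretch is removed by
an iterative rescaling, so the sheet bends but does not stretch: every
nearest-neighbor electrode distance stays within ±2% of the pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import InvalidInputError, InvalidParameterError
from ._seeding import substream
from .camera import RigidPose

__all__ = [
    "GridSpec",
    "GridState",
    "DeformationParams",
    "canonical_grid",
    "deform",
    "nearest_neighbor_distances",
]

ISOMETRY_TOL = 0.02  # admissible relative stretch of nearest-neighbor edges


@dataclass(frozen=True)
class GridSpec:
    """Physical layout of the electrode grid (meters)."""

    rows: int = 8
    cols: int = 8
    pitch: float = 0.005
    disk_diameter: float = 0.004
    n_tails: int = 4
    tail_offsets: np.ndarray | None = None

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise InvalidInputError("grid must have at least one row and column")
        if self.pitch <= self.disk_diameter / 2:
            raise InvalidInputError("pitch must exceed the disk radius")
        if self.n_tails < 0:
            raise InvalidInputError("n_tails must be non-negative")
        if self.tail_offsets is None:
            object.__setattr__(self, "tail_offsets", self._default_tail_offsets())
        else:
            off = np.asarray(self.tail_offsets, dtype=float)
            if off.shape != (self.n_tails, 2):
                raise InvalidInputError("tail_offsets must be (n_tails, 2)")
            object.__setattr__(self, "tail_offsets", off)

    def _default_tail_offsets(self) -> np.ndarray:
        """Tails one pitch apart, centered along the last-row edge, one
        disk diameter beyond it."""
        y = (self.rows - 1) * self.pitch + self.disk_diameter
        x0 = ((self.cols - 1) - (self.n_tails - 1)) / 2.0 * self.pitch
        return np.array([[x0 + i * self.pitch, y] for i in range(self.n_tails)])

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    @property
    def n_points(self) -> int:
        return self.n_electrodes + self.n_tails

    def plane_points(self) -> np.ndarray:
        """All keypoints in the flat grid frame, (n_points, 2): electrodes
        row-major then tails."""
        r, c = np.divmod(np.arange(self.n_electrodes), self.cols)
        elec = np.stack([c * self.pitch, r * self.pitch], axis=-1)
        return np.concatenate([elec, self.tail_offsets], axis=0)


@dataclass(frozen=True)
class DeformationParams:
    """Bend + random smooth height field.

    curvature: signed 1/m of the cylindrical bend (0 = flat);
    bend_axis_angle: in-plane angle (rad) of the bend axis;
    random_amplitude: peak height (m) of the random degree-<=3 field.
    """

    curvature: float = 0.0
    bend_axis_angle: float = 0.0
    random_amplitude: float = 0.0
    max_curvature: float = 25.0  # 1/m; radius >= 40 mm

    def __post_init__(self):
        vals = [self.curvature, self.bend_axis_angle, self.random_amplitude]
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError("deformation parameters must be finite")
        if abs(self.curvature) > self.max_curvature:
            raise InvalidParameterError(
                f"curvature {self.curvature} exceeds bound {self.max_curvature} 1/m"
            )
        if self.random_amplitude < 0:
            raise InvalidParameterError("random_amplitude must be >= 0")


@dataclass(frozen=True)
class GridState:
    """A (possibly deformed) grid placed in the world.

    ``points3d`` is (n_points, 3) in world meters, ordered electrodes
    row-major then tails.
    """

    spec: GridSpec
    points3d: np.ndarray
    pose: RigidPose = field(default_factory=RigidPose.identity)
    deform_params: DeformationParams | None = None

    def __post_init__(self):
        pts = np.asarray(self.points3d, dtype=float)
        if pts.shape != (self.spec.n_points, 3):
            raise InvalidInputError(
                f"points3d must be ({self.spec.n_points}, 3), got {pts.shape}"
            )
        object.__setattr__(self, "points3d", pts)

    @property
    def electrodes3d(self) -> np.ndarray:
        return self.points3d[: self.spec.n_electrodes]

    @property
    def tails3d(self) -> np.ndarray:
        return self.points3d[self.spec.n_electrodes:]

    def to_csv(self, path_or_buf) -> None:
        spec = self.spec
        labels = ["electrode"] * spec.n_electrodes + ["tail"] * spec.n_tails
        df = pd.DataFrame(
            {
                "index": np.arange(1, spec.n_points + 1),
                "x": self.points3d[:, 0],
                "y": self.points3d[:, 1],
                "z": self.points3d[:, 2],
                "label": labels,
            }
        )
        df.to_csv(path_or_buf, index=False)

    @staticmethod
    def points_from_csv(path_or_buf) -> np.ndarray:
        df = pd.read_csv(path_or_buf)
        return df[["x", "y", "z"]].to_numpy()


def canonical_grid(spec: GridSpec, pose: RigidPose | None = None) -> GridState:
    """The flat grid in the given pose (grid frame -> world)."""
    pose = pose or RigidPose.identity()
    plane = spec.plane_points()
    pts = np.concatenate([plane, np.zeros((len(plane), 1))], axis=1)
    return GridState(spec=spec, points3d=pose.apply(pts), pose=pose)


def nearest_neighbor_distances(state: GridState) -> np.ndarray:
    """Lengths of the horizontal+vertical electrode lattice edges
    (112 edges for the default 8x8 spec)."""
    spec = state.spec
    pts = state.electrodes3d.reshape(spec.rows, spec.cols, 3)
    horiz = np.linalg.norm(np.diff(pts, axis=1), axis=-1).ravel()
    vert = np.linalg.norm(np.diff(pts, axis=0), axis=-1).ravel()
    return np.concatenate([horiz, vert])


def _random_height_field(spec: GridSpec, amplitude: float, rng: np.random.Generator):
    """A random 2D polynomial of degree <= 3 scaled to the requested peak
    height over the electrode footprint; returns h(x, y)."""
    coeffs = rng.standard_normal((4, 4))
    for i in range(4):
        for j in range(4):
            if i + j > 3 or (i == 0 and j == 0):
                coeffs[i, j] = 0.0

    w = (spec.cols - 1) * spec.pitch
    h = (spec.rows - 1) * spec.pitch

    def raw(x, y):
        u = np.where(w > 0, x / max(w, 1e-12), 0.0) - 0.5
        v = np.where(h > 0, y / max(h, 1e-12), 0.0) - 0.5
        out = np.zeros_like(u, dtype=float)
        for i in range(4):
            for j in range(4):
                if coeffs[i, j]:
                    out = out + coeffs[i, j] * u**i * v**j
        return out

    # normalize peak over a sampling of the footprint
    gx, gy = np.meshgrid(np.linspace(0, w, 9), np.linspace(0, h, 9))
    peak = np.abs(raw(gx, gy)).max()
    scale = amplitude / peak if peak > 1e-12 else 0.0
    return lambda x, y: raw(x, y) * scale


def deform(state: GridState, params: DeformationParams, seed: int = 0) -> GridState:
    """Apply a near-isometric deformation to a grid state.

    The deformation acts in the grid frame of the state's pose: the flat
    plane coordinates are bent onto a cylinder (exact isometry) and lifted
    by a random smooth height field whose first-order in-plane stretch is
    removed; the result is validated against the ±2% nearest-neighbor
    isometry bound and re-posed into the world.
    """
    spec = state.spec
    if params.curvature == 0.0 and params.random_amplitude == 0.0:
        return state

    plane = spec.plane_points()
    center = plane[: spec.n_electrodes].mean(axis=0)
    rel = plane - center

    # coordinates along/across the bend axis
    ca, sa = np.cos(params.bend_axis_angle), np.sin(params.bend_axis_angle)
    axis = np.array([ca, sa])
    perp = np.array([-sa, ca])
    a = rel @ axis
    s = rel @ perp  # arc length across the bend

    if params.curvature != 0.0:
        radius = 1.0 / params.curvature
        across = radius * np.sin(s / radius)
        z = radius * (1.0 - np.cos(s / radius))
    else:
        across, z = s, np.zeros_like(s)

    xy = np.outer(a, axis) + np.outer(across, perp) + center

    if params.random_amplitude > 0.0:
        rng = substream(seed, "deform")
        field_fn = _random_height_field(spec, params.random_amplitude, rng)
        dz = field_fn(plane[:, 0], plane[:, 1])
        z = z + dz
        # remove first-order in-plane stretch introduced by the lift
        pts = np.concatenate([xy, z[:, None]], axis=1)
        for _ in range(3):
            elec = pts[: spec.n_electrodes].reshape(spec.rows, spec.cols, 3)
            stretch_h = np.linalg.norm(np.diff(elec, axis=1), axis=-1).mean() / spec.pitch
            stretch_v = np.linalg.norm(np.diff(elec, axis=0), axis=-1).mean() / spec.pitch
            c3 = pts[: spec.n_electrodes].mean(axis=0)
            pts[:, :2] = (pts[:, :2] - c3[:2]) / ((stretch_h + stretch_v) / 2.0) + c3[:2]
        xy, z = pts[:, :2], pts[:, 2]

    grid_pts = np.concatenate([xy, z[:, None]], axis=1)
    out = replace(
        state,
        points3d=state.pose.apply(grid_pts),
        deform_params=params,
    )
    edges = nearest_neighbor_distances(out)
    rel_err = np.abs(edges / spec.pitch - 1.0).max() if len(edges) else 0.0
    if rel_err > ISOMETRY_TOL:
        raise InvalidParameterError(
            f"deformation stretches the sheet by {rel_err:.1%} (> ±{ISOMETRY_TOL:.0%}); "
            "reduce curvature or random_amplitude"
        )
    return out
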