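"""Grid detection and cropping with the stereo acceptance rule.

The detector is pluggable: the paper-style trained network can be wired in
through the same list-of-scored-boxes contract; this module ships an
oracle detector (returns the ground-truth label box, optionally jittered)
and a classical detector (sheet/background contrast threshold + connected
components filtered by area and aspect ratio).

A stereo frame is accepted only when exactly one box was detected in each
view; rejections carry the side and cause.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._errors import InvalidBBoxError, InvalidInputError
from ._seeding import substream
from .render import LabeledFrame

__all__ = [
    "Detection",
    "CropRecord",
    "StereoAcceptance",
    "Detector",
    "OracleDetector",
    "ClassicalDetector",
    "detect_grid",
    "accept_stereo",
    "crop",
    "default_margin",
]


@dataclass(frozen=True)
class Detection:
    """A scored bounding box (x_min, y_min, w, h) in pixels."""

    bbox: tuple[float, float, float, float]
    score: float

    def __post_init__(self):
        x, y, w, h = self.bbox
        if not np.all(np.isfinite([x, y, w, h, self.score])):
            raise InvalidInputError("detection fields must be finite")
        if w <= 0 or h <= 0:
            raise InvalidInputError("bbox must have positive extent")
        if not 0.0 <= self.score <= 1.0:
            raise InvalidInputError("score must be in [0, 1]")

    @property
    def area(self) -> float:
        return self.bbox[2] * self.bbox[3]


@dataclass(frozen=True)
class CropRecord:
    """A crop plus the exact integer bookkeeping back to the full frame."""

    crop: np.ndarray
    offset: tuple[int, int]  # (x, y) of crop pixel (0, 0) in the full frame
    margin: int

    def to_full(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + np.array(self.offset, dtype=float)

    def to_crop(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) - np.array(self.offset, dtype=float)


@dataclass(frozen=True)
class StereoAcceptance:
    accepted: bool
    reason: str | None = None


class Detector(Protocol):
    def detect(self, image: np.ndarray, frame: LabeledFrame | None = None) -> list[Detection]:
        ...


def _sorted(dets: list[Detection]) -> list[Detection]:
    # stable: by descending score, ties broken by descending area
    return sorted(dets, key=lambda d: (-d.score, -d.area))


@dataclass
class OracleDetector:
    """Returns the ground-truth label bbox, optionally jittered by a
    configured pixel sigma (deterministic per image via the seed)."""

    jitter_px: float = 0.0
    seed: int = 0
    _calls: int = 0

    def detect(self, image: np.ndarray, frame: LabeledFrame | None = None) -> list[Detection]:
        if frame is None:
            raise InvalidInputError("oracle detector requires the labeled frame")
        x, y, w, h = frame.bbox
        if self.jitter_px > 0:
            rng = substream(self.seed, "oracle-detect", self._calls)
            dx, dy = rng.normal(0.0, self.jitter_px, size=2)
            x, y = x + dx, y + dy
        self._calls += 1
        return [Detection(bbox=(x, y, w, h), score=1.0)]


@dataclass
class ClassicalDetector:
    """Contrast-threshold + connected-component detector.

    The sheet is brighter than the (dim) background, so a global threshold
    (Otsu by default) separates it; components are filtered by area and
    aspect ratio and scored by their interior/exterior contrast.
    """

    threshold: float | None = None  # None -> Otsu
    min_area: int = 60
    max_area: int = 40000
    max_aspect: float = 3.0
    closing_radius: int = 2  # bridges sub-threshold gaps inside the sheet
    nms: bool = False
    nms_iou: float = 0.5

    def detect(self, image: np.ndarray, frame: LabeledFrame | None = None) -> list[Detection]:
        img = np.asarray(image, dtype=float)
        if img.ndim != 2:
            raise InvalidInputError("detector expects a grayscale image")
        thr = self.threshold
        if thr is None:
            if np.ptp(img) < 1e-6:
                return []
            thr = float(threshold_otsu(img))
        mask = img > thr
        if not mask.any():
            return []
        if self.closing_radius > 0:
            # when the sheet intensity grazes the threshold the mask breaks
            # into stripes between disk columns; closing restores one body
            r = self.closing_radius
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            mask = ndimage.binary_closing(mask, structure=yy * yy + xx * xx <= r * r)
        labels, n = ndimage.label(mask)
        dets: list[Detection] = []
        mean_out = float(img[~mask].mean()) if (~mask).any() else 0.0
        for sl in ndimage.find_objects(labels):
            if sl is None:
                continue
            h = sl[0].stop - sl[0].start
            w = sl[1].stop - sl[1].start
            region = labels[sl] > 0
            area = int(region.sum())
            if not (self.min_area <= area <= self.max_area):
                continue
            aspect = max(w / h, h / w)
            if aspect > self.max_aspect:
                continue
            mean_in = float(img[sl][region].mean())
            score = float(np.clip((mean_in - mean_out) / 0.5, 0.0, 1.0))
            dets.append(
                Detection(bbox=(sl[1].start - 0.5, sl[0].start - 0.5, float(w), float(h)),
                          score=score)
            )
        dets = _sorted(dets)
        if self.nms:
            dets = _non_max_suppression(dets, self.nms_iou)
        return dets


def _iou(a: Detection, b: Detection) -> float:
    ax, ay, aw, ah = a.bbox
    bx, by, bw, bh = b.bbox
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _non_max_suppression(dets: list[Detection], iou_thr: float) -> list[Detection]:
    kept: list[Detection] = []
    for d in dets:
        if all(_iou(d, k) < iou_thr for k in kept):
            kept.append(d)
    return kept


def detect_grid(
    image: np.ndarray, detector: Detector, frame: LabeledFrame | None = None
) -> list[Detection]:
    """Run a pluggable detector; detections come back sorted by score
    (ties by area).  An empty list is a valid outcome."""
    return _sorted(detector.detect(image, frame))


def accept_stereo(dets_left: list[Detection], dets_right: list[Detection]) -> StereoAcceptance:
    """The stereo acceptance rule: exactly one detection per view.

    The first failure is reported, checking none-left, none-right,
    multiple-left, multiple-right in that order."""
    if len(dets_left) == 0:
        return StereoAcceptance(False, "none-left")
    if len(dets_right) == 0:
        return StereoAcceptance(False, "none-right")
    if len(dets_left) > 1:
        return StereoAcceptance(False, "multiple-left")
    if len(dets_right) > 1:
        return StereoAcceptance(False, "multiple-right")
    return StereoAcceptance(True, None)


def default_margin(det: Detection) -> int:
    """Default crop padding: 10% of the larger bbox side, at least 2 px."""
    return max(2, int(round(0.1 * max(det.bbox[2], det.bbox[3]))))


def crop(image: np.ndarray, det: Detection, margin: int | None = None) -> CropRecord:
    """Crop the padded bbox out of the image with exact integer bookkeeping.

    The crop covers whole pixels: it starts at ``floor(x_min) - margin``
    (clamped to the image) and ends at ``ceil(x_min + w) + margin``."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    x, y, bw, bh = det.bbox
    if x + bw <= -0.5 or y + bh <= -0.5 or x >= w - 0.5 or y >= h - 0.5:
        raise InvalidBBoxError(f"bbox {det.bbox} lies outside the {w}x{h} image")
    m = default_margin(det) if margin is None else int(margin)
    x0 = max(0, int(np.floor(x)) - m)
    y0 = max(0, int(np.floor(y)) - m)
    x1 = min(w, int(np.ceil(x + bw)) + m)
    y1 = min(h, int(np.ceil(y + bh)) + m)
    return CropRecord(crop=img[y0:y1, x0:x1].copy(), offset=(x0, y0), margin=m)
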