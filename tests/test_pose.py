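"""Upscaling, candidate extraction, and electrode index assignment."""

import itertools

import numpy as np
import pytest

from gridsight._errors import (
    AmbiguityError,
    ContractError,
    InvalidInputError,
    InvalidParameterError,
)
from gridsight.detection import ClassicalDetector, CropRecord, crop, detect_grid
from gridsight.grid import GridSpec
from gridsight.pose import (
    CandidateSet,
    KeypointSet,
    assign_indices,
    detect_keypoint_candidates,
    match_one_to_one,
    to_full_frame,
    upscale,
)
from gridsight.render import RenderSettings, render_stereo


class TestUpscale:
    def test_26px_times_4_gives_104(self):
        out = upscale(np.random.default_rng(0).random((26, 26)), 4)
        assert out.shape == (104, 104)

    def test_factor_one_identity(self):
        img = np.random.default_rng(1).random((20, 30))
        np.testing.assert_array_equal(upscale(img, 1), img)

    def test_constant_image_stays_constant(self):
        out = upscale(np.full((15, 15), 0.37), 4)
        assert out.shape == (60, 60)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_invalid_factor_rejected(self):
        with pytest.raises(InvalidParameterError):
            upscale(np.zeros((10, 10)), 0)

    def test_coordinate_convention_corner_anchored(self):
        """A feature at crop coordinate x lands at factor*x: a delta spike
        at (5, 7) peaks at (20, 28) after x4."""
        img = np.zeros((16, 16))
        img[5, 7] = 1.0
        out = upscale(img, 4)
        assert np.unravel_index(np.argmax(out), out.shape) == (20, 28)

    def test_external_upscaler_contract_enforced(self):
        with pytest.raises(ContractError):
            upscale(np.zeros((10, 10)), 4, method=lambda im, f: np.zeros((5, 5)))

    def test_external_upscaler_used(self):
        out = upscale(np.zeros((10, 10)), 2, method=lambda im, f: np.ones((20, 20)))
        np.testing.assert_array_equal(out, 1.0)


@pytest.fixture(scope="module")
def upscaled_crop40(rig, scene40, clean_settings):
    """Noiseless 40 cm crop upscaled x4, with the ground truth mapped into
    the upscaled-crop frame."""
    left, _ = render_stereo(rig, scene40.state, clean_settings)
    rec = crop(left.image, detect_grid(left.image, ClassicalDetector())[0])
    up = upscale(rec.crop, 4)
    truth_up = (left.keypoints - np.array(rec.offset)) * 4
    return up, truth_up, rec


class TestCandidates:
    def test_disks_found_near_truth(self, upscaled_crop40):
        up, truth_up, _rec = upscaled_crop40
        cands = detect_keypoint_candidates(up)
        assert len(cands.disk_candidates) >= 60
        from scipy.spatial import cKDTree

        d, _ = cKDTree(cands.disk_candidates[:, :2]).query(truth_up[:64])
        assert (d < 1.0).mean() >= 0.95

    def test_tails_found(self, upscaled_crop40):
        up, _truth, _rec = upscaled_crop40
        cands = detect_keypoint_candidates(up)
        assert len(cands.tail_candidates) >= 1

    def test_blank_image_empty(self):
        cands = detect_keypoint_candidates(np.full((64, 64), 0.3))
        assert len(cands.disk_candidates) == 0
        assert len(cands.tail_candidates) == 0

    def test_deterministic(self, upscaled_crop40):
        up, _t, _r = upscaled_crop40
        a = detect_keypoint_candidates(up)
        b = detect_keypoint_candidates(up)
        np.testing.assert_array_equal(a.disk_candidates, b.disk_candidates)
        np.testing.assert_array_equal(a.tail_candidates, b.tail_candidates)

    def test_negative_strength_rejected(self):
        with pytest.raises(InvalidInputError):
            CandidateSet(np.array([[1.0, 1.0, -0.5]]), np.empty((0, 3)))


def _synthetic_candidates(spec, rng, jitter=0.0):
    """Exact (or jittered) plane-projected candidates with the front-face
    orientation (y axis flipped, as seen by a camera)."""
    theta = rng.uniform(0, 2 * np.pi)
    s = rng.uniform(18.0, 30.0) / spec.pitch
    R = s * np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]]) @ np.diag([1.0, -1.0])
    t = rng.uniform(120, 180, 2)
    pts = spec.plane_points() @ R.T + t
    pts = pts + rng.normal(0, jitter, pts.shape)
    disks = np.concatenate([pts[:64], np.full((64, 1), 0.8)], axis=1)
    tails = np.concatenate([pts[64:], np.full((4, 1), 5.0)], axis=1)
    return CandidateSet(disks, tails), pts


def _rot90(points, center):
    rel = points - center
    return np.stack([-rel[:, 1], rel[:, 0]], axis=-1) + center


class TestAssignIndices:
    def test_exact_candidates_recover_truth(self, grid_spec):
        rng = np.random.default_rng(8)
        cands, pts = _synthetic_candidates(grid_spec, rng)
        kps = assign_indices(cands, grid_spec, seed=1)
        assert kps.visible.all()
        np.testing.assert_allclose(kps.points, pts, atol=1e-6)

    def test_rotation_equivariance_100_sets(self, grid_spec):
        """Rotating the whole candidate set by 90 deg in the image plane
        (tails moving consistently) leaves the physical index assignment
        unchanged — the defining property of tail disambiguation."""
        rng = np.random.default_rng(17)
        failures = 0
        for trial in range(100):
            cands, _pts = _synthetic_candidates(grid_spec, rng, jitter=0.3)
            base = assign_indices(cands, grid_spec, seed=trial)
            center = np.array([200.0, 200.0])
            for k in (1, 2, 3):
                disks = cands.disk_candidates.copy()
                tails = cands.tail_candidates.copy()
                d, t = disks[:, :2], tails[:, :2]
                for _ in range(k):
                    d, t = _rot90(d, center), _rot90(t, center)
                rot = CandidateSet(
                    np.concatenate([d, disks[:, 2:]], axis=1),
                    np.concatenate([t, tails[:, 2:]], axis=1),
                )
                out = assign_indices(rot, grid_spec, seed=trial)
                expect = base.points.copy()
                for _ in range(k):
                    expect = _rot90(expect, center)
                if not (np.allclose(out.points[out.visible & base.visible],
                                    expect[out.visible & base.visible], atol=1.0)
                        and (out.visible == base.visible).all()):
                    failures += 1
                    break
        assert failures == 0

    def test_no_tails_square_grid_ambiguous(self, grid_spec):
        rng = np.random.default_rng(9)
        cands, _ = _synthetic_candidates(grid_spec, rng)
        no_tails = CandidateSet(cands.disk_candidates, np.empty((0, 3)))
        with pytest.raises(AmbiguityError):
            assign_indices(no_tails, grid_spec, seed=0)

    def test_too_few_disks_rejected(self, grid_spec):
        with pytest.raises(InvalidInputError):
            assign_indices(CandidateSet(np.array([[1.0, 1.0, 1.0]] * 3),
                                        np.array([[5.0, 5.0, 1.0]])), grid_spec)

    def test_end_to_end_2d_accuracy(self, rig, scenes, clean_settings, grid_spec):
        """On noiseless frames at 40-60 cm the classical path's full-frame
        keypoints land within 1 px of the ground-truth projections for
        >=95% of visible electrodes."""
        from dataclasses import replace as dc_replace

        total, good = 0, 0
        for s in scenes:
            if s.depth > 0.60 or s.lateral != pytest.approx(0.049):
                continue
            settings = dc_replace(clean_settings, seed=300 + int(s.depth * 100))
            left, _ = render_stereo(rig, s.state, settings)
            rec = crop(left.image, detect_grid(left.image, ClassicalDetector())[0])
            kps = assign_indices(detect_keypoint_candidates(upscale(rec.crop, 4)),
                                 grid_spec, seed=5)
            full = to_full_frame(kps, rec, 4)
            err = np.linalg.norm(full.points[:64] - left.keypoints[:64], axis=1)
            vis = full.visible[:64]
            total += int(vis.sum())
            good += int((err[vis] < 1.0).sum())
        assert total >= 180
        assert good / total >= 0.95


class TestMatching:
    def test_matches_brute_force_permutation_optimum(self):
        """Hungarian matching equals exhaustive enumeration on <=9 sites."""
        rng = np.random.default_rng(23)
        for n in (3, 5, 7, 9):
            pred = rng.uniform(0, 50, (n, 2))
            cand = rng.uniform(0, 50, (n, 2))
            _pairs, total = match_one_to_one(pred, cand)
            best = min(
                sum(np.linalg.norm(pred[i] - cand[p[i]]) for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert total == pytest.approx(best, abs=1e-9)

    def test_empty_inputs(self):
        pairs, total = match_one_to_one(np.empty((0, 2)), np.empty((0, 2)))
        assert pairs == [] and total == 0.0


class TestToFullFrame:
    def kps(self, pts, vis):
        return KeypointSet(points=np.asarray(pts, dtype=float),
                           visible=np.asarray(vis, dtype=bool),
                           frame="upscaled-crop")

    def rec(self, offset):
        return CropRecord(crop=np.zeros((4, 4)), offset=offset, margin=2)

    def test_offset_arithmetic(self):
        out = to_full_frame(self.kps([[8.0, 8.0]], [True]), self.rec((98, 98)), 4)
        np.testing.assert_allclose(out.points[0], [100.0, 100.0], atol=1e-12)
        assert out.frame == "full"

    def test_round_trip(self):
        rec = self.rec((31, 17))
        pts = np.array([[3.25, 9.5], [100.0, 50.0]])
        out = to_full_frame(self.kps(pts, [True, True]), rec, 4)
        back = (out.points - np.array(rec.offset)) * 4
        np.testing.assert_allclose(back, pts, atol=1e-12)

    def test_invisible_points_untouched(self):
        pts = np.array([[8.0, 8.0], [40.0, 40.0]])
        out = to_full_frame(self.kps(pts, [True, False]), self.rec((10, 10)), 4)
        np.testing.assert_array_equal(out.points[1], pts[1])
        assert not out.visible[1]

    def test_wrong_frame_tag_rejected(self):
        bad = KeypointSet(points=np.zeros((1, 2)), visible=np.ones(1, dtype=bool),
                          frame="full")
        with pytest.raises(ContractError):
            to_full_frame(bad, self.rec((0, 0)), 4)
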