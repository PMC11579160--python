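"""Centerline metrics: CLD, PWR, regional thirds, brute-force equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uroseg import metrics
from uroseg.core import MaskVolume, Centerline, AnatomyError
from uroseg.metrics import EmptyRegionError


def _prostate(n_slices=9, slice_mm=1.0):
    vox = np.ones((4, 4, n_slices), dtype=bool)
    return MaskVolume(vox, (1.0, 1.0, slice_mm), (0.0, 0.0, 0.0), "prostate")


def _line(n=9, x=0.0, y=0.0, slice_mm=1.0):
    z = np.arange(n) * slice_mm
    return Centerline(z=z, x=np.full(n, float(x)), y=np.full(n, float(y)))


class TestExtractCenterline:
    def test_single_voxel_per_slice(self):
        vox = np.zeros((5, 5, 3), dtype=bool)
        vox[1, 2, 0] = vox[3, 4, 1] = vox[0, 0, 2] = True
        m = MaskVolume(vox, (1, 1, 2), (10, 20, 30), "u")
        cl = metrics.extract_centerline(m)
        assert np.allclose(cl.x, [11, 13, 10])
        assert np.allclose(cl.y, [22, 24, 20])
        assert np.allclose(cl.z, [30, 32, 34])

    def test_square_centroid(self):
        vox = np.zeros((6, 6, 1), dtype=bool)
        vox[2:4, 2:4, 0] = True
        cl = metrics.extract_centerline(MaskVolume(vox, (1, 1, 1),
                                                   (0, 0, 0), "u"))
        assert cl.x[0] == pytest.approx(2.5)
        assert cl.y[0] == pytest.approx(2.5)

    def test_empty_mask_raises(self):
        with pytest.raises(AnatomyError):
            metrics.extract_centerline(
                MaskVolume(np.zeros((3, 3, 3)), (1, 1, 1), (0, 0, 0), "u"))


class TestCld:
    def test_identical_centerlines_give_zero(self):
        assert metrics.cld(_line(), _line()) == 0.0

    def test_pythagorean_shift(self):
        assert metrics.cld(_line(), _line(x=3.0, y=4.0)) == pytest.approx(5.0)

    def test_thirds_hand_computed(self):
        """9-slice prostate; top 3 slices shifted 3 mm: whole = 1.0 mm,
        top = 3.0 mm, mid = bottom = 0.0 mm."""
        prostate = _prostate(9)
        gt = _line(9)
        x = np.zeros(9)
        x[:3] = 3.0  # top = superior = smallest z
        pred = Centerline(z=gt.z, x=x, y=np.zeros(9))
        assert metrics.cld(pred, gt, "whole") == pytest.approx(1.0)
        assert metrics.cld(pred, gt, "top", prostate) == pytest.approx(3.0)
        assert metrics.cld(pred, gt, "mid", prostate) == 0.0
        assert metrics.cld(pred, gt, "bottom", prostate) == 0.0

    def test_disjoint_centerlines_raise(self):
        a = _line(5)
        b = Centerline(z=a.z + 100.0, x=a.x, y=a.y)
        with pytest.raises(EmptyRegionError):
            metrics.cld(a, b)


class TestPwr:
    def test_identical_is_100(self):
        assert metrics.pwr(_line(), _line(), 3.5) == 100.0

    def test_offset_between_radii(self):
        pred = _line(x=4.0)
        assert metrics.pwr(pred, _line(), 3.5) == 0.0
        assert metrics.pwr(pred, _line(), 5.0) == 100.0

    def test_half_within(self):
        gt = _line(10)
        x = np.zeros(10)
        x[:5] = 10.0
        pred = Centerline(z=gt.z, x=x, y=np.zeros(10))
        assert metrics.pwr(pred, gt, 3.5) == 50.0
        assert metrics.pwr(pred, gt, 5.0) == 50.0

    def test_monotone_in_radius(self, rng):
        gt = _line(20)
        pred = Centerline(z=gt.z, x=rng.normal(0, 3, 20),
                          y=rng.normal(0, 3, 20))
        values = [metrics.pwr(pred, gt, r) for r in (1.0, 2.5, 4.0, 8.0)]
        assert all(b >= a for a, b in zip(values, values[1:]))


def _brute_force_cld_pwr(pred, gt, radius):
    """Independent per-slice loop implementation (the oracle)."""
    dists = []
    for i, z in enumerate(pred.z):
        js = [j for j, zg in enumerate(gt.z) if abs(zg - z) <= 1e-6]
        if not js:
            continue
        j = js[0]
        dists.append(((pred.x[i] - gt.x[j]) ** 2
                      + (pred.y[i] - gt.y[j]) ** 2) ** 0.5)
    mean = sum(dists) / len(dists)
    within = sum(1 for d in dists if d <= radius)
    return mean, 100.0 * within / len(dists)


def test_matches_brute_force_on_random_pairs(rng):
    """cld/pwr agree with an independent per-slice loop to 1e-9."""
    for _ in range(200):
        n = int(rng.integers(3, 30))
        z = np.sort(rng.choice(np.arange(50), size=n, replace=False)) * 2.0
        gt = Centerline(z=z, x=rng.normal(0, 5, n), y=rng.normal(0, 5, n))
        keep = rng.random(n) < 0.8
        keep[0] = True
        pred = Centerline(z=z[keep], x=rng.normal(0, 5, keep.sum()),
                          y=rng.normal(0, 5, keep.sum()))
        radius = float(rng.uniform(1, 8))
        ref_cld, ref_pwr = _brute_force_cld_pwr(pred, gt, radius)
        assert metrics.cld(pred, gt) == pytest.approx(ref_cld, abs=1e-9)
        assert metrics.pwr(pred, gt, radius) == pytest.approx(ref_pwr,
                                                              abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(dx=st.floats(-10, 10, allow_nan=False),
       dy=st.floats(-10, 10, allow_nan=False),
       n=st.integers(2, 30))
def test_translation_shifts_cld_by_euclidean_norm(dx, dy, n):
    """Starting from pred = gt, a rigid (dx, dy) shift moves the CLD to
    exactly hypot(dx, dy)."""
    gt = _line(n)
    pred = Centerline(z=gt.z, x=gt.x + dx, y=gt.y + dy)
    assert metrics.cld(pred, gt) == pytest.approx(float(np.hypot(dx, dy)),
                                                  abs=1e-9)


def test_whole_cld_is_weighted_mean_of_thirds(rng):
    """Whenever the thirds partition the shared slices, the whole CLD is
    their slice-count-weighted mean."""
    for _ in range(50):
        n = int(rng.integers(6, 25))
        prostate = MaskVolume(np.ones((40, 40, n), bool), (1, 1, 1),
                              (-15.0, -15.0, 0.0), "prostate")
        gt = _line(n)
        pred = Centerline(z=gt.z, x=rng.normal(0, 4, n),
                          y=rng.normal(0, 4, n))
        rep = metrics.report(
            _cl_to_mask(pred, n), _cl_to_mask(gt, n), prostate)
        parts = [(rep.cld_top, rep.n_slices["top"]),
                 (rep.cld_mid, rep.n_slices["mid"]),
                 (rep.cld_bottom, rep.n_slices["bottom"])]
        total = sum(w for _, w in parts)
        weighted = sum(c * w for c, w in parts if w) / total
        assert total == rep.n_slices["whole"]
        assert rep.cld_whole == pytest.approx(weighted, abs=1e-9)


def _cl_to_mask(cl, n_slices, shape=(40, 40)):
    """Render a centerline as one voxel per slice (world = index here)."""
    vox = np.zeros(shape + (n_slices,), dtype=bool)
    for z, x, y in cl.as_array():
        vox[int(round(x)) + 15, int(round(y)) + 15, int(round(z))] = True
    m = MaskVolume(vox, (1, 1, 1), (-15.0, -15.0, 0.0), "cl")
    return m


class TestReport:
    def test_identical_masks_zero_cld_full_pwr(self, straight_case):
        rep = metrics.report(straight_case.urethra, straight_case.urethra,
                             straight_case.prostate)
        assert rep.cld_whole == 0.0
        assert rep.cld_top == 0.0
        assert rep.pwr[3.5] == 100.0 and rep.pwr[5.0] == 100.0

    def test_cld_symmetric_in_pred_and_gt(self, straight_case, tilted_case):
        # compare two different tubes on a shared grid
        a, b = straight_case.urethra, tilted_case.urethra
        r1 = metrics.report(a, b, straight_case.prostate)
        r2 = metrics.report(b, a, straight_case.prostate)
        assert r1.cld_whole == pytest.approx(r2.cld_whole, abs=1e-12)

    def test_report_matches_individual_operations(self, rng):
        n = 12
        prostate = MaskVolume(np.ones((40, 40, n), bool), (1, 1, 1),
                              (-15.0, -15.0, 0.0), "prostate")
        gt = _line(n)
        pred = Centerline(z=gt.z, x=rng.normal(0, 2, n),
                          y=rng.normal(0, 2, n))
        rep = metrics.report(_cl_to_mask(pred, n), _cl_to_mask(gt, n),
                             prostate)
        pred_cl = metrics.extract_centerline(_cl_to_mask(pred, n))
        gt_cl = metrics.extract_centerline(_cl_to_mask(gt, n))
        assert rep.cld_whole == pytest.approx(
            metrics.cld(pred_cl, gt_cl), abs=1e-12)
        for r in (3.5, 5.0):
            assert rep.pwr[r] == pytest.approx(
                metrics.pwr(pred_cl, gt_cl, r), abs=1e-12)
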