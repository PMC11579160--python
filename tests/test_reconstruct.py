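"""Coordinate extraction, gap filling, cylinder building, resampling."""

import numpy as np
import pytest

from uroseg import reconstruct, metrics
from uroseg.core import EmptyPredictionError
from uroseg.reconstruct import CoordinateSeries
from uroseg.structio import GridSpec


def _series(z, x, y, src="predicted"):
    n = len(z)
    return CoordinateSeries(np.asarray(z), np.asarray(x, float),
                            np.asarray(y, float),
                            np.full(n, src, dtype=object),
                            np.full(n, src, dtype=object))


class TestCoordsFromProjections:
    def _img(self):
        return np.zeros((256, 256), dtype=bool)

    def test_single_pixel_centroid(self):
        """A lone predicted pixel at u=100 maps to X = 50.0 mm."""
        cor, sag = self._img(), self._img()
        cor[100, 40:42] = True   # rows of slice k=20
        sag[80, 40:42] = True
        s = reconstruct.coords_from_projections(cor, sag, [20])
        assert s.x_mm[0] == pytest.approx(50.0)
        assert s.y_mm[0] == pytest.approx(40.0)

    def test_symmetric_pixels_average(self):
        cor, sag = self._img(), self._img()
        cor[98, 10:12] = cor[102, 10:12] = True
        sag[50, 10:12] = True
        s = reconstruct.coords_from_projections(cor, sag, [5])
        assert s.x_mm[0] == pytest.approx(50.0)

    def test_missing_axis_marked(self):
        cor, sag = self._img(), self._img()
        sag[60, 20:22] = True  # sagittal present, coronal empty at k=10
        sag[60, 24:26] = True
        cor[60, 24:26] = True
        s = reconstruct.coords_from_projections(cor, sag, [10, 12])
        assert np.isnan(s.x_mm[0]) and not np.isnan(s.y_mm[0])
        assert s.source_x[0] == reconstruct.SOURCE_MISSING
        filled = reconstruct.fill_missing(s)
        assert filled.complete
        assert filled.x_mm[0] == pytest.approx(filled.x_mm[1])

    def test_both_empty_raises(self):
        with pytest.raises(EmptyPredictionError):
            reconstruct.coords_from_projections(self._img(), self._img(),
                                                [1, 2])


class TestCoordsFromVolume:
    def test_single_voxel(self):
        vol = np.zeros((128, 128, 128), dtype=bool)
        vol[40, 60, 30] = True
        s = reconstruct.coords_from_volume(vol, [30])
        assert s.x_mm[0] == pytest.approx(40.0)
        assert s.y_mm[0] == pytest.approx(60.0)

    def test_l_shaped_region_centroid(self):
        vol = np.zeros((16, 16, 4), dtype=bool)
        for dx, dy in [(0, 0), (2, 0), (0, 2)]:
            vol[dx, dy, 1] = True
        s = reconstruct.coords_from_volume(vol, [1])
        assert s.x_mm[0] == pytest.approx(2.0 / 3.0)
        assert s.y_mm[0] == pytest.approx(2.0 / 3.0)

    def test_empty_plane_marked_missing(self):
        vol = np.zeros((8, 8, 6), dtype=bool)
        vol[4, 4, 2] = True
        s = reconstruct.coords_from_volume(vol, [2, 3])
        assert not np.isnan(s.x_mm[0])
        assert np.isnan(s.x_mm[1])

    def test_entirely_empty_raises(self):
        with pytest.raises(EmptyPredictionError):
            reconstruct.coords_from_volume(np.zeros((8, 8, 8), bool), [1])


class TestFillMissing:
    def test_no_gaps_is_identity(self):
        s = _series([1, 2, 3], [1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        out = reconstruct.fill_missing(s)
        assert np.array_equal(out.x_mm, s.x_mm)
        assert list(out.source_x) == ["predicted"] * 3

    def test_interior_gap_linear(self):
        """Gap between (z=10, x=20) and (z=12, x=24) fills to x=22."""
        s = _series([10, 11, 12], [20.0, np.nan, 24.0], [0.0, np.nan, 0.0])
        s.source_x[1] = s.source_y[1] = reconstruct.SOURCE_MISSING
        out = reconstruct.fill_missing(s)
        assert out.x_mm[1] == pytest.approx(22.0)
        assert out.source_x[1] == reconstruct.SOURCE_INTERPOLATED

    def test_leading_gap_copies_first_value(self):
        s = _series([0, 1, 2], [np.nan, 7.0, 9.0], [np.nan, 1.0, 1.0])
        s.source_x[0] = s.source_y[0] = reconstruct.SOURCE_MISSING
        out = reconstruct.fill_missing(s)
        assert out.x_mm[0] == pytest.approx(7.0)
        assert out.source_x[0] == reconstruct.SOURCE_EXTRAPOLATED

    def test_axis_with_no_predictions_raises(self):
        s = _series([0, 1], [np.nan, np.nan], [0.0, 0.0])
        with pytest.raises(EmptyPredictionError):
            reconstruct.fill_missing(s)


class TestBuildCylinder:
    def test_five_mm_disc_has_21_voxels(self):
        """5 mm diameter on a 1 mm grid, centered on a voxel center:
        exactly 21 lattice points lie within 2.5 mm."""
        s = _series([10], [64.0], [64.0])
        cyl = reconstruct.build_cylinder(s, 5.0)
        count = cyl.mask.voxels[:, :, 10].sum()
        # independent lattice-point oracle
        dx, dy = np.meshgrid(np.arange(-4, 5), np.arange(-4, 5))
        oracle = np.count_nonzero(dx ** 2 + dy ** 2 <= 2.5 ** 2)
        assert oracle == 21
        assert count == oracle

    def test_half_mm_disc_is_single_voxel(self):
        s = _series([0], [40.0], [40.0])
        cyl = reconstruct.build_cylinder(s, 0.5)
        assert cyl.mask.voxels.sum() == 1
        assert cyl.mask.voxels[40, 40, 0]

    def test_per_slice_count_constant_for_aligned_series(self):
        s = _series([3, 4, 5], [60.0, 60.0, 60.0], [50.0, 50.0, 50.0])
        cyl = reconstruct.build_cylinder(s, 5.0)
        counts = cyl.mask.voxels.sum(axis=(0, 1))
        assert set(counts[[3, 4, 5]]) == {21}

    def test_z_translation_symmetry(self):
        a = reconstruct.build_cylinder(_series([10, 11], [30.5, 31.0],
                                               [40.0, 40.2]), 5.0)
        b = reconstruct.build_cylinder(_series([20, 21], [30.5, 31.0],
                                               [40.0, 40.2]), 5.0)
        assert np.array_equal(a.mask.voxels[:, :, 10:12],
                              b.mask.voxels[:, :, 20:22])

    def test_incomplete_series_rejected(self):
        s = _series([0, 1], [1.0, np.nan], [0.0, 0.0])
        with pytest.raises(EmptyPredictionError):
            reconstruct.build_cylinder(s)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            reconstruct.build_cylinder(_series([0], [5.0], [5.0]), 0.0)


class TestResampleToOriginal:
    def _cylinder(self):
        z = np.arange(30, 60)
        return reconstruct.build_cylinder(
            _series(z, np.full(30, 64.0), np.full(30, 64.0)), 5.0)

    def test_identity_grid(self):
        cyl = self._cylinder()
        out = reconstruct.resample_to_original(
            cyl, GridSpec((128, 128, 128), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)))
        assert np.array_equal(out.mask.voxels, cyl.mask.voxels)

    def test_volume_preserved_on_thick_slices(self):
        """Resampling the 5 mm cylinder to 2.5 mm slices keeps its volume
        within 15%."""
        cyl = self._cylinder()
        target = GridSpec((128, 128, 52), (1.0, 1.0, 2.5), (0.0, 0.0, 0.0))
        out = reconstruct.resample_to_original(cyl, target)
        v_in = cyl.mask.voxels.sum() * cyl.mask.voxel_volume()
        v_out = out.mask.voxels.sum() * out.mask.voxel_volume()
        assert v_out == pytest.approx(v_in, rel=0.15)

    def test_centerline_preserved_within_1mm(self):
        cyl = self._cylinder()
        target = GridSpec((128, 128, 52), (1.2, 1.2, 2.5), (0.0, 0.0, 0.0))
        out = reconstruct.resample_to_original(cyl, target)
        cl = metrics.extract_centerline(out.mask)
        assert np.all(np.abs(cl.x - 64.0) <= 1.0)
        assert np.all(np.abs(cl.y - 64.0) <= 1.0)


def test_projection_and_volume_coordinates_agree_on_discs():
    """For symmetric per-slice discs the max-projection centroid equals
    the in-plane volume centroid."""
    vol = np.zeros((128, 128, 128), dtype=bool)
    gx, gy = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
    for k, (cx, cy) in zip([40, 41, 42], [(60, 64), (61, 64), (62, 65)]):
        vol[:, :, k] = (gx - cx) ** 2 + (gy - cy) ** 2 <= 2.5 ** 2
    # build the projections the encoder would produce for a target mask
    cor = np.repeat(np.repeat(vol.max(axis=1), 2, axis=0), 2, axis=1)
    sag = np.repeat(np.repeat(vol.max(axis=0), 2, axis=0), 2, axis=1)
    zs = [40, 41, 42]
    s3 = reconstruct.coords_from_volume(vol, zs)
    s2 = reconstruct.coords_from_projections(cor, sag, zs)
    # 0.5 mm/px grid offset of the upsampled projection is 0.25 mm
    assert np.allclose(s2.x_mm, s3.x_mm, atol=0.3)
    assert np.allclose(s2.y_mm, s3.y_mm, atol=0.3)
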