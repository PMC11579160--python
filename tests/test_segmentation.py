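"""Model configurations, splits, cross-validation, oracle backend."""

import numpy as np
import pytest

from uroseg import segmentation, pipeline
from uroseg.core import AnatomyError, ConfigurationError
from uroseg.segmentation import ModelConfig, make_split


class TestModelConfig:
    def test_reference_2d_conditions(self):
        cfg = ModelConfig.default_2d()
        assert cfg.residual_units == 3
        assert cfg.channels == (16, 32, 64, 128, 256)
        assert cfg.strides == 2
        assert cfg.dropout == 0.5
        assert cfg.batch_size == 4
        assert cfg.max_epochs == 1200
        assert cfg.learning_rate == 1e-4
        assert cfg.loss == "dice_ce" and cfg.optimizer == "adam"

    def test_reference_3d_conditions(self):
        cfg = ModelConfig.default_3d()
        assert cfg.residual_units == 4
        assert cfg.channels == (32, 64, 128, 256, 512)
        assert cfg.dropout == 0.0
        assert cfg.batch_size == 2
        assert cfg.max_epochs == 1000
        assert cfg.learning_rate == 1e-4

    def test_config_hash_distinguishes_configs(self):
        a, b = ModelConfig.tiny_2d(seed=0), ModelConfig.tiny_2d(seed=1)
        assert a.config_hash() != b.config_hash()
        assert a.config_hash() == ModelConfig.tiny_2d(seed=0).config_hash()


class TestMakeSplit:
    def test_rounding_at_ten_cases(self):
        plan = make_split(list(range(10)), seed=0)
        assert (len(plan.train), len(plan.validation), len(plan.test)) \
            == (7, 1, 2)

    def test_deterministic_and_exhaustive(self):
        ids = [f"c{i}" for i in range(23)]
        a = make_split(ids, seed=4)
        b = make_split(ids, seed=4)
        assert a.train == b.train and a.test == b.test
        combined = a.train + a.validation + a.test
        assert sorted(combined) == sorted(ids)
        assert len(set(combined)) == len(ids)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            make_split([1, 2, 3], fractions=(0.5, 0.2, 0.2))


class TestCrossvalidate:
    def _data(self, n=10):
        rng = np.random.default_rng(0)
        X = rng.random((n, 8, 8)).astype(np.float32)
        return X, X > 0.5

    def _cfg(self, seed=0):
        return ModelConfig(residual_units=1, channels=(2, 4), dropout=0.0,
                           max_epochs=1, batch_size=4, augmentations=(),
                           seed=seed, early_stopping=False)

    def test_single_candidate_returned(self):
        X, y = self._data()
        cfg = self._cfg()
        assert segmentation.crossvalidate(X, y, [cfg], k=2) is cfg

    def test_duplicate_winner_keeps_first(self):
        X, y = self._data(6)
        a, b = self._cfg(), self._cfg()
        winner = segmentation.crossvalidate(X, y, [a, b], k=2)
        assert winner is a

    def test_too_few_cases_raises(self):
        X, y = self._data(3)
        with pytest.raises(ConfigurationError):
            segmentation.crossvalidate(X, y, [self._cfg()], k=5)
        with pytest.raises(ConfigurationError):
            segmentation.crossvalidate(X, y, [], k=2)
        with pytest.raises(ConfigurationError):
            segmentation.crossvalidate(X, y, [self._cfg()], k=1)


class TestTrainOp:
    def test_empty_partitions_rejected(self):
        X = np.zeros((0, 8, 8), np.float32)
        with pytest.raises(ConfigurationError):
            segmentation.train({"train": (X, X)}, ModelConfig.tiny_2d())
        X1 = np.zeros((1, 8, 8), np.float32)
        with pytest.raises(ConfigurationError):
            segmentation.train({"train": (X1, X1 > 0.5),
                                "validation": (X, X)},
                               ModelConfig.tiny_2d())

    def test_smoke_run_returns_handle_with_finite_losses(self):
        rng = np.random.default_rng(0)
        X = rng.random((1, 16, 16)).astype(np.float32)
        y = X > 0.6
        cfg = ModelConfig(residual_units=1, channels=(2, 4), max_epochs=2,
                          augmentations=(), dropout=0.0, seed=0)
        est = segmentation.train({"train": (X, y)}, cfg)
        assert np.isfinite(est.history_["val_loss"]).all()
        assert est.best_val_loss_ < np.inf

    def test_checkpoint_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.random((2, 16, 16)).astype(np.float32)
        est = segmentation.train(
            {"train": (X, X > 0.5)},
            ModelConfig(residual_units=1, channels=(2, 4), max_epochs=1,
                        augmentations=(), dropout=0.0, seed=0))
        segmentation.save_model(est, tmp_path / "m.npz")
        loaded = segmentation.load_model(tmp_path / "m.npz")
        assert np.array_equal(loaded.predict(X), est.predict(X))


class TestAugmentations:
    def test_transforms_are_label_synchronized(self):
        rng = np.random.default_rng(0)
        img = np.zeros((64, 64), np.float32)
        img[20:40, 25:45] = 1.0
        lab = img > 0.5
        for kinds in [("rotation",), ("scaling", "translation"),
                      ("elastic",)]:
            ai, al = segmentation.augment_pair(img, lab, kinds,
                                               np.random.default_rng(3))
            # the label must track the image: overlap stays high
            inter = np.logical_and(ai > 0.5, al).sum()
            union = np.logical_or(ai > 0.5, al).sum()
            assert inter / union > 0.9

    def test_no_kinds_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16)).astype(np.float32)
        lab = img > 0.5
        ai, al = segmentation.augment_pair(img, lab, (), rng)
        assert ai is img and al is lab


class TestOracleBackend:
    def test_tube_centroids_match_truth(self, straight_case):
        enc = pipeline.encode_case(straight_case)
        pred = segmentation.oracle_predict_volume(straight_case,
                                                  enc.crop_grid)
        assert pred.mask.shape == (128, 128, 128)
        zs = np.flatnonzero(pred.mask.any(axis=(0, 1)))
        origin = np.asarray(enc.crop_grid.origin)
        cl = straight_case.true_centerline
        for k in zs[2:-2]:
            sl = np.argwhere(pred.mask[:, :, k])
            cx, cy = sl.mean(axis=0) + origin[:2]
            x_true = np.interp(origin[2] + k, cl.z, cl.x)
            y_true = np.interp(origin[2] + k, cl.z, cl.y)
            assert abs(cx - x_true) <= 1.0
            assert abs(cy - y_true) <= 1.0

    def test_tube_diameter_honored(self, straight_case):
        enc = pipeline.encode_case(straight_case)
        pred = segmentation.oracle_predict_volume(straight_case,
                                                  enc.crop_grid)
        for k in np.flatnonzero(pred.mask.any(axis=(0, 1))):
            idx = np.argwhere(pred.mask[:, :, k])
            extent = max(np.ptp(idx[:, 0]), np.ptp(idx[:, 1]))
            assert extent <= 5.0 + 1.0

    def test_projection_oracle_shape_and_extent(self, straight_case):
        enc = pipeline.encode_case(straight_case)
        pred = segmentation.oracle_predict_projection(
            straight_case, enc.crop_grid, "coronal")
        assert pred.mask.shape == (256, 256)
        cols = np.flatnonzero(pred.mask.any(axis=1))
        assert cols.size > 0
        assert (cols.max() - cols.min()) * 0.5 <= 5.0 + 0.5

    def test_full_pipeline_with_oracle_on_straight_phantom(self,
                                                           straight_case):
        """Oracle backend through the whole chain: reconstruction error
        alone stays within 1 mm CLD on a straight-urethra phantom."""
        for mode in ("2d", "3d"):
            rep, cld_true = pipeline.run_oracle_case(straight_case, mode)
            assert cld_true <= 1.0
            assert rep.pwr[5.0] == 100.0

    def test_empty_prostate_raises(self, straight_case):
        import dataclasses
        empty = straight_case.prostate.copy()
        empty.voxels[:] = False
        broken = dataclasses.replace(straight_case, prostate=empty)
        with pytest.raises(AnatomyError):
            segmentation.oracle_predict_volume(
                broken, pipeline.encode_case(straight_case).crop_grid)
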