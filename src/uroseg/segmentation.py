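"""Segmentation backends and training protocol.

Two families of backends satisfy one ``predict`` contract:

* **Trainable residual U-Nets** (:class:`UNetSegmenter`), scikit-learn
  style estimators wrapping a numpy U-Net.  The reference configurations
  (:meth:`ModelConfig.default_2d` / :meth:`ModelConfig.default_3d`) mirror
  the published training conditions: 2D with 3 residual units and channels
  16-256 at dropout 0.5, batch 4; 3D with 4 units and channels 32-512 at
  dropout 0, batch 2; both trained with DiceCE loss and Adam at lr 1e-4,
  early stopping on validation loss.  Reduced configurations
  (:meth:`ModelConfig.tiny_2d`) train in minutes on a CPU and are what the
  test suite exercises end to end.
* **A geometric oracle** that renders the phantom's analytic centerline as
  a 5 mm tube in the model-input geometry.  It lets the reconstruction and
  evaluation stages be tested with zero model error.

The 2D variant always consists of two models - one for coronal, one for
sagittal projections - trained and applied as a unit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import _nn
from .core import (
    GrayscaleVolume,
    ProjectionImage,
    AnatomyError,
    ConfigurationError,
)
from .phantom import PhantomCase, URETHRA_RADIUS_MM
from .structio import GridSpec

PREDICTION_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters of one model variant."""

    dimensionality: str = "2d"            # "2d" | "3d"
    residual_units: int = 3
    channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    strides: int = 2
    dropout: float = 0.5
    loss: str = "dice_ce"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 1200
    early_stopping: bool = True
    patience: int = 50
    augmentations: tuple[str, ...] = (
        "scaling", "crop", "rotation", "translation", "elastic")
    seed: int = 0

    @classmethod
    def default_2d(cls) -> "ModelConfig":
        return cls()

    @classmethod
    def default_3d(cls) -> "ModelConfig":
        return cls(dimensionality="3d", residual_units=4,
                   channels=(32, 64, 128, 256, 512), dropout=0.0,
                   batch_size=2, max_epochs=1000)

    @classmethod
    def tiny_2d(cls, seed: int = 0, max_epochs: int = 40) -> "ModelConfig":
        """Reduced 2D model for CPU-scale experiments on synthetic data."""
        return cls(residual_units=1, channels=(8, 16, 32), dropout=0.0,
                   max_epochs=max_epochs, patience=10, augmentations=(),
                   seed=seed)

    @classmethod
    def tiny_3d(cls, seed: int = 0, max_epochs: int = 20) -> "ModelConfig":
        return cls(dimensionality="3d", residual_units=1, channels=(8, 16),
                   dropout=0.0, batch_size=2, max_epochs=max_epochs,
                   patience=5, augmentations=(), seed=seed)

    @property
    def rank(self) -> int:
        return 3 if self.dimensionality == "3d" else 2

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SplitPlan:
    """Disjoint, exhaustive train/validation/test partition of case ids."""

    train: list
    validation: list
    test: list
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)


def make_split(case_ids: list, fractions=(0.7, 0.1, 0.2),
               seed: int = 0) -> SplitPlan:
    """Randomly partition case ids; deterministic under ``seed``.

    Sizes are nearest-integer rounded for train and validation, with the
    remainder as test (10 ids at 0.7/0.1/0.2 -> 7/1/2).  The same plan is
    meant to be reused by the 2D and 3D runs.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    ids = list(case_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(len(ids) * fractions[0]))
    n_val = int(round(len(ids) * fractions[1]))
    n_train = min(n_train, len(ids))
    n_val = min(n_val, len(ids) - n_train)
    shuffled = [ids[i] for i in order]
    return SplitPlan(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
        fractions=tuple(fractions),
    )


@dataclass
class PredictionMask:
    """Binary model output in the model-input geometry."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


# ---------------------------------------------------------------------------
# label-synchronized augmentations


@dataclass
class AugmentationRanges:
    """Magnitudes of the random training augmentations."""

    scale: float = 0.10          # +/- fractional zoom
    rotation_deg: float = 10.0   # +/- in-plane rotation
    translation: float = 10.0    # +/- voxels along each axis
    elastic_sigma: float = 5.0   # smoothing of the displacement field
    elastic_magnitude: float = 2.0  # voxels
    crop_fraction: float = 0.10  # random crop-and-pad extent


def augment_pair(image: np.ndarray, label: np.ndarray,
                 kinds: tuple[str, ...], rng: np.random.Generator,
                 ranges: AugmentationRanges | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random spatial transform to an (image, label) pair.

    The same geometric transform is applied to both; the image is
    interpolated linearly, the label with nearest-neighbor so it stays
    binary.  Works for 2D and 3D arrays.
    """
    if not kinds:
        return image, label
    ranges = ranges or AugmentationRanges()
    rank = image.ndim
    center = (np.asarray(image.shape) - 1) / 2.0

    matrix = np.eye(rank)
    if "scaling" in kinds:
        matrix *= 1.0 + rng.uniform(-ranges.scale, ranges.scale)
    if "rotation" in kinds:
        theta = np.radians(rng.uniform(-ranges.rotation_deg,
                                       ranges.rotation_deg))
        rot = np.eye(rank)
        c, s = np.cos(theta), np.sin(theta)
        rot[:2, :2] = [[c, -s], [s, c]]  # in-plane rotation
        matrix = matrix @ rot
    shift = np.zeros(rank)
    if "translation" in kinds or "crop" in kinds:
        reach = ranges.translation if "translation" in kinds else \
            ranges.crop_fraction * min(image.shape)
        shift = rng.uniform(-reach, reach, size=rank)
    offset = center - matrix @ center + shift

    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in image.shape],
                         indexing="ij")
    coords = np.stack(coords)
    flat = coords.reshape(rank, -1)
    warped = (matrix @ flat + offset[:, None]).reshape(coords.shape)

    if "elastic" in kinds:
        for axis in range(rank):
            noise = rng.normal(0.0, 1.0, image.shape)
            noise = ndimage.gaussian_filter(noise, ranges.elastic_sigma)
            peak = np.abs(noise).max() or 1.0
            warped[axis] += noise / peak * ranges.elastic_magnitude

    img_t = ndimage.map_coordinates(image.astype(np.float32), warped,
                                    order=1, mode="constant", cval=0.0)
    lab_t = ndimage.map_coordinates(label.astype(np.float32), warped,
                                    order=0, mode="constant", cval=0.0)
    return img_t, lab_t > 0.5


# ---------------------------------------------------------------------------
# trainable backend


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style residual U-Net segmenter.

    Parameters mirror :class:`ModelConfig`; ``fit`` accepts arrays shaped
    ``(n, H, W)`` (2D) or ``(n, D, H, W)`` (3D) with grayscale inputs in
    [0, 255] and binary targets.  Validation data drives checkpoint
    selection: the weights with the lowest validation DiceCE loss are
    restored after training.

    Fitted attributes: ``net_`` (the numpy U-Net), ``history_`` (DataFrame
    of per-epoch train/validation loss), ``best_epoch_``,
    ``best_val_loss_``.
    """

    def __init__(self, dimensionality="2d", residual_units=1,
                 channels=(8, 16, 32), dropout=0.0, learning_rate=1e-4,
                 batch_size=4, max_epochs=40, early_stopping=True,
                 patience=10, augmentations=(), seed=0):
        self.dimensionality = dimensionality
        self.residual_units = residual_units
        self.channels = channels
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stopping = early_stopping
        self.patience = patience
        self.augmentations = augmentations
        self.seed = seed

    @classmethod
    def from_config(cls, config: ModelConfig) -> "UNetSegmenter":
        return cls(
            dimensionality=config.dimensionality,
            residual_units=config.residual_units,
            channels=config.channels,
            dropout=config.dropout,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            early_stopping=config.early_stopping,
            patience=config.patience,
            augmentations=config.augmentations,
            seed=config.seed,
        )

    @property
    def _rank(self) -> int:
        return 3 if self.dimensionality == "3d" else 2

    def _check(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != self._rank + 1:
            raise ConfigurationError(
                f"expected (n, {'D, H, W' if self._rank == 3 else 'H, W'}) "
                f"input, got shape {X.shape}")
        if X.max() > 1.5:
            X = X / 255.0
        if y is None:
            return X
        y = (np.asarray(y) > 0.5).astype(np.float32)
        if y.shape != X.shape:
            raise ConfigurationError("inputs and targets differ in shape")
        return X, y

    def _loss_on(self, X: np.ndarray, y: np.ndarray, batch: int) -> float:
        total, count = 0.0, 0
        for i in range(0, X.shape[0], batch):
            xb = X[i:i + batch, None]
            yb = y[i:i + batch, None]
            logits = self.net_.forward(xb, train=False)
            loss, _ = _nn.dice_ce_loss(logits, yb)
            total += loss * xb.shape[0]
            count += xb.shape[0]
        return total / max(count, 1)

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._check(X, y)
        if X.shape[0] == 0:
            raise ConfigurationError("training partition is empty")
        if X_val is None:
            X_val, y_val = X, y  # degenerate but explicit: overfit-style run
        else:
            X_val, y_val = self._check(X_val, y_val)
            if X_val.shape[0] == 0:
                raise ConfigurationError("validation partition is empty")

        self.net_ = _nn.UNet(channels=self.channels, rank=self._rank,
                             residual_units=self.residual_units,
                             dropout=self.dropout, seed=self.seed)
        opt = _nn.Adam(self.net_.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)

        history = []
        best_val = np.inf
        best_state = self.net_.state()
        best_epoch = 0
        since_best = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(X.shape[0])
            ep_loss, seen = 0.0, 0
            for i in range(0, order.size, self.batch_size):
                sel = order[i:i + self.batch_size]
                xb, yb = X[sel], y[sel]
                if self.augmentations:
                    xb = xb.copy()
                    yb = yb.copy()
                    for j in range(xb.shape[0]):
                        xb[j], yb[j] = augment_pair(
                            xb[j], yb[j], tuple(self.augmentations), rng)
                logits = self.net_.forward(xb[:, None], train=True)
                loss, dlogits = _nn.dice_ce_loss(logits, yb[:, None])
                self.net_.backward(dlogits)
                opt.step()
                ep_loss += loss * sel.size
                seen += sel.size
            val_loss = self._loss_on(X_val, y_val, self.batch_size)
            history.append({"epoch": epoch, "train_loss": ep_loss / seen,
                            "val_loss": val_loss})
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = self.net_.state()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if self.early_stopping and since_best >= self.patience:
                    break
        self.net_.load_state(best_state)
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_val)
        self.n_iter_ = len(history)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._check(X)
        out = []
        for i in range(0, X.shape[0], max(int(self.batch_size), 1)):
            logits = self.net_.forward(X[i:i + self.batch_size, None],
                                       train=False)
            out.append(_nn.sigmoid(logits)[:, 0])
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= PREDICTION_THRESHOLD

    def provenance(self) -> str:
        cfg = json.dumps(self.get_params(), sort_keys=True, default=str)
        return "unet:" + hashlib.sha1(cfg.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# spec-level operations


def train(dataset: dict, config: ModelConfig,
          backend: UNetSegmenter | None = None) -> UNetSegmenter:
    """Train one model on an encoded dataset.

    ``dataset`` maps ``"train"``/``"validation"`` to ``(inputs, targets)``
    array pairs.  Returns the estimator restored to its best-validation
    checkpoint.  Raises :class:`ConfigurationError` on empty partitions.
    """
    if "train" not in dataset or len(dataset["train"][0]) == 0:
        raise ConfigurationError("training partition is empty")
    est = backend or UNetSegmenter.from_config(config)
    X, y = dataset["train"]
    if "validation" in dataset:
        Xv, yv = dataset["validation"]
        if len(Xv) == 0:
            raise ConfigurationError("validation partition is empty")
        est.fit(X, y, X_val=Xv, y_val=yv)
    else:
        est.fit(X, y)
    return est


def crossvalidate(X, y, candidate_configs: list[ModelConfig], k: int = 5,
                  seed: int = 0) -> ModelConfig:
    """Pick the candidate with the lowest mean held-fold DiceCE loss.

    Folds are seeded, disjoint and shared by all candidates; ties keep the
    first candidate in list order.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if not candidate_configs:
        raise ConfigurationError("no candidate configurations")
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] < k:
        raise ConfigurationError(f"{X.shape[0]} cases cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    folds = np.array_split(order, k)

    best_cfg, best_loss = None, np.inf
    for cfg in candidate_configs:
        losses = []
        for held in folds:
            train_idx = np.setdiff1d(order, held)
            est = UNetSegmenter.from_config(cfg)
            est.fit(X[train_idx], y[train_idx],
                    X_val=X[held], y_val=y[held])
            losses.append(est._loss_on(est._check(X[held], y[held])[0],
                                       est._check(X[held], y[held])[1],
                                       est.batch_size))
        mean_loss = float(np.mean(losses))
        if mean_loss < best_loss:
            best_loss, best_cfg = mean_loss, cfg
    return best_cfg


def predict(model: UNetSegmenter, item) -> PredictionMask:
    """Apply a trained model to one encoded input.

    ``item`` may be a :class:`GrayscaleVolume` (3D), a
    :class:`ProjectionImage` (2D), or a bare array.  Deterministic: the
    same input always yields the same mask.
    """
    if isinstance(item, GrayscaleVolume):
        arr = item.intensities
    elif isinstance(item, ProjectionImage):
        arr = item.intensities
    else:
        arr = np.asarray(item)
    mask = model.predict(arr[None])[0]
    return PredictionMask(mask, provenance=model.provenance())


def save_model(est: UNetSegmenter, path) -> None:
    """Checkpoint: weight arrays plus the estimator configuration."""
    arrays = est.net_.state()
    np.savez(path, config=json.dumps(est.get_params(), default=list),
             n_arrays=len(arrays),
             **{f"w{i}": a for i, a in enumerate(arrays)})


def load_model(path) -> UNetSegmenter:
    """Restore a checkpointed estimator (inference-ready)."""
    data = np.load(path, allow_pickle=False)
    params = json.loads(str(data["config"]))
    for key in ("channels", "augmentations"):
        params[key] = tuple(params[key])
    est = UNetSegmenter(**params)
    est.net_ = _nn.UNet(channels=est.channels, rank=est._rank,
                        residual_units=est.residual_units,
                        dropout=est.dropout, seed=est.seed)
    est.net_.load_state([data[f"w{i}"]
                         for i in range(int(data["n_arrays"]))])
    return est


# ---------------------------------------------------------------------------
# geometric oracle backend


def _centerline_on_crop(case: PhantomCase, crop_grid: GridSpec
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window-frame path coordinates at each 1 mm crop slice it crosses."""
    if not case.prostate.voxels.any():
        raise AnatomyError("phantom prostate mask is empty")
    origin = np.asarray(crop_grid.origin, dtype=float)
    nz = crop_grid.shape[2]
    z_world = origin[2] + np.arange(nz)  # 1 mm grid
    cl = case.true_centerline
    inside = (z_world >= cl.z[0] - 0.5) & (z_world <= cl.z[-1] + 0.5)
    ks = np.flatnonzero(inside)
    x = np.interp(z_world[ks], cl.z, cl.x) - origin[0]
    y = np.interp(z_world[ks], cl.z, cl.y) - origin[1]
    return ks, x, y


def oracle_predict_volume(case: PhantomCase,
                          crop_grid: GridSpec) -> PredictionMask:
    """Render the analytic centerline as a 5 mm tube on the 3D crop grid."""
    ks, x, y = _centerline_on_crop(case, crop_grid)
    shape = tuple(crop_grid.shape)
    vox = np.zeros(shape, dtype=bool)
    gx = np.arange(shape[0], dtype=float)
    gy = np.arange(shape[1], dtype=float)
    for k, xc, yc in zip(ks, x, y):
        d2 = (gx[:, None] - xc) ** 2 + (gy[None, :] - yc) ** 2
        vox[:, :, k] = d2 <= URETHRA_RADIUS_MM ** 2
    return PredictionMask(vox, provenance="oracle:3d")


def oracle_predict_projection(case: PhantomCase, crop_grid: GridSpec,
                              plane: str) -> PredictionMask:
    """Render the analytic tube silhouette in 256x256 projection space."""
    if plane not in ("coronal", "sagittal"):
        raise ValueError(f"unknown plane {plane!r}")
    ks, x, y = _centerline_on_crop(case, crop_grid)
    coord = x if plane == "coronal" else y
    size = 2 * crop_grid.shape[0]
    img = np.zeros((size, 2 * crop_grid.shape[2]), dtype=bool)
    us = 0.5 * np.arange(size)  # pixel -> window mm
    for k, c in zip(ks, coord):
        cols = np.abs(us - c) <= URETHRA_RADIUS_MM
        img[cols, 2 * k:2 * k + 2] = True
    return PredictionMask(img, provenance=f"oracle:{plane}")
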