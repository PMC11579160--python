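"""End-to-end wiring of the localization workflow.

One case flows through: organ masks -> 1 mm resampling -> grayscale
encoding -> prostate-anchored crop -> (projections) -> segmentation
backend -> per-slice coordinates -> 5 mm cylinder -> original CT grid ->
centerline metrics.  The functions here keep the per-stage modules free of
knowledge about each other's file formats and let the command-line layer
stay thin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import encode, metrics, reconstruct, segmentation
from .core import GrayscaleVolume, MaskVolume, ProjectionImage
from .metrics import MetricsReport
from .phantom import PhantomCase
from .reconstruct import CylinderMask
from .segmentation import ModelConfig, PredictionMask, UNetSegmenter
from .structio import GridSpec

PLANES = ("coronal", "sagittal")


@dataclass
class EncodedCase:
    """All encoded representations of one case."""

    case: PhantomCase
    input_volume: GrayscaleVolume        # 128^3, levels {0, 64, 128}
    target_volume: GrayscaleVolume       # 128^3, levels {0, 255}
    prostate_crop: MaskVolume            # prostate on the crop grid
    crop_grid: GridSpec
    original_grid: GridSpec
    proj_input: dict[str, ProjectionImage]
    proj_target: dict[str, ProjectionImage]


def encode_case(case: PhantomCase,
                margin: int = encode.CROP_INFERIOR_MARGIN) -> EncodedCase:
    """Run the full data-creation stage on one case."""
    bladder = encode.resample_isotropic(case.bladder)
    prostate = encode.resample_isotropic(case.prostate)
    urethra = encode.resample_isotropic(case.urethra)

    input_vol = encode.encode_input(bladder, prostate)
    target_vol = encode.encode_target(urethra)

    start = encode.crop_window(prostate, margin=margin)
    input_crop = encode.apply_window(input_vol, start)
    target_crop = encode.apply_window(target_vol, start)
    prostate_crop = encode.window_mask(prostate, start)

    return EncodedCase(
        case=case,
        input_volume=input_crop,
        target_volume=target_crop,
        prostate_crop=prostate_crop,
        crop_grid=GridSpec.of(prostate_crop),
        original_grid=GridSpec.of(case.prostate),
        proj_input={p: encode.project(input_crop, p) for p in PLANES},
        proj_target={p: encode.project(target_crop, p) for p in PLANES},
    )


def reconstruct_case(enc: EncodedCase,
                     pred_coronal: PredictionMask | None = None,
                     pred_sagittal: PredictionMask | None = None,
                     pred_volume: PredictionMask | None = None,
                     diameter_mm: float = reconstruct.DEFAULT_DIAMETER_MM
                     ) -> CylinderMask:
    """Coordinates -> gap filling -> cylinder -> original grid."""
    prostate_z = reconstruct.prostate_slice_range(enc.prostate_crop)
    if pred_volume is not None:
        series = reconstruct.coords_from_volume(pred_volume, prostate_z)
    else:
        series = reconstruct.coords_from_projections(
            pred_coronal, pred_sagittal, prostate_z)
    series = reconstruct.fill_missing(series)
    cyl = reconstruct.build_cylinder(series, diameter_mm, grid=enc.crop_grid)
    return reconstruct.resample_to_original(cyl, enc.original_grid)


def evaluate_case(recon: CylinderMask, case: PhantomCase,
                  radii=metrics.DEFAULT_RADII,
                  case_id: str = "") -> MetricsReport:
    """Mask-based evaluation against the case's ground-truth urethra."""
    return metrics.report(recon.mask, case.urethra, case.prostate,
                          radii=radii, case_id=case_id)


def cld_vs_analytic(recon: CylinderMask, case: PhantomCase,
                    region: str = "whole") -> float:
    """CLD of the reconstruction against the analytic centerline (mm)."""
    pred_cl = metrics.extract_centerline(recon.mask)
    return metrics.cld(pred_cl, case.true_centerline, region=region,
                       prostate=case.prostate)


# ---------------------------------------------------------------------------
# oracle-backed runs (no training)


def run_oracle_case(case: PhantomCase, mode: str = "2d",
                    case_id: str = "") -> tuple[MetricsReport, float]:
    """One case through encoding, the oracle backend, and reconstruction.

    Returns the mask-based report and the CLD against the analytic
    centerline.
    """
    enc = encode_case(case)
    if mode == "3d":
        pred = segmentation.oracle_predict_volume(case, enc.crop_grid)
        recon = reconstruct_case(enc, pred_volume=pred)
    else:
        cor = segmentation.oracle_predict_projection(case, enc.crop_grid,
                                                     "coronal")
        sag = segmentation.oracle_predict_projection(case, enc.crop_grid,
                                                     "sagittal")
        recon = reconstruct_case(enc, pred_coronal=cor, pred_sagittal=sag)
    return (evaluate_case(recon, case, case_id=case_id),
            cld_vs_analytic(recon, case))


def run_oracle_population(cases: list[PhantomCase],
                          mode: str = "2d") -> pd.DataFrame:
    """Oracle pipeline over a population; one row per case."""
    rows = []
    for i, case in enumerate(cases):
        rep, cld_true = run_oracle_case(case, mode=mode, case_id=f"case_{i:03d}")
        row = rep.to_dict()
        row["cld_vs_analytic_mm"] = cld_true
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# learned 2D pipeline


def projection_dataset(encoded: list[EncodedCase], plane: str
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Stack one plane's (input, target) projection pairs as arrays."""
    if not encoded:
        from .core import ConfigurationError
        raise ConfigurationError("no cases in this partition")
    X = np.stack([e.proj_input[plane].intensities for e in encoded])
    y = np.stack([e.proj_target[plane].intensities > 127 for e in encoded])
    return X.astype(np.float32), y


def train_2d(train_encoded: list[EncodedCase],
             val_encoded: list[EncodedCase],
             config: ModelConfig) -> dict[str, UNetSegmenter]:
    """Train the coronal + sagittal model pair (always both, as a unit)."""
    models = {}
    for plane in PLANES:
        X, y = projection_dataset(train_encoded, plane)
        Xv, yv = projection_dataset(val_encoded, plane)
        models[plane] = segmentation.train(
            {"train": (X, y), "validation": (Xv, yv)}, config)
    return models


def predict_and_reconstruct_2d(models: dict[str, UNetSegmenter],
                               enc: EncodedCase) -> CylinderMask:
    preds = {plane: segmentation.predict(models[plane],
                                         enc.proj_input[plane])
             for plane in PLANES}
    return reconstruct_case(enc, pred_coronal=preds["coronal"],
                            pred_sagittal=preds["sagittal"])


def parameter_recovery_experiment(seed: int = 0, n_train: int = 60,
                                  n_val: int = 8, n_test: int = 20,
                                  max_epochs: int = 15
                                  ) -> tuple[pd.DataFrame, dict[str, UNetSegmenter]]:
    """Scaled-down end-to-end learning run on synthetic phantoms.

    Samples a fresh population, trains the reduced coronal + sagittal 2D
    models on ``n_train`` cases (validation drives checkpoint selection),
    and evaluates the full reconstruction on ``n_test`` held-out cases.
    Returns the per-case metrics table and the trained models.
    """
    from . import phantom
    from .segmentation import make_split

    n = n_train + n_val + n_test
    cases = phantom.sample_population(n, seed=seed)
    split = make_split(list(range(n)),
                       fractions=(n_train / n, n_val / n, n_test / n),
                       seed=seed + 1)
    encoded = [encode_case(c) for c in cases]
    config = ModelConfig.tiny_2d(seed=seed, max_epochs=max_epochs)
    models = train_2d([encoded[i] for i in split.train],
                      [encoded[i] for i in split.validation], config)
    frame = evaluate_learned_2d(models, [encoded[i] for i in split.test])
    return frame, models


def evaluate_learned_2d(models: dict[str, UNetSegmenter],
                        test_encoded: list[EncodedCase]) -> pd.DataFrame:
    rows = []
    for i, enc in enumerate(test_encoded):
        recon = predict_and_reconstruct_2d(models, enc)
        rep = evaluate_case(recon, enc.case, case_id=f"test_{i:03d}")
        row = rep.to_dict()
        row["cld_vs_analytic_mm"] = cld_vs_analytic(recon, enc.case)
        rows.append(row)
    return pd.DataFrame(rows)
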