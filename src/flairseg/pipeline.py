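"""End-to-end composition: phantoms -> preprocessing -> training -> evaluation.

This module wires the library stages into the reference synthetic
experiment: generate a cohort of FLAIR-like phantoms, bias-correct and
Nyul-standardize them (standard scale fit on the training partition only),
train the autoencoder on class-balanced ROIs, then segment the held-out
cases and score them against the known truth. It exists so the command
line, the test suite and reproduction scripts all run the identical
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autoencoder import ModelConfig, TrainedModel, build_model, predict_volume, sample_rois, train_model
from .metrics import MetricsReport, evaluate_cohort
from .phantom import Case, Cohort, PhantomSpec, derive_seed, generate_cohort
from .postprocess import segment
from .preprocess import (
    StandardizationModel,
    apply_standardization,
    correct_bias,
    fit_bias_field,
    fit_standardization,
)
from .volumes import BinaryMask

__all__ = ["ExperimentConfig", "ExperimentResult", "preprocess_cohort", "run_synthetic_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Conditions of the reference synthetic segmentation experiment.

    Defaults are the desk-scale study conditions: 20 phantoms of
    64 x 64 x 24 voxels with 1-2 lesions each, mild bias (amplitude 1.2)
    and low noise (SD 4 on a tissue baseline of 100); 5000 training tiles
    of 10 x 10; 30 epochs; threshold 0.5 and minimum component size 11
    (components of <= 10 voxels removed).
    """

    n_cases: int = 20
    train_fraction: float = 0.75
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_rois: int = 5000
    tile_size: int = 10
    tumor_fraction: float = 0.5
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    bias_order: int = 2
    threshold: float = 0.5
    min_voxels: int = 10


@dataclass
class ExperimentResult:
    cohort: Cohort
    model: TrainedModel
    standardization: StandardizationModel
    predictions: list[BinaryMask]
    report: MetricsReport

    @property
    def mean_test_dice(self) -> float:
        return float(self.report.per_case["dice"].mean())


def preprocess_cohort(
    cohort: Cohort, bias_order: int = 2, std_model: StandardizationModel | None = None
) -> tuple[Cohort, StandardizationModel]:
    """Bias-correct every case, then standardize intensities.

    The standard scale is fit on the training partition only (unless a
    fitted model is supplied) and applied to every case, mirroring how a
    deployed pipeline treats unseen volumes.
    """
    corrected: list[Case] = []
    for case in cohort.cases:
        f = fit_bias_field(case.volume, case.brain, order=bias_order)
        corrected.append(
            Case(
                case_id=case.case_id,
                volume=correct_bias(case.volume, f),
                truth=case.truth,
                brain=case.brain,
                seed=case.seed,
            )
        )
    if std_model is None:
        train_cases = [corrected[i] for i in cohort.train_idx]
        std_model = fit_standardization(
            [c.volume for c in train_cases], [c.brain for c in train_cases]
        )
    standardized = [
        Case(
            case_id=c.case_id,
            volume=apply_standardization(c.volume, c.brain, std_model),
            truth=c.truth,
            brain=c.brain,
            seed=c.seed,
        )
        for c in corrected
    ]
    return (
        Cohort(
            cases=standardized,
            train_idx=list(cohort.train_idx),
            test_idx=list(cohort.test_idx),
            master_seed=cohort.master_seed,
        ),
        std_model,
    )


def run_synthetic_experiment(seed: int, cfg: ExperimentConfig | None = None) -> ExperimentResult:
    """Run the full reference experiment; every stage is seeded from ``seed``."""
    cfg = cfg or ExperimentConfig()
    cohort = generate_cohort(cfg.n_cases, cfg.phantom, cfg.train_fraction, seed=seed)
    cohort, std_model = preprocess_cohort(cohort, bias_order=cfg.bias_order)
    rois = sample_rois(
        cohort.train,
        n_total=cfg.n_rois,
        tile_size=cfg.tile_size,
        tumor_fraction=cfg.tumor_fraction,
        seed=derive_seed(seed, 10_001),
    )
    model = build_model(cfg.model, seed=derive_seed(seed, 10_002))
    train_model(
        model,
        rois,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        seed=derive_seed(seed, 10_003),
    )
    preds = [
        segment(model, case.volume, threshold=cfg.threshold, min_voxels=cfg.min_voxels)
        for case in cohort.test
    ]
    report = evaluate_cohort(
        preds,
        [c.truth for c in cohort.test],
        case_ids=[c.case_id for c in cohort.test],
    )
    return ExperimentResult(
        cohort=cohort,
        model=model,
        standardization=std_model,
        predictions=preds,
        report=report,
    )
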