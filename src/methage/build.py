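"""Training recipe for a multi-tissue DNAm clock and its robustness study.

Pipeline: tissue-stratified 80/20 split -> lambda path -> stratified K-fold
CV on the training split -> final elastic-net refit at the MSE-minimizing
penalty -> clock = the nonzero-coefficient sites with their weights,
intercept and per-site training means. The robustness study repeats the whole
recipe under different split seeds and counts how often each site is
selected.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .enet import cross_validate, fit_elastic_net, lambda_path, standardize
from .predict import predict_age
from .qc import stratified_split
from .stats import TestResult, mann_whitney_u
from .types import (
    AgePrediction,
    ClockDefinition,
    ClockEntry,
    CpGSite,
    MethylationMatrix,
    SampleMetadata,
    TransformSpec,
)

__all__ = [
    "TrainConfig",
    "TrainingReport",
    "RobustnessResult",
    "train_clock",
    "evaluate_clock",
    "resample_clocks",
    "robustness_stats",
]

RESPONSE_SCALES = ("linear_days", "log_days")


@dataclass(frozen=True)
class TrainConfig:
    test_fraction: float = 0.2
    n_folds: int = 10
    l1_ratio: float = 0.5
    seed: int = 0
    response_scale: str = "linear_days"
    n_lambda: int = 100
    lambda_eps: float = 1e-3
    # coefficient-update tolerance; responses are on the days scale, so 1e-4
    # is far below any meaningful precision while keeping CV affordable
    tol: float = 1e-4
    max_iter: int = 10000
    min_site_fraction: float = 0.9
    #: "min" picks the MSE-minimizing penalty; "1se" the largest penalty
    #: within one standard error of it (sparser support)
    lambda_selection: str = "min"

    def __post_init__(self) -> None:
        if self.response_scale not in RESPONSE_SCALES:
            raise ValueError(f"unknown response_scale {self.response_scale!r}")
        if self.lambda_selection not in ("min", "1se"):
            raise ValueError(f"unknown lambda_selection {self.lambda_selection!r}")


@dataclass
class TrainingReport:
    clock_name: str
    n_train: int
    n_test: int
    mae_train: float
    mae_test: float
    r2_train: float
    r2_test: float
    per_tissue_mae_test: Dict[str, float]
    best_lambda: float
    l1_ratio: float
    n_nonzero_sites: int
    seed: int
    train_ids: List[str] = field(default_factory=list)
    test_ids: List[str] = field(default_factory=list)
    train_predictions: Dict[str, float] = field(default_factory=dict)
    test_predictions: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "clock_name": self.clock_name,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "mae_train_days": self.mae_train,
            "mae_test_days": self.mae_test,
            "r2_train": self.r2_train,
            "r2_test": self.r2_test,
            "per_tissue_mae_test": self.per_tissue_mae_test,
            "best_lambda": self.best_lambda,
            "l1_ratio": self.l1_ratio,
            "n_nonzero_sites": self.n_nonzero_sites,
            "seed": self.seed,
        }


def _mae_r2(predicted: np.ndarray, actual: np.ndarray) -> Tuple[float, float]:
    resid = predicted - actual
    mae = float(np.abs(resid).mean())
    ss_res = float(resid @ resid)
    centered = actual - actual.mean()
    ss_tot = float(centered @ centered)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return mae, r2


def train_clock(
    matrix: MethylationMatrix,
    config: TrainConfig = TrainConfig(),
    name: str = "trained_clock",
) -> Tuple[ClockDefinition, TrainingReport]:
    """Train a clock on a fully observed methylation matrix."""
    if not matrix.fully_observed():
        raise ValueError(
            "training requires a fully observed matrix; apply common_sites first"
        )
    ages = matrix.ages
    if len(np.unique(ages)) < 2:
        raise ValueError("degenerate response: all chronological ages identical")

    train_ids, test_ids = stratified_split(
        matrix.samples, test_fraction=config.test_fraction, seed=config.seed
    )
    train_m = matrix.subset_samples(train_ids)
    test_m = matrix.subset_samples(test_ids) if test_ids else None

    X = train_m.pct
    y_days = train_m.ages
    y = np.log(y_days) if config.response_scale == "log_days" else y_days

    Xs, _, _ = standardize(X)
    grid = lambda_path(
        Xs, y - y.mean(), l1_ratio=config.l1_ratio,
        n_lambda=config.n_lambda, eps=config.lambda_eps,
    )
    cv = cross_validate(
        X, y, strata=train_m.tissues, n_folds=config.n_folds,
        l1_ratio=config.l1_ratio, lambda_grid=grid, seed=config.seed,
        tol=config.tol, max_iter=config.max_iter,
    )
    chosen_lambda = (
        cv.best_lambda_1se() if config.lambda_selection == "1se" else cv.best_lambda
    )
    fit = fit_elastic_net(
        X, y, chosen_lambda, config.l1_ratio, tol=config.tol, max_iter=config.max_iter
    )
    nonzero = fit.nonzero_indices
    if nonzero.size == 0:
        raise ValueError("selected penalty left no sites in the model")

    transform = (
        TransformSpec("exp_linear", {"a": 1.0, "b": 0.0})
        if config.response_scale == "log_days"
        else TransformSpec()
    )
    entries = [
        ClockEntry(
            site=train_m.sites[j],
            weight=float(fit.coefficients[j]),
            train_mean=float(X[:, j].mean()),
        )
        for j in nonzero
    ]
    clock = ClockDefinition(
        name=name,
        entries=entries,
        intercept=float(fit.intercept),
        transform=transform,
        min_site_fraction=config.min_site_fraction,
    )

    train_preds = predict_age(clock, train_m)
    train_pred = np.array([p.predicted_age_days for p in train_preds])
    mae_train, r2_train = _mae_r2(train_pred, train_m.ages)
    if test_m is not None and test_m.n_samples:
        test_preds = predict_age(clock, test_m)
        test_pred = np.array([p.predicted_age_days for p in test_preds])
        mae_test, r2_test = _mae_r2(test_pred, test_m.ages)
        per_tissue: Dict[str, float] = {}
        for tissue in sorted(set(test_m.tissues)):
            rows = [i for i, t in enumerate(test_m.tissues) if t == tissue]
            per_tissue[tissue] = float(
                np.abs(test_pred[rows] - test_m.ages[rows]).mean()
            )
        test_predictions = {
            p.sample_id: p.predicted_age_days for p in test_preds
        }
    else:
        mae_test = r2_test = float("nan")
        per_tissue = {}
        test_predictions = {}

    report = TrainingReport(
        clock_name=name,
        n_train=len(train_ids),
        n_test=len(test_ids),
        mae_train=mae_train,
        mae_test=mae_test,
        r2_train=r2_train,
        r2_test=r2_test,
        per_tissue_mae_test=per_tissue,
        best_lambda=chosen_lambda,
        l1_ratio=config.l1_ratio,
        n_nonzero_sites=len(entries),
        seed=config.seed,
        train_ids=train_ids,
        test_ids=test_ids,
        train_predictions={p.sample_id: p.predicted_age_days for p in train_preds},
        test_predictions=test_predictions,
    )
    return clock, report


def evaluate_clock(
    clock: ClockDefinition,
    matrix: MethylationMatrix,
    subset: Optional[Sequence[str]] = None,
    missing_policy: Optional[str] = None,
) -> dict:
    """MAE (days), R^2, per-tissue MAE and n for a clock on (a subset of) a
    cohort. Predictions flagged invalid by the coverage rule are excluded."""
    target = matrix if subset is None else matrix.subset_samples(subset)
    if target.n_samples == 0:
        raise ValueError("evaluation subset is empty")
    preds = predict_age(clock, target, missing_policy=missing_policy)
    valid = [(p, meta) for p, meta in zip(preds, target.samples) if p.valid]
    if not valid:
        raise ValueError(
            f"no valid predictions: 0/{target.n_samples} samples reach the "
            f"clock's coverage threshold {clock.min_site_fraction}"
        )
    predicted = np.array([p.predicted_age_days for p, _ in valid])
    actual = np.array([meta.age_days for _, meta in valid])
    mae, r2 = _mae_r2(predicted, actual)
    per_tissue: Dict[str, float] = {}
    tissues = [meta.tissue for _, meta in valid]
    for tissue in sorted(set(tissues)):
        rows = [i for i, t in enumerate(tissues) if t == tissue]
        per_tissue[tissue] = float(np.abs(predicted[rows] - actual[rows]).mean())
    return {
        "mae_days": mae,
        "r2": r2,
        "per_tissue_mae": per_tissue,
        "n": len(valid),
        "n_invalid": target.n_samples - len(valid),
    }


@dataclass
class RobustnessResult:
    n_resamples: int
    site_counts: Dict[CpGSite, int]
    clock_summaries: List[dict]
    base_seed: int
    n_failed: int = 0

    def counts_for(self, sites: Sequence[CpGSite]) -> np.ndarray:
        return np.array([self.site_counts.get(s, 0) for s in sites], dtype=float)


def resample_clocks(
    matrix: MethylationMatrix,
    n_resamples: int = 100,
    base_seed: int = 0,
    config: TrainConfig = TrainConfig(),
) -> RobustnessResult:
    """Repeat the training recipe under varying split seeds (base_seed + i)
    and count per-site appearances across the resulting clocks. A failed fit
    is recorded, skipped, and the denominator adjusted."""
    site_counts: Dict[CpGSite, int] = {}
    summaries: List[dict] = []
    n_failed = 0
    for i in range(n_resamples):
        seed = base_seed + i
        try:
            clock, report = train_clock(
                matrix,
                config=TrainConfig(**{**config.__dict__, "seed": seed}),
                name=f"resample_{i}",
            )
        except ValueError as exc:
            warnings.warn(f"resample {i} (seed {seed}) failed: {exc}")
            n_failed += 1
            continue
        for site in clock.sites:
            site_counts[site] = site_counts.get(site, 0) + 1
        summaries.append(
            {
                "resample": i,
                "seed": seed,
                "n_sites": len(clock),
                "mae_test_days": report.mae_test,
                "best_lambda": report.best_lambda,
            }
        )
    return RobustnessResult(
        n_resamples=n_resamples - n_failed,
        site_counts=site_counts,
        clock_summaries=summaries,
        base_seed=base_seed,
        n_failed=n_failed,
    )


def robustness_stats(
    robustness: RobustnessResult,
    reference_clock: ClockDefinition,
    highlight_sites: Sequence[CpGSite],
) -> dict:
    """Enrichment of a highlighted subset of reference-clock sites in the
    resample appearance counts (two-sample rank-sum, two-tailed) plus the
    squared Pearson correlation between |weight| and appearance count."""
    ref_sites = reference_clock.sites
    highlight = set(highlight_sites)
    if not highlight:
        raise ValueError("highlight set is empty")
    if not highlight <= set(ref_sites):
        raise ValueError("highlight sites must be a subset of the reference clock")
    if highlight == set(ref_sites):
        raise ValueError("highlight set equals the full reference clock")

    counts = robustness.counts_for(ref_sites)
    is_highlight = np.array([s in highlight for s in ref_sites])
    enrichment = mann_whitney_u(counts[is_highlight], counts[~is_highlight])

    abs_w = np.abs(reference_clock.weights)
    if np.ptp(abs_w) == 0 or np.ptp(counts) == 0:
        warnings.warn("zero variance in weights or counts; correlation undefined")
        weight_frequency = {"r2": float("nan"), "p_value": float("nan")}
    else:
        r, p = sps.pearsonr(abs_w, counts)
        weight_frequency = {"r2": float(r**2), "p_value": float(p), "r": float(r)}
    return {"enrichment": enrichment, "weight_frequency": weight_frequency}
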