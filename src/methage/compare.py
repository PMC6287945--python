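"""Comparing clocks, testing group differences and intervention effects.

All p-values are two-tailed and reported raw; Benjamini-Hochberg adjustment
is an optional extra column, never a replacement.
"""
from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import TestResult, bartlett_test, benjamini_hochberg, mann_whitney_u
from .types import AgePrediction, ClockDefinition

__all__ = [
    "compare_clock_errors",
    "residual_slope_test",
    "group_regression_comparison",
    "intervention_effect",
    "clock_correlations",
    "weight_distribution_tests",
    "delta_ages",
]


def _aligned_predictions(
    predictions: Dict[str, Sequence[AgePrediction]], require_valid: bool = True
) -> Tuple[List[str], Dict[str, Dict[str, AgePrediction]]]:
    """Sample ids shared by all clocks (optionally valid everywhere), plus a
    clock -> sample -> prediction lookup."""
    lookup = {
        clock: {p.sample_id: p for p in preds} for clock, preds in predictions.items()
    }
    shared = set.intersection(*(set(d) for d in lookup.values()))
    if require_valid:
        shared = {
            sid for sid in shared if all(lookup[c][sid].valid for c in lookup)
        }
    return sorted(shared), lookup


def compare_clock_errors(
    predictions: Dict[str, Sequence[AgePrediction]],
    ages: Dict[str, float],
    require_valid: bool = True,
    bh_adjust: bool = False,
) -> dict:
    """Per-clock MAE on shared samples plus all pairwise two-tailed MWU tests
    on the per-sample absolute errors."""
    if len(predictions) < 2:
        raise ValueError("need at least two clocks to compare")
    shared, lookup = _aligned_predictions(predictions, require_valid)
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared valid sample(s) across clocks; need >= 2"
        )
    clocks = sorted(predictions)
    abs_err = pd.DataFrame(
        {
            clock: [
                abs(lookup[clock][sid].predicted_age_days - ages[sid]) for sid in shared
            ]
            for clock in clocks
        },
        index=shared,
    )
    mae = abs_err.mean(axis=0)
    pairwise: List[dict] = []
    for i, ca in enumerate(clocks):
        for cb in clocks[i + 1 :]:
            res = mann_whitney_u(abs_err[ca].to_numpy(), abs_err[cb].to_numpy())
            pairwise.append(
                {
                    "clock_a": ca,
                    "clock_b": cb,
                    "mae_a": float(mae[ca]),
                    "mae_b": float(mae[cb]),
                    "U": res.statistic,
                    "p_value": res.p_value,
                }
            )
    if bh_adjust and pairwise:
        adj = benjamini_hochberg([row["p_value"] for row in pairwise])
        for row, q in zip(pairwise, adj):
            row["p_bh"] = float(q)
    return {
        "n_shared_samples": len(shared),
        "mae_days": mae.to_dict(),
        "abs_errors": abs_err,
        "pairwise": pairwise,
    }


def residual_slope_test(
    predictions: Sequence[float], chronological_ages: Sequence[float]
) -> dict:
    """OLS of (predicted - chronological) on chronological age with a t-test
    of the slope against zero. A clock without systematic age-dependent bias
    has slope indistinguishable from 0 (equivalently, slope 1 for predicted
    vs chronological)."""
    pred = np.asarray(predictions, dtype=float)
    age = np.asarray(chronological_ages, dtype=float)
    if len(pred) != len(age):
        raise ValueError("length mismatch")
    if len(pred) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(age) == 0:
        raise ValueError("chronological ages are constant")
    resid = pred - age
    fit = sps.linregress(age, resid)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_slope_vs_0": float(fit.pvalue),
        "stderr": float(fit.stderr),
        "n": len(pred),
    }


def group_regression_comparison(
    group1: Tuple[Sequence[float], Sequence[float]],
    group2: Tuple[Sequence[float], Sequence[float]],
) -> dict:
    """Compare predicted-age-vs-age regressions between two groups.

    Slope difference comes from the group x age interaction term in a
    combined OLS; intercept difference from the group indicator in the
    additive (no-interaction) model. Each group supplies (ages, predictions).
    """
    out: Dict[str, float] = {}
    ages, preds, indicator = [], [], []
    for g, (a, p) in enumerate((group1, group2)):
        a = np.asarray(a, dtype=float)
        p = np.asarray(p, dtype=float)
        if len(a) != len(p):
            raise ValueError("ages/predictions length mismatch")
        if len(a) < 3:
            raise ValueError("each group needs >= 3 samples")
        ages.append(a)
        preds.append(p)
        indicator.append(np.full(len(a), float(g)))
    age = np.concatenate(ages)
    pred = np.concatenate(preds)
    grp = np.concatenate(indicator)
    if np.ptp(age) == 0:
        raise ValueError("collinear design: constant age")

    X_int = sm.add_constant(np.column_stack([age, grp, age * grp]))
    model_int = sm.OLS(pred, X_int).fit()
    X_add = sm.add_constant(np.column_stack([age, grp]))
    model_add = sm.OLS(pred, X_add).fit()

    out["slope_difference"] = float(model_int.params[3])
    out["p_slope_difference"] = float(model_int.pvalues[3])
    out["intercept_difference"] = float(model_add.params[2])
    out["p_intercept_difference"] = float(model_add.pvalues[2])
    out["n_group1"] = len(ages[0])
    out["n_group2"] = len(ages[1])
    return out


def delta_ages(predictions: Sequence[AgePrediction]) -> np.ndarray:
    deltas = [p.delta_age_days for p in predictions]
    if any(d is None for d in deltas):
        missing = [p.sample_id for p in predictions if p.delta_age_days is None]
        raise ValueError(f"delta_age undefined for samples: {missing[:10]}")
    return np.asarray(deltas, dtype=float)


def intervention_effect(
    control: Sequence[AgePrediction], treated: Sequence[AgePrediction]
) -> TestResult:
    """Two-tailed MWU on the delta-age (DNAm age minus chronological age)
    distributions of control vs treated samples. A lifespan-extending
    intervention is expected to shift treated delta-ages negative."""
    if not control or not treated:
        raise ValueError("both groups must be nonempty")
    d_control = delta_ages(control)
    d_treated = delta_ages(treated)
    res = mann_whitney_u(d_treated, d_control)
    shift = float(np.median(d_treated) - np.median(d_control))
    return TestResult(
        test_name="intervention_effect_mwu",
        statistic=res.statistic,
        p_value=res.p_value,
        n_per_group=(len(control), len(treated)),
        effect=shift,
        effect_direction=int(np.sign(shift)),
        details=res.details,
    )


def clock_correlations(
    predictions: Dict[str, Sequence[AgePrediction]],
    ages: Dict[str, float],
    require_valid: bool = True,
) -> dict:
    """Pearson correlation matrices of DNAm ages and of delta-ages across
    clocks, on the shared (valid) samples."""
    shared, lookup = _aligned_predictions(predictions, require_valid)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    clocks = sorted(predictions)
    dnam = np.array(
        [[lookup[c][sid].predicted_age_days for sid in shared] for c in clocks]
    )
    chron = np.array([ages[sid] for sid in shared])
    delta = dnam - chron

    def corr(matrix: np.ndarray) -> pd.DataFrame:
        out = np.eye(len(clocks))
        for i in range(len(clocks)):
            for j in range(i + 1, len(clocks)):
                if np.std(matrix[i]) == 0 or np.std(matrix[j]) == 0:
                    warnings.warn(
                        f"zero-variance predictions for {clocks[i]} or {clocks[j]}; "
                        "correlation set to NA"
                    )
                    out[i, j] = out[j, i] = np.nan
                else:
                    out[i, j] = out[j, i] = np.corrcoef(matrix[i], matrix[j])[0, 1]
        return pd.DataFrame(out, index=clocks, columns=clocks)

    return {
        "n_shared_samples": len(shared),
        "dnam_age_r": corr(dnam),
        "delta_age_r": corr(delta),
    }


def weight_distribution_tests(clocks: Sequence[ClockDefinition]) -> dict:
    """Zero-symmetry of each clock's weights (two-tailed MWU of positive
    weights vs absolute values of negative weights) and variance homogeneity
    across clocks (Bartlett)."""
    symmetry: Dict[str, Optional[TestResult]] = {}
    for clock in clocks:
        w = clock.weights
        pos = w[w > 0]
        neg = -w[w < 0]
        if len(pos) < 2 or len(neg) < 2:
            warnings.warn(
                f"clock {clock.name!r} has a one-signed weight distribution; "
                "symmetry test skipped"
            )
            symmetry[clock.name] = None
            continue
        symmetry[clock.name] = mann_whitney_u(pos, neg)
    result: Dict[str, object] = {"symmetry": symmetry}
    if len(clocks) >= 2:
        result["variance_homogeneity"] = bartlett_test([c.weights for c in clocks])
    return result
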