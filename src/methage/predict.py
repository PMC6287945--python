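"""Apply a clock definition to methylation data.

score = intercept + sum_i w_i * m_i over clock sites (m_i in percent),
age = transform(score). Clock sites missing from a sample are imputed
according to the missing-site policy; predictions whose clock-site coverage
falls below the clock's ``min_site_fraction`` are flagged invalid but still
returned so downstream filters can decide.
"""
from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AgePrediction,
    ClockDefinition,
    MethylationMatrix,
    SampleMethylome,
    apply_transform,
)

__all__ = ["predict_age", "clock_coverage", "predictions_to_frame"]

MISSING_POLICIES = ("train_mean", "global_mean_50", "strict")


def _resolve_policy(clock: ClockDefinition, policy: Optional[str]) -> str:
    if policy is None:
        return "train_mean" if clock.train_means is not None else "global_mean_50"
    if policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {policy!r}")
    if policy == "train_mean" and clock.train_means is None:
        raise ValueError(
            f"clock {clock.name!r} stores no training means; cannot use 'train_mean'"
        )
    return policy


def _predict_one(
    clock: ClockDefinition,
    sample_id: str,
    observed_pct: np.ndarray,  # len(clock), NaN where missing
    policy: str,
    age_days: Optional[float],
) -> AgePrediction:
    weights = clock.weights
    missing = np.isnan(observed_pct)
    if policy == "strict" and missing.any():
        names = [
            f"{e.site.chrom}:{e.site.pos}"
            for e, miss in zip(clock.entries, missing)
            if miss
        ]
        raise ValueError(
            f"sample {sample_id!r} is missing {len(names)} clock site(s) under "
            f"strict policy: {', '.join(names[:10])}"
            + ("..." if len(names) > 10 else "")
        )
    m = observed_pct.copy()
    if missing.any():
        if policy == "train_mean":
            m[missing] = clock.train_means[missing]
        else:  # global_mean_50
            m[missing] = 50.0
    score = float(clock.intercept + weights @ m)
    n_covered = int((~missing).sum())
    fraction = n_covered / len(clock)
    return AgePrediction(
        sample_id=sample_id,
        predicted_age_days=float(apply_transform(score, clock.transform)),
        score=score,
        n_clock_sites_covered=n_covered,
        fraction_covered=fraction,
        valid=fraction >= clock.min_site_fraction,
        delta_age_days=None if age_days is None else
        float(apply_transform(score, clock.transform)) - age_days,
    )


def predict_age(
    clock: ClockDefinition,
    data: Union[MethylationMatrix, SampleMethylome],
    missing_policy: Optional[str] = None,
    ages: Optional[Dict[str, float]] = None,
) -> Union[List[AgePrediction], AgePrediction]:
    """Predict DNAm age for a matrix (list of predictions, in sample order)
    or a single methylome (one prediction).

    ``missing_policy`` defaults to ``train_mean`` when the clock stores
    training means, else ``global_mean_50``. ``ages`` optionally supplies
    chronological ages (sample_id -> days) to fill ``delta_age_days``; for a
    matrix, metadata ages are used automatically.
    """
    policy = _resolve_policy(clock, missing_policy)
    if isinstance(data, SampleMethylome):
        observed = np.full(len(clock), np.nan)
        for k, entry in enumerate(clock.entries):
            if entry.site in data.counts:
                observed[k] = data.pct(entry.site)
        age = None if ages is None else ages.get(data.sample_id)
        return _predict_one(clock, data.sample_id, observed, policy, age)

    matrix = data
    site_idx = matrix.site_index()
    cols = np.array([site_idx.get(e.site, -1) for e in clock.entries])
    present = cols >= 0
    preds: List[AgePrediction] = []
    for i, meta in enumerate(matrix.samples):
        observed = np.full(len(clock), np.nan)
        if present.any():
            vals = matrix.pct[i, cols[present]]
            obs_mask = matrix.mask[i, cols[present]]
            slot = np.flatnonzero(present)
            observed[slot[obs_mask]] = vals[obs_mask]
        age = meta.age_days if ages is None else ages.get(meta.sample_id, meta.age_days)
        preds.append(_predict_one(clock, meta.sample_id, observed, policy, age))
    return preds


def clock_coverage(
    clock: ClockDefinition,
    data: Union[MethylationMatrix, SampleMethylome, Sequence[SampleMethylome]],
) -> dict:
    """Per-sample clock-site coverage and the cohort median.

    Returns ``{"per_sample": {id: {"n_covered", "fraction"}},
    "median_n_covered", "median_fraction", "clock_size"}``.
    """
    clock_sites = clock.site_set()
    per_sample: Dict[str, dict] = {}

    def add(sample_id: str, n_covered: int) -> None:
        per_sample[sample_id] = {
            "n_covered": n_covered,
            "fraction": n_covered / len(clock),
        }

    if isinstance(data, SampleMethylome):
        add(data.sample_id, len(clock_sites & data.sites()))
    elif isinstance(data, MethylationMatrix):
        site_idx = data.site_index()
        cols = [site_idx[s] for s in clock_sites if s in site_idx]
        counts = data.mask[:, cols].sum(axis=1) if cols else np.zeros(data.n_samples, int)
        for meta, n in zip(data.samples, counts):
            add(meta.sample_id, int(n))
    else:
        for methylome in data:
            add(methylome.sample_id, len(clock_sites & methylome.sites()))

    n_values = [v["n_covered"] for v in per_sample.values()]
    return {
        "per_sample": per_sample,
        "median_n_covered": float(np.median(n_values)) if n_values else 0.0,
        "median_fraction": float(np.median(n_values)) / len(clock) if n_values else 0.0,
        "clock_size": len(clock),
    }


def predictions_to_frame(predictions: Sequence[AgePrediction]) -> pd.DataFrame:
    df = pd.DataFrame([p.as_dict() for p in predictions])
    return df[
        [
            "sample_id",
            "predicted_age_days",
            "score",
            "n_clock_sites_covered",
            "fraction_covered",
            "valid",
            "delta_age_days",
        ]
    ]
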