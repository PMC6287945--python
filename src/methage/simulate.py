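"""Age-structured synthetic RRBS cohorts.

Informative CpG sites drift linearly with age toward an intermediate
methylation state (50% by default): sites starting low gain methylation,
sites starting high lose it. Observed data are binomial read counts at
negative-binomial sequencing depth, with optional per-cell dropout, tissue
offsets and batch offsets on the mean scale. Everything is deterministic for
a fixed seed.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import write_bismark_coverage, write_metadata
from .types import (
    CpGSite,
    MethylationMatrix,
    SampleMetadata,
    SampleMethylome,
)

__all__ = ["SyntheticConfig", "S1", "simulate_cohort", "write_fixture_files"]

_AUTOSOMES = [f"chr{i}" for i in range(1, 20)]


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 100
    n_sites: int = 1000
    n_informative: int = 20
    age_range_days: Tuple[float, float] = (21.0, 1050.0)
    tissues: Tuple[str, ...] = ("blood", "liver", "lung", "cortex")
    tissue_offset_sd: float = 2.0
    tissue_affected_fraction: float = 0.1
    drift_target_pct: float = 50.0
    #: fraction of the baseline-to-target gap an informative site traverses
    #: over the full age range (drawn uniformly per site)
    drift_fraction_range: Tuple[float, float] = (0.5, 1.0)
    #: baseline methylation: "bimodal" mimics real CpG methylation (most
    #: sites near 0% or 100%), "uniform" spreads baselines over [5, 95]
    baseline_mode: str = "bimodal"
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    dropout_prob: float = 0.0
    n_batches: int = 1
    batch_offset_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_sites:
            raise ValueError("n_informative exceeds n_sites")
        if not 0.0 <= self.drift_target_pct <= 100.0:
            raise ValueError("drift_target_pct must be within [0, 100]")
        lo, hi = self.age_range_days
        if not 0 < lo < hi:
            raise ValueError("age_range_days must satisfy 0 < min < max")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be a probability")
        if not 0.0 <= self.tissue_affected_fraction <= 1.0:
            raise ValueError("tissue_affected_fraction must be a probability")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if not self.tissues:
            raise ValueError("at least one tissue required")
        if self.baseline_mode not in ("bimodal", "uniform"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Documented preset: the scale used for the pipeline parameter-recovery
#: checks (200 samples, 2000 sites, 40 age-informative, depth 30).
S1 = SyntheticConfig(
    n_samples=200,
    n_sites=2000,
    n_informative=40,
    mean_depth=30.0,
    depth_dispersion=5.0,
    dropout_prob=0.001,
    tissue_offset_sd=2.0,
    seed=1,
)


def _make_sites(n_sites: int) -> List[CpGSite]:
    sites = []
    for j in range(n_sites):
        chrom = _AUTOSOMES[j % len(_AUTOSOMES)]
        pos = 10_000 + 250 * (j // len(_AUTOSOMES))
        sites.append(CpGSite(chrom, pos))
    return sites


def simulate_cohort(
    config: SyntheticConfig,
) -> Tuple[MethylationMatrix, List[SampleMetadata], dict]:
    """Generate a cohort.

    Returns (matrix, metadata, truth) where truth holds the informative
    sites, their column indices and the true per-day slopes (percent/day,
    signed toward the drift target).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_sites

    ages = rng.uniform(*config.age_range_days, size=n)
    tissues = [config.tissues[i % len(config.tissues)] for i in range(n)]
    sexes = rng.choice(["male", "female"], size=n)
    batches = rng.integers(0, config.n_batches, size=n)
    metadata = [
        SampleMetadata(
            sample_id=f"S{i:04d}",
            tissue=tissues[i],
            age_days=float(ages[i]),
            sex=str(sexes[i]),
            strain="C57BL/6",
        )
        for i in range(n)
    ]

    sites = _make_sites(p)
    if config.baseline_mode == "bimodal":
        low = rng.random(p) < 0.5
        baseline = np.where(
            low, rng.uniform(2.0, 15.0, size=p), rng.uniform(85.0, 98.0, size=p)
        )
    else:
        baseline = rng.uniform(5.0, 95.0, size=p)
    informative_idx = np.sort(rng.choice(p, size=config.n_informative, replace=False))
    slopes = np.zeros(p)
    if config.n_informative:
        gap = config.drift_target_pct - baseline[informative_idx]
        gap = np.where(gap == 0, 1.0, gap)  # degenerate baseline exactly at target
        frac = rng.uniform(*config.drift_fraction_range, size=config.n_informative)
        slopes[informative_idx] = frac * gap / config.age_range_days[1]

    # mean percent methylation per cell, before noise
    mean = baseline[None, :] + np.outer(ages, slopes)

    if config.tissue_offset_sd > 0 and config.tissue_affected_fraction > 0:
        affected = rng.random(p) < config.tissue_affected_fraction
        for tissue in set(tissues):
            offs = np.where(
                affected, rng.normal(0.0, config.tissue_offset_sd, size=p), 0.0
            )
            rows = [i for i, t in enumerate(tissues) if t == tissue]
            mean[rows] += offs[None, :]
    if config.batch_offset_sd > 0 and config.n_batches > 1:
        for batch in range(config.n_batches):
            offs = rng.normal(0.0, config.batch_offset_sd, size=p)
            rows = np.flatnonzero(batches == batch)
            mean[rows] += offs[None, :]
    mean = np.clip(mean, 0.0, 100.0)

    nb_p = config.depth_dispersion / (config.depth_dispersion + config.mean_depth)
    depth = rng.negative_binomial(config.depth_dispersion, nb_p, size=(n, p))
    dropped = rng.random((n, p)) < config.dropout_prob
    mask = (depth >= 1) & ~dropped
    meth = rng.binomial(np.where(mask, depth, 0), mean / 100.0)

    pct = np.full((n, p), np.nan)
    pct[mask] = 100.0 * meth[mask] / depth[mask]
    coverage = np.where(mask, depth, 0).astype(np.int64)

    matrix = MethylationMatrix(
        samples=metadata, sites=sites, pct=pct, coverage=coverage, mask=mask
    )
    truth = {
        "informative_sites": [sites[j] for j in informative_idx],
        "site_indices": informative_idx,
        "slopes": slopes[informative_idx],
        "baseline": baseline,
        "mean": mean,
        "meth_counts": np.where(mask, meth, 0),
        "batches": batches,
    }
    return matrix, metadata, truth


def write_fixture_files(
    matrix: MethylationMatrix, directory, truth: Optional[dict] = None
) -> dict:
    """Write a cohort as per-sample bismark coverage files plus metadata.tsv.

    Read counts are reconstructed from pct and coverage (exact, since pct was
    computed from integer counts). Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sample_paths = {}
    for i, meta in enumerate(matrix.samples):
        counts = {}
        observed = np.flatnonzero(matrix.mask[i])
        for j in observed:
            cov = int(matrix.coverage[i, j])
            meth = int(round(matrix.pct[i, j] * cov / 100.0))
            counts[matrix.sites[j]] = (meth, cov - meth)
        methylome = SampleMethylome(sample_id=meta.sample_id, counts=counts)
        path = directory / f"{meta.sample_id}.cov"
        write_bismark_coverage(methylome, path)
        sample_paths[meta.sample_id] = path
    metadata_path = directory / "metadata.tsv"
    write_metadata(matrix.samples, metadata_path)
    if truth is not None:
        truth_path = directory / "truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("chrom\tpos\ttrue_slope_pct_per_day\n")
            for site, slope in zip(truth["informative_sites"], truth["slopes"]):
                fh.write(f"{site.chrom}\t{site.pos}\t{slope!r}\n")
    return {"samples": sample_paths, "metadata": metadata_path}
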