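"""Sample- and site-level inclusion filters and the tissue-stratified split.

Threshold semantics are strict on both sides: a sample is dropped when it has
*fewer than* ``min_sites`` covered CpGs, and a site is dropped when it is
low-coverage in *more than* ``max_low_fraction`` of samples. Filters run
samples-first, then sites.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import MethylationMatrix, SampleMetadata, SampleMethylome

__all__ = [
    "QCReport",
    "filter_samples_by_site_count",
    "soft_coverage_cutoff",
    "common_sites",
    "stratified_split",
    "pca_outlier_flags",
]

MIN_SITES_DEFAULT = 2_000_000
MIN_COMMON_DEFAULT = 100_000


@dataclass
class QCReport:
    """Serializable record of one QC step."""

    step: str
    thresholds: Dict[str, float] = field(default_factory=dict)
    samples_in: List[str] = field(default_factory=list)
    samples_excluded: Dict[str, str] = field(default_factory=dict)  # id -> reason
    sites_before: Optional[int] = None
    sites_after: Optional[int] = None

    def __post_init__(self) -> None:
        overlap = set(self.samples_in) & set(self.samples_excluded)
        if overlap:
            raise ValueError(f"samples both kept and excluded: {sorted(overlap)}")

    @property
    def n_samples_total(self) -> int:
        return len(self.samples_in) + len(self.samples_excluded)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "thresholds": self.thresholds,
            "samples_in": self.samples_in,
            "samples_excluded": self.samples_excluded,
            "sites_before": self.sites_before,
            "sites_after": self.sites_after,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def filter_samples_by_site_count(
    methylomes: Sequence[SampleMethylome],
    min_sites: int = MIN_SITES_DEFAULT,
    min_read_depth: int = 1,
) -> Tuple[List[SampleMethylome], QCReport]:
    """Drop samples with fewer than ``min_sites`` CpGs at depth >= ``min_read_depth``.

    The boundary is retained: exactly ``min_sites`` covered sites passes.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    kept: List[SampleMethylome] = []
    report = QCReport(
        step="filter_samples_by_site_count",
        thresholds={"min_sites": min_sites, "min_read_depth": min_read_depth},
    )
    for methylome in methylomes:
        n = methylome.n_sites_covered(min_read_depth)
        if n < min_sites:
            report.samples_excluded[methylome.sample_id] = (
                f"{n} sites covered at depth >= {min_read_depth} (< {min_sites})"
            )
        else:
            kept.append(methylome)
            report.samples_in.append(methylome.sample_id)
    if not kept:
        raise ValueError(
            f"all {len(methylomes)} samples excluded by the site-count filter; "
            f"report: {report.to_json()}"
        )
    return kept, report


def soft_coverage_cutoff(
    matrix: MethylationMatrix,
    min_cov: int = 5,
    max_low_fraction: float = 0.9,
) -> Tuple[MethylationMatrix, QCReport]:
    """Drop sites with coverage < ``min_cov`` in more than ``max_low_fraction`` of samples.

    Unobserved cells count as coverage 0. Strict '>' on the fraction: with 10
    samples and the 0.9 default, 9 low-coverage samples retains the site and
    10 drops it.
    """
    if matrix.n_samples == 0 or matrix.n_sites == 0:
        raise ValueError("matrix is empty")
    cov = np.where(matrix.mask, matrix.coverage, 0)
    n_low = (cov < min_cov).sum(axis=0)
    keep = ~(n_low > max_low_fraction * matrix.n_samples)
    report = QCReport(
        step="soft_coverage_cutoff",
        thresholds={"min_cov": min_cov, "max_low_fraction": max_low_fraction},
        samples_in=list(matrix.sample_ids),
        sites_before=matrix.n_sites,
        sites_after=int(keep.sum()),
    )
    if not keep.any():
        warnings.warn("soft_coverage_cutoff removed every site")
    return matrix.subset_sites(keep), report


def common_sites(
    matrix: MethylationMatrix, min_common: int = MIN_COMMON_DEFAULT
) -> Tuple[MethylationMatrix, QCReport]:
    """Restrict to sites observed in every sample.

    Errors unless the intersection is strictly larger than ``min_common``
    (set 0 to disable the check for toy inputs).
    """
    if matrix.n_samples == 0:
        raise ValueError("matrix is empty")
    keep = matrix.mask.all(axis=0)
    n_common = int(keep.sum())
    if min_common > 0 and n_common <= min_common:
        raise ValueError(
            f"only {n_common} sites are covered in all {matrix.n_samples} samples "
            f"(required: > {min_common})"
        )
    report = QCReport(
        step="common_sites",
        thresholds={"min_common": min_common},
        samples_in=list(matrix.sample_ids),
        sites_before=matrix.n_sites,
        sites_after=n_common,
    )
    return matrix.subset_sites(keep), report


def stratified_split(
    metadata: Sequence[SampleMetadata],
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify_key: str = "tissue",
) -> Tuple[List[str], List[str]]:
    """Split sample ids into train/test, stratified (by tissue by default).

    Within each stratum round(n * test_fraction) samples go to the test set;
    remainders go to training. Deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata: Dict[str, List[str]] = {}
    for meta in metadata:
        strata.setdefault(getattr(meta, stratify_key), []).append(meta.sample_id)
    train: List[str] = []
    test: List[str] = []
    for label in sorted(strata):
        ids = sorted(strata[label])
        if len(ids) == 1:
            warnings.warn(f"stratum {label!r} has a single sample; assigned to training")
            train.extend(ids)
            continue
        n_test = int(round(len(ids) * test_fraction))
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        test.extend(shuffled[:n_test])
        train.extend(shuffled[n_test:])
    return sorted(train), sorted(test)


def pca_outlier_flags(
    matrix: MethylationMatrix, k_mad: float = 5.0, n_components: int = 2
) -> Dict[str, bool]:
    """Optional replacement for figure-based batch exclusion: flag samples
    beyond ``k_mad`` median-absolute-deviations on the leading principal
    components of the fully observed matrix. OFF by default in pipelines.
    """
    if not matrix.fully_observed():
        raise ValueError("PCA outlier flagging requires a fully observed matrix")
    X = matrix.pct - matrix.pct.mean(axis=0)
    # economy SVD; scores = U * s
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    flags = np.zeros(matrix.n_samples, dtype=bool)
    for j in range(min(n_components, scores.shape[1])):
        col = scores[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        if mad == 0:
            continue
        flags |= np.abs(col - med) > k_mad * mad
    return dict(zip(matrix.sample_ids, flags.tolist()))
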