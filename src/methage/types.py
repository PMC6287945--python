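"""Core domain types shared across the toolkit.

Coordinates are 1-based inclusive throughout (genome-browser style, matching
bismark coverage output); BED input/output converts at the boundary.
Methylation levels are always *percent* (0-100), never fractions.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

#: Contigs excluded from clock construction by default (mitochondrial genome
#: and sex chromosomes).
DEFAULT_EXCLUDED_CONTIGS = frozenset({"chrM", "chrMT", "chrX", "chrY"})


def normalize_chrom(chrom: str) -> str:
    """Canonicalize a chromosome name to the ``chr``-prefixed form.

    ``"1"`` -> ``"chr1"``, ``"chr1"`` -> ``"chr1"``, ``"MT"`` -> ``"chrMT"``.
    """
    chrom = chrom.strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    if chrom.lower().startswith("chr"):
        return "chr" + chrom[3:]
    return "chr" + chrom


def _chrom_sort_key(chrom: str) -> Tuple[int, str, int]:
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (0, "", int(body))
    return (1, body, 0)


class CpGSite(NamedTuple):
    """A CpG dinucleotide anchored at the forward-strand cytosine (1-based)."""

    chrom: str
    pos: int

    @staticmethod
    def make(chrom: str, pos: int) -> "CpGSite":
        pos = int(pos)
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        return CpGSite(normalize_chrom(chrom), pos)

    def sort_key(self) -> Tuple[Tuple[int, str, int], int]:
        return (_chrom_sort_key(self.chrom), self.pos)

    def is_excluded(self, excluded: Iterable[str] = DEFAULT_EXCLUDED_CONTIGS) -> bool:
        return self.chrom in set(excluded)


def sort_sites(sites: Iterable[CpGSite]) -> List[CpGSite]:
    """Sites in (chrom, pos) order, chromosomes numerically where possible."""
    return sorted(sites, key=CpGSite.sort_key)


@dataclass
class SampleMethylome:
    """Per-sample methylated/unmethylated read counts at covered CpG sites."""

    sample_id: str
    counts: Dict[CpGSite, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, (meth, unmeth) in self.counts.items():
            if meth < 0 or unmeth < 0:
                raise ValueError(f"negative read count at {site}")
            if meth + unmeth < 1:
                raise ValueError(f"zero coverage stored at {site}")

    def __len__(self) -> int:
        return len(self.counts)

    def coverage(self, site: CpGSite) -> int:
        meth, unmeth = self.counts[site]
        return meth + unmeth

    def pct(self, site: CpGSite) -> float:
        meth, unmeth = self.counts[site]
        return 100.0 * meth / (meth + unmeth)

    def sites(self) -> set:
        return set(self.counts)

    def n_sites_covered(self, min_read_depth: int = 1) -> int:
        return sum(
            1 for meth, unmeth in self.counts.values() if meth + unmeth >= min_read_depth
        )

    def total_reads(self) -> int:
        return sum(meth + unmeth for meth, unmeth in self.counts.values())


VALID_SEXES = ("male", "female", "unknown")
UNTREATED = "untreated_wildtype"


@dataclass(frozen=True)
class SampleMetadata:
    """Cohort metadata for one sample."""

    sample_id: str
    tissue: str
    age_days: float
    sex: str = "unknown"
    strain: str = ""
    condition: str = UNTREATED

    def __post_init__(self) -> None:
        if not math.isfinite(self.age_days) or self.age_days <= 0:
            raise ValueError(
                f"age_days must be finite and positive for {self.sample_id!r}, "
                f"got {self.age_days}"
            )
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if self.condition != UNTREATED and not self.condition.startswith("intervention:"):
            raise ValueError(
                "condition must be 'untreated_wildtype' or 'intervention:<name>', "
                f"got {self.condition!r}"
            )

    @property
    def is_intervention(self) -> bool:
        return self.condition != UNTREATED


@dataclass
class MethylationMatrix:
    """Samples x sites percent methylation with parallel coverage and mask.

    ``pct`` holds NaN and ``coverage`` holds 0 wherever ``mask`` is False.
    """

    samples: List[SampleMetadata]
    sites: List[CpGSite]
    pct: np.ndarray
    coverage: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n, p = len(self.samples), len(self.sites)
        for name, arr in (("pct", self.pct), ("coverage", self.coverage), ("mask", self.mask)):
            if arr.shape != (n, p):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, p)}")
        if self.mask.any():
            observed = self.pct[self.mask]
            if np.isnan(observed).any():
                raise ValueError("pct contains NaN at observed cells")
            if observed.size and (observed.min() < 0 or observed.max() > 100):
                raise ValueError("pct outside [0, 100]")
            if (self.coverage[self.mask] < 1).any():
                raise ValueError("coverage < 1 at observed cells")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_days for s in self.samples], dtype=float)

    @property
    def tissues(self) -> List[str]:
        return [s.tissue for s in self.samples]

    def site_index(self) -> Dict[CpGSite, int]:
        return {site: j for j, site in enumerate(self.sites)}

    def fully_observed(self) -> bool:
        return bool(self.mask.all())

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        wanted = list(sample_ids)
        index = {s.sample_id: i for i, s in enumerate(self.samples)}
        missing = [sid for sid in wanted if sid not in index]
        if missing:
            raise KeyError(f"sample ids not in matrix: {missing}")
        rows = [index[sid] for sid in wanted]
        return MethylationMatrix(
            samples=[self.samples[i] for i in rows],
            sites=list(self.sites),
            pct=self.pct[rows],
            coverage=self.coverage[rows],
            mask=self.mask[rows],
        )

    def subset_sites(self, keep: np.ndarray) -> "MethylationMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            cols = np.flatnonzero(keep)
        else:
            cols = keep
        return MethylationMatrix(
            samples=list(self.samples),
            sites=[self.sites[j] for j in cols],
            pct=self.pct[:, cols],
            coverage=self.coverage[:, cols],
            mask=self.mask[:, cols],
        )


TRANSFORM_FORMS = ("identity", "exp_linear", "logistic")


@dataclass(frozen=True)
class TransformSpec:
    """Monotone map from a clock's linear score to age in days.

    identity:   age = score
    exp_linear: age = exp(a*score + b)
    logistic:   age = c / (1 + exp(-a*score - b))
    """

    form: str = "identity"
    parameters: Dict[str, float] = field(default_factory=dict)

    _REQUIRED = {"identity": (), "exp_linear": ("a", "b"), "logistic": ("a", "b", "c")}

    def __post_init__(self) -> None:
        if self.form not in TRANSFORM_FORMS:
            raise ValueError(f"unknown transform form {self.form!r}")
        missing = [k for k in self._REQUIRED[self.form] if k not in self.parameters]
        if missing:
            raise ValueError(f"transform {self.form!r} missing parameters {missing}")

    def __call__(self, score: float) -> float:
        return apply_transform(score, self)


# exp() overflows past ~709 for float64; clip with a warning rather than return inf
_EXP_CLIP = 700.0


def apply_transform(score, transform: TransformSpec):
    """Map a linear clock score (scalar or array) to age in days."""
    score = np.asarray(score, dtype=float)
    if transform.form == "identity":
        out = score
    elif transform.form == "exp_linear":
        a, b = transform.parameters["a"], transform.parameters["b"]
        z = a * score + b
        if np.any(np.abs(z) > _EXP_CLIP):
            warnings.warn("exp_linear argument clipped to avoid overflow")
            z = np.clip(z, -_EXP_CLIP, _EXP_CLIP)
        out = np.exp(z)
    elif transform.form == "logistic":
        a, b, c = (transform.parameters[k] for k in ("a", "b", "c"))
        z = -a * score - b
        z = np.clip(z, -_EXP_CLIP, _EXP_CLIP)
        out = c / (1.0 + np.exp(z))
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown transform form {transform.form!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ClockEntry:
    site: CpGSite
    weight: float
    train_mean: Optional[float] = None  # percent methylation in the training set


STRAND_POLICIES = ("forward_only", "dinucleotide_merged")


@dataclass
class ClockDefinition:
    """A named linear DNAm clock: weighted CpG sites, intercept, age transform.

    Predicted age = transform(intercept + sum_i w_i * m_i) with m_i the
    percent methylation at clock site i.
    """

    name: str
    entries: List[ClockEntry]
    intercept: float
    transform: TransformSpec = field(default_factory=TransformSpec)
    min_site_fraction: float = 0.9
    strand_policy: str = "forward_only"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("clock has no entries")
        sites = [e.site for e in self.entries]
        if len(set(sites)) != len(sites):
            raise ValueError("duplicate sites in clock definition")
        if not math.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        weights = np.array([e.weight for e in self.entries])
        if not np.all(np.isfinite(weights)):
            raise ValueError("non-finite weight in clock definition")
        if np.all(weights == 0):
            raise ValueError("all clock weights are zero")
        if not 0.0 <= self.min_site_fraction <= 1.0:
            raise ValueError("min_site_fraction must be in [0, 1]")
        if self.strand_policy not in STRAND_POLICIES:
            raise ValueError(f"unknown strand_policy {self.strand_policy!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sites(self) -> List[CpGSite]:
        return [e.site for e in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([e.weight for e in self.entries], dtype=float)

    @property
    def train_means(self) -> Optional[np.ndarray]:
        means = [e.train_mean for e in self.entries]
        if any(m is None for m in means):
            return None
        return np.array(means, dtype=float)

    def site_set(self) -> set:
        return {e.site for e in self.entries}


@dataclass
class AgePrediction:
    """One sample's clock readout."""

    sample_id: str
    predicted_age_days: float
    score: float
    n_clock_sites_covered: int
    fraction_covered: float
    valid: bool
    delta_age_days: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "predicted_age_days": self.predicted_age_days,
            "score": self.score,
            "n_clock_sites_covered": self.n_clock_sites_covered,
            "fraction_covered": self.fraction_covered,
            "valid": self.valid,
            "delta_age_days": self.delta_age_days,
        }
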