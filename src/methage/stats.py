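"""Low-level statistical tests used throughout the clock comparisons.

The Mann-Whitney U test is implemented in-repo because both an exact mode
(full permutation distribution, tie-aware) and a tie-corrected normal
approximation are needed with explicit control over which is used; the test
suite checks it against brute-force enumeration and scipy. Bartlett's test
and chi-square tail probabilities come from scipy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "yates_chi2",
    "bartlett_test",
    "benjamini_hochberg",
]

#: Largest group size for which the exact permutation distribution is used by
#: default; beyond it the tie-corrected normal approximation takes over.
EXACT_THRESHOLD = 12


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: Tuple[int, ...]
    effect: Optional[float] = None
    effect_direction: Optional[int] = None
    details: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "effect": self.effect,
            "effect_direction": self.effect_direction,
            **self.details,
        }


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_ranksum_p(doubled_ranks: np.ndarray, n_a: int, observed_doubled: int) -> float:
    """Two-tailed exact p for the rank-sum of group a under random labeling.

    Works on doubled midranks (integers even with ties). Dynamic program over
    (#items chosen, doubled rank sum) counts every labeling exactly once.
    """
    total = int(doubled_ranks.sum())
    ways = np.zeros((n_a + 1, total + 1), dtype=np.float64)
    ways[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        # descending k so each item is used at most once
        ways[1:, r:] += ways[:-1, : total + 1 - r]
    dist = ways[n_a]
    n_total = dist.sum()
    p_low = dist[: observed_doubled + 1].sum() / n_total
    p_high = dist[observed_doubled:].sum() / n_total
    return min(1.0, 2.0 * min(p_low, p_high))


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
    exact_threshold: int = EXACT_THRESHOLD,
) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    ``mode='exact'`` enumerates the full permutation distribution of the rank
    sum (tie-aware); ``'normal_approx'`` uses the tie-corrected normal
    approximation with continuity correction; ``'auto'`` picks exact when both
    groups have at most ``exact_threshold`` observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0  # U for group a; U_a + U_b = n_a * n_b

    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p set to 1")
        return TestResult("mann_whitney_u", u_a, 1.0, (n_a, n_b), details={"mode": 0})

    use_exact = mode == "exact" or (mode == "auto" and max(n_a, n_b) <= exact_threshold)
    if use_exact:
        doubled = np.rint(2 * ranks).astype(int)
        p = _exact_ranksum_p(doubled, n_a, int(doubled[:n_a].sum()))
        mode_used = "exact"
    else:
        mn = n_a * n_b
        N = n_a + n_b
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
        sigma2 = mn / 12.0 * ((N + 1) - tie_term)
        if sigma2 <= 0:
            warnings.warn("zero variance in rank distribution; p set to 1")
            return TestResult("mann_whitney_u", u_a, 1.0, (n_a, n_b))
        mu = mn / 2.0
        # continuity correction toward the mean
        z = (u_a - mu - 0.5 * np.sign(u_a - mu)) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        mode_used = "normal_approx"
    med_diff = float(np.median(a) - np.median(b))
    return TestResult(
        test_name="mann_whitney_u",
        statistic=float(u_a),
        p_value=float(p),
        n_per_group=(n_a, n_b),
        effect=med_diff,
        effect_direction=int(np.sign(med_diff)),
        details={"mode": mode_used},
    )


def yates_chi2(table: np.ndarray) -> TestResult:
    """Two-tailed chi-square test on a 2x2 table with Yates continuity
    correction; the correction floors the statistic at zero."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("negative cell count")
    (a, b), (c, d) = table
    N = table.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: a table margin is zero")
    diff = abs(a * d - b * c)
    if diff <= N / 2.0:
        stat = 0.0
        p = 1.0
    else:
        stat = N * (diff - N / 2.0) ** 2 / np.prod(margins)
        p = float(sps.chi2.sf(stat, df=1))
    return TestResult(
        test_name="chi2_yates",
        statistic=float(stat),
        p_value=p,
        n_per_group=(int(a + b), int(c + d)),
        details={"N": float(N)},
    )


def bartlett_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Bartlett's test of equal variances across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("Bartlett's test needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs >= 2 observations")
    variances = [float(np.var(g, ddof=1)) for g in arrays]
    if all(v == 0 for v in variances):
        warnings.warn("all group variances are zero; Bartlett p set to 1")
        return TestResult("bartlett", 0.0, 1.0, tuple(len(g) for g in arrays))
    stat, p = sps.bartlett(*arrays)
    return TestResult(
        test_name="bartlett",
        statistic=float(stat),
        p_value=float(p),
        n_per_group=tuple(len(g) for g in arrays),
        details={"variances": variances},
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional output column; raw p is the default)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
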