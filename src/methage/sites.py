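"""Clock-site set comparisons, genomic-context annotation and
chromosome representation.

Interval files (CpG islands, genes) are BED: 0-based half-open on disk,
converted to 1-based inclusive internally like every other coordinate in the
package.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .stats import TestResult, yates_chi2
from .types import ClockDefinition, CpGSite, normalize_chrom

__all__ = [
    "read_bed",
    "write_bed",
    "site_overlap",
    "OverlapResult",
    "gene_overlap_test",
    "annotate_genomic_context",
    "sites_to_genes",
    "chromosome_representation",
    "MOUSE_AUTOSOMES",
]

MOUSE_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 20))

SHORE_BP = 2000
SHELF_BP = 4000

#: chrom -> interval list; intervals are (start, end, name) 1-based inclusive
IntervalMap = Dict[str, List[Tuple[int, int, str]]]


def read_bed(path) -> IntervalMap:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    intervals: IntervalMap = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom = normalize_chrom(fields[0])
            start0, end0 = int(fields[1]), int(fields[2])
            if end0 <= start0:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start0}-{end0}"
            intervals.setdefault(chrom, []).append((start0 + 1, end0, name))
    for chrom in intervals:
        intervals[chrom].sort()
    return intervals


def write_bed(intervals: IntervalMap, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start1, end1, name in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{start1 - 1}\t{end1}\t{name}\n")


def merge_intervals(intervals: IntervalMap) -> IntervalMap:
    """Collapse overlapping/adjacent intervals per chromosome."""
    merged: IntervalMap = {}
    for chrom, ivals in intervals.items():
        out: List[Tuple[int, int, str]] = []
        for start, end, name in sorted(ivals):
            if out and start <= out[-1][1] + 1:
                prev = out[-1]
                out[-1] = (prev[0], max(prev[1], end), prev[2])
            else:
                out.append((start, end, name))
        merged[chrom] = out
    return merged


def site_overlap(clock_a: ClockDefinition, clock_b: ClockDefinition) -> Set[CpGSite]:
    """Exact (chrom, pos) intersection of two clocks' site sets."""
    return clock_a.site_set() & clock_b.site_set()


@dataclass
class OverlapResult:
    shared: Set[str]
    n_a: int
    n_b: int
    n_universe: int
    table: np.ndarray  # 2x2: (in A, not in A) x (in B, not in B)
    test: TestResult

    def to_dict(self) -> dict:
        return {
            "n_shared": len(self.shared),
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_universe": self.n_universe,
            "table": self.table.tolist(),
            "chi2_yates": self.test.statistic,
            "p_value": self.test.p_value,
        }


def gene_overlap_test(
    genes_a: Iterable[str], genes_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Chi-square (Yates) test of the overlap between two gene sets against a
    background universe."""
    universe = set(universe)
    genes_a = set(genes_a)
    genes_b = set(genes_b)
    if len(universe) < 4:
        raise ValueError("universe must contain at least 4 genes")
    stray = (genes_a | genes_b) - universe
    if stray:
        raise ValueError(f"gene sets contain items outside the universe: {sorted(stray)[:5]}")
    a = len(genes_a & genes_b)
    b = len(genes_a - genes_b)
    c = len(genes_b - genes_a)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    test = yates_chi2(table)
    return OverlapResult(
        shared=genes_a & genes_b,
        n_a=len(genes_a),
        n_b=len(genes_b),
        n_universe=len(universe),
        table=table,
        test=test,
    )


def annotate_genomic_context(
    sites: Sequence[CpGSite], islands: IntervalMap
) -> dict:
    """Classify sites as island / shore / shelf / open_sea.

    island: inside a (merged) CpG-island interval; shore: within 2 kb of an
    island edge; shelf: 2-4 kb; open_sea: beyond 4 kb or on a contig absent
    from the annotation (with a warning).
    """
    merged = merge_intervals(islands)
    # flat sorted arrays per chromosome for bisection
    per_chrom = {
        chrom: (
            np.array([iv[0] for iv in ivals]),
            np.array([iv[1] for iv in ivals]),
        )
        for chrom, ivals in merged.items()
        if ivals
    }
    labels: Dict[CpGSite, str] = {}
    missing_contigs = set()
    for site in sites:
        arrays = per_chrom.get(site.chrom)
        if arrays is None:
            missing_contigs.add(site.chrom)
            labels[site] = "open_sea"
            continue
        starts, ends = arrays
        k = int(np.searchsorted(starts, site.pos, side="right")) - 1
        dist = None
        if k >= 0 and site.pos <= ends[k]:
            labels[site] = "island"
            continue
        candidates = []
        if k >= 0:
            candidates.append(site.pos - ends[k])  # gap to island on the left
        if k + 1 < len(starts):
            candidates.append(starts[k + 1] - site.pos)  # gap to the right
        dist = min(candidates) if candidates else np.inf
        if dist <= SHORE_BP:
            labels[site] = "shore"
        elif dist <= SHELF_BP:
            labels[site] = "shelf"
        else:
            labels[site] = "open_sea"
    if missing_contigs:
        warnings.warn(
            f"contigs absent from island annotation treated as open sea: "
            f"{sorted(missing_contigs)}"
        )
    n = len(sites)
    fractions = {
        label: sum(1 for v in labels.values() if v == label) / n if n else 0.0
        for label in ("island", "shore", "shelf", "open_sea")
    }
    return {"labels": labels, "fractions": fractions, "n_sites": n}


def sites_to_genes(
    sites: Sequence[CpGSite],
    genes: IntervalMap,
    promoter_extension: int = 0,
) -> Dict[CpGSite, Set[str]]:
    """Map each site to every gene interval containing it, with an optional
    symmetric promoter extension in bp. Multi-gene hits are allowed."""
    hits: Dict[CpGSite, Set[str]] = {site: set() for site in sites}
    for chrom, ivals in genes.items():
        chrom_sites = [s for s in sites if s.chrom == chrom]
        if not chrom_sites:
            continue
        for start, end, name in ivals:
            lo, hi = start - promoter_extension, end + promoter_extension
            for site in chrom_sites:
                if lo <= site.pos <= hi:
                    hits[site].add(name)
    return hits


def chromosome_representation(
    clock: ClockDefinition, expected_chroms: Sequence[str] = MOUSE_AUTOSOMES
) -> dict:
    """Per-chromosome clock-site counts plus a completeness flag (every
    expected chromosome represented). Sex-chromosome sites are an error:
    the construction recipe excludes them."""
    expected = [normalize_chrom(c) for c in expected_chroms]
    forbidden = {"chrX", "chrY"}
    bad = sorted({s.chrom for s in clock.sites} & forbidden)
    if bad:
        raise ValueError(f"clock {clock.name!r} contains sex-chromosome sites: {bad}")
    counts = {chrom: 0 for chrom in expected}
    for site in clock.sites:
        counts[site.chrom] = counts.get(site.chrom, 0) + 1
    complete = all(counts.get(chrom, 0) >= 1 for chrom in expected)
    return {"counts": counts, "complete": complete, "expected": expected}
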