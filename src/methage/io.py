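"""Readers and writers for methylation call files, clocks and metadata.

Supported formats
-----------------
bismark coverage (TSV, 6 columns)
    chrom, start, end, pct_methylation, meth_count, unmeth_count with
    start == end == the 1-based cytosine position.
bismark cytosine report (TSV, 7 columns)
    chrom, pos, strand, meth_count, unmeth_count, context, trinucleotide;
    used for strand-resolved input.
clock definition (TSV)
    ``#key=value`` header lines (name, intercept, transform,
    min_site_fraction, strand_policy) followed by columns
    chrom, pos_1based, weight, train_mean ("NA" allowed).
metadata (TSV)
    sample_id, tissue, age_days, sex, strain, condition.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_EXCLUDED_CONTIGS,
    ClockDefinition,
    ClockEntry,
    CpGSite,
    MethylationMatrix,
    SampleMetadata,
    SampleMethylome,
    TransformSpec,
    normalize_chrom,
    sort_sites,
)

__all__ = [
    "read_bismark_coverage",
    "write_bismark_coverage",
    "read_cytosine_report",
    "merge_strands",
    "build_matrix",
    "read_clock_definition",
    "write_clock_definition",
    "read_metadata",
    "write_metadata",
    "write_matrix_dir",
    "read_matrix_dir",
]


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


# Upstream emitters round the percent column; counts are authoritative and a
# discrepancy beyond this many percentage points only triggers a warning.
PCT_MISMATCH_WARN = 0.5


def read_bismark_coverage(
    path,
    min_coverage: int = 1,
    sample_id: Optional[str] = None,
    exclude_contigs: Iterable[str] = DEFAULT_EXCLUDED_CONTIGS,
) -> SampleMethylome:
    """Parse one bismark ``.cov`` file into a :class:`SampleMethylome`.

    Counts are authoritative: the percent column is recomputed from them and a
    mismatch > 0.5 percentage points triggers a warning. Lines on excluded
    contigs are dropped silently.
    """
    path = Path(path)
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    excluded = {normalize_chrom(c) for c in exclude_contigs}
    counts: Dict[CpGSite, Tuple[int, int]] = {}
    n_mismatch = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom = normalize_chrom(fields[0])
                start, end = int(fields[1]), int(fields[2])
                pct_stated = float(fields[3])
                meth, unmeth = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            if start != end:
                raise ParseError(
                    f"{path}:{lineno}: start != end ({start} != {end}); "
                    "expected per-cytosine coverage lines"
                )
            if start < 1:
                raise ParseError(f"{path}:{lineno}: position {start} < 1")
            if chrom in excluded:
                continue
            cov = meth + unmeth
            if cov < min_coverage:
                continue
            if cov > 0:
                pct_true = 100.0 * meth / cov
                if abs(pct_true - pct_stated) > PCT_MISMATCH_WARN:
                    n_mismatch += 1
            site = CpGSite(chrom, start)
            if site in counts:
                raise ParseError(f"{path}:{lineno}: duplicate site {chrom}:{start}")
            counts[site] = (meth, unmeth)
    if n_mismatch:
        warnings.warn(
            f"{path}: {n_mismatch} line(s) with percent column inconsistent with "
            "counts; counts kept as authoritative"
        )
    if not counts:
        warnings.warn(f"{path}: no usable methylation calls")
    return SampleMethylome(sample_id=sample_id, counts=counts)


def write_bismark_coverage(methylome: SampleMethylome, path) -> None:
    """Serialize a methylome back to bismark coverage format."""
    with open(path, "w") as fh:
        for site in sort_sites(methylome.counts):
            meth, unmeth = methylome.counts[site]
            pct = 100.0 * meth / (meth + unmeth)
            fh.write(f"{site.chrom}\t{site.pos}\t{site.pos}\t{pct:g}\t{meth}\t{unmeth}\n")


def read_cytosine_report(
    path,
    min_coverage: int = 1,
    sample_id: Optional[str] = None,
    exclude_contigs: Iterable[str] = DEFAULT_EXCLUDED_CONTIGS,
) -> Tuple[SampleMethylome, Dict[CpGSite, str]]:
    """Parse a bismark CpG cytosine report, keeping per-site strand labels.

    Returns the methylome (covered positions only) and a site -> strand map
    suitable for :func:`merge_strands`.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    excluded = {normalize_chrom(c) for c in exclude_contigs}
    counts: Dict[CpGSite, Tuple[int, int]] = {}
    strands: Dict[CpGSite, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, got {len(fields)}"
                )
            chrom = normalize_chrom(fields[0])
            try:
                pos = int(fields[1])
                strand = fields[2]
                meth, unmeth = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            if chrom in excluded or meth + unmeth < min_coverage or meth + unmeth == 0:
                continue
            site = CpGSite(chrom, pos)
            counts[site] = (meth, unmeth)
            strands[site] = strand
    return SampleMethylome(sample_id=sample_id, counts=counts), strands


def merge_strands(
    methylome: SampleMethylome, strand_table: Dict[CpGSite, str]
) -> SampleMethylome:
    """Collapse strand-resolved calls onto the forward-strand CpG anchor.

    A reverse-strand cytosine at position p+1 is summed onto the forward
    anchor at p. Total read counts are conserved exactly. A reverse-strand
    site with no forward partner stays as its own anchor with a warning.
    """
    merged: Dict[CpGSite, Tuple[int, int]] = {}
    orphans = 0
    for site, (meth, unmeth) in methylome.counts.items():
        strand = strand_table.get(site, "+")
        if strand == "+":
            anchor = site
        else:
            candidate = CpGSite(site.chrom, site.pos - 1)
            if candidate.pos >= 1 and (
                candidate in methylome.counts or strand_table.get(candidate) == "+"
            ):
                anchor = candidate
            else:
                orphans += 1
                anchor = site
        prev = merged.get(anchor, (0, 0))
        merged[anchor] = (prev[0] + meth, prev[1] + unmeth)
    if orphans:
        warnings.warn(
            f"{methylome.sample_id}: {orphans} reverse-strand site(s) without a "
            "forward partner kept as their own anchors"
        )
    return SampleMethylome(sample_id=methylome.sample_id, counts=merged)


def build_matrix(
    methylomes: Sequence[SampleMethylome],
    metadata: Sequence[SampleMetadata],
    site_policy: str = "union",
) -> MethylationMatrix:
    """Assemble per-sample methylomes into a cohort matrix.

    ``site_policy='union'`` keeps every site seen in any sample, masking the
    missing cells; ``'intersection'`` keeps only sites observed in all samples.
    Sample order follows ``metadata``; sites are (chrom, pos) sorted.
    """
    if site_policy not in ("union", "intersection"):
        raise ValueError(f"site_policy must be 'union' or 'intersection', got {site_policy!r}")
    meta_ids = [m.sample_id for m in metadata]
    if len(set(meta_ids)) != len(meta_ids):
        dupes = sorted({x for x in meta_ids if meta_ids.count(x) > 1})
        raise ValueError(f"duplicate metadata sample ids: {dupes}")
    by_id = {m.sample_id: m for m in methylomes}
    if len(by_id) != len(methylomes):
        raise ValueError("duplicate methylome sample ids")
    missing_meta = sorted(set(by_id) - set(meta_ids))
    if missing_meta:
        raise ValueError(f"methylome sample ids without metadata: {missing_meta}")
    missing_data = sorted(set(meta_ids) - set(by_id))
    if missing_data:
        raise ValueError(f"metadata sample ids without methylomes: {missing_data}")

    site_sets = [m.sites() for m in methylomes]
    if site_policy == "union":
        all_sites = set().union(*site_sets) if site_sets else set()
    else:
        all_sites = set.intersection(*site_sets) if site_sets else set()
    sites = sort_sites(all_sites)
    site_idx = {s: j for j, s in enumerate(sites)}

    n, p = len(metadata), len(sites)
    pct = np.full((n, p), np.nan)
    coverage = np.zeros((n, p), dtype=np.int64)
    mask = np.zeros((n, p), dtype=bool)
    for i, meta in enumerate(metadata):
        methylome = by_id[meta.sample_id]
        for site, (meth, unmeth) in methylome.counts.items():
            j = site_idx.get(site)
            if j is None:
                continue
            cov = meth + unmeth
            pct[i, j] = 100.0 * meth / cov
            coverage[i, j] = cov
            mask[i, j] = True
    return MethylationMatrix(
        samples=list(metadata), sites=sites, pct=pct, coverage=coverage, mask=mask
    )


# ---------------------------------------------------------------------------
# clock definition TSV


def write_clock_definition(clock: ClockDefinition, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={clock.name}\n")
        fh.write(f"#intercept={clock.intercept!r}\n")
        parts = [clock.transform.form]
        parts += [f"{k}={v!r}" for k, v in sorted(clock.transform.parameters.items())]
        fh.write(f"#transform={';'.join(parts)}\n")
        fh.write(f"#min_site_fraction={clock.min_site_fraction!r}\n")
        fh.write(f"#strand_policy={clock.strand_policy}\n")
        fh.write("chrom\tpos_1based\tweight\ttrain_mean\n")
        for entry in clock.entries:
            mean = "NA" if entry.train_mean is None else repr(entry.train_mean)
            fh.write(f"{entry.site.chrom}\t{entry.site.pos}\t{entry.weight!r}\t{mean}\n")


def _parse_transform(text: str) -> TransformSpec:
    parts = text.split(";")
    form = parts[0].strip()
    params = {}
    for chunk in parts[1:]:
        if not chunk.strip():
            continue
        key, _, value = chunk.partition("=")
        params[key.strip()] = float(value)
    return TransformSpec(form=form, parameters=params)


def read_clock_definition(path) -> ClockDefinition:
    """Read a clock definition TSV; round-trips :func:`write_clock_definition`."""
    path = Path(path)
    header: Dict[str, str] = {}
    entries: List[ClockEntry] = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                header[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # column header line
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: missing weight column")
            try:
                site = CpGSite.make(fields[0], int(fields[1]))
                weight = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            mean: Optional[float] = None
            if len(fields) > 3 and fields[3] not in ("", "NA", "na", "NaN"):
                mean = float(fields[3])
            if site in seen:
                raise ParseError(f"{path}:{lineno}: duplicate site {site.chrom}:{site.pos}")
            seen.add(site)
            entries.append(ClockEntry(site=site, weight=weight, train_mean=mean))
    if "intercept" not in header:
        raise ParseError(f"{path}: missing '#intercept=' header")
    transform = (
        _parse_transform(header["transform"]) if "transform" in header else TransformSpec()
    )
    return ClockDefinition(
        name=header.get("name", path.stem),
        entries=entries,
        intercept=float(header["intercept"]),
        transform=transform,
        min_site_fraction=float(header.get("min_site_fraction", 0.9)),
        strand_policy=header.get("strand_policy", "forward_only"),
    )


# ---------------------------------------------------------------------------
# metadata TSV

METADATA_COLUMNS = ["sample_id", "tissue", "age_days", "sex", "strain", "condition"]


def read_metadata(path) -> List[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "tissue", "age_days") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            SampleMetadata(
                sample_id=str(rec["sample_id"]),
                tissue=str(rec["tissue"]),
                age_days=float(rec["age_days"]),
                sex=str(rec.get("sex", "unknown") or "unknown"),
                strain=str(rec.get("strain", "") or ""),
                condition=str(rec.get("condition", "untreated_wildtype") or "untreated_wildtype"),
            )
        )
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return rows


def write_metadata(metadata: Sequence[SampleMetadata], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "tissue": m.tissue,
                "age_days": m.age_days,
                "sex": m.sex,
                "strain": m.strain,
                "condition": m.condition,
            }
            for m in metadata
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrix directory (pct.tsv + coverage.tsv + metadata.tsv)


def write_matrix_dir(matrix: MethylationMatrix, directory) -> None:
    """Persist a matrix as three TSVs (pct, coverage, metadata) in a
    directory; missing cells are NA in pct and 0 in coverage."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = [f"{s.chrom}:{s.pos}" for s in matrix.sites]
    pct = pd.DataFrame(matrix.pct, index=matrix.sample_ids, columns=cols)
    pct.to_csv(directory / "pct.tsv", sep="\t", na_rep="NA", index_label="sample_id")
    cov = pd.DataFrame(
        np.where(matrix.mask, matrix.coverage, 0), index=matrix.sample_ids, columns=cols
    )
    cov.to_csv(directory / "coverage.tsv", sep="\t", index_label="sample_id")
    write_metadata(matrix.samples, directory / "metadata.tsv")


def read_matrix_dir(directory) -> MethylationMatrix:
    directory = Path(directory)
    metadata = read_metadata(directory / "metadata.tsv")
    pct = pd.read_csv(directory / "pct.tsv", sep="\t", index_col="sample_id")
    cov = pd.read_csv(directory / "coverage.tsv", sep="\t", index_col="sample_id")
    order = [m.sample_id for m in metadata]
    pct = pct.loc[order]
    cov = cov.loc[order]
    sites = []
    for col in pct.columns:
        chrom, _, pos = col.rpartition(":")
        sites.append(CpGSite.make(chrom, int(pos)))
    coverage = cov.to_numpy(dtype=np.int64)
    mask = coverage >= 1
    values = pct.to_numpy(dtype=float)
    values[~mask] = np.nan
    return MethylationMatrix(
        samples=metadata, sites=sites, pct=values, coverage=coverage, mask=mask
    )
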