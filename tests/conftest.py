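import numpy as np
import pytest

from methage.types import (
    ClockDefinition,
    ClockEntry,
    CpGSite,
    MethylationMatrix,
    SampleMetadata,
    SampleMethylome,
    TransformSpec,
)


@pytest.fixture
def toy_sites():
    return [CpGSite(f"chr{c}", p) for c, p in [(1, 100), (1, 200), (2, 50), (2, 300), (3, 10)]]


@pytest.fixture
def toy_methylomes(toy_sites):
    a, b, c, d, e = toy_sites
    m1 = SampleMethylome("S1", {a: (3, 1), b: (5, 5), c: (0, 4), d: (2, 2), e: (6, 0)})
    m2 = SampleMethylome("S2", {a: (1, 3), b: (4, 6), c: (8, 2)})
    return [m1, m2]


@pytest.fixture
def toy_metadata():
    return [
        SampleMetadata("S1", "liver", 100.0, "male", "C57BL/6"),
        SampleMetadata("S2", "blood", 400.0, "female", "C57BL/6"),
    ]


def make_matrix(pct, coverage=None, ages=None, tissues=None, sites=None):
    """Small helper used across test modules to build a MethylationMatrix
    from a dense percent array (NaN = missing)."""
    pct = np.asarray(pct, dtype=float)
    n, p = pct.shape
    mask = ~np.isnan(pct)
    if coverage is None:
        coverage = np.where(mask, 10, 0)
    else:
        coverage = np.asarray(coverage)
    if ages is None:
        ages = np.linspace(50, 500, n)
    if tissues is None:
        tissues = ["liver"] * n
    if sites is None:
        sites = [CpGSite("chr1", 100 + 10 * j) for j in range(p)]
    samples = [
        SampleMetadata(f"S{i}", tissues[i], float(ages[i])) for i in range(n)
    ]
    return MethylationMatrix(
        samples=samples, sites=sites, pct=pct,
        coverage=np.where(mask, coverage, 0), mask=mask,
    )


@pytest.fixture
def one_site_clock():
    return ClockDefinition(
        name="one_site",
        entries=[ClockEntry(CpGSite("chr1", 100), weight=2.0)],
        intercept=10.0,
        transform=TransformSpec(),
        min_site_fraction=0.9,
    )
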