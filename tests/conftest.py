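import numpy as np
import pytest

from altiscan import GenotypeMatrix, PopulationMap
import pandas as pd


def make_matrix(
    dosages,
    positions=None,
    chrom="chr1",
    sample_ids=None,
    qual=None,
    info=None,
    is_biallelic=None,
):
    """Small GenotypeMatrix from a nested list of dosages (sites x samples)."""
    d = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = d.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chrom=np.full(n_sites, chrom, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        sample_ids=sample_ids,
        dosages=d,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        qual=qual,
        info=info or {},
        is_biallelic=is_biallelic,
    )


def random_matrix(rng, n_sites=30, n_samples=10, missing_rate=0.0):
    d = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    if missing_rate:
        mask = rng.random((n_sites, n_samples)) < missing_rate
        d[mask] = -1
    return make_matrix(d, positions=np.sort(
        rng.choice(np.arange(1, 10_000), size=n_sites, replace=False)))


def make_popmap(groups: dict[str, list[str]], altitudes: dict[str, float] | None = None):
    """PopulationMap from {population: [samples]}; group QT iff name 'QT'."""
    altitudes = altitudes or {}
    rows = []
    for pop, samples in groups.items():
        grp = "QT" if pop == "QT" else "LL"
        alt = altitudes.get(pop, 4000.0 if grp == "QT" else 600.0)
        rows += [(s, pop, grp, alt) for s in samples]
    df = pd.DataFrame(rows, columns=["sample", "population", "group", "altitude"])
    return PopulationMap(df.set_index("sample"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
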