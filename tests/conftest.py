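import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dollotrace as dt

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def quartet() -> dt.Tree:
    """((A,B),(C,D)) rooted via the implicit all-absent ancestor."""
    return dt.Tree.from_topology(((0, 1), (2, 3)), ["A", "B", "C", "D"])


@pytest.fixture
def toy_genome() -> dt.GenomeConfig:
    return dt.GenomeConfig(
        chrom_lengths={"chr1": 1_000_000, "chr2": 500_000},
        normal_recomb_regions=[("chr1", 0, 1_000_000), ("chr2", 0, 500_000)],
    )


@pytest.fixture
def fly_genome() -> dt.GenomeConfig:
    return dt.default_genome()


def make_call(
    sample="s1",
    chrom="chr1",
    start=100,
    end=101,
    family="copia",
    strand="+",
) -> dt.TEInsertionCall:
    return dt.TEInsertionCall(
        sample_id=sample, chrom=chrom, start=start, end=end, family=family, strand=strand
    )


def random_matrix(n_samples: int, n_loci: int, rng: np.random.Generator) -> dt.PresenceMatrix:
    """Random binary matrix without all-absent columns, with canonical ids."""
    values = rng.integers(0, 2, size=(n_samples, n_loci))
    empty = values.sum(axis=0) == 0
    for j in np.flatnonzero(empty):
        values[rng.integers(0, n_samples), j] = 1
    samples = [f"S{i + 1}" for i in range(n_samples)]
    ids = [dt.make_locus_id("chr1", 100 * j, 100 * j + 1, "+", "copia") for j in range(n_loci)]
    return dt.PresenceMatrix.from_arrays(samples, ids, values)


@pytest.fixture
def flat_windows() -> pd.DataFrame:
    """3,000 fully mappable windows at constant count, mid-range GC."""
    n = 3000
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 10_000,
            "end": (np.arange(n) + 1) * 10_000,
            "count": 100,
            "gc": np.linspace(0.31, 0.44, n),
            "mappability": 1.0,
        }
    )
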