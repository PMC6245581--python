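import numpy as np
import pandas as pd
import pytest

from peakscape.intervals import GenomicInterval
from peakscape.simulate import simulate_in_memory


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=300):
    """Random valid intervals on a small genome."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_tss(rng, n, chroms=("chr1", "chr2"), span=10_000):
    rows = []
    for i in range(n):
        rows.append(
            (
                f"g{i:03d}",
                chroms[int(rng.integers(len(chroms)))],
                int(rng.integers(0, span)),
                "+" if rng.random() < 0.5 else "-",
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"])


@pytest.fixture(scope="session")
def small_dataset():
    """One shared reduced-scale two-species synthetic dataset."""
    return simulate_in_memory(seed=11, species=("human", "mouse"), scale=0.3)


@pytest.fixture(scope="session")
def small_human(small_dataset):
    return small_dataset["human"]
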