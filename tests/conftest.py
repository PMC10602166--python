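import numpy as np
import pandas as pd
import pytest

from chromrisk.synthetic import SimulationConfig


@pytest.fixture
def small_config():
    """A light simulation configuration for fast unit tests."""
    return SimulationConfig(
        seed=7,
        n_celltypes=3,
        n_libraries_per_celltype=3,
        genome=(("chr1", 2_000_000),),
        depth_per_celltype=20_000,
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=300):
    """Random half-open intervals for oracle comparisons."""
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, max_pos, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})


def brute_force_overlap_counts(intervals: pd.DataFrame, fragments: pd.DataFrame):
    """O(n*m) pairwise overlap oracle, independent of the search-based engine."""
    qs = intervals["start"].to_numpy()[:, None]
    qe = intervals["end"].to_numpy()[:, None]
    qc = intervals["chrom"].to_numpy()[:, None]
    fs = fragments["start"].to_numpy()[None, :]
    fe = fragments["end"].to_numpy()[None, :]
    fc = fragments["chrom"].to_numpy()[None, :]
    hit = (qc == fc) & (fs < qe) & (qs < fe)
    return hit.sum(axis=1)
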