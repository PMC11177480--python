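import numpy as np
import pandas as pd
import pytest

from labs_cfdna import build_reference_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """Five-type atlas with strong markers, reused across read-level tests."""
    return build_reference_atlas(5, 333, marker_fraction=0.6, margin=0.7, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_call_table(rng, n_sites=200, chroms=("chr1", "chr2"), max_pos=100_000):
    """A valid random call table (sorted, unique sites, non-negative counts)."""
    rows = []
    for chrom in chroms:
        pos = np.sort(rng.choice(max_pos, size=n_sites // len(chroms), replace=False))
        for p in pos:
            m, u = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            rows.append((chrom, int(p), "+", "CpG", m, u))
    return pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "context", "n_meth", "n_unmeth"])
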