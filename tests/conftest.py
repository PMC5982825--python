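import numpy as np
import pandas as pd
import pytest

from xomap import calling, phasing, simulate
from xomap.io import ChromosomeMeta, meta_dict


@pytest.fixture
def toy_meta():
    return [ChromosomeMeta("chr1", 20_000_000, 5_000_000),
            ChromosomeMeta("chr2", 15_000_000, 3_000_000)]


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free 3-chromosome, 4-quartet simulation shared across tests."""
    meta = [ChromosomeMeta("chr1", 20_000_000, 5_000_000),
            ChromosomeMeta("chr2", 18_000_000, None),
            ChromosomeMeta("chr3", 15_000_000, 6_500_000)]
    return simulate.simulate_dataset(
        meta=meta, n_quartets=4, n_female_used=4, snp_spacing_mean=5000.0,
        error_rate=0.0, missing_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_calls(clean_dataset):
    """Phased gamete pairs and the called crossover table for the clean sim."""
    pairs = []
    for i, table in enumerate(clean_dataset.tables):
        p, _ = phasing.phase_quartet(table, pair_id=f"pair{i}")
        pairs += p
    co = calling.call_crossovers(pairs, meta_dict(clean_dataset.meta))
    return pairs, co


def make_co_table(chroms, midpoints, sexes=None, width=2000, pair="pair0"):
    """Hand-built retained-CO table for statistics tests."""
    n = len(midpoints)
    sexes = ["male"] * n if sexes is None else sexes
    mid = np.asarray(midpoints, dtype=float)
    return pd.DataFrame({
        "chrom": chroms, "parent_sex": sexes,
        "parent_id": ["p0"] * n, "pair_id": [pair] * n,
        "left": (mid - width / 2).astype(int),
        "right": (mid + width / 2).astype(int),
        "midpoint": mid, "resolution": [width] * n,
        "status": ["validated"] * n,
    })
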