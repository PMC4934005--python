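import numpy as np
import pandas as pd
import pytest

import methylhet as mh


def make_table(sample_id, records):
    """Build a CpGCallTable from (chrom, pos, count_meth, count_unmeth) tuples."""
    return mh.CpGCallTable(
        sample_id,
        pd.DataFrame(records, columns=["chrom", "pos", "count_meth", "count_unmeth"]),
    )


def random_table(rng, n_sites=30, sample_id="rand", chrom="chr1", max_depth=12):
    pos = np.sort(rng.choice(np.arange(1, 5000), size=n_sites, replace=False))
    depth = rng.integers(1, max_depth + 1, size=n_sites)
    meth = rng.binomial(depth, rng.random(n_sites))
    return mh.CpGCallTable(
        sample_id,
        pd.DataFrame(
            {"chrom": chrom, "pos": pos, "count_meth": meth,
             "count_unmeth": depth - meth}
        ),
    )


@pytest.fixture(scope="session")
def small_config():
    # one 400-kb chromosome, ~4,000 CpGs: big enough for windowed statistics,
    # small enough that every module test stays fast
    return mh.SimulationConfig(n_chromosomes=1, chrom_length_bp=400_000, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return mh.simulate_dataset(small_config, n_cells=4)


@pytest.fixture(scope="session")
def small_windows(small_config):
    return mh.build_windows({"chr1": small_config.chrom_length_bp})
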