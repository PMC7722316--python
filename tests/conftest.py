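import numpy as np
import pandas as pd
import pytest

from starrcall.genome import ChromSizes, make_bins
from starrcall.simulate import SimConfig, simulate_experiment


def make_fragments(chrom, starts, ends, strands=None):
    """Build a fragment frame from parallel coordinate lists."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if strands is None:
        strands = ["+"] * len(starts)
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                       "strand": list(strands)})
    df["center"] = (df["start"] + df["end"]) // 2
    return df


@pytest.fixture(scope="session")
def small_config():
    # a compact experiment: 0.6 Mb, 6 controls — enough structure for
    # pipeline behavior without full benchmark runtimes
    return SimConfig(genome_length=600_000, n_controls=6, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def spikein_experiment():
    """Benchmark-scale experiment: ~2.6 Mb, 28 controls, defaults."""
    return simulate_experiment(SimConfig(seed=1))


@pytest.fixture
def toy_sizes():
    return ChromSizes({"chr1": 10_000, "chr2": 4_000})


@pytest.fixture
def toy_bins(toy_sizes):
    return make_bins(toy_sizes, l=500, s=100)
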