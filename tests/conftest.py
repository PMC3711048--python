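import numpy as np
import pytest

import histurn as h


@pytest.fixture(scope="session")
def small_model():
    """8 genes (2 per stratum) plus one heterochromatin block."""
    return h.build_genome(8, (8, 4, 2, 0.5), 1, seed=1)


@pytest.fixture(scope="session")
def default_model():
    """The default 40-gene / 2-heterochromatin-domain genome."""
    return h.build_genome(40, (8, 4, 2, 0.5), 2, seed=0)


@pytest.fixture()
def sim_cfg():
    return h.SimConfig(seed=11)


def make_uniform_reads(rng, chrom, chrom_len, n, read_length=49):
    starts = rng.integers(0, chrom_len - read_length, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return [
        h.ReadAlignment(chrom, int(s), int(s) + read_length, str(st))
        for s, st in zip(starts, strands)
    ]
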