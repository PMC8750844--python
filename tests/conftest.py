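import numpy as np
import pytest

from dmrsmooth.data_io import SiteTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_site_table(
    pos,
    level_a=0.5,
    level_b=0.5,
    depth=20,
    n_reps=3,
    seed=0,
    chrom="chrT",
):
    """Small binomial-count SiteTable with constant or per-site levels."""
    rng = np.random.default_rng(seed)
    pos = np.asarray(pos, dtype=np.int64)
    n = pos.shape[0]
    la = np.broadcast_to(np.asarray(level_a, dtype=float), (n,))
    lb = np.broadcast_to(np.asarray(level_b, dtype=float), (n,))
    a_total = rng.poisson(depth, (n, n_reps)) + 1
    b_total = rng.poisson(depth, (n, n_reps)) + 1
    a_meth = rng.binomial(a_total, la[:, None])
    b_meth = rng.binomial(b_total, lb[:, None])
    return SiteTable(chrom, pos, a_meth, a_total, b_meth, b_total)


@pytest.fixture
def site_table_factory():
    return make_site_table
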