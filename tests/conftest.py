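import numpy as np
import pytest

from pooldyn import formats, popgen


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_pool():
    return popgen.PoolSpec("p1", 40, min_count=2, min_coverage=4, max_coverage=500)


@pytest.fixture
def b1_pool():
    return popgen.PoolSpec("p1", 40, min_count=1, min_coverage=2, max_coverage=500)


def random_sites(rng, n=100, n_pools=1, chrom="sc1", max_count=40):
    """Sorted random SiteCounts with zero N/del columns."""
    positions = np.sort(rng.choice(np.arange(1, 10 * n), size=n, replace=False))
    sites = []
    for pos in positions:
        counts = tuple(
            tuple(int(x) for x in rng.integers(0, max_count, size=4)) + (0, 0)
            for _ in range(n_pools)
        )
        ref = "ATCG"[rng.integers(0, 4)]
        sites.append(formats.SiteCounts(chrom, int(pos), ref, counts))
    return sites


@pytest.fixture
def site_factory():
    def make(counts, chrom="sc1", pos=10, ref="A", indels=None):
        if isinstance(counts[0], int):
            counts = (counts,)
        counts = tuple(tuple(c) + (0,) * (6 - len(c)) for c in counts)
        kwargs = {}
        if indels is not None:
            kwargs["indels"] = tuple(indels)
        return formats.SiteCounts(chrom, pos, ref, counts, **kwargs)

    return make
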