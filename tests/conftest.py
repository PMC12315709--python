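import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitoloop.core import GenomicInterval, MotifSite

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_site(center: int, strand: str = "+", category: str = "bookmarked",
              chrom: str = "chrA", half: int = 9) -> MotifSite:
    return MotifSite(GenomicInterval(chrom, center - half, center + half + 1, strand), category)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def motif_grid():
    """200 oriented bookmarked sites spaced 10 kb apart on chrA."""
    return [
        make_site(100_000 + 10_000 * i, "+" if i % 2 == 0 else "-")
        for i in range(200)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
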