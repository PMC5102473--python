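import numpy as np
import pytest

from allogrowth.allometry import RatePoint
from allogrowth.synthetic_data import DEFAULT_GROUPS, generate_groups


@pytest.fixture(scope="session")
def default_groups():
    """The default four-group synthetic scenario, fixed seed."""
    return generate_groups(DEFAULT_GROUPS, seed=7)


@pytest.fixture(scope="session")
def default_points(default_groups):
    return [p for pts in default_groups.values() for p in pts]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_points(x, y, group="g", taxon_prefix="t"):
    """RatePoints from log10 mass / log10 kC arrays (helper for tests)."""
    pts = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        M = 10.0**xi
        kC = 10.0**yi
        pts.append(
            RatePoint(
                taxon=f"{taxon_prefix}{i}",
                group=group,
                M=M,
                rate_kC=kC,
                rate_Gmax=M * kC,
            )
        )
    return pts
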