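import numpy as np
import pytest

from phenokin import GrowthTransitionModel, bundled_model


def random_model(rng, m=3, g_low=-0.5, g_high=1.0, k_scale=0.5,
                 irreducible=True):
    """Random growth-transition model; by default every directed transition
    is present, which makes the off-diagonal structure strongly connected."""
    g = rng.uniform(g_low, g_high, size=m)
    if irreducible:
        k = rng.uniform(0.01, k_scale, size=(m, m))
    else:
        k = rng.uniform(0.0, k_scale, size=(m, m)) * (rng.random((m, m)) < 0.5)
    np.fill_diagonal(k, 0.0)
    labels = tuple(f"P{i}" for i in range(m))
    return GrowthTransitionModel(labels=labels, growth=g, transitions=k)


def random_two_state(rng, k_low=0.02, k_high=1.0):
    from phenokin import TwoStateParams

    return TwoStateParams(
        g_x=rng.uniform(-0.5, 1.0),
        g_y=rng.uniform(-0.5, 1.0),
        k_xy=rng.uniform(k_low, k_high),
        k_yx=rng.uniform(k_low, k_high),
    )


@pytest.fixture(scope="session")
def sum159():
    return bundled_model("sum159")


@pytest.fixture(scope="session")
def sum149():
    return bundled_model("sum149")
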