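import numpy as np
import pytest

from seirsat import Parameters, get_preset


@pytest.fixture(scope="session")
def case1() -> Parameters:
    """R0 < 1, b > 0: disease-free regime (strong treatment supply)."""
    return get_preset("case1").parameters


@pytest.fixture(scope="session")
def case2() -> Parameters:
    """R0 > 1, k < k1, d > r: unique globally stable endemic point."""
    return get_preset("case2").parameters


@pytest.fixture(scope="session")
def case3() -> Parameters:
    """R0c < R0 < 1, b < 0: backward bifurcation, bistable regime."""
    return get_preset("case3").parameters


@pytest.fixture(scope="session")
def all_presets(case1, case2, case3):
    return {"case1": case1, "case2": case2, "case3": case3}


def random_parameters(rng: np.random.Generator) -> Parameters:
    """A random valid parameter draw over scientifically plausible ranges."""
    return Parameters(
        A=rng.uniform(0.5, 50),
        beta=rng.uniform(0.001, 1.0),
        alpha=rng.uniform(0, 2.0),
        d=rng.uniform(0.01, 1.0),
        epsilon=rng.uniform(0.05, 2.0),
        mu=rng.uniform(0.01, 1.0),
        upsilon=rng.uniform(0.01, 1.0),
        r=rng.uniform(0.01, 3.0),
        k=rng.uniform(0, 4.0),
    )
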