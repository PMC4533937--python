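import numpy as np
import pytest

from kmtchain import ModelParams, StateSpace, build_kernel


@pytest.fixture(scope="session")
def space_n2():
    return StateSpace(2)


@pytest.fixture(scope="session")
def space_n10():
    return StateSpace(10)


@pytest.fixture(scope="session")
def meiosis_ideal(space_n10):
    """Ideal meiosis I: p = q = 0.05, alpha = beta = 0, n = 10."""
    return build_kernel(ModelParams.meiosis_I(), space_n10)


@pytest.fixture(scope="session")
def meiosis_random(space_n10):
    """Random meiosis I condition: alpha = beta = 1, p = q = 0.05."""
    params = ModelParams(n=10, p=0.05, q=0.05, alpha=1.0, beta=1.0,
                         gamma=1.0, mode="meiosis_I")
    return build_kernel(params, space_n10)


def random_params(rng: np.random.Generator, mode: str | None = None,
                  n: int | None = None) -> ModelParams:
    """A parameter set drawn uniformly from the admissible ranges."""
    mode = mode or rng.choice(["meiosis_I", "mitosis"])
    n = int(n if n is not None else rng.integers(2, 7))
    return ModelParams(
        n=n,
        p=float(rng.uniform(0, 0.25)),
        q=float(rng.uniform(0, 1 / (2 * n))),
        alpha=0.0 if mode == "mitosis" else float(rng.uniform(0, 1)),
        beta=float(rng.uniform(0, 1)),
        gamma=1.0 if mode == "meiosis_I" else float(rng.uniform(0, 1)),
        mode=mode,
    )
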