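import numpy as np
import pytest

from gmr3.model_spec import Dataset, VariableSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_numeric_dataset(rng, N=200, P=4, R=3, S=2, sigma=1.0):
    """All-numeric predictors/responses with a true rank-S structure."""
    X = rng.standard_normal((N, P))
    B = np.linalg.qr(rng.standard_normal((P, S)))[0]
    V = rng.uniform(-1, 1, (R, S))
    Y = 0.5 + X @ B @ V.T + sigma * rng.standard_normal((N, R))
    return Dataset(
        X=X, Y=Y,
        predictor_specs=[VariableSpec(f"x{j}", "predictor", "numeric") for j in range(P)],
        response_specs=[VariableSpec(f"y{r}", "response", "numeric") for r in range(R)],
    ), B @ V.T


@pytest.fixture
def numeric_dataset(rng):
    return make_numeric_dataset(rng)[0]


@pytest.fixture
def mixed_dataset():
    """Small fully mixed dataset from the built-in generator."""
    from gmr3.simulation import gen_study1

    return gen_study1("gmr3-pr", N=150, seed=7).dataset
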