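import numpy as np
import pytest

from fireflyfit import ModelSpec, generate_dataset, get_model


def sphere(x):
    return float(np.sum(np.asarray(x, float) ** 2))


@pytest.fixture
def sphere_objective():
    return sphere


@pytest.fixture(scope="session")
def p53():
    """(spec, nominal params) for the base p53 negative-feedback model."""
    return get_model("p53_E1")


@pytest.fixture(scope="session")
def arginine():
    """(spec, nominal params) for the base arginine catabolism model."""
    return get_model("arginine_F1")


@pytest.fixture(scope="session")
def arginine_noiseless(arginine):
    spec, params = arginine
    return generate_dataset(spec, params, level=0.0, seed=0)


@pytest.fixture(scope="session")
def arginine_noisy(arginine):
    spec, params = arginine
    return generate_dataset(spec, params, level=0.25, seed=0)


def make_constant_model(initial, n_params=2, name="constant"):
    """A model whose trajectory is frozen at its initial state (zero field)."""
    initial = np.asarray(initial, float)
    k = len(initial)
    return ModelSpec(
        name=name,
        state_names=tuple(f"s{i}" for i in range(k)),
        param_names=tuple(f"p{i}" for i in range(n_params)),
        rhs=lambda s, x, t, u: np.zeros_like(s),
        initial_state=initial,
        observed_indices=tuple(range(k)),
        default_bounds=np.column_stack([np.zeros(n_params), np.ones(n_params)]),
    )
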