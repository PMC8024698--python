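import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("deterministic")

from priorpool import (
    MCMCConfig,
    NormalDensity,
    PriorAssignment,
    default_generator_spec,
    default_scheme,
    generate_dyads,
)
from priorpool.pathmodel import Equation, PathModelSpec


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_dyads():
    """102 complete dyads from the calibrated generator."""
    return generate_dyads(default_generator_spec(n=102, include_aux=False), seed=314)


@pytest.fixture
def single_equation_spec():
    """y = beta * x + e, no intercept — the conjugate-oracle workhorse."""
    return PathModelSpec(
        label="toy",
        equations=(Equation("y", ("x",), ("beta",)),),
        include_intercepts=False,
    )


@pytest.fixture
def toy_regression():
    rng = np.random.default_rng(42)
    n = 200
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y})
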