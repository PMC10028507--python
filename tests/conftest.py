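import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from ehrgame import BASELINE, PARAM_NAMES, MixedState, ParameterSet

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


def finite_floats(lo, hi):
    return st.floats(lo, hi, allow_nan=False, allow_infinity=False)


@st.composite
def parameter_sets(draw, lo=0.0, hi=120.0):
    """Strategy for strict-mode parameter sets (Cg > Kg, Ch > Kh)."""
    values = {name: draw(finite_floats(lo, hi)) for name in PARAM_NAMES}
    values["Cg"] = values["Kg"] + draw(finite_floats(1e-6, hi))
    values["Ch"] = values["Kh"] + draw(finite_floats(1e-6, hi))
    return ParameterSet(**values)


@st.composite
def mixed_states(draw, margin=0.0):
    return MixedState(
        draw(finite_floats(margin, 1.0 - margin)),
        draw(finite_floats(margin, 1.0 - margin)),
        draw(finite_floats(margin, 1.0 - margin)),
    )


@pytest.fixture
def baseline():
    return BASELINE


@pytest.fixture
def rng():
    return np.random.default_rng(20230306)


def random_parameter_set(rng, scale=100.0):
    """Seeded strict-mode parameter set for loop-style property tests."""
    values = dict(zip(PARAM_NAMES, rng.uniform(0.0, scale, size=len(PARAM_NAMES))))
    values["Cg"] = values["Kg"] + rng.uniform(1e-6, scale)
    values["Ch"] = values["Kh"] + rng.uniform(1e-6, scale)
    return ParameterSet(**values)
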