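import numpy as np
import pytest

import navresurge as nv


@pytest.fixture(scope="session")
def wt_params():
    return nv.wild_type()


@pytest.fixture(scope="session")
def ko_params():
    return nv.scn4b_null()


@pytest.fixture(scope="session")
def wt_model(wt_params):
    return nv.NavModel(wt_params)


@pytest.fixture(scope="session")
def ko_model(ko_params):
    return nv.NavModel(ko_params)


@pytest.fixture(scope="session")
def ob_model():
    return nv.build_ob_scheme(nv.synthetic_ob_rates())


@pytest.fixture(scope="session")
def three_component(wt_model):
    """Classic paradigm: hold -80 mV, 5 ms at 0 mV, 100 ms at -45 mV."""
    return nv.three_component_trace(wt_model)


def exact_rates(params, v):
    """Independent high-precision evaluation of the printed rate laws.

    Pure-math re-derivation (math.exp, no numpy) used as the oracle for
    the kinetics module.
    """
    import math

    tf = 1.0 / params.q10 ** ((37.0 - (params.temperature_K - 273.0)) / 10.0)
    a11 = tf / (params.a11_variable1 * math.exp(-v / params.a11_variable2))
    b11 = tf / (params.b11_variable1 * math.exp(v / params.b11_variable2))
    out = {
        "a11": a11,
        "a12": params.a12 * a11,
        "a13": params.a13 * a11,
        "b11": b11,
        "b12": params.b12 * b11,
        "b13": params.b13 * b11,
        "a3": tf * params.a3_variable1 * math.exp(-v / params.a3_variable2),
        "b3": tf * params.b3_variable1 * math.exp(v / params.b3_variable2),
        "a2": tf * params.a2_variable1 * math.exp(v / params.a2_variable2),
        "a6": tf * params.a6_variable1 * math.exp(v / params.a6_variable2),
        "b6": tf * params.b6_variable1 * math.exp(-v / params.b6_variable2),
        "a2s": tf * params.a2s_variable1 * math.exp(v / params.a2s_variable2),
        "b2s": tf * params.b2s_variable1 * math.exp(-v / params.b2s_variable2),
        "a3s": tf * params.a3s_variable1 * math.exp(-v / params.a3s_variable2),
    }
    out["b2"] = out["a13"] * out["a2"] * out["a3"] / (out["b13"] * out["b3"])
    out["b3s"] = out["a2s"] * out["a3s"] * out["a13"] / (out["b2s"] * out["b13"])
    return out


@pytest.fixture(scope="session")
def rate_oracle():
    return exact_rates


def euler_propagate(q, p0, duration_ms, dt_ms):
    """Forward-Euler integration oracle for occupancy propagation."""
    n = int(round(duration_ms / dt_ms))
    p = np.array(p0, dtype=float)
    for _ in range(n):
        p = p + dt_ms * (p @ q)
    return p


@pytest.fixture(scope="session")
def euler_oracle():
    return euler_propagate
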