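import numpy as np
import pytest

import ergwave as ew
from ergwave.protocol import default_protocol


@pytest.fixture(scope="session")
def da3():
    return ew.default_template("dark", 3.0)


@pytest.fixture(scope="session")
def da10():
    return ew.default_template("dark", 10.0)


@pytest.fixture(scope="session")
def dark_steps():
    """The two higher-intensity dark-adapted protocol steps (3, 10 cd*s/m^2)."""
    proto = default_protocol()
    return (proto[1], proto[2])


@pytest.fixture
def small_cohort(dark_steps):
    """A 4-animal cohort restricted to the WDS-bearing dark-adapted steps."""
    spec = ew.CohortSpec(n_animals=4, steps=dark_steps, seed=11)
    return ew.generate_cohort(spec)


def dense_extrema(params, lo, hi, mode, dt=0.01):
    """Brute-force extremum of the closed-form component sum on a dense grid."""
    t = np.arange(lo, hi, dt)
    v = ew.component_model(params, t)
    idx = np.argmax(v) if mode == "max" else np.argmin(v)
    return float(t[idx]), float(v[idx])


def dense_local_maxima(params, lo, hi, dt=0.01):
    """All strict local maxima (time, value) of the component sum in [lo, hi]."""
    t = np.arange(lo, hi, dt)
    v = ew.component_model(params, t)
    d = np.diff(v)
    idx = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    return [(float(t[i]), float(v[i])) for i in idx]
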