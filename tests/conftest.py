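import numpy as np
import pytest

import heatchain as hc
from heatchain.nemd import SimConfig, run_current_stats, thermalized_state


@pytest.fixture(scope="session")
def band_dk1():
    return hc.PhononBand(onsite=1.0, coupling=1.0, mass=1.0)


@pytest.fixture(scope="session")
def uniform12():
    spec = hc.UniformHarmonicSpec(n_sites=12, n_reservoir=2)
    res = hc.ReservoirConfig(gamma=0.8, t_left=1.25, t_right=0.75, n_reservoir=2)
    return spec, res


@pytest.fixture(scope="session")
def nemd_uniform12(uniform12):
    """One moderately long NEMD run shared across tests."""
    spec, res = uniform12
    x0, v0 = thermalized_state(spec, 1.0, 42)
    cfg = SimConfig(dt=0.02, n_steps=2_000_000, seed=3)
    return run_current_stats(spec, res, cfg, x0=x0, v0=v0), spec, res, cfg


@pytest.fixture(scope="session")
def equilibrium12():
    spec = hc.UniformHarmonicSpec(n_sites=12, n_reservoir=2)
    res = hc.ReservoirConfig(gamma=0.8, t_left=1.0, t_right=1.0, n_reservoir=2)
    x0, v0 = thermalized_state(spec, 1.0, 43)
    st = run_current_stats(spec, res, SimConfig(dt=0.02, n_steps=2_000_000, seed=5),
                           x0=x0, v0=v0)
    return st, spec, res


def rel_err(a, b):
    return abs(a - b) / abs(b)
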