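import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mgmin import MethylMatrix, MixtureSpec, SimulationSpec, simulate_array

TYPE_I_MIX = MixtureSpec(((0.3, -4.0, 1.0), (0.3, 0.0, 1.0), (0.4, 4.0, 1.0)))


@pytest.fixture(scope="session")
def mixture_draws():
    """200k draws from the canonical three-state mixture, with labels."""
    rng = np.random.default_rng(2024)
    comp = rng.choice(3, size=200_000, p=[0.3, 0.3, 0.4])
    x = np.array([-4.0, 0.0, 4.0])[comp] + rng.standard_normal(200_000)
    return x, comp


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated array: 3 replicates with noise, default bias."""
    spec = SimulationSpec(n_typeI=4_000, n_typeII=10_000, n_samples=3,
                          replicate_noise_sd=0.3, seed=11)
    return simulate_array(spec)


@pytest.fixture
def tiny_matrix():
    """3 probes x 2 samples on the beta scale, one NA cell."""
    values = pd.DataFrame(
        {"s1": [0.1, 0.5, np.nan], "s2": [0.2, 0.6, 0.9]},
        index=pd.Index(["cg01", "cg02", "cg03"], name="probe_id"),
    )
    probe_type = pd.Series(["I", "II", "II"],
                           index=values.index, name="probe_type")
    return MethylMatrix(values=values, probe_type=probe_type, scale="beta")
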