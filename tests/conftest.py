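import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from oescreen.io_model import AnalysisConfig
from oescreen.synthetic import SimulationParams, emit_fixture, simulate_cohort

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


SMALL_PARAMS = SimulationParams(
    n_probes=400, n_de_probes=30, n_cognition_linked=7,
    n_coregulated_pairs=10)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def cohort(small_params):
    return simulate_cohort(small_params, seed=11)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_params):
    """A complete synthetic input directory shared across tests."""
    out = tmp_path_factory.mktemp("fixture")
    emit_fixture(small_params, out, seed=11)
    return out


@pytest.fixture(scope="session")
def fast_config() -> AnalysisConfig:
    return AnalysisConfig(n_permutations=5000, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_samples(n_sz=8, n_ctrl=8, sex=None, education=None) -> pd.DataFrame:
    """Minimal handcrafted sample table for unit tests."""
    ids = [f"S{i}" for i in range(n_sz)] + [f"C{i}" for i in range(n_ctrl)]
    n = len(ids)
    return pd.DataFrame({
        "sample_id": ids,
        "group": ["SZ"] * n_sz + ["control"] * n_ctrl,
        "sex": sex if sex is not None else ["male", "female"] * (n // 2),
        "age": np.linspace(25, 55, n),
        "race": ["Caucasian", "African American"] * (n // 2),
        "education": education if education is not None
        else np.tile([10, 12, 14, 16], n)[:n],
        "smoking_packs_per_day": [0.0, 1.0] * (n // 2),
        "cpz_equivalent": [300.0] * n_sz + [np.nan] * n_ctrl,
        "tissue": "OE",
    })
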