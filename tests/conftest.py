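import numpy as np
import pytest

from vaxstab.core_io import Container, StabilityDataset, StabilityRecord
from vaxstab.hier_model import McmcConfig, fit_gibbs
from vaxstab.synthetic_data import (
    GeneratorConfig,
    default_cohort_design,
    sample_true_parameters,
    simulate_dataset,
)


def make_records(n=3, temperature=5.0, container=Container.VIAL):
    return [
        StabilityRecord(
            batch_id="B01",
            molecular_type="A",
            container=container,
            temperature_C=temperature,
            time_months=float(3 * i),
            potency=100.0 - 0.5 * i,
        )
        for i in range(n)
    ]


@pytest.fixture
def tiny_dataset():
    return StabilityDataset(make_records())


@pytest.fixture(scope="session")
def default_design():
    return default_cohort_design()


@pytest.fixture(scope="session")
def default_params():
    return sample_true_parameters(GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def default_cohort(default_params, default_design):
    """Full-grid default cohort, fixed seed (shared across tests)."""
    return simulate_dataset(default_params, default_design, seed=7)


@pytest.fixture(scope="session")
def default_training_cohort(default_params, default_design):
    return simulate_dataset(default_params, default_design, seed=7,
                            use_training_grid=True)


@pytest.fixture(scope="session")
def fitted_default_draws(default_cohort):
    """One moderately sized full-grid fit reused by posterior-facing tests."""
    return fit_gibbs(
        default_cohort,
        mcmc=McmcConfig(n_iterations=2000, burn_in=500, n_chains=2, seed=11),
    )


def single_group_dataset(n=10, intercept=100.0, slope=-0.5, noise_sd=2.0, seed=42):
    rng = np.random.default_rng(seed)
    x = np.arange(n, dtype=float)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    records = [
        StabilityRecord("B01", "A", Container.VIAL, 5.0, float(t), float(v))
        for t, v in zip(x, y)
    ]
    return x, y, StabilityDataset(records)
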