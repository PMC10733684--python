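import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nirconfound as nc
from nirconfound.spectra import Inventory, SampleRecord, Spectrum, WavelengthGrid

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Root seed for every randomised fixture in the suite.
SUITE_SEED = 0


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic inventory at the study's default design, raw intensities."""
    return nc.generate_dataset(nc.GeneratorConfig(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def preprocessed_dataset(default_dataset):
    return nc.preprocess_inventory(default_dataset)


@pytest.fixture(scope="session")
def cleaned_dataset(preprocessed_dataset):
    return nc.clean_inventory(preprocessed_dataset)


@pytest.fixture(scope="session")
def workflow_a_table(preprocessed_dataset):
    """Full 4-constituent x 9-algorithm evaluation, shared across tests."""
    return nc.run_workflow_a(preprocessed_dataset, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def step1_comparison(preprocessed_dataset):
    """Full workflow B step 1 comparison, shared across tests."""
    return nc.run_step1(preprocessed_dataset, seed=SUITE_SEED)


def make_inventory(n_channels=32, samples=None):
    """Tiny hand-built inventory for unit tests."""
    grid = nc.default_grid(n_channels)
    rng = np.random.default_rng(42)
    if samples is None:
        samples = [
            dict(sample_id="A", day=7, mper=True),
            dict(sample_id="B", day=28, hav=True),
        ]
    records = []
    for meta in samples:
        n_reps = meta.pop("n_reps", 3)
        rec = SampleRecord(**meta)
        rec.replicates = [
            Spectrum(grid, rng.normal(0.5, 0.05, n_channels), r + 1)
            for r in range(n_reps)
        ]
        records.append(rec)
    return Inventory(records, grid)


@pytest.fixture
def tiny_inventory():
    return make_inventory()
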