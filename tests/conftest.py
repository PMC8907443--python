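import numpy as np
import pytest

from deltarad.radiomics import extract_catalog
from deltarad.synthetic_cohort import CohortConfig, simulate_cohort


def digitized_ball(radius: float, spacing: float) -> np.ndarray:
    """Binary mask of a ball of ``radius`` mm at isotropic ``spacing`` mm."""
    n = int(2 * radius / spacing) + 5
    c = (n - 1) / 2.0
    g = np.arange(n)
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    return ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= (radius / spacing) ** 2


@pytest.fixture(scope="session")
def ball_factory():
    return digitized_ball


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared across tests (6 patients, 6 timepoints)."""
    config = CohortConfig(n_patients=6, event_prevalence=0.35, rng_seed=11)
    series, records = simulate_cohort(config)
    return config, series, records


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    """Extracted per-timepoint feature vectors for the shared cohort."""
    _, series, _ = small_cohort
    return {s.patient_id: extract_catalog(s) for s in series}
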