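import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nichecontact import GeometryConfig, make_zone_masks, simulate_clinical_cohort
from nichecontact.io_core import CohortTable


@pytest.fixture(scope="session")
def geometry():
    return GeometryConfig()


@pytest.fixture(scope="session")
def zones(geometry):
    return make_zone_masks(geometry)


@pytest.fixture(scope="session")
def tabular_cohort():
    """Default-condition cohort: n=177, 12 censored, seed 42."""
    clinical, spatial, truth = simulate_clinical_cohort(
        n=177, seed=42, target_censored=12
    )
    return clinical, spatial, truth


@pytest.fixture(scope="session")
def cohort_table(tabular_cohort):
    clinical, spatial, _ = tabular_cohort
    return CohortTable(clinical=clinical, spatial=spatial)


@pytest.fixture
def rng():
    return np.random.default_rng(20240429)
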