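import logging

import numpy as np
import pytest

from clonetime.sigbranch import synthetic_spectra
from clonetime.simdata import SimConfig, simulate_patient

logging.getLogger("clonetime.simdata").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def spectra():
    return synthetic_spectra()


@pytest.fixture(scope="session")
def small_patient():
    """20-colony patient with a driver clade, clean reads (depth 30x)."""
    cfg = SimConfig(
        colonies_per_patient=20, age_at_diagnosis=40.0, depth_mean=30.0,
        mutant_fraction=0.45, clonality=1.0, seed=1,
    )
    return simulate_patient(cfg)


@pytest.fixture(scope="session")
def wt_patient():
    """Wild-type-only patient (no driver clade)."""
    cfg = SimConfig(
        colonies_per_patient=15, age_at_diagnosis=50.0, depth_mean=30.0,
        mutant_fraction=0.0, clonality=1.0, seed=3,
    )
    return simulate_patient(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
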