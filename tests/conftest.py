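import numpy as np
import pytest

from vesselmech.calibration import ground_truth_for
from vesselmech.mechanics import ConstitutiveParams
from vesselmech.synthetic import GeneratorConfig, generate_passive_dataset

NOISE_FREE = GeneratorConfig(diameter_noise_cv=0.0, force_noise_sd=0.0,
                             parameter_cv=0.0, geometry_cv=0.0, lam_iv_sd=0.0)


@pytest.fixture(scope="session")
def wt_truth():
    return ground_truth_for("WT", 168, "DTA")


@pytest.fixture(scope="session")
def generic_params():
    """A full 8-parameter set exercising every energy term."""
    return ConstitutiveParams(c=20.0, c1_axial=5.0, c2_axial=0.5,
                              c1_circ=8.0, c2_circ=1.2, c1_diag=6.0,
                              c2_diag=0.8, alpha0=0.7)


@pytest.fixture(scope="session")
def wt_noise_free_dataset():
    """Noise-free WT aorta dataset at the group-mean ground truth."""
    ds, truth = generate_passive_dataset("WT", 168, "DTA",
                                         specimen_id="wt_nf", seed=0,
                                         config=NOISE_FREE)
    return ds, truth


def random_admissible_states(n, rng):
    """Random incompressible biaxial states in the physiologic range."""
    lam_t = rng.uniform(0.9, 1.8, n)
    lam_z = rng.uniform(0.9, 1.8, n)
    return lam_t, lam_z


def random_admissible_params(rng):
    return ConstitutiveParams(
        c=rng.uniform(1, 40), c1_axial=rng.uniform(0.1, 20),
        c2_axial=rng.uniform(0.05, 4), c1_circ=rng.uniform(0.1, 20),
        c2_circ=rng.uniform(0.05, 4), c1_diag=rng.uniform(0.1, 20),
        c2_diag=rng.uniform(0.05, 4), alpha0=rng.uniform(0.2, 1.3))
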