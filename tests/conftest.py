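import numpy as np
import pytest
from hypothesis import settings

import fpt_recruit as fr

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def geometry():
    return fr.CellGeometry()


@pytest.fixture(scope="session")
def coarse_lattice():
    return fr.lattice_preset("coarse", fr.NBS1.diffusion_D)


@pytest.fixture(scope="session")
def kmc_ensembles(geometry, coarse_lattice):
    """Fixed-start NBS1 ensembles on the coarse lattice, keyed by r0.

    500 replicas at the mean start radius (also used for censoring and
    tail checks), 300 at the other radii of the starting range.
    """
    out = {}
    for r0, n in [(11.0, 300), (14.0, 300), (17.0, 500), (20.0, 300)]:
        out[r0] = fr.run_ensemble(fr.NBS1, coarse_lattice, geometry,
                                  n_replicas=n, horizon=1800.0,
                                  base_seed=20 + int(r0), r0=r0)
    return out


@pytest.fixture(scope="session")
def nbs1_recovery():
    """Synthetic NBS1 curve (truth mean 17 μm, σ_noise = 0.02) and its fit."""
    spec = fr.SyntheticSpec(fr.NBS1, true_mean_r0=17.0, noise_sigma=0.02,
                            seed=11)
    curve, truth = fr.generate_curve(spec)
    fit = fr.fit_start_mean(curve, fr.NBS1, search=(14.0, 20.0), step=0.25)
    return curve, truth, fit


@pytest.fixture(scope="session")
def mre11_recovery():
    """Synthetic MRE11-like curve (truth mean 14 μm) and its fit."""
    spec = fr.SyntheticSpec(fr.MRE11, true_mean_r0=14.0, noise_sigma=0.02,
                            seed=12)
    curve, truth = fr.generate_curve(spec)
    fit = fr.fit_start_mean(curve, fr.MRE11, search=(11.0, 17.0), step=0.25)
    return curve, truth, fit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
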