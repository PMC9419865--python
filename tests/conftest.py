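import numpy as np
import pytest

from epimech import synthetic
from epimech.datatypes import ContactModelParams

JUNCTION_E = 30.73     # Pa, cell-to-cell junction on the nanofibrous insert
SUBSTRATE_E = 118.1    # Pa, bare nanofibrous substrate
PROBE_R = 2.6e-6       # m, colloidal probe radius (5.2 um sphere)
BETA_NCCI = 1.37
BETA_TCPS = 0.0314


@pytest.fixture(scope="session")
def junction_curve():
    """Noise-free curve at the junction modulus, no adhesion/membrane."""
    params = ContactModelParams(E=JUNCTION_E, R=PROBE_R, z0=1.0)
    curve, truth = synthetic.gen_force_curve(params, z_range=1.4, n_points=500, seed=11)
    return curve, truth


@pytest.fixture(scope="session")
def adhesive_curve():
    """Noise-free adhesive curve (w = 1e-4 J/m^2) with membrane term.

    At this work of adhesion on a 100 Pa half-space the adhesive neck
    extends ~1.8 um below the contact point, so the piezo range must be
    generous for the retract tail to reach the force baseline.
    """
    params = ContactModelParams(E=100.0, R=PROBE_R, w=1e-4, K_m=1e-4, z0=3.0)
    curve, truth = synthetic.gen_force_curve(params, z_range=3.4, n_points=500, seed=12)
    return curve, truth


@pytest.fixture(scope="session")
def fiber_mat():
    """Noise-free isotropic mat at the reported diameter distribution."""
    img, truth = synthetic.gen_fiber_image(
        n_fibers=100, diameter_mean=622.0, diameter_sd=31.0,
        orientation_kappa=0.0, pixel_size=50.0, image_size=1024,
        noise_sd=0.0, seed=21,
    )
    return img, truth


@pytest.fixture(scope="session")
def monolayer():
    """Noise-free 12-cell monolayer with elliptical cells (e = 0.6)."""
    image, labels, truth = synthetic.gen_monolayer_image(
        n_cells=12, mean_area=400.0, eccentricity_target=0.6,
        intensity_mean_per_group=100.0, pixel_size=0.5, seed=31,
    )
    return image, labels, truth


@pytest.fixture(scope="session")
def wound_series():
    """Linear closure: 400 um wound, 10 um/h per front (closes at 20 h)."""
    return synthetic.gen_wound_series(
        initial_width=400.0, front_velocity=10.0,
        timepoints=[0, 6, 12, 18, 24], seed=41,
    )
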