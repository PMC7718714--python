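"""Shared fixtures: small textured images and phantoms, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from roireg import (PerturbationConfig, PhantomConfig, VesselConfig,
                    generate_phantom)


@pytest.fixture(scope="session")
def textured_image() -> np.ndarray:
    """256x256 band-limited texture with enough structure for SIFT."""
    rng = np.random.default_rng(42)
    t1 = ndi.gaussian_filter(rng.standard_normal((256, 256)), 1.5)
    t2 = ndi.gaussian_filter(rng.standard_normal((256, 256)), 4.0)
    img = 128 + 40 * t1 / t1.std() + 30 * t2 / t2.std()
    return np.clip(img, 0, 255)


@pytest.fixture(scope="session")
def static_pair_config() -> PhantomConfig:
    """Two-slice phantom with a drift-free vessel: truth is exactly the
    recorded perturbation, so parameter recovery is unambiguous."""
    return PhantomConfig(
        n_slices=2,
        vessel=VesselConfig(drift=(0.0, 0.0), curve=(0.0, 0.0), radius_drift=0.0),
        perturbation=PerturbationConfig(theta_max=6.0, shift_max=20.0),
        seed=123,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """Tiny 3-slice stack for fast pipeline smoke tests."""
    return generate_phantom(PhantomConfig(
        n_slices=3, canvas=(256, 256), roi_size=96,
        vessel=VesselConfig(center=(150.0, 130.0), lumen_radius=14.0,
                            wall_thickness=5.0),
        perturbation=PerturbationConfig(theta_max=5.0, shift_max=12.0),
        seed=5,
    ))
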