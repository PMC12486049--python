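"""Shared fixtures: Monte Carlo tables are expensive, so they are built once
per session at moderate photon counts and reused across test modules."""

from __future__ import annotations

import math

import numpy as np
import pytest

from tfosim.optics_model import BloodState, Hemodynamics, build_state_pair
from tfosim.photon_mc import Geometry, geometry_from_state, simulate_paths

#: photon budget for the shared layered tables
N_PHOTONS = 100_000
#: layered-run transport cutoffs: paths beyond these carry absorption weight
#: below e^-15 at physiological mu_a
MAX_PATH_MM = 800.0
MAX_DEPTH_BELOW_FETAL_MM = 100.0


def reference_hemodynamics() -> Hemodynamics:
    return Hemodynamics(
        maternal=BloodState(hb_conc=120.0, saturation=0.95),
        fetal=BloodState(hb_conc=165.0, saturation=0.40),
    )


def make_layered_table(dm: float, wavelength: float, n_photons: int = N_PHOTONS,
                       seed: int = 11):
    _, dia = build_state_pair(dm, reference_hemodynamics(), wavelength)
    geometry = geometry_from_state(dia)
    return simulate_paths(
        geometry,
        n_photons,
        seed=seed,
        max_path_mm=MAX_PATH_MM,
        max_depth_mm=dia.fetal_depth + MAX_DEPTH_BELOW_FETAL_MM,
    )


@pytest.fixture(scope="session")
def hemo():
    return reference_hemodynamics()


@pytest.fixture(scope="session")
def table_dm14_735():
    """dm = 14 mm (fetal depth 20 mm), 735 nm."""
    return make_layered_table(14.0, 735.0)


@pytest.fixture(scope="session")
def table_dm14_850():
    return make_layered_table(14.0, 850.0)


@pytest.fixture(scope="session")
def table_dm4_735():
    """Shallow geometry (fetal depth 10 mm), 735 nm."""
    return make_layered_table(4.0, 735.0)


@pytest.fixture(scope="session")
def table_dm6_735():
    """Fetal depth 12 mm, 735 nm (ambiguity partner of the 10 mm geometry)."""
    return make_layered_table(6.0, 735.0)


@pytest.fixture(scope="session")
def table_dm4_850():
    return make_layered_table(4.0, 850.0)


@pytest.fixture(scope="session")
def table_dm34_735():
    """Deepest sweep geometry (fetal depth 40 mm), 735 nm."""
    return make_layered_table(34.0, 735.0)


@pytest.fixture(scope="session")
def table_dm34_850():
    return make_layered_table(34.0, 850.0)


@pytest.fixture(scope="session")
def small_table():
    """A fast, small layered table for API-level tests."""
    return make_layered_table(14.0, 735.0, n_photons=20_000, seed=7)


def farrell_reflectance(rho_mm: np.ndarray, mu_a: float, mu_s_prime: float,
                        n_rel: float = 1.0) -> np.ndarray:
    """Diffusion-theory spatially resolved reflectance of a semi-infinite
    homogeneous medium (dipole source model), per mm^2 per launched photon.

    Independent closed-form oracle for the Monte Carlo: an isotropic point
    source at one transport mean free path below the surface plus its image
    above the extrapolated boundary.
    """
    rho = np.asarray(rho_mm, dtype=float)
    mu_t = mu_a + mu_s_prime
    mu_eff = math.sqrt(3.0 * mu_a * mu_t)
    z0 = 1.0 / mu_t
    d_coef = 1.0 / (3.0 * mu_t)
    if n_rel == 1.0:
        a_coef = 1.0
    else:  # Groenhuis internal-reflection approximation
        r_d = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
        a_coef = (1 + r_d) / (1 - r_d)
    zb = 2.0 * a_coef * d_coef
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2 * zb) ** 2 + rho**2)
    return (1.0 / (4.0 * math.pi)) * (
        z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
        + (z0 + 2 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    )


@pytest.fixture(scope="session")
def diffusion_oracle():
    return farrell_reflectance


@pytest.fixture(scope="session")
def homogeneous_geometry():
    """Semi-infinite homogeneous medium: mu_s' = 1 mm^-1, g = 0, matched index."""
    return Geometry(thickness=(math.inf,), mu_s=(1.0,), g=(0.0,), n=(1.0,))


# property tests must be reproducible run-to-run
try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass
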