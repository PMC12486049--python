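"""Tissue geometry, chromophore absorption and hemodynamic parameterisation.

The pregnant abdomen is modelled as four flat homogeneous layers — maternal
abdominal wall, uterine wall, amniotic fluid, fetal tissue (semi-infinite) —
each described by an absorption coefficient ``mu_a`` (mm^-1), a scattering
coefficient ``mu_s`` (mm^-1), a Henyey–Greenstein anisotropy ``g`` and a
refractive index ``n``.  Only the maternal wall and the fetal layer carry
blood: their ``mu_a`` is rebuilt from hemoglobin spectra for every
hemodynamic state, while the uterus and amniotic fluid keep fixed literature
values.

Absorption of a blood compartment is

    mu_a_blood = [Hb] * (S * eps_HbO2 + (1 - S) * eps_HHb)

with [Hb] the total hemoglobin concentration (g/L), S the oxygen saturation
and eps the extinction coefficients converted to mm^-1 per (g/L).  A
perfused layer combines equal arterial and venous compartments (5 % blood
volume fraction each) on top of a wavelength power-law background:

    mu_a_tissue = 0.05 * (mu_a_arterial + mu_a_venous)
                  + 7.84e7 * lambda_nm ** -3.255          [mm^-1]

Venous saturation defaults to 0.75 x arterial.  Fetal cardiac pulsation is
represented by two static states: systole carries 2.5 % more fetal
hemoglobin than diastole, all other parameters identical.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "UnsupportedWavelengthError",
    "ConfigError",
    "ExtinctionTable",
    "BloodState",
    "LayerOptics",
    "Hemodynamics",
    "TissueState",
    "SweepGrid",
    "EXTINCTION",
    "mu_a_blood",
    "mu_a_tissue",
    "venous_from_arterial",
    "build_state",
    "build_state_pair",
    "geometry_fetal_depth",
    "pulsation_pair",
    "enumerate_sweep",
    "static_layer_properties",
]


class UnsupportedWavelengthError(ValueError):
    """Requested wavelength is outside the embedded extinction data."""


class ConfigError(ValueError):
    """A tissue-model parameter is outside its configured range."""


# ---------------------------------------------------------------------------
# Constants (all exposed so a config file can override them)
# ---------------------------------------------------------------------------

#: blood volume fraction per compartment (arterial and venous each)
BLOOD_VOLUME_FRACTION = 0.05
#: venous saturation = VENOUS_SAT_FACTOR * arterial saturation
VENOUS_SAT_FACTOR = 0.75
#: fetal [Hb] is this much higher at systole than at diastole
PULSATION_FRACTION = 0.025
#: background (non-blood) absorption power law: A * lambda_nm**-P, mm^-1
BACKGROUND_A = 7.84e7
BACKGROUND_P = 3.255
#: hemoglobin molar mass, g/mol (tetramer)
HEMOGLOBIN_MOLAR_MASS = 64500.0
#: supported wavelength window for the embedded extinction table, nm
WAVELENGTH_RANGE = (600.0, 1000.0)

#: maternal wall thickness range, mm (fetal depth = dm + 5 mm uterus + 1 mm fluid)
DM_RANGE_MM = (4.0, 34.0)

_UTERUS_THICKNESS_MM = 5.0
_AMNIOTIC_THICKNESS_MM = 1.0


@dataclass(frozen=True)
class ExtinctionTable:
    """Decadic molar extinction coefficients of oxy/deoxy-hemoglobin.

    ``molar`` maps wavelength (nm) to ``(eps_HbO2, eps_HHb)`` in cm^-1/M
    from the standard compiled hemoglobin spectra.  :meth:`coefficients`
    returns them converted to mm^-1 per (g/L), i.e. multiplied by
    ``ln(10) / (64500 * 10)`` so they plug directly into the natural-log
    Beer–Lambert exponent used throughout the package.
    """

    molar: dict[float, tuple[float, float]]

    def coefficients(self, wavelength_nm: float) -> tuple[float, float]:
        lo, hi = WAVELENGTH_RANGE
        if not (lo <= wavelength_nm <= hi):
            raise UnsupportedWavelengthError(
                f"wavelength {wavelength_nm} nm outside supported range {lo}-{hi} nm"
            )
        try:
            eps_hbo, eps_hhb = self.molar[float(wavelength_nm)]
        except KeyError:
            raise UnsupportedWavelengthError(
                f"no extinction data embedded at {wavelength_nm} nm "
                f"(available: {sorted(self.molar)})"
            ) from None
        scale = math.log(10.0) / (HEMOGLOBIN_MOLAR_MASS * 10.0)
        return eps_hbo * scale, eps_hhb * scale

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.molar))


#: 740/850 nm rows from the compiled spectra; 735 nm linearly interpolated
#: between the 730 nm (390, 1102.2) and 740 nm rows.
EXTINCTION = ExtinctionTable(
    molar={
        735.0: (418.0, 1109.04),
        740.0: (446.0, 1115.88),
        850.0: (1058.0, 691.32),
    }
)


@dataclass(frozen=True)
class BloodState:
    """Total hemoglobin concentration (g/L) and arterial-style saturation."""

    hb_conc: float
    saturation: float

    def __post_init__(self) -> None:
        if self.hb_conc < 0:
            raise ConfigError(f"hb_conc must be >= 0, got {self.hb_conc}")
        if not 0.0 <= self.saturation <= 1.0:
            raise ConfigError(f"saturation must be in [0, 1], got {self.saturation}")


@dataclass(frozen=True)
class LayerOptics:
    """Optical properties of one homogeneous slab (thickness in mm)."""

    mu_a: float
    mu_s: float
    g: float
    n: float
    thickness: float  # math.inf marks a semi-infinite layer

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ConfigError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ConfigError(f"mu_s must be >= 0, got {self.mu_s}")
        if not 0.0 <= self.g < 1.0:
            raise ConfigError(f"anisotropy g must be in [0, 1), got {self.g}")
        if self.n < 1.0:
            raise ConfigError(f"refractive index must be >= 1, got {self.n}")
        if not self.thickness > 0:
            raise ConfigError(f"thickness must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class Hemodynamics:
    """Arterial blood states of the two perfused layers.

    Venous compartments are derived via ``venous_sat_factor``.
    """

    maternal: BloodState
    fetal: BloodState
    venous_sat_factor: float = VENOUS_SAT_FACTOR


@dataclass(frozen=True)
class TissueState:
    """Four-layer model at one instant (systole or diastole) and wavelength."""

    layers: tuple[LayerOptics, LayerOptics, LayerOptics, LayerOptics]
    dm: float
    hemodynamics: Hemodynamics
    wavelength: float
    phase: str  # "systole" | "diastole"

    def __post_init__(self) -> None:
        if len(self.layers) != 4:
            raise ConfigError("exactly 4 layers required")
        if self.phase not in ("systole", "diastole"):
            raise ConfigError(f"phase must be systole/diastole, got {self.phase!r}")
        if not math.isclose(self.layers[0].thickness, self.dm):
            raise ConfigError("dm must equal the maternal-wall layer thickness")

    @property
    def fetal_depth(self) -> float:
        """Depth of the fetal-tissue interface below the surface, mm."""
        return self.dm + self.layers[1].thickness + self.layers[2].thickness

    @property
    def mu_a(self) -> np.ndarray:
        """Per-layer absorption coefficients as a length-4 vector, mm^-1."""
        return np.array([lay.mu_a for lay in self.layers])


# ---------------------------------------------------------------------------
# Static literature properties (wavelength-keyed at the two source lines)
# ---------------------------------------------------------------------------

# per layer: {wavelength: (mu_a or None if hemodynamic, mu_s)}, plus g, n
_STATIC = {
    "maternal": {
        "spectral": {735.0: (None, 11.816), 850.0: (None, 11.169)},
        "g": 0.9,
        "n": 1.4,
    },
    "uterus": {
        "spectral": {735.0: (0.0158, 10.575), 850.0: (0.0991, 8.125)},
        "g": 0.9,
        "n": 1.4,
    },
    "amniotic": {
        "spectral": {735.0: (0.0125, 0.1), 850.0: (0.0042, 0.1)},
        "g": 0.9,
        "n": 1.33,
    },
    "fetal": {
        "spectral": {735.0: (None, 12.5), 850.0: (None, 9.916)},
        "g": 0.9,
        "n": 1.4,
    },
}

#: wavelengths at which static layer properties are tabulated
STATIC_WAVELENGTHS = (735.0, 850.0)


def _static_key(wavelength_nm: float) -> float:
    """Nearest tabulated wavelength for the static (non-blood) properties.

    The in-vivo probe uses a 740 nm LED; its static tissue properties are
    taken from the 735 nm column (within 10 nm the literature values are
    indistinguishable at the precision tabulated).
    """
    key = min(STATIC_WAVELENGTHS, key=lambda w: abs(w - wavelength_nm))
    if abs(key - wavelength_nm) > 10.0:
        raise UnsupportedWavelengthError(
            f"no static layer properties within 10 nm of {wavelength_nm} nm"
        )
    return key


def static_layer_properties(layer: str, wavelength_nm: float) -> dict:
    """Static optical properties of ``layer`` at the nearest tabulated line."""
    entry = _STATIC[layer]
    mu_a, mu_s = entry["spectral"][_static_key(wavelength_nm)]
    return {"mu_a": mu_a, "mu_s": mu_s, "g": entry["g"], "n": entry["n"]}


# ---------------------------------------------------------------------------
# Absorption model
# ---------------------------------------------------------------------------

def mu_a_blood(
    blood: BloodState,
    wavelength_nm: float,
    extinction: ExtinctionTable = EXTINCTION,
) -> float:
    """Absorption coefficient of whole blood, mm^-1.

    Linear in hemoglobin concentration and affine in saturation:
    ``[Hb] * (S * eps_HbO2 + (1 - S) * eps_HHb)``.
    """
    eps_hbo, eps_hhb = extinction.coefficients(wavelength_nm)
    s = blood.saturation
    return blood.hb_conc * (s * eps_hbo + (1.0 - s) * eps_hhb)


def venous_from_arterial(
    arterial: BloodState, factor: float = VENOUS_SAT_FACTOR
) -> BloodState:
    """Venous compartment with saturation scaled down from arterial."""
    return BloodState(hb_conc=arterial.hb_conc, saturation=factor * arterial.saturation)


def mu_a_tissue(
    arterial: BloodState,
    venous: BloodState,
    wavelength_nm: float,
    blood_fraction: float = BLOOD_VOLUME_FRACTION,
    extinction: ExtinctionTable = EXTINCTION,
) -> float:
    """Absorption of a perfused layer: blood compartments plus background.

    ``blood_fraction * (mu_a_arterial + mu_a_venous) + 7.84e7 * wl**-3.255``;
    the power-law background is independent of the blood states.
    """
    blood = mu_a_blood(arterial, wavelength_nm, extinction) + mu_a_blood(
        venous, wavelength_nm, extinction
    )
    background = BACKGROUND_A * wavelength_nm ** (-BACKGROUND_P)
    return blood_fraction * blood + background


# ---------------------------------------------------------------------------
# State construction
# ---------------------------------------------------------------------------

def geometry_fetal_depth(dm_mm: float) -> float:
    """Fetal depth (mm) for a maternal wall thickness: dm + uterus + fluid."""
    return dm_mm + _UTERUS_THICKNESS_MM + _AMNIOTIC_THICKNESS_MM


def build_state(
    dm_mm: float,
    hemodynamics: Hemodynamics,
    wavelength_nm: float,
    phase: str = "diastole",
    dm_range: tuple[float, float] = DM_RANGE_MM,
) -> TissueState:
    """Assemble the four-layer state for one hemodynamic instant.

    Layers 2-3 (uterus, amniotic fluid) use fixed literature ``mu_a``;
    layers 1 and 4 get ``mu_a`` from :func:`mu_a_tissue` with the maternal
    and fetal blood states.  Scattering, anisotropy and refractive index
    never depend on hemodynamics.  At systole the fetal hemoglobin
    concentration is raised by 2.5 % relative to the stored (diastolic)
    baseline.
    """
    if not dm_range[0] <= dm_mm <= dm_range[1]:
        raise ConfigError(
            f"maternal wall thickness {dm_mm} mm outside configured "
            f"range {dm_range[0]}-{dm_range[1]} mm"
        )

    fetal_art = hemodynamics.fetal
    if phase == "systole":
        fetal_art = replace(fetal_art, hb_conc=fetal_art.hb_conc * (1.0 + PULSATION_FRACTION))
    elif phase != "diastole":
        raise ConfigError(f"phase must be systole/diastole, got {phase!r}")

    vf = hemodynamics.venous_sat_factor
    maternal_art = hemodynamics.maternal
    mu_a_m = mu_a_tissue(maternal_art, venous_from_arterial(maternal_art, vf), wavelength_nm)
    mu_a_f = mu_a_tissue(fetal_art, venous_from_arterial(fetal_art, vf), wavelength_nm)

    p_m = static_layer_properties("maternal", wavelength_nm)
    p_u = static_layer_properties("uterus", wavelength_nm)
    p_a = static_layer_properties("amniotic", wavelength_nm)
    p_f = static_layer_properties("fetal", wavelength_nm)

    layers = (
        LayerOptics(mu_a=mu_a_m, mu_s=p_m["mu_s"], g=p_m["g"], n=p_m["n"], thickness=dm_mm),
        LayerOptics(mu_a=p_u["mu_a"], mu_s=p_u["mu_s"], g=p_u["g"], n=p_u["n"],
                    thickness=_UTERUS_THICKNESS_MM),
        LayerOptics(mu_a=p_a["mu_a"], mu_s=p_a["mu_s"], g=p_a["g"], n=p_a["n"],
                    thickness=_AMNIOTIC_THICKNESS_MM),
        LayerOptics(mu_a=mu_a_f, mu_s=p_f["mu_s"], g=p_f["g"], n=p_f["n"],
                    thickness=math.inf),
    )
    return TissueState(
        layers=layers, dm=dm_mm, hemodynamics=hemodynamics,
        wavelength=wavelength_nm, phase=phase,
    )


def build_state_pair(
    dm_mm: float, hemodynamics: Hemodynamics, wavelength_nm: float
) -> tuple[TissueState, TissueState]:
    """(systole, diastole) pair for one geometry/hemodynamics/wavelength."""
    return (
        build_state(dm_mm, hemodynamics, wavelength_nm, phase="systole"),
        build_state(dm_mm, hemodynamics, wavelength_nm, phase="diastole"),
    )


def pulsation_pair(state: TissueState) -> tuple[TissueState, TissueState]:
    """Expand one state into its (systole, diastole) fetal-pulsation pair.

    Only the fetal-layer ``mu_a`` differs between the two: systolic fetal
    [Hb] = diastolic x 1.025, so systolic fetal ``mu_a`` is the larger and
    the intensity ratio I_diastole / I_systole is >= 1.
    """
    return build_state_pair(state.dm, state.hemodynamics, state.wavelength)


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepGrid:
    """Cartesian sweep of the five hemodynamic/geometry parameters.

    Iteration order is dm (outermost), sm, sf, [Hb]m, [Hb]f, wavelength
    (innermost); every combination yields one (systole, diastole) pair.
    Defaults emulate a realistic term-pregnancy population: maternal
    saturation 85-100 %, fetal saturation 10-70 % (hypoxia range of
    interest), maternal [Hb] around 120 g/L, fetal [Hb] around 165 g/L.
    """

    dm: Sequence[float] = tuple(np.arange(4.0, 35.0, 1.0))
    sm: Sequence[float] = (0.85, 0.90, 0.95, 1.00)
    sf: Sequence[float] = tuple(np.round(np.arange(0.10, 0.7001, 0.05), 2))
    hb_m: Sequence[float] = (105.0, 120.0, 135.0)
    hb_f: Sequence[float] = (150.0, 165.0, 180.0)
    wavelengths: Sequence[float] = (735.0, 850.0)

    def __post_init__(self) -> None:
        for name in ("dm", "sm", "sf", "hb_m", "hb_f", "wavelengths"):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"sweep list {name!r} is empty")

    @property
    def n_states(self) -> int:
        """Number of (systole, diastole) pairs the sweep enumerates."""
        return (
            len(self.dm) * len(self.sm) * len(self.sf)
            * len(self.hb_m) * len(self.hb_f) * len(self.wavelengths)
        )

    @property
    def n_hemodynamic(self) -> int:
        """Hemodynamic combinations per geometry (excluding wavelength)."""
        return len(self.sm) * len(self.sf) * len(self.hb_m) * len(self.hb_f)


def enumerate_sweep(
    grid: SweepGrid,
) -> Iterator[tuple[dict, TissueState, TissueState]]:
    """Yield ``(params, systole, diastole)`` over the grid, deterministically.

    ``params`` records dm, sm, sf, hb_m, hb_f and wavelength for labelling.
    """
    for dm, sm, sf, hb_m, hb_f, wl in itertools.product(
        grid.dm, grid.sm, grid.sf, grid.hb_m, grid.hb_f, grid.wavelengths
    ):
        hemo = Hemodynamics(
            maternal=BloodState(hb_conc=hb_m, saturation=sm),
            fetal=BloodState(hb_conc=hb_f, saturation=sf),
        )
        systole, diastole = build_state_pair(dm, hemo, wl)
        params = {"dm": dm, "sm": sm, "sf": sf, "hb_m": hb_m, "hb_f": hb_f,
                  "wavelength": wl}
        yield params, systole, diastole
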