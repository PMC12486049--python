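"""Forward computation on a pathlength table: intensity, sensitivity, EPR, RoR.

Everything here is a deterministic functional of a
:class:`~tfosim.photon_mc.PathlengthTable` plus one or two per-layer
absorption assignments.  The central quantities:

* normalized detected intensity  ``I = (1/N) sum_i w_i exp(-sum_j mu_a,j L_ij)``
* its derivative w.r.t. a layer absorption, ``dI/dmu_a,j = -(1/N) sum_i w_i L_ij exp(...)``
* fetal sensitivity  ``|dI/dmu_a,f| / (|dI/dmu_a,f| + |dI/dmu_a,m|)``
* the exponential pulsation ratio  ``EPR = I_diastole / I_systole`` (>= 1,
  since systole carries the extra fetal hemoglobin)
* the two-wavelength ratio-of-ratios baseline ``RoR = ln EPR_wl1 / ln EPR_wl2``

plus the EPR-vs-SDD curve smoothing used to de-noise Monte Carlo features:
central differences, a 2-point moving average of the differences, and
regeneration of the curve by cumulative summation from the first point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .optics_model import ConfigError, TissueState
from .photon_mc import PathlengthTable, ring_collect, classify_fetal_sensitive

__all__ = [
    "MuAssignment",
    "DistributionSummary",
    "GeometryMismatchError",
    "UndefinedRatioError",
    "mu_from_state",
    "intensity",
    "sensitivity_derivative",
    "fetal_sensitivity",
    "fetal_sensitive_intensity",
    "epr",
    "ror",
    "ring_intensities",
    "epr_curve",
    "smooth_epr_curve",
    "interp_epr",
    "epr_features",
    "ror_features",
    "find_saturation_collision",
    "pathlength_summary",
]

MATERNAL_LAYER = 0
FETAL_LAYER = 3

#: the five probe SDDs (mm) used to form the ten-EPR feature vector
FEATURE_SDDS = (15.0, 33.0, 46.0, 68.0, 94.0)


class GeometryMismatchError(ValueError):
    """Absorption assignment belongs to a different geometry than the table."""


class UndefinedRatioError(ZeroDivisionError):
    """EPR/RoR undefined (empty ring, zero intensity, or log of 1)."""


@dataclass(frozen=True)
class MuAssignment:
    """Per-layer absorption coefficients (mm^-1) of one tissue state.

    ``wavelength``/``dm`` are optional provenance used to guard against
    applying an assignment to a table with a different geometry.
    """

    mu_a: tuple[float, ...]
    wavelength: float | None = None
    dm: float | None = None

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.mu_a):
            raise ConfigError("mu_a entries must be >= 0")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.mu_a, dtype=float)


def mu_from_state(state: TissueState) -> MuAssignment:
    return MuAssignment(
        mu_a=tuple(float(m) for m in state.mu_a),
        wavelength=state.wavelength,
        dm=state.dm,
    )


def _as_mu_vector(table: PathlengthTable, mu) -> np.ndarray:
    if isinstance(mu, MuAssignment):
        if mu.wavelength is not None and table.geometry.wavelength is not None:
            if not np.isclose(mu.wavelength, table.geometry.wavelength):
                raise GeometryMismatchError(
                    f"assignment at {mu.wavelength} nm vs table at "
                    f"{table.geometry.wavelength} nm"
                )
        if mu.dm is not None and not np.isclose(mu.dm, table.geometry.thickness[0]):
            raise GeometryMismatchError(
                f"assignment dm={mu.dm} mm vs table dm={table.geometry.thickness[0]} mm"
            )
        vec = mu.vector
    else:
        vec = np.asarray(mu, dtype=float)
    if vec.shape != (table.geometry.n_layers,):
        raise GeometryMismatchError(
            f"mu_a length {vec.shape} does not match table layers "
            f"({table.geometry.n_layers})"
        )
    if np.any(vec < 0):
        raise ConfigError("mu_a entries must be >= 0")
    return vec


# ---------------------------------------------------------------------------
# Intensity and sensitivity
# ---------------------------------------------------------------------------

def intensity(
    table: PathlengthTable, mu, sdd: float, per_area: bool = False
) -> float:
    """Normalized detected intensity of the ring at ``sdd``.

    ``(1/n_launched) * sum_i w_i exp(-mu_a . L_i)`` over the ring's records;
    strictly decreasing in each ``mu_a,j`` with positive pathlength mass.
    With ``per_area`` the value is divided by the ring annulus area (mm^-2),
    the form compared against diffusion theory.
    """
    vec = _as_mu_vector(table, mu)
    mask = ring_collect(table, sdd)
    w = table.weight[mask] * np.exp(-table.lengths[mask] @ vec)
    val = float(w.sum()) / table.n_launched
    if per_area:
        val /= table.detectors.ring_area(sdd)
    return val


def sensitivity_derivative(table: PathlengthTable, mu, sdd: float, layer: int) -> float:
    """``dI/dmu_a,layer`` — always <= 0 (more absorption, less light)."""
    vec = _as_mu_vector(table, mu)
    if not 0 <= layer < table.geometry.n_layers:
        raise ConfigError(f"layer index {layer} out of range")
    mask = ring_collect(table, sdd)
    w = table.weight[mask] * np.exp(-table.lengths[mask] @ vec)
    return -float((w * table.lengths[mask, layer]).sum()) / table.n_launched


def fetal_sensitivity(
    table: PathlengthTable,
    mu,
    sdd: float,
    fetal_layer: int = FETAL_LAYER,
    maternal_layer: int = MATERNAL_LAYER,
) -> float:
    """Fraction of pulsatile signal strength attributable to the fetal layer.

    ``|dI/dmu_a,f| / (|dI/dmu_a,f| + |dI/dmu_a,m|)``; 0 when no detected
    photon probes the fetal layer, approaching 1 at large SDD where every
    photon does.
    """
    df = abs(sensitivity_derivative(table, mu, sdd, fetal_layer))
    dm_ = abs(sensitivity_derivative(table, mu, sdd, maternal_layer))
    if df + dm_ == 0.0:
        raise UndefinedRatioError(
            f"both sensitivity derivatives vanish at SDD {sdd} mm (empty ring?)"
        )
    return df / (df + dm_)


def fetal_sensitive_intensity(
    table: PathlengthTable, mu, sdd: float, fetal_layer: int = FETAL_LAYER
) -> tuple[float, float]:
    """(intensity from fetal-probing photons only, total intensity)."""
    vec = _as_mu_vector(table, mu)
    mask = ring_collect(table, sdd)
    w = table.weight[mask] * np.exp(-table.lengths[mask] @ vec)
    sens = classify_fetal_sensitive(table.lengths[mask], fetal_layer)
    total = float(w.sum()) / table.n_launched
    sensitive = float(w[sens].sum()) / table.n_launched
    return sensitive, total


# ---------------------------------------------------------------------------
# EPR and RoR
# ---------------------------------------------------------------------------

def epr(
    table: PathlengthTable,
    mu_systole,
    mu_diastole,
    sdd: float,
    fetal_layer: int = FETAL_LAYER,
) -> float:
    """Exponential pulsation ratio ``I_diastole / I_systole`` at one ring.

    The two assignments should differ only in the fetal layer (the
    pulsation model); anything else triggers a warning but the ratio is
    still computed.
    """
    v_sys = _as_mu_vector(table, mu_systole)
    v_dia = _as_mu_vector(table, mu_diastole)
    other = np.delete(np.arange(v_sys.size), fetal_layer)
    if not np.allclose(v_sys[other], v_dia[other]):
        warnings.warn(
            "systole/diastole assignments differ outside the fetal layer",
            stacklevel=2,
        )
    i_sys = intensity(table, v_sys, sdd)
    if i_sys == 0.0:
        raise UndefinedRatioError(f"zero systolic intensity at SDD {sdd} mm")
    return intensity(table, v_dia, sdd) / i_sys


def ror(epr_wl1: float, epr_wl2: float) -> float:
    """Ratio-of-ratios baseline: ``ln(EPR_wl1) / ln(EPR_wl2)``."""
    if epr_wl1 <= 0 or epr_wl2 <= 0:
        raise UndefinedRatioError("EPRs must be positive")
    denom = np.log(epr_wl2)
    if denom == 0.0:
        raise UndefinedRatioError("EPR at the reference wavelength equals 1")
    return float(np.log(epr_wl1) / denom)


def ring_intensities(table: PathlengthTable, mu) -> np.ndarray:
    """Normalized intensity at every ring at once (vectorised intensity())."""
    vec = _as_mu_vector(table, mu)
    w = table.weight * np.exp(-table.lengths @ vec)
    return (
        np.bincount(table.detector_index, weights=w,
                    minlength=len(table.detectors.sdds))
        / table.n_launched
    )


def epr_curve(table: PathlengthTable, mu_systole, mu_diastole) -> np.ndarray:
    """Raw EPR at every ring SDD; empty rings yield NaN."""
    i_sys = ring_intensities(table, mu_systole)
    i_dia = ring_intensities(table, mu_diastole)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(i_sys > 0, i_dia / np.where(i_sys > 0, i_sys, 1.0), np.nan)
    return out


def smooth_epr_curve(sdds: np.ndarray, eprs: np.ndarray) -> np.ndarray:
    """De-noise an EPR-vs-SDD curve through its finite differences.

    Central divided differences on interior points (one-sided at the two
    ends), a 2-point moving average of the difference sequence, then curve
    regeneration by cumulative summation anchored at the first point.
    Affine curves are exact fixed points.  Fewer than 3 points pass through
    unchanged with a warning.
    """
    x = np.asarray(sdds, dtype=float)
    y = np.asarray(eprs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("sdds and eprs must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        warnings.warn("fewer than 3 points: smoothing is a passthrough", stacklevel=2)
        return y.copy()
    if np.any(np.diff(x) <= 0):
        raise ConfigError("SDDs must be strictly increasing")

    d = np.empty(n)
    d[0] = (y[1] - y[0]) / (x[1] - x[0])
    d[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
    d[1:-1] = (y[2:] - y[:-2]) / (x[2:] - x[:-2])

    m = 0.5 * (d[:-1] + d[1:])  # 2-point moving average of the differences

    out = np.empty(n)
    out[0] = y[0]
    out[1:] = y[0] + np.cumsum(m * np.diff(x))
    return out


def interp_epr(
    sdds: np.ndarray, eprs: np.ndarray, target_sdds, smooth: bool = True
) -> np.ndarray:
    """EPR values at the probe SDDs, via smoothing + linear interpolation.

    NaN entries (empty rings) are first filled by linear interpolation over
    their finite neighbours so the smoothing pass stays well defined.
    """
    x = np.asarray(sdds, dtype=float)
    y = np.asarray(eprs, dtype=float).copy()
    finite = np.isfinite(y)
    if not finite.any():
        raise UndefinedRatioError("EPR curve has no finite values")
    if not finite.all():
        y[~finite] = np.interp(x[~finite], x[finite], y[finite])
    if smooth:
        y = smooth_epr_curve(x, y)
    return np.interp(np.asarray(target_sdds, dtype=float), x, y)


def epr_features(
    tables: dict,
    mu_sys_by_wl: dict,
    mu_dia_by_wl: dict,
    target_sdds=FEATURE_SDDS,
    smooth: bool = True,
) -> np.ndarray:
    """Ten-EPR feature vector: detector-major, wavelength-minor ordering.

    ``tables`` maps wavelength -> PathlengthTable; the assignments map
    wavelength -> (systole, diastole) MuAssignments.  With 5 target SDDs and
    2 wavelengths the result has length 10:
    ``[EPR(sdd1, wl1), EPR(sdd1, wl2), EPR(sdd2, wl1), ...]``.
    """
    wavelengths = sorted(tables)
    cols = []
    for wl in wavelengths:
        tab = tables[wl]
        curve = epr_curve(tab, mu_sys_by_wl[wl], mu_dia_by_wl[wl])
        cols.append(interp_epr(np.asarray(tab.detectors.sdds), curve, target_sdds, smooth))
    stacked = np.stack(cols, axis=1)  # (n_sdd, n_wl)
    return stacked.reshape(-1)


def ror_features(
    epr_vector: np.ndarray,
    n_wavelengths: int = 2,
    on_undefined: str = "zero",
) -> np.ndarray:
    """Per-detector RoR baseline features from a detector-major EPR vector.

    Collapses each detector's two per-wavelength EPRs into one
    ``ln(EPR_wl1)/ln(EPR_wl2)`` value (input width halves: 10 -> 5).  A
    channel whose reference EPR equals 1 (no detected fetal pulsation, e.g.
    a near detector over a deep fetus) has no defined RoR; with
    ``on_undefined="zero"`` it is encoded as 0 so feature matrices stay
    complete, with ``"raise"`` the strict error propagates.
    """
    arr = np.asarray(epr_vector, dtype=float).reshape(-1, n_wavelengths)
    if n_wavelengths != 2:
        raise ConfigError("RoR baseline is defined for two wavelengths")
    out = np.empty(arr.shape[0])
    for k, (e1, e2) in enumerate(arr):
        try:
            out[k] = ror(e1, e2)
        except UndefinedRatioError:
            if on_undefined != "zero":
                raise
            out[k] = 0.0
    return out


def find_saturation_collision(
    epr_a,
    epr_b,
    sf_grid=None,
    ring_indices=None,
    min_sf_gap: float = 0.05,
):
    """Construct a saturation-geometry ambiguity pair.

    ``epr_a(sf, ring_index)`` / ``epr_b(sf, ring_index)`` evaluate the EPR
    of two different geometries.  Searches for a ring and a saturation
    ``sf_a`` such that geometry B reaches the same EPR at a genuinely
    different saturation ``sf_b`` (root-finding on the fixed tables, so the
    two single-detector EPRs agree to solver precision), demonstrating that
    one detector cannot separate saturation from geometry.  Returns
    ``(ring_index, sf_a, sf_b)`` or ``None`` if the two geometries' EPR
    ranges never overlap.
    """
    from scipy.optimize import brentq

    sf_grid = np.arange(0.05, 0.951, 0.05) if sf_grid is None else np.asarray(sf_grid)
    ring_indices = range(6, 16) if ring_indices is None else ring_indices
    for idx in ring_indices:
        vals_b = np.array([epr_b(sf, idx) for sf in sf_grid])
        lo, hi = vals_b.min(), vals_b.max()
        for sf_a in sf_grid:
            target = epr_a(sf_a, idx)
            if not lo < target < hi:
                continue
            k = int(np.flatnonzero(np.diff(np.sign(vals_b - target)))[0])
            sf_b = brentq(
                lambda sf: epr_b(sf, idx) - target,
                sf_grid[k], sf_grid[k + 1], xtol=1e-6,
            )
            if abs(sf_b - sf_a) > min_sf_gap:
                return idx, float(sf_a), float(sf_b)
    return None


# ---------------------------------------------------------------------------
# Pathlength distribution summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSummary:
    """Quartiles and mean of a pathlength sample (mm)."""

    q1: float
    median: float
    q3: float
    q4: float  # maximum
    mean: float
    minimum: float
    n: int


def pathlength_summary(
    table: PathlengthTable, sdd: float, component="total"
) -> DistributionSummary:
    """Empirical quartiles/mean of total or per-layer pathlength at a ring.

    ``component`` is ``"total"`` or a 0-based layer index.  An empty ring is
    an error (there is no distribution to summarise).
    """
    mask = ring_collect(table, sdd)
    if not mask.any():
        raise UndefinedRatioError(f"empty ring at SDD {sdd} mm")
    if component == "total":
        sample = table.lengths[mask].sum(axis=1)
    else:
        layer = int(component)
        if not 0 <= layer < table.geometry.n_layers:
            raise ConfigError(f"layer index {layer} out of range")
        sample = table.lengths[mask, layer]
    q1, med, q3 = np.percentile(sample, [25, 50, 75])
    return DistributionSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        q4=float(sample.max()),
        mean=float(sample.mean()),
        minimum=float(sample.min()),
        n=int(sample.size),
    )
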