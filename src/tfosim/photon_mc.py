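"""White Monte Carlo photon transport through a flat layered medium.

Photons are launched as a pencil beam at the origin, normally incident, and
propagated with exponential step sampling on ``mu_s``, Henyey–Greenstein
scattering and Snell/Fresnel handling at refractive-index-mismatched
interfaces.  Absorption is *not* applied in flight ("white" Monte Carlo):
instead the per-layer geometric pathlengths L1..L4 of every detected photon
are recorded, so the detected intensity for *any* absorption assignment
follows afterwards by weighting each photon with ``exp(-sum_j mu_a,j L_j)``.
One simulation per geometry therefore serves every hemodynamic state.

Detection exploits cylindrical symmetry: the nominal probe is a line of
discrete detectors, but a photon exiting the top surface at radial distance
``r`` is captured by the ring ``|r - SDD| <= capture_radius``.  The absolute
intensity scale then differs from a discrete detector by a fixed geometric
(ring-area) factor which cancels in every ratio quantity (EPR, RoR, fetal
sensitivity).

An in-flight-absorption mode (``mode="absorb"``) exists as an independent
cross-check: run with the same seed it traverses byte-identical paths while
multiplying the photon weight by ``exp(-mu_a s)`` at every substep, so its
ring intensities must match the white-table reweighting to float precision.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .optics_model import ConfigError, TissueState

__all__ = [
    "DetectorGrid",
    "PathlengthTable",
    "Geometry",
    "simulate_paths",
    "ring_collect",
    "classify_fetal_sensitive",
    "geometry_from_state",
]

#: lateral termination radius, mm (negligible return probability at SDD <= 100)
DEFAULT_R_MAX_MM = 150.0
#: total-pathlength cutoff, mm (bounds runtime; recorded in the fingerprint)
DEFAULT_MAX_PATH_MM = 2000.0
#: depth cutoff, mm (inf = none; recorded in the fingerprint).  A photon this
#: deep can only return with a bottom-layer pathlength so large that its
#: absorption weight is negligible for any physiological mu_a.
DEFAULT_MAX_DEPTH_MM = math.inf
#: ambient (air) refractive index above the surface
N_AMBIENT = 1.0


@dataclass(frozen=True)
class DetectorGrid:
    """Ring detectors: SDD centres (mm) and a capture half-width (mm)."""

    sdds: tuple[float, ...] = tuple(np.round(np.linspace(10.0, 95.0, 20), 6))
    capture_radius: float = 2.0
    ring_averaging: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.sdds, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ConfigError("detector grid needs at least one SDD")
        if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
            raise ConfigError("SDDs must be strictly increasing and positive")
        if self.capture_radius <= 0:
            raise ConfigError("capture radius must be positive")
        if arr.size > 1 and np.min(np.diff(arr)) <= 2 * self.capture_radius:
            warnings.warn(
                "adjacent detector rings overlap (spacing <= 2 x capture radius)",
                stacklevel=2,
            )

    def index_of(self, sdd: float) -> int:
        arr = np.asarray(self.sdds)
        idx = int(np.argmin(np.abs(arr - sdd)))
        if not math.isclose(arr[idx], sdd, rel_tol=0, abs_tol=1e-6):
            raise ConfigError(f"SDD {sdd} mm is not in the detector grid")
        return idx

    def ring_area(self, sdd: float) -> float:
        """Annulus area (mm^2) of the ring centred at ``sdd``."""
        c = self.capture_radius
        r_in = max(sdd - c, 0.0)
        return math.pi * ((sdd + c) ** 2 - r_in**2)


@dataclass(frozen=True)
class Geometry:
    """Layer geometry and transport properties (no absorption).

    ``thickness[-1]`` may be ``inf`` for a semi-infinite bottom layer.
    """

    thickness: tuple[float, ...]
    mu_s: tuple[float, ...]
    g: tuple[float, ...]
    n: tuple[float, ...]
    wavelength: float | None = None

    def __post_init__(self) -> None:
        k = len(self.thickness)
        if not (len(self.mu_s) == len(self.g) == len(self.n) == k) or k == 0:
            raise ConfigError("geometry arrays must be non-empty and equal length")
        for j, (t, ms) in enumerate(zip(self.thickness, self.mu_s)):
            if not t > 0:
                raise ConfigError(f"layer {j} thickness must be > 0")
            if ms <= 0:
                raise ConfigError(f"layer {j} mu_s must be > 0 (scattering layer)")

    @property
    def n_layers(self) -> int:
        return len(self.thickness)


def geometry_from_state(state: TissueState) -> Geometry:
    """Strip the absorption coefficients off a tissue state."""
    return Geometry(
        thickness=tuple(lay.thickness for lay in state.layers),
        mu_s=tuple(lay.mu_s for lay in state.layers),
        g=tuple(lay.g for lay in state.layers),
        n=tuple(lay.n for lay in state.layers),
        wavelength=state.wavelength,
    )


@dataclass
class PathlengthTable:
    """Per-detected-photon partial pathlengths, the substrate of the forward model.

    Row ``i`` holds the geometric pathlength (mm) through each layer for one
    detected photon, its detector (ring) index, its exit radius and its
    launch weight (specular entry loss, and in-flight absorption when the
    oracle mode produced the table).
    """

    detector_index: np.ndarray  # (n,) int32
    lengths: np.ndarray         # (n, n_layers) float64
    weight: np.ndarray          # (n,) float64
    radius: np.ndarray          # (n,) float64
    n_launched: int
    seed: int
    detectors: DetectorGrid
    geometry: Geometry
    mode: str = "white"
    max_path_mm: float = DEFAULT_MAX_PATH_MM
    r_max_mm: float = DEFAULT_R_MAX_MM
    max_depth_mm: float = DEFAULT_MAX_DEPTH_MM
    mu_a: tuple[float, ...] | None = None  # set only in "absorb" mode

    @property
    def n_detected(self) -> int:
        return int(self.lengths.shape[0])

    def fingerprint(self) -> str:
        """Digest of everything that shapes the photon paths.

        Tables may be reused for any absorption assignment whose geometry
        matches this fingerprint; a mismatch is a hard error downstream.
        """
        payload = {
            "thickness": [t if math.isfinite(t) else "inf" for t in self.geometry.thickness],
            "mu_s": list(self.geometry.mu_s),
            "g": list(self.geometry.g),
            "n": list(self.geometry.n),
            "wavelength": self.geometry.wavelength,
            "sdds": list(self.detectors.sdds),
            "capture_radius": self.detectors.capture_radius,
            "max_path_mm": self.max_path_mm,
            "r_max_mm": self.r_max_mm,
            "max_depth_mm": self.max_depth_mm if math.isfinite(self.max_depth_mm) else "inf",
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        """Write the table to an HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("detector_index", data=self.detector_index)
            f.create_dataset("lengths", data=self.lengths)
            f.create_dataset("weight", data=self.weight)
            f.create_dataset("radius", data=self.radius)
            f.attrs["n_launched"] = self.n_launched
            f.attrs["seed"] = self.seed
            f.attrs["mode"] = self.mode
            f.attrs["max_path_mm"] = self.max_path_mm
            f.attrs["r_max_mm"] = self.r_max_mm
            f.attrs["max_depth_mm"] = (self.max_depth_mm
                                       if math.isfinite(self.max_depth_mm) else -1.0)
            f.attrs["fingerprint"] = self.fingerprint()
            f.attrs["geometry"] = json.dumps(
                {
                    "thickness": [t if math.isfinite(t) else "inf"
                                  for t in self.geometry.thickness],
                    "mu_s": list(self.geometry.mu_s),
                    "g": list(self.geometry.g),
                    "n": list(self.geometry.n),
                    "wavelength": self.geometry.wavelength,
                }
            )
            f.attrs["sdds"] = list(self.detectors.sdds)
            f.attrs["capture_radius"] = self.detectors.capture_radius
            if self.mu_a is not None:
                f.attrs["mu_a"] = list(self.mu_a)

    @classmethod
    def load(cls, path) -> "PathlengthTable":
        import h5py

        with h5py.File(path, "r") as f:
            geo = json.loads(f.attrs["geometry"])
            geometry = Geometry(
                thickness=tuple(math.inf if t == "inf" else float(t)
                                for t in geo["thickness"]),
                mu_s=tuple(geo["mu_s"]),
                g=tuple(geo["g"]),
                n=tuple(geo["n"]),
                wavelength=geo["wavelength"],
            )
            detectors = DetectorGrid(
                sdds=tuple(float(s) for s in f.attrs["sdds"]),
                capture_radius=float(f.attrs["capture_radius"]),
            )
            mu_a = tuple(f.attrs["mu_a"]) if "mu_a" in f.attrs else None
            return cls(
                detector_index=f["detector_index"][:],
                lengths=f["lengths"][:],
                weight=f["weight"][:],
                radius=f["radius"][:],
                n_launched=int(f.attrs["n_launched"]),
                seed=int(f.attrs["seed"]),
                detectors=detectors,
                geometry=geometry,
                mode=str(f.attrs["mode"]),
                max_path_mm=float(f.attrs["max_path_mm"]),
                r_max_mm=float(f.attrs["r_max_mm"]),
                max_depth_mm=(math.inf if float(f.attrs.get("max_depth_mm", -1.0)) < 0
                              else float(f.attrs["max_depth_mm"])),
                mu_a=mu_a,
            )

    def to_frame(self):
        """Columnar export (one row per detected photon) for small tables."""
        import pandas as pd

        cols = {f"L{j + 1}": self.lengths[:, j] for j in range(self.lengths.shape[1])}
        return pd.DataFrame(
            {"detector_index": self.detector_index,
             "sdd": np.asarray(self.detectors.sdds)[self.detector_index],
             "radius": self.radius, **cols, "weight": self.weight}
        )


# ---------------------------------------------------------------------------
# Transport kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _fresnel_r(n1, n2, cos_i):  # pragma: no cover - exercised via kernel
    """Unpolarized Fresnel reflectance; returns (R, cos_t)."""
    if n1 == n2:
        return 0.0, cos_i
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0, 0.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, fastmath=True)
def _transport_kernel(
    n_photons,
    seed,
    thickness,
    mu_s,
    g_arr,
    n_arr,
    n_ambient,
    sdds,
    capture,
    r_max,
    max_path,
    max_depth,
    mu_a,
    apply_absorption,
    roulette_threshold,
    roulette_survival,
):  # pragma: no cover - numba-compiled
    np.random.seed(seed)
    n_layers = thickness.shape[0]
    n_rings = sdds.shape[0]
    r_detect_max = sdds[n_rings - 1] + capture

    # layer z-boundaries: z_edges[j] is the top of layer j
    z_edges = np.empty(n_layers + 1)
    z_edges[0] = 0.0
    for j in range(n_layers):
        z_edges[j + 1] = z_edges[j] + thickness[j]

    cap = n_photons
    det_idx = np.empty(cap, dtype=np.int32)
    lengths = np.zeros((cap, n_layers))
    weights = np.empty(cap)
    radii = np.empty(cap)
    n_det = 0

    # specular loss at normal-incidence entry
    r_spec, _ = _fresnel_r(n_ambient, n_arr[0], 1.0)
    w0 = 1.0 - r_spec

    path = np.zeros(n_layers)

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        w = w0
        total = 0.0
        for j in range(n_layers):
            path[j] = 0.0
        alive = True

        while alive:
            # dimensionless scattering optical depth for this free flight
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            tau = -math.log(u)

            # advance, crossing boundaries while optical depth remains
            while tau > 0.0:
                s = tau / mu_s[layer]
                # distance to the layer boundary along the flight direction
                if uz > 0.0:
                    db = (z_edges[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_edges[layer] - z) / uz
                else:
                    db = 1.0e30

                if s < db:
                    # stays inside the layer: move and scatter
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    path[layer] += s
                    total += s
                    if apply_absorption == 1:
                        w *= math.exp(-mu_a[layer] * s)
                    tau = 0.0
                else:
                    # move to the boundary and handle the interface
                    x += ux * db
                    y += uy * db
                    z += uz * db
                    path[layer] += db
                    total += db
                    if apply_absorption == 1:
                        w *= math.exp(-mu_a[layer] * db)
                    tau -= db * mu_s[layer]

                    # strict cutoffs: applied before any boundary interaction
                    # so detected records always satisfy them
                    if total > max_path or z > max_depth:
                        alive = False
                        break
                    if x * x + y * y > r_max * r_max:
                        alive = False
                        break

                    going_up = uz < 0.0
                    n1 = n_arr[layer]
                    if going_up:
                        n2 = n_ambient if layer == 0 else n_arr[layer - 1]
                    else:
                        n2 = n_arr[layer + 1]  # bottom layer is semi-infinite

                    cos_i = abs(uz)
                    refl, cos_t = _fresnel_r(n1, n2, cos_i)
                    if np.random.random() < refl:
                        uz = -uz  # specular reflection at the interface
                        # nudge stays implicit: z sits exactly on the edge
                    else:
                        # refract
                        ratio = n1 / n2
                        ux *= ratio
                        uy *= ratio
                        uz = cos_t if uz > 0.0 else -cos_t
                        if going_up:
                            if layer == 0:
                                # escaped the top surface: detect
                                r = math.sqrt(x * x + y * y)
                                if r <= r_detect_max:
                                    # nearest ring within the capture half-width
                                    best = -1
                                    bestd = capture + 1.0
                                    for k in range(n_rings):
                                        d = abs(r - sdds[k])
                                        if d <= capture and d < bestd:
                                            bestd = d
                                            best = k
                                    if best >= 0:
                                        det_idx[n_det] = best
                                        for j in range(n_layers):
                                            lengths[n_det, j] = path[j]
                                        weights[n_det] = w
                                        radii[n_det] = r
                                        n_det += 1
                                alive = False
                                break
                            layer -= 1
                        else:
                            layer += 1

                if total > max_path:
                    alive = False
                    break
                if x * x + y * y > r_max * r_max:
                    alive = False
                    break
                if z > max_depth:
                    alive = False
                    break

            if not alive:
                break

            # optional Russian roulette (oracle mode only)
            if apply_absorption == 1 and roulette_threshold > 0.0 and w < roulette_threshold:
                if np.random.random() < 1.0 / roulette_survival:
                    w *= roulette_survival
                else:
                    break

            # Henyey-Greenstein scatter
            g = g_arr[layer]
            if g == 0.0:
                ct = 1.0 - 2.0 * np.random.random()
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                denom = math.sqrt(1.0 - uz * uz)
                ux_n = st * (ux * uz * cp - uy * sp) / denom + ux * ct
                uy_n = st * (uy * uz * cp + ux * sp) / denom + uy * ct
                uz_n = -st * cp * denom + uz * ct
                # renormalize against drift
                norm = math.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm

    return det_idx[:n_det], lengths[:n_det], weights[:n_det], radii[:n_det]


def simulate_paths(
    geometry: Geometry,
    n_photons: int,
    seed: int,
    detectors: DetectorGrid | None = None,
    mode: str = "white",
    mu_a: np.ndarray | None = None,
    max_path_mm: float = DEFAULT_MAX_PATH_MM,
    r_max_mm: float = DEFAULT_R_MAX_MM,
    max_depth_mm: float = DEFAULT_MAX_DEPTH_MM,
    roulette_threshold: float = 0.0,
    roulette_survival: float = 10.0,
) -> PathlengthTable:
    """Run the transport and return the per-photon pathlength table.

    ``mode="white"`` (default) applies no absorption in flight; the table
    serves any later ``mu_a`` assignment.  ``mode="absorb"`` multiplies the
    photon weight by ``exp(-mu_a s)`` per substep (requires ``mu_a``) and is
    the independent cross-check: with the same seed the geometric paths are
    identical to the white run because continuous weighting consumes no
    extra random draws (unless Russian roulette is switched on via
    ``roulette_threshold > 0``).
    """
    if n_photons < 1:
        raise ConfigError("n_photons must be >= 1")
    if mode not in ("white", "absorb"):
        raise ConfigError(f"unknown mode {mode!r}")
    if detectors is None:
        detectors = DetectorGrid()

    k = geometry.n_layers
    if mode == "absorb":
        if mu_a is None:
            raise ConfigError("mode='absorb' requires a mu_a vector")
        mu_a_arr = np.asarray(mu_a, dtype=float)
        if mu_a_arr.shape != (k,) or np.any(mu_a_arr < 0):
            raise ConfigError("mu_a must be a non-negative length-n_layers vector")
        apply_absorption = 1
    else:
        mu_a_arr = np.zeros(k)
        apply_absorption = 0

    # numba needs a finite sentinel for the semi-infinite bottom layer; any
    # value beyond the pathlength cutoff is unreachable
    thickness = np.asarray(
        [t if math.isfinite(t) else 10.0 * max_path_mm for t in geometry.thickness]
    )
    det_idx, lengths, weights, radii = _transport_kernel(
        int(n_photons),
        int(seed),
        thickness,
        np.asarray(geometry.mu_s, dtype=float),
        np.asarray(geometry.g, dtype=float),
        np.asarray(geometry.n, dtype=float),
        float(N_AMBIENT),
        np.asarray(detectors.sdds, dtype=float),
        float(detectors.capture_radius),
        float(r_max_mm),
        float(max_path_mm),
        float(max_depth_mm) if math.isfinite(max_depth_mm) else 1.0e30,
        mu_a_arr,
        apply_absorption,
        float(roulette_threshold),
        float(roulette_survival),
    )
    return PathlengthTable(
        detector_index=det_idx,
        lengths=lengths,
        weight=weights,
        radius=radii,
        n_launched=int(n_photons),
        seed=int(seed),
        detectors=detectors,
        geometry=geometry,
        mode=mode,
        max_path_mm=max_path_mm,
        r_max_mm=r_max_mm,
        max_depth_mm=max_depth_mm,
        mu_a=tuple(mu_a_arr) if mode == "absorb" else None,
    )


# ---------------------------------------------------------------------------
# Table queries
# ---------------------------------------------------------------------------

def ring_collect(table: PathlengthTable, sdd: float) -> np.ndarray:
    """Boolean mask of the detected records belonging to the ring at ``sdd``.

    An empty ring (e.g. a far detector at tiny photon count) is a valid,
    empty selection — not an error.
    """
    idx = table.detectors.index_of(sdd)
    return table.detector_index == idx


def classify_fetal_sensitive(
    lengths: np.ndarray, fetal_layer: int = -1
) -> np.ndarray:
    """True for photons with any pathlength in the fetal (bottom) layer."""
    arr = np.atleast_2d(np.asarray(lengths))
    return arr[:, fetal_layer] > 0.0
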