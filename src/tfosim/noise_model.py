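"""Photodetector noise injection for simulated intensities.

Models the front-end of a transimpedance-amplified photodiode:

* shot noise       ``sigma_shot    = sqrt(2 q B i_k)``        (A)
* thermal noise    ``sigma_thermal = sqrt(4 k_B T B / R)``    (A)
* per-detector op-amp gain G chosen to equalise received optical power

with ``i_k = responsivity x received optical power`` the generated
photocurrent.  Two scenarios are supported: shot-only
(``I + N(0, sigma_shot)``) and shot plus measurement noise
(``G I + N(0, sqrt(sigma_shot^2 + sigma_thermal^2))``), both expressed back
in the normalized-intensity units of the forward engine through a
configurable source-power scale.  Dark current and physiological noise are
deliberately excluded.  Because the absolute simulated intensities are
normalized, the source-power scale sets the effective SNR and must be
reported alongside any noisy-data result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics_model import ConfigError

__all__ = [
    "NoiseConfig",
    "photocurrent",
    "shot_sigma",
    "thermal_sigma",
    "compute_gains",
    "inject",
]

ELECTRON_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class NoiseConfig:
    """Physical constants and scenario selection for noise injection.

    Bandwidth/temperature/resistor defaults (80 Hz, 300 K, 10 MOhm) are
    typical of a slow TIA front end; the source power (W) converts
    normalized intensity to received optical watts.
    """

    q: float = ELECTRON_CHARGE
    k_b: float = BOLTZMANN
    bandwidth_hz: float = 80.0
    temperature_k: float = 300.0
    gain_resistor_ohm: float = 10e6
    responsivity: float = 0.60
    source_power_w: float = 0.05
    gains: np.ndarray | None = None
    scenario: str = "shot_only"  # or "shot_plus_measurement"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q", "k_b", "bandwidth_hz", "temperature_k",
                     "gain_resistor_ohm", "responsivity", "source_power_w"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.scenario not in ("shot_only", "shot_plus_measurement"):
            raise ConfigError(f"unknown noise scenario {self.scenario!r}")


def photocurrent(optical_power_w, responsivity: float = 0.60):
    """Generated photocurrent (A) = responsivity x received optical power."""
    power = np.asarray(optical_power_w, dtype=float)
    if np.any(power < 0):
        raise ConfigError("optical power must be >= 0")
    out = responsivity * power
    return float(out) if np.isscalar(optical_power_w) else out


def shot_sigma(i_k, bandwidth_hz: float, q: float = ELECTRON_CHARGE):
    """Shot-noise current standard deviation sqrt(2 q B i_k), A."""
    i = np.asarray(i_k, dtype=float)
    out = np.sqrt(2.0 * q * bandwidth_hz * i)
    return float(out) if np.isscalar(i_k) else out


def thermal_sigma(
    temperature_k: float,
    bandwidth_hz: float,
    resistor_ohm: float,
    k_b: float = BOLTZMANN,
) -> float:
    """Thermal (Johnson) noise current of the gain resistor sqrt(4kTB/R), A."""
    return float(np.sqrt(4.0 * k_b * temperature_k * bandwidth_hz / resistor_ohm))


def compute_gains(baseline_powers, reference_index: int = 0) -> np.ndarray:
    """Per-detector gains normalising received power to the reference's.

    ``G_d = P_ref / P_d`` so that ``G_d P_d`` is constant across detectors.
    """
    p = np.asarray(baseline_powers, dtype=float)
    if np.any(p <= 0):
        raise ConfigError("baseline powers must be positive")
    return p[reference_index] / p


def inject(
    intensities: np.ndarray,
    cfg: NoiseConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add photodetector noise to normalized per-detector intensities.

    Scenario "shot_only" adds a zero-mean Gaussian whose shot-noise sigma is
    converted to intensity units via responsivity and source power;
    "shot_plus_measurement" first applies the per-detector gain vector, then
    adds the combined shot+thermal sigma.  Draws are independent per value
    and reproducible from ``cfg.seed`` (or the supplied generator).
    """
    inten = np.asarray(intensities, dtype=float)
    if np.any(inten < 0):
        raise ConfigError("intensities must be >= 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    power = inten * cfg.source_power_w
    i_k = photocurrent(power, cfg.responsivity)
    sig_shot = shot_sigma(i_k, cfg.bandwidth_hz, cfg.q)
    # current -> intensity units
    to_intensity = 1.0 / (cfg.responsivity * cfg.source_power_w)

    if cfg.scenario == "shot_only":
        return inten + rng.normal(0.0, 1.0, inten.shape) * sig_shot * to_intensity

    gains = cfg.gains
    if gains is None:
        raise ConfigError("scenario 'shot_plus_measurement' requires a gain vector")
    gains = np.asarray(gains, dtype=float)
    if gains.shape[0] != inten.shape[0]:
        raise ConfigError(
            f"gain vector length {gains.shape[0]} does not match "
            f"{inten.shape[0]} detectors"
        )
    sig_th = thermal_sigma(cfg.temperature_k, cfg.bandwidth_hz,
                           cfg.gain_resistor_ohm, cfg.k_b)
    sig = np.sqrt(sig_shot**2 + sig_th**2)
    gshape = gains.reshape((-1,) + (1,) * (inten.ndim - 1))
    return gshape * inten + rng.normal(0.0, 1.0, inten.shape) * sig * to_intensity
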