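"""Synthetic frequency-multiplexed PPG and the EPR extraction chain.

The acquisition being emulated: two LEDs (nominally 740 nm and 850 nm) are
toggled at 690 Hz and 940 Hz (50 % duty square waves) and the mixed light is
sampled at 8000 S/s on each detector.  The baseband of each
detector/wavelength channel is a mixture of quasi-periodic components —
fetal cardiac (1.5–3.5 Hz), maternal cardiac (1.1–2 Hz), maternal
respiratory (0.2–0.33 Hz) — on top of a DC level.  The fetal component is
modelled as ``AC * (1 + sin(phase))`` so the waveform troughs at the DC
(systolic) level and peaks at ``DC + 2 AC`` (diastolic), giving the ground
truth ``EPR = (2 AC + DC) / DC``.

Extraction chain: synchronous I/Q demodulation at the carrier (recovered
baseband = pi x magnitude, the square-wave fundamental factor), low-pass
anti-aliasing at 30 Hz and decimation to 80 S/s; lower envelope
(morphological opening over one fetal cardiac period) for the DC; lock-in
detection at the instantaneous fetal heart rate (4 s Hann window) for the
AC amplitude; then the EPR series with a 90 s centred moving average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .optics_model import ConfigError

__all__ = [
    "PPGConfig",
    "PPGRecord",
    "DEMOD_SCALE",
    "square_carrier",
    "synthesize",
    "demodulate",
    "lower_envelope",
    "lockin_fetal_ac",
    "epr_series",
    "extract_epr",
]

#: baseband = DEMOD_SCALE x I/Q magnitude after demodulating a 50 %-duty
#: 0/1 square-wave carrier (fundamental 2/pi, I/Q magnitude halves it)
DEMOD_SCALE = np.pi

#: physiological bands (Hz): fetal heart, maternal heart, maternal respiration
FHR_BAND = (1.5, 3.5)
MHR_BAND = (1.1, 2.0)
MRR_BAND = (0.2, 0.33)


@dataclass
class PPGConfig:
    """Parameters of the synthetic dual-wavelength multiplexed recording.

    ``dc`` and ``ac_fetal`` are (n_detectors, n_wavelengths) arrays in
    normalized intensity units; they may be taken from forward-engine
    outputs so the recovered EPR has a physics-grounded target.  Clutter
    amplitudes are fractions of the local DC.  Heart/respiration rates are
    scalars or per-sample traces at ``fs``.
    """

    dc: np.ndarray
    ac_fetal: np.ndarray
    fs: float = 8000.0
    out_rate: float = 80.0
    carriers_hz: tuple[float, ...] = (690.0, 940.0)
    wavelengths_nm: tuple[float, ...] = (740.0, 850.0)
    duration_s: float = 60.0
    fhr_hz: float | np.ndarray = 2.8
    mhr_hz: float | np.ndarray = 1.3
    mrr_hz: float | np.ndarray = 0.25
    maternal_frac: float = 0.0
    resp_frac: float = 0.0
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.dc = np.atleast_2d(np.asarray(self.dc, dtype=float))
        self.ac_fetal = np.atleast_2d(np.asarray(self.ac_fetal, dtype=float))
        if self.dc.shape != self.ac_fetal.shape:
            raise ConfigError("dc and ac_fetal must have the same shape")
        if self.dc.shape[1] != len(self.carriers_hz):
            raise ConfigError("dc must have one column per carrier/wavelength")
        if np.any(self.dc <= 0) or np.any(self.ac_fetal < 0):
            raise ConfigError("dc must be positive, ac_fetal non-negative")
        nyq = self.fs / 2.0
        if any(c >= nyq for c in self.carriers_hz):
            raise ConfigError("carriers must be below Nyquist")
        for name, band in (("fhr_hz", FHR_BAND), ("mhr_hz", MHR_BAND),
                           ("mrr_hz", MRR_BAND)):
            val = np.asarray(getattr(self, name), dtype=float)
            if np.any(val < band[0]) or np.any(val > band[1]):
                warnings.warn(
                    f"{name} outside the physiological band {band}", stacklevel=2
                )
        f_lo, f_hi = np.min(np.asarray(self.fhr_hz)), np.max(np.asarray(self.mhr_hz))
        if self.maternal_frac > 0 and f_hi >= f_lo:
            warnings.warn(
                "maternal band overlaps the fetal heart rate: lock-in "
                "rejection is not guaranteed", stacklevel=2,
            )

    @property
    def n_detectors(self) -> int:
        return self.dc.shape[0]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def true_epr(self) -> np.ndarray:
        """(2 AC + DC) / DC per detector and wavelength."""
        return (2.0 * self.ac_fetal + self.dc) / self.dc


@dataclass
class PPGRecord:
    """Raw multiplexed waveforms plus ground-truth annotations."""

    raw: np.ndarray  # (n_detectors, n_samples) at cfg.fs
    config: PPGConfig
    fhr_trace: np.ndarray  # instantaneous FHR at cfg.fs (Hz)

    @property
    def fs(self) -> float:
        return self.config.fs

    def fhr_at_out_rate(self) -> np.ndarray:
        step = int(round(self.config.fs / self.config.out_rate))
        return self.fhr_trace[::step]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("raw", data=self.raw)
            f.create_dataset("fhr_trace", data=self.fhr_trace)
            f.create_dataset("dc", data=self.config.dc)
            f.create_dataset("ac_fetal", data=self.config.ac_fetal)
            f.attrs["fs"] = self.config.fs
            f.attrs["out_rate"] = self.config.out_rate
            f.attrs["carriers_hz"] = list(self.config.carriers_hz)
            f.attrs["wavelengths_nm"] = list(self.config.wavelengths_nm)
            f.attrs["duration_s"] = self.config.duration_s
            f.attrs["seed"] = self.config.seed

    @classmethod
    def load(cls, path) -> "PPGRecord":
        import h5py

        with h5py.File(path, "r") as f:
            cfg = PPGConfig(
                dc=f["dc"][:],
                ac_fetal=f["ac_fetal"][:],
                fs=float(f.attrs["fs"]),
                out_rate=float(f.attrs["out_rate"]),
                carriers_hz=tuple(f.attrs["carriers_hz"]),
                wavelengths_nm=tuple(f.attrs["wavelengths_nm"]),
                duration_s=float(f.attrs["duration_s"]),
                seed=int(f.attrs["seed"]),
            )
            return cls(raw=f["raw"][:], config=cfg, fhr_trace=f["fhr_trace"][:])


def square_carrier(carrier_hz: float, t: np.ndarray, fs: float) -> np.ndarray:
    """50 %-duty 0/1 toggling waveform, band-limited below Nyquist.

    Built from the square wave's Fourier series truncated at ``fs/2``:
    ``1/2 + sum_{odd k} (2/(pi k)) sin(2 pi k f t)``.  Truncation keeps the
    sampled carrier free of alias products (an ideal discontinuous square
    sampled at ``fs`` would fold its high harmonics across the whole band);
    the fundamental amplitude ``2/pi`` is what the demodulator locks to.
    """
    out = np.full_like(t, 0.5)
    k = 1
    while k * carrier_hz < fs / 2.0:
        out += (2.0 / (np.pi * k)) * np.sin(2.0 * np.pi * k * carrier_hz * t)
        k += 2
    return out


def _as_trace(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ConfigError(f"trace length {arr.shape} does not match {n} samples")
    return arr


def synthesize(cfg: PPGConfig) -> PPGRecord:
    """Generate the multiplexed raw waveforms with ground truth attached."""
    n = cfg.n_samples
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(n) / cfg.fs

    fhr = _as_trace(cfg.fhr_hz, n)
    mhr = _as_trace(cfg.mhr_hz, n)
    mrr = _as_trace(cfg.mrr_hz, n)
    ph_f = 2.0 * np.pi * np.cumsum(fhr) / cfg.fs
    ph_m = 2.0 * np.pi * np.cumsum(mhr) / cfg.fs
    ph_r = 2.0 * np.pi * np.cumsum(mrr) / cfg.fs

    carriers = [square_carrier(fc, t, cfg.fs) for fc in cfg.carriers_hz]

    raw = np.zeros((cfg.n_detectors, n))
    for d in range(cfg.n_detectors):
        for w, sq in enumerate(carriers):
            dc = cfg.dc[d, w]
            ac = cfg.ac_fetal[d, w]
            base = (
                dc
                + ac * (1.0 + np.sin(ph_f))
                + cfg.maternal_frac * dc * np.sin(ph_m)
                + cfg.resp_frac * dc * np.sin(ph_r)
            )
            if cfg.noise_std > 0:
                base = base + rng.normal(0.0, cfg.noise_std, n)
            raw[d] += base * sq
    return PPGRecord(raw=raw, config=cfg, fhr_trace=fhr)


# ---------------------------------------------------------------------------
# Extraction chain
# ---------------------------------------------------------------------------

def demodulate(
    raw: np.ndarray,
    fs: float,
    carrier_hz: float,
    out_rate: float = 80.0,
    lp_cutoff_hz: float = 30.0,
    numtaps: int = 1025,
) -> np.ndarray:
    """Synchronous I/Q demodulation of one channel at one carrier.

    Mixes with cos/sin at the carrier, zero-phase low-pass FIR filters below
    ``lp_cutoff_hz`` (both anti-alias for the decimation and >60 dB
    rejection of the other carrier landing at the 250 Hz offset), decimates
    to ``out_rate`` and returns ``DEMOD_SCALE x magnitude`` — the recovered
    baseband.  Samples within one filter length of the edges are transient.
    """
    if carrier_hz >= fs / 2:
        raise ConfigError("carrier at or above Nyquist")
    factor = fs / out_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigError("fs must be an integer multiple of out_rate")
    factor = int(round(factor))
    x = np.asarray(raw, dtype=float)
    t = np.arange(x.size) / fs
    lo_i = np.cos(2.0 * np.pi * carrier_hz * t)
    lo_q = np.sin(2.0 * np.pi * carrier_hz * t)
    taps = scipy.signal.firwin(numtaps, lp_cutoff_hz, fs=fs)
    i_bb = scipy.signal.filtfilt(taps, [1.0], x * lo_i)
    q_bb = scipy.signal.filtfilt(taps, [1.0], x * lo_q)
    mag = np.sqrt(i_bb**2 + q_bb**2)
    return DEMOD_SCALE * mag[::factor]


def lower_envelope(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Lower signal envelope: morphological opening over the window.

    An erosion (running minimum) followed by a dilation (running maximum)
    with the same window; everywhere <= the input and idempotent on its own
    output.  With the window set to one fetal cardiac period this tracks the
    systolic (DC) trough of the pulsatile waveform.
    """
    w = int(window_samples)
    if w < 1:
        raise ConfigError("envelope window must cover at least one sample")
    mn = scipy.ndimage.minimum_filter1d(np.asarray(x, dtype=float), w, mode="nearest")
    return scipy.ndimage.maximum_filter1d(mn, w, mode="nearest")


def lockin_fetal_ac(
    x: np.ndarray,
    fs: float,
    fhr_hz,
    window_s: float = 4.0,
) -> np.ndarray:
    """Amplitude of the component at the (possibly drifting) fetal rate.

    Complex demodulation at the instantaneous FHR with a Hann-weighted
    sliding window; returns the sinusoid amplitude A (half the peak-to-peak
    swing), NaN within half a window of the edges.  The EPR formula consumes
    this as AC_fetal with peak-to-trough = 2 A.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    fhr = _as_trace(fhr_hz, n)
    phase = 2.0 * np.pi * np.cumsum(fhr) / fs
    z = x * np.exp(-1j * phase)
    w = scipy.signal.windows.hann(max(int(round(window_s * fs)), 3))
    w = w / w.sum()
    zi = scipy.signal.fftconvolve(z.real, w, mode="same")
    zq = scipy.signal.fftconvolve(z.imag, w, mode="same")
    amp = 2.0 * np.sqrt(zi**2 + zq**2)
    half = w.size // 2
    amp[:half] = np.nan
    amp[-half:] = np.nan
    return amp


def epr_series(
    dc: np.ndarray,
    ac: np.ndarray,
    rate: float,
    smooth_window_s: float = 90.0,
) -> np.ndarray:
    """Elementwise ``(2 AC + DC) / DC`` with a centred moving average.

    Non-positive DC samples are masked to NaN; the moving average ignores
    NaNs (it is computed over the valid samples in each window).
    """
    dc = np.asarray(dc, dtype=float)
    ac = np.asarray(ac, dtype=float)
    if dc.shape != ac.shape:
        raise ConfigError("dc and ac series must be aligned")
    raw = np.where(dc > 0, (2.0 * ac + dc) / np.where(dc > 0, dc, 1.0), np.nan)
    if smooth_window_s <= 0:
        return raw
    import pandas as pd

    win = max(int(round(smooth_window_s * rate)), 1)
    return (
        pd.Series(raw).rolling(win, center=True, min_periods=1).mean().to_numpy()
    )


def extract_epr(
    record: PPGRecord,
    smooth_window_s: float = 90.0,
    lockin_window_s: float = 4.0,
    edge_trim_s: float = 5.0,
):
    """Full chain: demodulate, envelope, lock-in, EPR, smooth — all channels.

    Returns ``(epr_point, series)``: the per-(detector, wavelength) time
    average of the smoothed EPR over the settled region, and the per-channel
    smoothed series at the output rate.
    """
    cfg = record.config
    rate = cfg.out_rate
    fhr80 = record.fhr_at_out_rate()
    env_window = max(int(round(rate / np.median(fhr80))), 2)

    n_det, n_wl = cfg.dc.shape
    series = {}
    point = np.full((n_det, n_wl), np.nan)
    trim = int(round(edge_trim_s * rate))
    for d in range(n_det):
        for w, fc in enumerate(cfg.carriers_hz):
            bb = demodulate(record.raw[d], cfg.fs, fc, out_rate=rate)
            fhr = fhr80[: bb.size]
            dc = lower_envelope(bb, env_window)
            ac = lockin_fetal_ac(bb, rate, fhr, window_s=lockin_window_s)
            s = epr_series(dc, ac, rate, smooth_window_s=smooth_window_s)
            series[(d, w)] = s
            core = s[trim: s.size - trim] if s.size > 2 * trim else s
            point[d, w] = np.nanmean(core)
    return point, series
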