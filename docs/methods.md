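# Methods

## The physical model

`tfosim` models transabdominal fetal oximetry (TFO): near-infrared light is
launched into the maternal abdomen and the diffusely reflected intensity is
sensed at several source–detector distances (SDDs); the fetal cardiac
pulsation modulates that intensity, and the modulation depth carries the
fetal arterial oxygen saturation (fSpO₂).

The tissue is a flat, four-layer, laterally infinite slab:

| layer | thickness | μs (735 nm) | μs (850 nm) | g | n | μa |
|---|---|---|---|---|---|---|
| maternal abdominal wall | dm = 4–34 mm | 11.816 mm⁻¹ | 11.169 | 0.9 | 1.4 | hemodynamic |
| uterine wall | 5 mm | 10.575 | 8.125 | 0.9 | 1.4 | 0.0158 / 0.0991 mm⁻¹ |
| amniotic fluid | 1 mm | 0.1 | 0.1 | 0.9 | 1.33 | 0.0125 / 0.0042 mm⁻¹ |
| fetal tissue | semi-infinite | 12.5 | 9.916 | 0.9 | 1.4 | hemodynamic |

The fetal depth is dm + 6 mm, i.e. 10–40 mm over the configured dm range.
Only the two perfused layers respond to hemodynamics, and only through
their absorption:

```
mu_a = 0.05 (mu_a_arterial + mu_a_venous) + 7.84e7 * lambda_nm^-3.255   [mm^-1]
mu_a_blood = [Hb] (S eps_HbO2 + (1 - S) eps_HHb)
```

with a 5 % blood volume fraction per compartment, venous saturation
0.75 × arterial (a config knob; the common convention for "75 % less
oxygenated venous blood"), and extinction coefficients embedded at
735/740/850 nm from the standard compiled hemoglobin molar spectra,
converted by `ln(10) · eps · C / (64500 · 10)` to natural-log units of
mm⁻¹ per (g/L). Melanin is not modelled. Fetal pulsation is two static
states: systole carries 2.5 % more fetal hemoglobin than diastole,
nothing else changes.

## White Monte Carlo transport

Photon transport uses exponential step sampling on μs, Henyey–Greenstein
scattering, and unpolarized Fresnel/Snell handling at the index-mismatched
interfaces (air 1.0 / tissue 1.4 / amniotic 1.33); the specular entry loss
is a launch-weight factor. No absorption is applied in flight: the
per-layer geometric pathlengths L1..L4 of every detected photon are stored,
and the detected intensity for an absorption assignment μa follows as

```
I(mu_a) = (1/N) sum_i w_i exp(-sum_j mu_a,j L_ij)
```

so one simulation per geometry and wavelength serves the entire
hemodynamic sweep (systole and diastole included). An in-flight-absorption
mode exists as an independent cross-check: run with the same seed it
traverses identical paths (continuous weighting draws no extra random
numbers) and must agree with the reweighted table to ~1e-10 relative;
optional Russian roulette (threshold 1e-4, survival 10) is available in
that mode but disabled when exactness is being checked.

Detection exploits cylindrical symmetry: the probe's discrete detectors
become surface rings of half-width 2 mm at 20 SDDs from 10 to 95 mm. The
absolute scale differs from a discrete detector by a fixed area factor that
cancels in every ratio (EPR, RoR, fetal sensitivity); the diffusion-limit
validation uses the per-area form directly.

Transport cutoffs (all recorded in the geometry fingerprint, which guards
every table against reuse under a mismatched geometry):

- lateral radius 150 mm (negligible return probability at SDD ≤ 95 mm);
- total pathlength 2000 mm by default; the layered feature runs use
  800 mm, where discarded paths carry absorption weight below e⁻¹⁵ at
  physiological μa ≥ ~0.05 mm⁻¹ — far beneath the Monte Carlo noise;
- optional depth cutoff (feature runs: fetal depth + 100 mm): a photon
  that deep can only return with a bottom-layer pathlength whose weight is
  negligible, yet it dominates runtime if followed.

The homogeneous diffusion check keeps the full 2000 mm cap because at
μa = 0.01 mm⁻¹ contributing paths extend much further.

RNG is the Numba-compiled legacy NumPy generator seeded per run;
identical (geometry, photon count, seed) triples give byte-identical
tables, and every seed is recorded in the output.

## EPR, RoR, and curve smoothing

The exponential pulsation ratio at one detector and wavelength is
EPR = I_diastole / I_systole ≥ 1 (systole is the intensity trough, since it
carries the extra fetal hemoglobin). On a pathlength table this equals,
exactly, the expectation of `exp(-Δmu_a,f Lf)` over the fetal pathlength
distribution with the non-fetal attenuation folded into the weights — the
identity that motivates the feature: the non-fetal layers enter only
through the (weighted) fetal pathlength distribution, not through their
absorption directly.

The conventional two-wavelength feature is the ratio-of-ratios,
RoR = ln(EPR_wl1)/ln(EPR_wl2), one per detector. A channel with EPR exactly
1 (no detected fetal pulsation — typical for near detectors over a deep
fetus) has no defined RoR; feature matrices encode it as 0.

Monte Carlo EPR curves over SDD are de-noised before use: central divided
differences (one-sided at the two ends), a 2-point moving average of the
difference sequence, and regeneration by cumulative summation anchored at
the first point. Affine curves are exact fixed points; non-uniform SDD
grids use the actual spacings. The ten-feature vector is the smoothed
curve linearly interpolated at the probe SDDs {15, 33, 46, 68, 94} mm for
both wavelengths (detector-major ordering); empty rings are filled by
linear interpolation over their finite neighbours first.

## Photodetector noise

Shot noise `sqrt(2 q B i_k)` and thermal noise `sqrt(4 k_B T B / R)` are
injected as zero-mean Gaussians in normalized-intensity units via a
configurable source power; defaults B = 80 Hz, T = 300 K, R = 10 MΩ,
responsivity 0.60 A/W, source power 50 mW. The source power sets the
effective SNR of the noisy-data experiments and is therefore always
reported with their results. The two scenarios are shot-only and
gain + shot + thermal, with per-detector gains `G_d = P_ref / P_d`
equalising received power. Systolic and diastolic intensities receive
independent draws (they are separate measurements in time). Dark current,
1/f noise and motion artifacts are excluded. The noisy evaluation protocol
trains on clean features and evaluates on noise-injected ones.

## Synthetic PPG and the extraction chain

The synthetic recording emulates the in-vivo acquisition: per detector,
the two wavelength basebands are multiplied by 0/1 square carriers at
690 and 940 Hz and summed, sampled at 8000 S/s. Each baseband is
`DC + AC_f (1 + sin φ_f) + clutter`, so the waveform troughs at DC
(systole) and peaks at DC + 2 AC (diastole); maternal cardiac and
respiratory clutter are sinusoids at configurable fractions of DC with
frequency traces inside the physiological bands (FHR 1.5–3.5 Hz,
MHR 1.1–2 Hz, MRR 0.2–0.33 Hz). The carrier is the square wave's Fourier
series truncated at Nyquist: an ideal discontinuous square sampled at
8 kS/s would fold its high harmonics across the band, which no physical
band-limited front end exhibits.

Extraction: synchronous I/Q demodulation at the carrier (recovered
baseband = π × magnitude; π is the documented scale constant — the 2/π
square-wave fundamental times the ½ of I/Q averaging), zero-phase FIR
low-pass at 30 Hz (anti-alias and >60 dB rejection of the other carrier's
250 Hz offset), decimation to 80 S/s; the DC series is the lower envelope,
implemented as a morphological opening (running minimum then maximum) over
one fetal cardiac period — idempotent and never above the signal; the AC
series is Hann-weighted complex demodulation at the instantaneous FHR with
a 4 s window (resolves FHR from MHR at their minimum separation while
tracking drift); EPR = (2 AC + DC)/DC with a 90 s centred moving average.
The FHR trace is ground truth in synthetic mode (the in-vivo system had an
arterial-line reference); FHR estimation from the PPG itself is out of
scope. Edge samples within the lock-in window are NaN-masked, and the
chain's point estimate averages the settled region.

## The estimator

A multilayer perceptron maps the 10 EPRs (or 5 RoRs — halved input width
under identical preprocessing) to fSpO₂ in percent: hidden widths
n, n/2, …, 8 (default n = 64; the first width is not fixed by the source
protocol and is config-exposed), each stage linear → ReLU → batch
normalization (order switchable), single linear output. Training: MSE
(optionally sample-weighted), Adam at 1e-3 with weight decay 1e-4 (applied
to weights only), batch 32, ≤300 epochs, early stopping with patience 25
and best-validation-weight restore; He-scaled normal weight init, zero
biases. The implementation is plain NumPy and bit-reproducible given the
seed.

Numerical choice: features and the target are z-scored internally (the
predictions are mapped back to percent). With desk-scale sample counts the
optimizer sees a few thousand updates rather than the millions of the
full-scale study, and an un-normalised 0–100 target does not converge in
that budget; standardisation changes no reported metric, only the
optimisation path.

Validation schemes: per-geometry random 80/20 split (simulation arm) and
contiguous temporal k-folds with inverse-round-size sample weights
(longitudinal arm; random splits would leak between overlapping PPG
windows). The EPR-vs-RoR comparison retrains the same network five times
with different initialisation seeds on a fixed split and averages MAE,
error std and Pearson r; improvements are percent reductions of the RoR
value.

## Problem sizes and what the desk-scale results show

The full-scale study behind this model runs ~10⁹ photons per geometry and
sweeps ~16 600 hemodynamic states per depth over 31 depths. The package's
defaults and its acceptance script are deliberately desk-scale:

- 1.5–2 × 10⁵ photons per (geometry, wavelength) feature table;
- 5 depths spanning fetal depths 10–40 mm;
- 468 hemodynamic combinations per depth (sm ∈ {0.85…1.0},
  sf ∈ {0.10…0.70 step 0.05}, [Hb]m ∈ {105,120,135} g/L,
  [Hb]f ∈ {150,165,180} g/L) — realistic term-pregnancy ranges chosen
  once; the fetal range covers the hypoxia regime of interest;
- 10⁷ photons for the homogeneous diffusion-limit validation;
- 10⁶ photons for the isolation-property measurement.

At this scale the far-detector EPRs are strongly Monte-Carlo-noisy
(exactly as the full-scale study reports for deep geometries), so absolute
estimator errors are a few percent worse than the full-scale figures; the
*orderings* — EPR features beating the RoR baseline on MAE and Pearson r,
errors growing with fetal depth, noise injection degrading accuracy — are
the reproducible content.

One measurement is known not to meet its nominal bound at desk scale: the
quantitative isolation check (maternal ±20 % μa moving (EPR−1) by <10 % of
the fetal 20→60 % saturation shift at fetal depth 20 mm, SDD 46 mm). Two
effects combine against it. Physically, at 735 nm a higher fetal
saturation simultaneously lowers the systole–diastole fetal Δμa
(deoxyhemoglobin dominates) and lowers the baseline fetal μa, which
up-weights long fetal pathlengths; the two nearly cancel, leaving a fetal
shift of only a few percent of (EPR−1) at that depth. Statistically, the
maternal-perturbation response there is below the reweighting noise floor
of any desk-scale table (the ring estimator's effective sample size is set
by a handful of shortest-path photons). The check is implemented and
reported as measured; the same measurement at fetal depth 10 mm, where the
fetal shift is strong, is reported alongside for context. The isolation
identity itself (the expectation form of the EPR) is exact and separately
verified.

## What the synthetic data does not capture

Flat homogeneous layers, a static geometry, sinusoidal physiological
components and stationary noise are idealisations. Real recordings add
curved heterogeneous anatomy, probe-pressure and motion effects,
non-sinusoidal pulse shapes, drifting signal quality, and maternal–fetal
band overlap, none of which are modelled here. Passing tests therefore
demonstrate the correctness of the computational chain and the relative
merit of the EPR feature under the stated model — not clinical accuracy.

## Known limitations

- Single-CPU vectorised transport; no GPU kernels, voxel media or
  time-of-flight outputs.
- The estimator does not generalise across geometries far outside the
  training depths (an extrapolation problem inherited from the feature's
  geometry sensitivity).
- Extinction data are embedded only at 735/740/850 nm; other wavelengths
  within 600–1000 nm raise an unsupported-wavelength error rather than
  silently interpolating.
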