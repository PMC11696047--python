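# Methods

This note records the scientific and numerical choices behind `ca3theta`:
what each stage assumes, the defaults and why, what the synthetic generator
does and does not emulate, and the known limitations.

## Conventions

Time in seconds, position in centimeters, LFP in microvolts. All phases at
public interfaces are degrees on [0, 360). Phase 0 is the peak of the
6–10 Hz filtered LFP (the `atan2` convention of the analytic signal); a
theta cycle runs between successive phase-0 crossings, and onset/offset
phases, initial-cycle counts and pair cycle labels all inherit this
boundary convention.

## LFP analysis

* **Filters.** Zero-phase (forward–backward) 3rd-order Butterworth
  band-passes. Zero-phase filtering is required because phase estimates
  must not be biased by filter delay; the order is a compromise between
  band edge sharpness and transient length and is exposed per call.
* **Phase.** Hilbert-transform phase of the 6–10 Hz signal, linearly
  interpolated on the unwrapped phase at arbitrary spike times. Pure-tone
  phase error is < 1° away from the record edges.
* **Band power.** Mean squared amplitude of the band-passed signal in
  delta (1–4), theta (6–10), slow gamma (25–50) and fast gamma
  (50–100 Hz). Butterworth passbands are not ideal rectangles, so absolute
  powers carry the filter's equivalent-bandwidth factor; ratios between
  bands are accurate to a few percent.
* **Wave asymmetry.** Cycle windows come from the theta phase; the peak is
  the 1–80 Hz signal's maximum over phase [0°, 180°) and the trough its
  minimum over [180°, 360°); the index is ln(ascent/descent) durations,
  0 for a symmetric wave, with antisymmetry under time reversal. Because
  the windows are anchored to the wave's 8 Hz fundamental, strongly skewed
  waveforms whose true extrema drift across a window boundary are measured
  with attenuated magnitude — an intrinsic property of the windowed rule,
  verified in the tests against a continuous-domain oracle of the same
  rule.
* **Theta frequency vs. speed.** Sliding-window spectrogram (5 s window,
  0.5 s step, zero-padded Welch/STFT; no multitaper estimator is available
  in the environment, and the window parameters dominate the estimate),
  6–10 Hz peak frequency interpolated to tracking samples, speed binned at
  2 cm/s, linear regression on per-bin means.

## Train detection and spatial measures

* Speed is the boxcar-smoothed (0.25 s) central difference of tracked
  position; the movement threshold (2 cm/s) applies to the smoothed speed.
* A train's *duration* is last-spike minus first-spike time; its path runs
  from the last tracking sample before the first spike to the first sample
  after the last spike, and the mean-speed criterion uses path length over
  anchor-to-anchor time.
* The cell-level rate gate [0.1, 5] Hz uses λ = N/T with T the summed
  trial time.
* Rate maps: 5 cm bins, occupancy from frame counts at the camera rate,
  Gaussian smoothing with σ = 2.5 cm truncated at 3σ (a "15 cm kernel"
  read as total support; reading it as σ would blur adjacent place fields
  into one and defeat pair-distance measurement).
* Spatial information is implemented exactly as the conventional
  H = Σ λ(x) log2(λ(x)/λ) p(x) (bits/s); selectivity S = E[λ]/E[λ²] and
  sparsity s = λ_max/λ follow the printed forms even though S behaves like
  an inverse sparsity — the naming is preserved, not corrected.
* Place fields: marching-squares contour at 20 % of the smoothed peak,
  keeping the peak-containing region; sub-bin peak location by separable
  quadratic interpolation.

## Circular-linear regression

The slope maximizes the mean resultant length of θ − a·d over a ±720°
bound (two theta cycles per traversal, covering all plausible precession
magnitudes with margin) on a 1° grid with bounded local refinement; tests
verify grid-oracle equivalence on random instances. Significance comes
from the circular-circular correlation between observed and fitted phases
with the standard normal approximation; R² is its square. Slopes are
bounded reals, so per-cell averages of train slopes are arithmetic, not
circular.

## Circular statistics

* **Circular MANOVA**: one-factor MANOVA on (cos θ, sin θ), Wilks' Λ with
  the Bartlett correction referred to χ²(2·(g−1)); Pillai trace exposed as
  a non-default alternative. Type-I error calibrates to 0.05 ± 0.015 at
  n = 100/group.
* **Concentration test**: Fisher's two-sample procedure keyed on the
  weighted resultant length (variance-stabilized angular transforms with a
  normal reference for dispersed data; a two-sided dispersion-ratio F for
  concentrated data). The tangential-ANOVA variant was evaluated and
  rejected for insufficient power (≈ 0.64 vs. the required > 0.9 at
  κ 1.9 vs 0.4, n = 80).
* κ is estimated by the standard piecewise A⁻¹(R̄) approximation.
* The circular Cohen's d wraps the mean difference to (−180°, 180°] and
  pools circular variances; its units are therefore degrees over a
  dimensionless spread, usable for within-study comparison only.

## Cell pairs

Correlogram bins are 10 ms wide with centers on integer multiples of the
bin (so a zero lag is representable exactly), smoothed with a Gaussian of
σ = 20 ms; the lag τ is the local maximum closest to zero within ±200 ms
(≈ ±1.5 theta cycles), plateau ties broken toward smaller |lag|. None of
these constants are dictated by theory; they resolve theta-scale lags
while suppressing spike-count noise and are all exposed as arguments.
A "reliable" run direction defaults to ≥ 50 spikes.

## The interference model

Drive G(t) = H(M_DG·G_DG + M_MEC·G_MEC − G_INH/8) with
G_DG = γ_DG(1 + cos 2πν_DG t), G_MEC = γ_MEC(1 + cos(ψ + 2πν_MEC t)),
G_INH = I_DC + A cos(φ_inh + 2πν_INH t), ν = (8.6, 8.5, 8.0) Hz, and
spatial envelopes M = N(x; 0.3, 0.45)^0.128 and N(x; 0.7, 0.75)^1.88.

* **Gaussian normalization.** N is taken as the normalized density; for a
  single input the density-vs-kernel ambiguity is absorbed by the rate
  scale, and the choice affects only the relative DG/MEC weighting. Both
  readings were evaluated; conclusions reported by the tests hold under
  either except where noted below.
* **Traversal duration T = 2 s** at constant velocity over x ∈ [0, 1].
  The slope magnitude is proportional to the beat frequency times T
  (≈ 0.55 Hz × 2 s × 360° ≈ 430°/traversal), so T is exposed and should be
  set to ≈ 0.75 s when matching measurements on the empirical scale
  (≈ −150°/traversal).
* **Spiking.** The drive is normalized to a peak intensity r_max (default
  15 Hz) and spikes are drawn exactly from the inhomogeneous Poisson law:
  a Poisson count with the intensity integral as mean, times by
  inverse-CDF sampling. Spike phases are read from the 8 Hz reference
  phase-locked to the inhibition, with LFP phase 180° at the inhibition
  minimum. I_DC is redrawn once per pass (variance 0.025); its mean
  defaults to 0, the value used for the model's headline parameter point.
* **Scan.** The full-resolution grid is 250 × 1000 over A ∈ [0, 5],
  φ_inh ∈ [0°, 360°); the default here is 25 × 40 with 50 passes per
  point (the full grid is hours-scale on one CPU) with deterministic
  per-point seeding, so any grid cell can be reproduced standalone.
  Admissibility bands are percentile intervals centered on the median
  (circular intervals, wrapped around the circular median, for Φ_on and
  Φ_off); a grid point is accepted when all four measurements are
  admissible.
* **Known limitation.** A MEC lesion (γ_MEC = 0) leaves the faster 8.6 Hz
  input alone and therefore *steepens* the measured slope slightly
  relative to the full model (≈ +2 %), rather than reducing it; this
  follows from the beat-frequency arithmetic of the drive equations
  and is insensitive to seeds, Gaussian normalization and distance
  renormalization. The corresponding qualitative check is kept in the
  acceptance suite and fails honestly. The DG lesion reduces the slope
  robustly, and the MEC-lesion phenotype of increased phase variability is
  reproduced.

## Synthetic sessions

The generator emulates: an 8 Hz theta LFP (amplitude 500 µV) with 1/f
noise at −20 dB (so reference-channel selection is exercised), a weaker
second channel, constant-speed (20 cm/s) straight runs over a 90 cm track
embedded in a 100 × 100 cm arena at 29.97 frames/s, place cells with
30 cm fields whose spike phases follow θ(d) = onset + slope·d with von
Mises within-cycle jitter, per-cell onsets drawn from a von Mises around
228.4° and per-train onset jitter of 15°, and co-active pairs firing once
per theta cycle under Gaussian field gates with a fixed inter-unit lag.

Spike times are placed on the *exact* solutions of the congruence between
the LFP phase ramp and the phase-distance line, with the line
pre-compensated per pass for the tracking-frame anchors the detector will
use; with zero jitter the downstream fitted slope therefore equals the
configured slope to numerical precision, which is what makes the
generator a calibration instrument rather than a qualitative fixture.

Preset calibration: `control` (slope −150°, κ_on = 1.91, jitter 40°),
`dg_lesion` (slope −80°, κ_on = 0.42, jitter 55°, 25 % early-phase
excess), `mec_lesion` (slope −150°, κ_on = 1.3, jitter 70°). Jitter and
per-train onset spread are generator choices (the phenotypes constrain
onset concentration and slope, not a generative noise model); von Mises
is the circular analogue of Gaussian noise.

Not emulated: maze topology and turning behavior, speed variability and
its theta-frequency covariation (a dedicated constructor exists in the
tests), interneurons, sharp-wave ripples, multi-field cells, and
electrode drift. A green test against this generator therefore
establishes correctness of the measurement chain under the stated
statistical structure, not robustness to real-recording artifacts.

## Degenerate inputs and tie-breaks

Empty units are retained through I/O; cells failing the rate gate return
empty train lists rather than errors; regressions require n ≥ 5 and
non-degenerate distances; flat correlograms and flat rate maps return
null/raise with explicit messages; the circular median breaks ties toward
the circular mean; phase 360.0 arising from floating-point wrap is mapped
to 0.
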