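# Methods

`pdus` implements a non-contrast power-Doppler ultrasound (PD-US) analysis
chain for tracking skeletal-muscle perfusion, together with a synthetic
RF-echo and cohort simulator that provides ground truth for every stage.
This note records the models, the parameters that matter, the numerical
choices, and the limits of what the synthetic tests demonstrate.

## Signal model and acquisition

A recording consists of 96 Doppler frames acquired over 12 s at 8 fps with
a 24 MHz transmit pulse; each Doppler frame is a color-flow burst of 17 echo
frames at 1000 fps. The pipeline takes the first echo frame of every
Doppler frame, giving a slow-time sequence at 8 Hz, and partitions it into
six 16-frame ensembles of 2 s each. Each ensemble therefore supports a
Doppler spectrum with 0.5 Hz bins over ±4 Hz; at 24 MHz in soft tissue
(c = 1540 m/s) a 0.5 Hz bin corresponds to an axial velocity step of
v = f·c/(2f₀) ≈ 0.016 mm/s, well matched to capillary flow (< 2 mm/s).
Analysis regions sit ~2 mm deep, where the two-way attenuation
(0.5 dB/cm·MHz × 2×0.2 cm × 24 MHz ≈ 5 dB) is constant across scans and is
therefore not compensated.

When recordings arrive as complex baseband IQ, conversion to RF resamples
the baseband spectrally (FFT zero-padding) to at least 4× the demodulation
frequency and takes `Re{iq·exp(2πi f_d t)}`. The demodulation frequency
must be supplied explicitly; vendor conventions vary and a silent default
would corrupt every downstream power estimate.

## Synthetic RF ensembles

Frames are synthesized by summing pulse-echo point responses over random
scatterers: axially a Gaussian envelope (FWHM 0.10 mm) modulated at the
two-way carrier (2f₀/c cycles per unit depth), laterally a Gaussian beam
profile (FWHM 0.15 mm). These widths are not measured system values; they
give realistic fully-developed speckle at the default scatterer density
(150/mm², several scatterers per resolution cell) and keep 0.01 mm motion
in the high-correlation regime. Three components are generated
independently and summed:

* **Tissue clutter** moves rigidly: a lateral sinusoid emulating
  respiration (amplitude 0.010 mm, period 0.4 s, i.e. 2.5 Hz) plus a slow
  axial drift (0.002 mm/s).
* **Blood scatterers** perform an independent Gaussian random walk with RMS
  step magnitude `speed/frame rate` (default 1 mm/s), giving the symmetric
  Doppler spectrum characteristic of diffuse motion. Blood echo power is
  scaled by the true perfusion curve at each schedule time.
* **White Gaussian noise** is added last.

Component powers are stated in dB relative to the baseline blood power.
Defaults: clutter +40 dB (not a measured value — chosen so the first
singular value dominates the ensemble as observed in practice), noise
+25 dB, which puts the echo SNR (tissue+blood over noise) at 15 dB, the
quoted typical scanning condition. Each component is normalized
per-realization over the whole ensemble so its mean power equals its
target exactly; ROI statistics then fluctuate with ordinary speckle
variance. Scatterers populate a margin of 3 PSF widths beyond the field so
frame statistics are stationary to the edges. Everything is deterministic
given the spec seed and schedule time.

**What this emulates and what it does not.** The simulator reproduces the
statistical structure the pipeline depends on — speckle correlation under
micron translations, clutter/blood subspace geometry, power additivity —
but not transmit/receive diffraction (no Field-II-style field simulation),
attenuation gradients, electronic noise coloration, nonrigid or
out-of-plane motion, or vessel geometry. Tests passing on this model show
the *pipeline* is correct under its stated assumptions, not that those
assumptions hold in any particular animal.

## Registration

Each frame is registered to frame 1 of its ensemble by a rigid translation
(the paper's own protocol; no progressive chaining, no affine model).
Estimation is FFT cross-correlation with two numerical details that matter
at micron scales:

* Frames are **Hann-apodized** first. With a plain rectangular aperture the
  correlation peak is biased toward zero by several percent of the shift
  (up to ~1.5 µm here) because the aperture-overlap factor tilts the peak;
  apodization removes the tilt's first-order effect.
* The peak is located on the **real-valued** correlation surface and
  refined by a two-stage local matrix DFT (0.1-sample pass, then
  1/200-sample pass). RF frames carry a carrier, so the correlation
  *magnitude* has a negative lobe half a carrier period (16 µm) from the
  true peak at ≈97% of its height; magnitude-based peak search
  occasionally hops onto it, a classic cycle-skipping failure. Restricting
  the search to the real surface removes the failure mode entirely.

Measured precision is ≤ 1 µm for injected shifts up to 0.02 mm at 15 dB
echo SNR (property-tested). Resampling uses the Fourier phase shift, which
preserves RF phase and is exactly invertible for band-limited content; the
Nyquist row/column of the shift kernel is zeroed because a fractional phase
ramp has no Hermitian-symmetric value there (physical RF carries no energy
at the folding frequency — what a cropped frame shows there is a crop
artifact). The shift is circular; the wrapped margin is a couple of samples
for micron corrections and the analysis ROIs are interior, so no margin
zeroing is applied — hard-zeroing would inject ringing that breaks exact
invertibility. Displacements beyond 10% of the field reject the rigid
model. Registration is optional in configuration, since with an immobilized
probe the unregistered and registered paths give statistically
indistinguishable profiles.

## Clutter filtering and power estimation

Each ensemble's ROI samples form a space×time Casorati matrix. Tissue
clutter is typically ~40 dB stronger than blood but highly coherent across
slow time, so it concentrates in the leading singular components; the
filter subtracts the first `n_removed` rank-1 components (default 1, the
same threshold at every time point) and the PD-US estimate is the mean
squared sample of the filtered matrix. Diagnostics include the singular
spectrum, the s₁/s₂ gap in dB (registration widens it), and the slow-time
periodogram (no taper — a window would widen the 0.5 Hz bins — and no mean
removal, since the 0 Hz bin is part of the filtered spectrum). PSD
normalization satisfies Parseval exactly: the PSD integral equals the mean
power to 1e−10 relative.

The rank-1 threshold presumes near-motionless tissue over the 2-s
ensemble. With 0.01 mm coherent motion, clutter energy spreads into the
second component and a fixed threshold leaks clutter; this is visible in
the simulator and is the reason the echo-level demonstration pipeline runs
under motionless-probe conditions (below). The filter operates on the
ROI-restricted matrix by default (powers are only needed inside ROIs);
full-frame filtering is available for image rendering.

Aggregation order is fixed and asserted: linear powers are averaged over 3
ROIs × 6 ensembles within a mouse, the 12-s mean is normalized by the same
limb's pre-ligation baseline and converted to dB
(`10·log10(P(t)/P(pre))`, so any constant processing offset cancels), and
group statistics are computed on the per-mouse dB values (mean, se = sd/√n;
n may vary by time point through attrition). Standard errors shown on
group curves are across mice only.

## Ischemic-response parameters

Three parameters summarize a profile over the 28-day schedule:

* **P_max** — the 20-min perfusion spike: a quadratic is fit (ordinary
  unweighted least squares) through the pre, 10-, 30-, and 60-min points
  and P_max is the measured 20-min value minus the fit value. Its
  uncertainty is the sd of the 20-min measurements when available.
* **P_min** — the minimum *measured* dB value post-ligation, not a fit
  value.
* **T** — the recovery time: a quadratic through days 1, 2, 3, 7, 14,
  with T the upward 0-dB crossing (positive slope at the root) within
  (1, 28] days, earlier crossing on ties; censored if no crossing exists.
  An identically-at-baseline profile reports the day-1 boundary with a
  warning.

Both fits use a log10(time) abscissa — profiles are near-linear on
log-time axes — and the pre-ligation point is assigned 1 min so it has a
finite abscissa. This choice is a documented default, not a claim about
the original analysis; fit diagnostics (coefficients, residuals) are
returned so sensitivity can be examined. Parameters are estimated
per-mouse and then averaged across a group (the group-mean-profile
alternative is a one-liner via `cohort_average`).

Closed-loop recovery on the profile simulator: noiseless profiles return
(P_max, P_min, T) exactly to fit tolerance; with 0.5 dB per-point noise the
median |T̂−T| over 200 seeds is below 1 day.

## Endothelial indices

Following a 5-min cuff occlusion, FMD = (Da−Db)/Db with Db the mean
pre-cuff femoral diameter and Da the largest diameter within the 5-min
post-release window (measurements every minute; peak typically ~1 min
after release); RH = 10·log10(PDUSa/PDUSb) analogously on PD-US power.
The baseline is the average of pre-cuff samples. Normal murine ranges:
FMD 0.13–0.14, RH 3.9–5.2 dB; classification uses an inclusive lower
edge (FMD ≥ 0.13, RH ≥ 3.9 dB are normal), a documented convention.
Repeatability is summarized by the coefficient of variation with the
sample (n−1) standard deviation.

## Statistics

Whole-profile two-group comparisons offset the pooled values to
positivity (x + 1 + |min|, offset recorded), apply one shared Box-Cox
transform — (x^λ−1)/λ with λ chosen by profile likelihood within
0.1–1.1 — and test two-sided with a t-test, Kruskal-Wallis, or Wilcoxon
rank-sum. Point-wise comparisons use the rank-sum test on raw values.
Rank-sum p-values are exact (Mann-Whitney enumeration) for tie-free
combined samples up to n = 12, normal approximation with continuity
correction otherwise; Kruskal-Wallis p-values are exact permutation
enumerations of the H statistic up to combined n = 10, chi-square above.
Only prespecified pairs differing in one biological variable are compared;
no multiple-testing correction is applied, by design.

The covariate-adjusted comparison (age and weight as continuous
covariates) is a rank-transform linear model with **Freedman-Lane
permutation** inference: residuals of the covariates-only model are
permuted, added back to its fitted values, and the full-model group
coefficient is recomputed for every permutation. Refitting per permutation
is essential — a naive residual-permutation test collapses to zero power
*and* zero size when the covariates are strongly confounded with group
membership, exactly the pooling scenario this test exists for (sub-cohorts
measured years apart at different ages/weights). Measured type-I error is
≈0.05–0.07 at nominal 0.05 over 500 null simulations. The exact
non-parametric ANCOVA of the original analysis is not public; this is a
labelled stand-in.

Diabetic classification: positive iff fasting glucose (−30 min) exceeds
200 mg/dL **and** both trapezoid AUCs — over 0–30 and 30–90 min of the
tolerance assay — are significantly elevated versus a non-diabetic
reference cohort. With one AUC per mouse, elevation is tested by the
placement of the mouse's AUC within the reference distribution (one-sided,
p = (1+#{ref ≥ value})/(n_ref+1)); significance at α = 0.05 therefore
requires at least 19 reference animals, and the function warns below that.

## Echo-level demonstration pipeline

`run_pipeline` analyzes a simulated cohort at the profile level
(parameters, group curves, pairwise statistics) and optionally runs one
mouse through the full echo path: simulate ensembles at every schedule
time → register → SVD-filter → power → baseline-normalize. Two conditions
are required for the echo path to track a perfusion curve and are the
demo defaults: a motionless probe (the rank-1 filter premise) and blood
echoes above the noise floor (noise 10 dB below blood). Under the quoted
in-vivo numbers — clutter 40 dB above blood with 15 dB echo SNR — the
post-filter signal is noise-dominated (noise ~25 dB above blood) and
baseline-normalized profiles compress toward 0 dB; the blood-to-noise
ratio that made the in-vivo measurements sensitive is not derivable from
the published acquisition numbers alone. This is a known limitation of
the emulation, not of the estimators.

## Problem sizes and reproducibility

Default synthetic frames are 300×72 samples (2.4×3.6 mm at 96 MHz axial
sampling, 0.05 mm pitch) with three 1 mm² ROIs; a 150×24 "small" geometry
serves quick experiments. Simulation studies in the test suite use
6–20 seeds per condition and 200–500 replicates for calibration checks.
Every stochastic stage draws from `numpy` Generators seeded through
`SeedSequence` spawning, so identical configuration and seed reproduce
every artifact byte for byte; run bundles embed the config hash, seed, and
package version.
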