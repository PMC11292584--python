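# pdus

Non-contrast **power-Doppler ultrasound (PD-US) perfusion analysis** for
longitudinal studies of skeletal-muscle blood flow — built around the
mouse hindlimb-ischemia model, where perfusion drops after femoral
ligation and recovers over four weeks, and cuff-occlusion tests of
endothelial function.

PD-US needs no contrast agent: after removing tissue clutter, the
remaining echo power is dominated by moving red blood cells and serves as
a relative perfusion index. The package covers the full chain, plus a
synthetic-data layer so every stage is testable without any recorded data:

* **simdata** — synthetic RF echo ensembles (speckle from point scatterers
  under a Gaussian-modulated 24 MHz PSF; rigid tissue motion, diffuse
  blood motion, controlled echo SNR) and synthetic cohorts with known
  ground-truth parameters;
* **acquisition** — IQ→RF conversion, assembly of 96-frame recordings
  into six 16-frame slow-time ensembles (8 Hz, 2 s), ROI handling,
  analytic sampling relations;
* **registration** — rigid sub-sample frame registration (micron-scale)
  via FFT cross-correlation with upsampled-DFT peak refinement;
* **clutterfilter** — SVD (PCA) filtering of the space×time Casorati
  matrix, removing the leading clutter subspace;
* **perfusion** — Doppler spectra (0.5 Hz bins over ±4 Hz), PD-US power,
  baseline normalization to dB, within-mouse and cohort aggregation;
* **ischemia** — the ischemic-response triplet: the 20-min spike
  `P_max` (dB above a quadratic trend through the pre/10/30/60-min
  points), the minimum `P_min`, and the recovery time `T` (0-dB upward
  crossing of a quadratic through days 1–14, log-time abscissa);
* **endothelium** — flow-mediated dilation `FMD = (Da − Db)/Db` and the
  reactive-hyperemia index `RH = 10·log10(PDUSa/PDUSb)` after 5-min cuff
  occlusion, with normal-range classification (FMD ≥ 0.13, RH ≥ 3.9 dB);
* **stats** — Box-Cox-transformed profile comparisons (t, Kruskal-Wallis,
  Wilcoxon with exact small-sample enumeration), rank-based
  covariate-adjusted group comparison (Freedman-Lane permutation ANCOVA),
  and the glucose-tolerance diabetes-positivity rule;
* **cli / pipeline** — a `pdus` console command and a reproducible
  end-to-end runner (`simulate / process / params / endothelium / stats /
  run`), YAML-configured, fully seeded.

## Worked example

Simulate one 2-s ensemble under typical scanning conditions — tissue
clutter 40 dB above blood, 15 dB echo SNR, 0.010 mm lateral respiration
motion — then register, clutter-filter, and estimate power:

```python
import numpy as np
from pdus import (AcquisitionGeometry, GroundTruthSpec, default_rois,
                  simulate_ensemble, register_ensemble, interframe_correlation,
                  casorati, svd_filter, pdus_power, subspace_gap)

geom = AcquisitionGeometry()          # 24 MHz, 8 fps, 2.4 x 3.6 mm field
spec = GroundTruthSpec(seed=1)        # clutter +40 dB, echo SNR 15 dB,
                                      # 0.010 mm respiration motion
ens = simulate_ensemble(spec, geom)   # 16 RF frames spanning 2 s
roi = default_rois(geom)[0]

reg, trace = register_ensemble(ens)
print(f"peak lateral motion : {1e3 * np.max(np.abs(trace.lateral_mm)):.1f} um")
print(f"correlation raw     : {interframe_correlation(ens, roi):.3f}")
print(f"correlation aligned : {interframe_correlation(reg, roi):.3f}")

filtered, spectrum = svd_filter(casorati(reg, roi))
print(f"subspace gap        : {subspace_gap(spectrum):.1f} dB")
blood_noise_truth = 1.0 + 10 ** (spec.noise_power_db / 10)
err = 10 * np.log10(pdus_power(filtered) / blood_noise_truth)
print(f"PD-US power error   : {err:+.2f} dB re true blood+noise")
```

```
peak lateral motion : 10.3 um
correlation raw     : 0.875
correlation aligned : 0.969
subspace gap        : 26.3 dB
PD-US power error   : -0.31 dB re true blood+noise
```

The estimator recovers the injected 10 µm respiration motion; registration
lifts the inter-frame correlation from ~0.87 to ~0.97; and after removing
the first singular component the ROI power sits within a fraction of a dB
of the true blood-plus-noise power despite clutter 40 dB stronger.

From the shell, the same machinery runs on stored data or simulations:

```bash
pdus simulate profile --p-max 3 --p-min -6 --t-days 9 --noise-sd 0.5 \
     --seed 1 --out profile.csv
pdus params --profiles profile.csv --out params.csv
cat params.csv
```

```
mouse_id,group,sex,p_max_db,p_min_db,t_days,censored
sim,,,3.134772155848357,-5.7768127138179945,8.776380577025277,False
```

With 0.5 dB measurement noise per point, the estimators return the truth
(P_max = 3 dB, P_min = −6 dB, T = 9 d) to within a few tenths.
`pdus run --seed 1 --out bundle` runs a full synthetic cohort — profiles,
per-mouse parameters, group curves, and pairwise statistics — and writes a
byte-reproducible artifact bundle with config hash and seed.

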