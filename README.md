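# xedwi — hyperpolarised ¹²⁹Xe diffusion-weighted MRI analysis

`xedwi` analyses multiple-b-value hyperpolarised ¹²⁹Xe diffusion-weighted
MRI of the lung, the kind of acquisition used to track microstructural
change in fibrotic lung disease (e.g. idiopathic pulmonary fibrosis), where
enlarging or disrupted acinar airspaces raise the apparent diffusivity of
the inhaled gas. It is aimed at imaging scientists who need a tested,
reproducible pipeline from reconstructed magnitude volumes to cohort-level
statistics — plus a synthetic phantom/cohort generator with known ground
truth, so every stage can be validated without patient data.

## What it computes

For a signal S(b) acquired at b-values b = 0, 12, 20, 30 s·cm⁻²
(1 s·cm⁻² = 100 s·mm⁻²):

* **ADC** — the two-point mono-exponential apparent diffusion coefficient,
  `ADC = ln(S(0)/S(b₁))/b₁` with b₁ = 12 s·cm⁻², solved exactly per voxel.
* **Stretched-exponential fit** — per-voxel nonlinear least squares of
  `S(b) = S₀·exp(−(b·DDC)^α)` with DDC ∈ (0, D_free] and α ∈ (0, 1],
  run as a vectorised Levenberg–Marquardt over all voxels at once
  (`StretchedExpModel(dw, mask).fit()` → results object with maps,
  diagnostics and `summary()`).
* **Lm_D (mean acinar dimension)** — the stretched exponential is the
  Laplace transform of a diffusivity distribution p(D) (a one-sided
  α-stable law); each diffusivity maps to a diffusive length
  ℓ(D) = √(2·D·Δ) over the diffusion time Δ, and
  `Lm_D = ∫ p(D)·√(2·D·Δ) dD` (µm). For α = 1 this reduces to √(2·DDC·Δ).
* **Regional analysis** — lung masking, partition into upper/middle/lower
  thirds of lung height along the cranio-caudal axis (read from the NIfTI
  affine), and per-region summaries.
* **Cohort statistics** — Shapiro–Wilk-gated paired comparisons (paired t /
  Wilcoxon signed-rank with Hodges–Lehmann CIs), across-zone omnibus tests
  (repeated-measures ANOVA / Friedman), and gated Pearson/Spearman
  correlations with gas-exchange covariates (D_LCO, K_CO), all two-tailed.

The synthetic cohort emulates a longitudinal study: two ellipsoidal lungs,
zone-dependent (DDC, α) ground truth calibrated to published regional ADC
and Lm_D medians in IPF, Rician noise at configurable SNR, between-subject
and visit-to-visit variability, a progression effect concentrated in the
lower zone, and covariates with a known negative correlation to ADC.

## Worked example

```python
import numpy as np
from xedwi import (build_phantom, simulate_signal, ADCModel,
                   StretchedExpModel, split_zones, summarize_map)

phantom = build_phantom()                          # two-lung digital phantom
dw = simulate_signal(phantom, (0, 12, 20, 30), snr=30, seed=7)

adc = ADCModel(dw, mask=phantom.mask).fit()
sx = StretchedExpModel(dw, mask=phantom.mask).fit()
lmd = sx.lmd_map()                                 # delta = 8.5 ms default

zones = split_zones(phantom.mask, dw.affine)
for s in summarize_map(lmd, zones):
    print(f"{s.region:>7}: median {s.median:6.1f} um  (n={s.n_voxels})")
```

prints

```
 global: median  319.5 um  (n=5936)
  upper: median  314.5 um  (n=1632)
 middle: median  330.1 um  (n=2976)
  lower: median  304.3 um  (n=1328)
```

— the regional mean acinar dimension recovered from noisy simulated signal,
within ~1.5% of the generator's zone truths (313, 326, 302 µm), with the
middle zone highest, as reported in fibrotic cohorts where proximal airways
inflate the mid-lung values.

The command-line demo runs the whole study in one call:

```bash
xedwi demo --out demo_run --seed 1            # 20 subjects, two visits
```

writing parameter maps, per-subject regional summaries, a
baseline-vs-12-month report per metric and region (with normality-gate
routing and 95% CIs), and baseline correlations with K_CO and D_LCO.

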