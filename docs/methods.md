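# Methods

## Signal model

A diffusion-weighted hyperpolarised-gas acquisition samples the decay of
the inhaled-gas magnetisation under increasing diffusion weighting b
(s·cm⁻²; the clinical s·mm⁻² convention differs by a factor of 100). Two
per-voxel models are fitted:

**Two-point ADC.** The mono-exponential apparent diffusion coefficient
uses only b = 0 and the first non-zero weighting b₁:
ADC = ln(S(0)/S(b₁))/b₁. With two unknowns and two points the log-ratio is
the exact least-squares solution; both residuals are zero by construction,
so no iterative solver is involved. Voxels with S(b₁) > S(0) (non-physical
"decay", possible under noise) are marked invalid rather than floored at
zero — flooring would bias regional means downward asymmetrically — and
are counted in the QC output, as are voxels whose S(0) falls below the
noise floor (3× the corner-estimated background σ by default).

**Stretched exponential.** S(b) = S₀·exp(−(b·DDC)^α) with the distributed
diffusion coefficient DDC ∈ (0, D_free] and heterogeneity exponent
α ∈ (0, 1]. α = 1 recovers mono-exponential decay; α < 1 indicates a
distribution of diffusivities within the voxel, as expected in
heterogeneous acinar microstructure. The fit is a damped (Levenberg-style)
least-squares iteration in log-parameters (ln S₀, ln DDC, ln α), run
simultaneously over all masked voxels with per-voxel damping factors.
Steps are accepted only if they lower that voxel's SSE, so the final SSE
never exceeds the SSE at the initialisation (two-point ADC for DDC,
α₀ = 0.9, S₀ = S(0)). Voxels whose unconstrained optimum has α > 1 are
refit with α pinned at exactly 1 — the boundary solution of the
constrained problem. Per-voxel fits are independent: results do not depend
on execution order or on which other voxels share the mask (tested).

Defaults: D_free = 0.14 cm²·s⁻¹ (free-diffusion scale of dilute ¹²⁹Xe in
air/N₂), α optimisation floor 0.05, max 200 iterations.

## Diffusivity spectrum and Lm_D

For α < 1 the stretched exponential is the Laplace transform of a
diffusivity distribution,
exp(−(b·DDC)^α) = ∫ p(D)·e^(−bD) dD with p(D) = f_α(D/DDC)/DDC,
where f_α is the one-sided α-stable density with transform exp(−s^α).
Each diffusivity corresponds to a diffusive length scale ℓ(D) = √(2·D·Δ)
over the diffusion time Δ, and the mean acinar dimension is the
spectrum-weighted mean length

Lm_D = ∫ p(D)·√(2·D·Δ) dD / ∫ p(D) dD, reported in µm.

**Evaluating f_α.** Two complementary schemes are combined:

* the alternating inverse-Laplace series
  f(x) = (1/π) Σ (−1)^(n+1) Γ(αn+1) sin(παn)/n! · x^(−αn−1),
  evaluated in log space with a per-point error bound (truncation tail —
  taken over the last 20 terms, since sin(παn) has spurious zeros — plus
  max-term magnitude × machine epsilon). The series is mathematically
  convergent for all x > 0, but in float64 the terms near the bulk grow to
  ~1e80 before decaying for α ≳ 0.7 and the sum is cancellation noise; the
  monitor flags exactly those points, and series values are used only
  where the bound is below 1e-8 of the value (in practice: the right
  tail, and everything for small α).
* the Zolotarev integral representation, whose integrand is non-negative —
  no cancellation is possible. It is integrated by composite
  Gauss–Legendre after the substitution ψ = −ln(1 − φ/π), which resolves
  the endpoint boundary layer; the panels are split at the integrand's
  mode (located by bisection on the monotone function A(φ)) and at the
  point where the integrand has fallen by e⁻³⁰, keeping each panel within
  a few e-folds of dynamic range.

The hybrid is validated in the tests against the α = 1/2 closed form
(Lévy distribution) and scipy's independent stable-density evaluation to
≲1e-5 relative in the bulk. (scipy itself is the weaker reference in the
far tail, where the monitored series is provably convergent.)

**Spectrum grid.** p(D) is discretised on a log-spaced grid, by default
[1e-6, 1e4] cm²·s⁻¹ with 1000 points, renormalised to unit integral with
trapezoid weights. The grid deliberately extends far beyond the
free-diffusion coefficient: the stable law's heavy right tail carries
substantial √D weight, and the extended grid reproduces the untruncated
spectral moment E[√D] = √DDC·Γ(1−1/(2α))/Γ(1/2) to ~1% for α ≥ 0.8
(within ~4% at α = 0.75; for α ≤ 0.65 the moment itself is
truncation-dominated — the tail index approaches the moment order — and
any reported Lm_D there is convention-dependent). This convention is what
makes published-scale Lm_D values (≈1.2× √(2·ADC·Δ) at α ≈ 0.82)
attainable at all: under a strict cutoff at D_free the spectral mean can
never exceed √(2·ADC·Δ). A strict physical truncation remains available
by setting `d_max = 0.14` in `FitOptions`. For α within 5×10⁻³ of 1 the
peak (relative width ~1−α) is narrower than the default grid resolves; a
fine grid insert around the peak is added for α ≥ 0.95, and α ≥ 0.999 is
represented as an exact single-bin delta at DDC (the spectral enhancement
there is < 0.1%).

**Lm_D maps.** `compute_lmd_map` quantises (DDC, α) to steps of
2.5×10⁻⁴ cm²·s⁻¹ and 2.5×10⁻³ (≤0.5% effect on Lm_D) and factors the
computation per α: f_α is tabulated once on a master x = D/DDC grid, and
the truncated moments for any DDC follow from two cumulative-integral
lookups. The per-α tables are cached process-wide, so a 40-volume cohort
pays the spectral cost once. Memoisation is transparent (disabling it
recomputes voxel-by-voxel through the identical path), and the factored
path agrees with building each voxel's full spectrum to ≲0.3%.

**Diffusion time.** Δ is not recoverable from the data and Lm_D scales as
√Δ, so Δ is an explicit, mandatory field at pipeline level (default
8.5 ms at the level of `FitOptions`, a typical value for ¹²⁹Xe lung
protocols at 1.5 T) and is recorded in every output sidecar. Absolute
Lm_D values are therefore calibration-dependent; comparisons within a
protocol are not.

**Independent oracle.** `spectrum_from_curve_nnls` inverts the analytic
decay curve with a non-negative least-squares mono-exponential dictionary
on the same grid under a second-difference smoothness penalty, with b
sampled log-spaced so every grid diffusivity is probed. It shares no
machinery with the analytic construction and agrees with it on Lm_D to
≤2% for α ≥ 0.7. At α ≤ 0.65 the two approaches diverge by ~3–5%
irreducibly: the √D moment there is dominated by diffusivities whose
signature in any finite decay curve is below resolvable levels, so the
inverse problem does not determine Lm_D to 2% — a limitation of the
quantity, not of either algorithm.

## Lung mask and zones

The lung mask is estimated from the b = 0 volume: threshold at 5× the
background noise σ (estimated from the eight corner cubes via the
Rayleigh-mean relation σ̂ = mean/√(π/2)), keep the two largest connected
components, morphological closing. A user-supplied mask bypasses
estimation. Zones are thirds of the lung height — the span of
mask-containing slices along the cranio-caudal axis, which is identified
from the NIfTI affine, never assumed from array order. Remainder slices
are assigned superior-first (31 slices → 11/10/10). Left and right lungs
are pooled per zone; an optional airway mask is subtracted before
summarising. Regional summaries always report both mean and median: the
voxel-wise Lm_D distribution under noise is right-skewed (low-α outliers
have heavy-tailed spectra), so the median is the default subject-level
value in cohort statistics, with means available in every table.

## Synthetic phantom and cohort

The phantom is two axis-aligned ellipsoids on a 32×32×30 grid of 4 mm
isotropic voxels (≈5 900 lung voxels) — enough geometric structure for
the zone logic, with no claim to anatomical realism. Zone ground truths
(DDC, α) are calibrated so the noiseless pipeline reproduces published
regional medians in newly diagnosed IPF: baseline two-point ADC of
(0.042, 0.044, 0.039) cm²·s⁻¹ and Lm_D of (313, 326, 302) µm for the
upper/middle/lower zones at Δ = 8.5 ms, giving α ≈ 0.82 and
DDC ≈ 0.033–0.038 cm²·s⁻¹ (`calibrate_zone_truth` solves the two-equation
system per zone; the frozen defaults are re-verified by the test suite).
An optional smooth Gaussian random field (SD 0.003 cm²·s⁻¹, correlation
length 3 voxels, re-centred per zone so zone medians are exact) keeps maps
from being implausibly flat. Noise is Rician — the magnitude of a complex
Gaussian perturbation with per-channel σ = S̄₀/SNR, SNR 30 at b = 0 by
default (per-voxel SNR of such acquisitions is rarely reported; the value
is exposed in config) — so background voxels are Rayleigh and signal
voxels carry the correct noise floor bias.

The cohort generator emulates a 20-subject two-visit longitudinal study:
a subject-level DDC offset (SD 0.006 cm²·s⁻¹, matching a cross-sectional
global ADC SD of ~0.007 cm²·s⁻¹), a visit-level offset (SD
0.003 cm²·s⁻¹, consistent with a borderline-significant +0.002 cm²·s⁻¹
global ADC change at n = 20), and an additive follow-up progression of
(0, +0.001, +0.004) cm²·s⁻¹ in the upper/middle/lower zones —
concentrated basally, as fibrosis typically advances. Gas-exchange
covariates are linear in the subject's true global mean ADC plus Gaussian
noise, with the slope set from the closed-form relation
β = r·σ_K/σ_ADC so the population correlation is exactly the configured
target (−0.73 for K_CO, −0.65 for D_LCO by default). A single seed drives
everything; outputs are bit-reproducible.

What the generator does *not* emulate: realistic anatomy or partial-volume
boundaries, airway signal (the middle-zone elevation is injected in the
truths, not mechanistically generated), compressed-sensing reconstruction
artefacts, cardiac or respiratory motion, B₁/polarisation-decay
inhomogeneity, and dropout. Passing tests therefore demonstrate that the
estimators and statistics are correct and well-calibrated under the
stated noise model — not that the pipeline is robust to every property of
patient data.

## Statistics

Every test routes through a Shapiro–Wilk gate at α = 0.05 on the analysis
quantity (paired differences; each margin for correlations): paired t /
Pearson / repeated-measures ANOVA on the parametric route, Wilcoxon
signed-rank / Spearman / Friedman otherwise. The route and gate p-value
are carried in every result. Wilcoxon uses the exact null distribution
for n ≤ 25 without ties and the continuity-corrected normal approximation
otherwise, with zero differences dropped and counted; its effect estimate
is the Hodges–Lehmann pseudo-median with a distribution-free CI from the
Walsh averages (exact signed-rank quantiles by dynamic programming for
n ≤ 25). Pearson correlations carry Fisher-z 95% CIs. All p-values are
two-tailed and unadjusted by default — many comparisons at p < 0.05 is
the reporting convention being reproduced — with an opt-in Holm column to
make the multiplicity visible. The across-zone omnibus test is the
natural paired generalisation (RM-ANOVA/Friedman); no claim is made that
it matches any particular historical analysis choice. Calibration is
verified by simulation: type-I error of the paired comparison within
[3%, 7%] at nominal 5%, CI coverage ~95%, and >50% power against a
+0.004 cm²·s⁻¹ lower-zone effect with 0.005 within-subject SD at n = 20.

Shapiro–Wilk's power against Cauchy-tailed alternatives at n = 20 is
~85%; a gate at this sample size will occasionally route heavy-tailed
data parametrically.

## Problem sizes and determinism

The packaged demonstration uses 20 subjects × 2 visits on the default
phantom (≈5 900 voxels/volume), chosen so the full simulate → fit →
zones → statistics chain plus the calibration simulations (1000 null
replicates, 200 power replicates, 100 correlation cohorts) completes in a
few minutes on one CPU. All randomness flows from explicit seeds through
`numpy.random.Generator`; identical configs give bit-identical outputs,
including the written CSV reports.

## Known limitations

* Absolute Lm_D depends on Δ, on D_free and on the spectral-truncation
  convention (see above); only within-protocol comparisons are meaningful.
* For α ≤ 0.65 the √D spectral moment is intrinsically ill-conditioned.
* The two-point ADC inherits noise-floor bias at low SNR; the noise-floor
  QC counts flag affected voxels, but no Rician bias correction is applied.
* `zone_omnibus` requires complete zone triples; subjects with a missing
  zone are dropped (counted), not imputed.
* The lung-mask estimator assumes signal-free image corners and two
  dominant components; pathology-driven signal voids will erode its Dice.
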