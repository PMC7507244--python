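# Methods

## Zonal geometry and index conventions

The vertical corneal meridian is represented by 30 ordered zones in
three imaging regions (superior z1–z10, central z11–z20, inferior
z21–z30); zone index is the spatial unit throughout, since the
physical zone width in mm depends on acquisition geometry and is not
needed by any index. Two conventions are fixed here because the
clinical definitions leave them open:

- **Half boundary.** "Superior half" = z1–z15, "inferior half" =
  z16–z30, i.e. the split is at the centre of the central region. This
  is the symmetric choice consistent with an inferior-vs-superior
  ectasia contrast along the vertical meridian; the inferior minimum
  and superior maximum entering the ectasia indices are taken over
  these halves, not over the outer regions only.
- **RMS divisor.** Profile variation (PV) and profile deviation (PSD)
  are population root-mean-squares (divisor N = 30), computed over all
  30 zones jointly. PV is the RMS deviation from the eye's own profile
  mean; PSD is the RMS difference from the normative pattern average
  (the per-zone arithmetic mean over a reference cohort of normal
  eyes). PV is therefore invariant to adding a constant to the
  profile, and PSD to adding the same constant to profile and pattern.

All indices are computed on the repeat-averaged profile, matching a
measurement pipeline in which three acquisitions are averaged before
analysis.

## Synthetic cohort generator

No raw imaging data are deposited for this screening problem, so the
package ships a generator whose *group-level* statistics are calibrated
to a published three-group cohort (50 normal, 33 subclinical-KC, 38 KC
eyes). Per eye, a latent severity scalar ζ ~ N(0,1) — clipped at ±2 σ
and rescaled to unit variance, so that a single tail draw cannot carry
an eye across the entire group separation — couples everything the
disease does:

```
thickness_L(z) = base_L(z) + offset + irregularity_L(z) − cone_L(z) + noise_L(z)
```

- **base_L**: fixed smooth meridional curve (level + unit-RMS shape in
  μm). Defaults: epithelium 52.5 μm, slightly thicker inferiorly;
  Bowman's layer 17.4 μm, near-uniform; stroma 480 μm, thicker
  peripherally.
- **offset**: per-eye Gaussian thickness offset (between-eye biometry;
  SD 2.5 / 1.3 / 25 μm for epithelium / Bowman / stroma). This is what
  makes deviation-from-pattern (PSD) exceed within-eye variation (PV)
  in normal eyes, as observed clinically.
- **irregularity_L**: a random smooth curve in two bands of meridional
  cosine harmonics orthogonalised against the constant and the fixed
  shape — a macro band (harmonics 2–5, long-wavelength) and a micro
  band (harmonics 6–9). Each band's curve has a uniformly random
  direction within the band and a lognormal RMS amplitude, so the
  drawn amplitude *is* the band's RMS contribution to PV. Disease
  scales the macro band only, through a per-group median multiplier
  (subKC 2.33, KC 1.60 for the epithelium): epithelial remodelling
  raises profile irregularity diffusely, which drives EPV upward while
  moving zonal extremes (and hence the ectasia indices and the
  inferior minimum) much less than an equally sized focal defect
  would. This separation is what reproduces the clinical finding that
  EPV — not the epithelial minimum — is the most discriminative
  feature for subclinical disease.
- **cone_L**: a Gaussian-in-zone-index thinning bump, centre drawn
  uniformly over the inferior paracentral zones 17–27, width uniform
  over 3–5 zones, shared across layers within an eye. The per-layer
  depth is κ_L(group) · exp(τζ − τ²/2) · d_L, with τ = 0.32 and d_L an
  extra mean-one lognormal dispersion factor (σ = 0.5 / 0.8 / 0.3)
  expressing heterogeneous layer involvement — Bowman involvement in
  particular varies strongly across subclinical eyes. Depth saturates
  exponentially at 85 % of the local baseline thickness, so thinning
  can never exceed the layer; a non-positive generated thickness
  raises an error rather than being clamped (clamping would silently
  bias the calibration). The normal group's cone amplitude is exactly
  zero. Defaults (mean depth, μm): subKC 1.5 / 3.2 / 16; KC 25.7 /
  9.6 / 45 for epithelium / Bowman / stroma.
- **noise_L**: per-zone Gaussian measurement noise (SD 1.5 / 0.9 / 3.0
  μm per acquisition), averaged over 3 independent repeats.

The 21 Scheimpflug features are simulated as calibrated Gaussians per
group — never computed from surfaces; best-fit-sphere ray tracing is
out of scope — with an equicorrelated block (ρ = 0.7) realised through
the shared severity factor, each feature loading on ζ with the sign of
its disease direction. Published group means/SDs are used where they
exist (anterior keratometry; posterior elevations; ISV, IVA, KI); the
remaining features carry literature-plausible values chosen once, with
normal-vs-subKC standardised shifts kept below the posterior maximum
elevation's so that invented numbers cannot dominate the ranking.
Elevation values are treated as unitless calibrated scores labelled as
the instrument prints them; gender is Bernoulli(½), independent of
group.

### Calibration

Structural constants were fitted once by iterative stochastic
root-finding (20 000 eyes per evaluation, common random numbers;
second-moment matching for means, log-spread updates for SDs) against
the reference group values, then frozen into `_calibration.py`.
Verified at n = 10⁵–2·10⁵ eyes per group, the generator reproduces:
epithelial PV 2.80 ± 0.70 / 4.10 ± 1.00 / 6.82 ± 2.75 μm
(normal / subKC / KC), Bowman PV 1.30 / 1.71 / 2.67 μm, normal Bowman
inferior minimum 15.20 ± 1.50 μm, normal epithelial PSD 3.30 μm. The
correlation parameters (ρ, the irregularity–severity coupling, and the
per-layer dispersions), which no table prints, were calibrated against
the published classifier AUC matrix: they are the only remaining
degrees of freedom that move multivariate separability without
touching any marginal.

### What the generator does and does not emulate

It emulates group-calibrated 1-D meridional profiles, severity coupling
across instruments, repeat-averaged measurement noise and realistic
eye-to-eye heterogeneity. It does **not** emulate 2-D thickness maps
(minima over a map are systematically deeper than over a meridian —
the generator's subKC/KC Bowman minima run ~0.9 μm above the reference
values, and the reference subKC PSD cannot be hit exactly by *any*
additive thinning model, since thinning adds more to PSD² than to PV²
while the published increments go the other way), optical distortion,
segmentation error, or demographic structure. Consequently, passing
tests show that the analysis pipeline is correct and that the
generator matches the calibrated group statistics — not that the
classifier performance would transfer to real patients.

## Feature table and normalization

The 49-feature contract (21 Scheimpflug + 27 OCT + gender, female = 0 /
male = 1) lives in a single registry module shared by every component;
column names and order are fixed there. Normalization is a per-feature
z-score (mean, SD with divisor n−1) fitted on training rows only;
validation rows are always transformed with training statistics, so no
information leaks through scaling. A zero-variance training feature is
an error naming the feature, not a silent drop.

## Ranking and evaluation

Fisher scores use the two-class criterion F = (μ₁−μ₂)²/(s₁²+s₂²) with
sample variances; F is invariant under shared affine maps, so raw and
normalized features rank identically, and scores are computed on the
whole dataset (the ranking is a descriptive statistic here, not a model
component). Ties break by registry order. Both class variances zero
with equal means yields F = 0; with unequal means it is reported as a
distinct infinite-separation error.

The evaluation engine repeats, 100 times from a master seed (per-repeat
seeds spawned via counter-based sequences): stratified 70/30 split
(per-class training count = round-half-up of n·0.7), normalizer fit on
the training rows, classifier fit, validation scoring. AUC is the
Mann–Whitney pair statistic (ties ½), identical to the trapezoidal
area under the empirical ROC; the operating point maximises Youden's J
over all thresholds of the form score ≥ t (plus the degenerate
"predict none"), ties resolved toward higher sensitivity — "highest
sensitivity and specificity" is not otherwise a well-defined
criterion. Summaries are means and SDs over repeats.

Classifiers: logistic regression with L2 ridge (C = 1 on normalized
features — an unpenalised fit diverges on separable synthetic cohorts
with p ≈ n) and a one-hidden-layer perceptron (10 logistic units,
α = 10⁻³, L-BFGS, ≤ 1000 iterations, seeded) — the smallest standard
neural network sensible for 49 features and ~120 eyes. Non-convergence
is flagged in the result metadata, not fatal. Group comparisons use
equal-variance two-sample t-tests at α = 0.05 with no multiplicity
correction.

## Known limitations

- The Scheimpflug-only separation of subclinical eyes comes out
  stronger than the reference study reports (AUC ≈ 0.85 vs 0.68–0.74):
  the published group marginals for ISV/IVA/KI/posterior elevation are
  more separative than the published single-instrument AUCs imply, and
  the generator is calibrated to the former.
- Within-group SDs of ratio-type Bowman features (BEI-MAX, inferior
  minimum) remain below the reference values even with the dispersion
  factors; matching them exactly would require a 2-D map model.
- The 49-feature count is reconciled as 21 + 27 + gender; the source
  catalogue never itemises the arithmetic.
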