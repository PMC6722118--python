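# Methods

This note records the models behind `mosaicquant`, the parameter choices
that matter, and what the synthetic benchmarks do and do not demonstrate.

## 1. The area-ratio statistic

The quantity of interest is the fraction of myocyte area that stains
strongly for the target protein:
`% mosaicism = 100 · A⁺ / A`, with `A⁺` the pixel area of the selected
strongly-positive mask and `A` the area of the all-myocyte mask. An
area ratio, not a cell count, is used because cell segmentation in
brightfield cardiac tissue is unreliable; the validation module
quantifies how well the area ratio tracks the per-cell fraction (on
synthetic cores with uniform cell sizes the two agree to r > 0.99; with
the default ±25% cell-size spread agreement remains above 0.99 because
positive status is assigned independently of cell size).

### Brown intensity

Brightfield absorbance is modelled with Beer-Lambert optics: each stain
adds optical density OD = −log₁₀(I/255) along a fixed unit RGB vector.
We use the Ruifrok-Johnston hematoxylin (0.650, 0.704, 0.286) and DAB
(0.268, 0.570, 0.776) vectors, completed by their cross product; the DAB
channel of the inverted 3×3 system is the brown-intensity map. Negative
deconvolved values (quantization noise) are clipped to zero. A
channel-arithmetic mode (`brown_mode="blue_norm"`, brown = (R−B)/255) is
provided for sensitivity analysis only.

### Thresholding

One global 2-class Otsu cut is computed per core on a 256-bin histogram.
Pixels with DAB OD below `background_od_epsilon` (default 0.10) are
excluded from the histogram so that empty background and bare
counterstain cannot dominate the class statistics — without this, the
cut separates tissue from background instead of blush from dark brown.
Candidate cuts are restricted to bin boundaries that close a non-empty
bin: cuts sliding across empty bins yield the identical pixel partition,
and evaluating one canonical representative per partition makes the
argmax independent of floating-point summation order. Ties go to the
lowest cut.

The published-style workflow then applies **threshold correction
factors** — multipliers on the Otsu cut, the CellProfiler convention —
of 1.5 to 2.75 in steps of 0.125 (11 masks) for the strongly-positive
candidates and 0.5 for the all-myocyte mask. The step size is the
uniform spacing that yields exactly 11 values over the stated range.
This geometry encodes two assumptions about the histogram: half the
Otsu cut must fall between counterstain background and blush staining
(so the 0.5 mask captures every myocyte), and some factor in
[1.5, 2.75] must fall in the gap between blush and dark brown.

### Size filter and selection

Connected components (8-connectivity by default; 4 available) smaller
than 50 px are removed from every mask; a 50-px component is kept. The
threshold is in pixels, deliberately resolution-agnostic, matching the
original workflow's published value.

Factor selection is manual (a per-core index, reproducing blinded human
choice) or automatic: the all-myocyte mask is labelled into objects, a
factor "captures" an object when it covers ≥ 50% of its area, and the
factor maximizing the gap between the dimmest captured object mean and
the brightest uncaptured object mean wins (ties → lowest factor). On a
genuinely bimodal core every factor whose cut lies in the blush/dark gap
induces the same capture set and the same gap, so the rule picks the
lowest such factor deterministically.

Degenerate cores — constant intensity, fully excluded, zero myocyte
area — raise typed errors and are recorded as *unevaluable*, mirroring
the practice of dropping unevaluable images; the pipeline flags them and
the exclusion log counts them.

## 2. The synthetic core generator

The generator emulates the phenomenology the quantifier must handle, not
histological realism:

- **Geometry.** Convex elliptical "myocytes" (requested areas truncated
  normal, default mean 700 px, SD 180 px, clipped to 300–3000 px) on a
  jittered grid with no overlap; thin elongated unstained "vessel" holes
  (marked in the exclusion mask); dark debris specks below 50 px placed
  with clearance from cells so components never merge. A stress setting
  (`debris_area_px_max ≥ 50`) demonstrates the size filter's limit.
- **Staining.** Per-cell DAB amounts are drawn from two truncated
  normals — blush (mean 0.32 OD) for negative cells, dark (mean 0.95 OD)
  for positive cells, SD 0.025 truncated at ±2 SD — plus pixel noise
  (SD 0.01, ±3 SD) and a hematoxylin field everywhere. These numbers are
  chosen from the threshold algebra above: with the Otsu cut landing at
  the top of the blush class (~0.40), factor 0.5 (~0.20) sits safely
  between counterstain (<0.05 after deconvolution) and the dimmest blush
  pixel (~0.24), while factors 1.5–2.0 land in the blush/dark gap.
  Intensity distributions of real blush vs strong staining are not
  quantitatively documented anywhere we know of; these defaults are
  stated, not fitted.
- **Ground truth from rendered pixels.** The positive subset is chosen
  by greedy subset-sum with swap refinement to match the requested area
  fraction, and the stored truth is the exact pixel count of what was
  rendered, so recovery tests compare against exact integers. Rendering
  uses the forward stain transform; the quantifier uses its inverse, so
  the only recovery error sources are 8-bit quantization and boundary
  pixels — in practice recovery is pixel-exact across 0.5–92% true
  mosaicism.
- **Determinism.** All randomness flows from `numpy` Generators seeded
  from the spec; per-core seeds are `crc32("{master_seed}:{core_id}")`
  masked to 31 bits, so image sets are reproducible and row-order
  independent.

Passing these benchmarks shows the pipeline is algorithmically correct
and unbiased on cleanly bimodal tissue; it does not certify performance
on real slides with stain gradients, folds, or continuous intensity
distributions.

## 3. The synthetic cohort and its calibration

One row per core; subjects carry sex (69.2% male), age (normal 54.7 ±
16.4 y, clipped to 18–95), ethnicity, disease (prevalences from a
700-subject autopsy-cohort profile), heart weight (log-normal around
400 g, ~41% missing), BMI, and a home TMA among five; ~12% of subjects
contribute a second core and ~5% of those a third, optionally on a
different TMA — which is what makes the subject and TMA random effects
*crossed* rather than nested. The outcome is generated on the √fraction
scale:

```
s = 0.29 + 0.097·male − 0.00013·age + disease effect + u_subject + v_TMA + ε
percent = 100 · clip(s, 0, 1)²
```

with `u ~ N(0, 0.08²)`, `v ~ N(0, 0.02²)`, `ε ~ N(0, 0.045²)`. The
residual SD is calibrated analytically so that replicate cores of one
subject differ by ≈3.5 points on the percent scale: to first order
E|Δ%| ≈ 200·E[s]·(2σ_ε/√π) ≈ 79·σ_ε at E[s] ≈ 0.35, giving σ_ε ≈ 0.044
for 3.5 points; we fix 0.045. Disease shifts default to a hypertrophic
cardiomyopathy effect of +0.21 and small sudden-death-class effects;
parameter-recovery simulations that target the sex/age/variance
components set the disease effects to zero, because a fitted model
without disease terms would otherwise (correctly) absorb the disease
variance into the subject component and the "planted vs recovered"
comparison would be ill-posed.

`generate_cohort(spec, noise_sign=-1)` negates every random draw while
keeping covariates fixed. Recovery studies use such antithetic pairs:
the GLS estimator is nearly linear in the noise, so pair-averaging
cancels first-order Monte-Carlo error and bias checks at the 10⁻⁵ level
(the age effect) become meaningful at 200 replicates.

## 4. The mixed model

`fit_mixed_model` computes the REML fit of the outcome on fixed effects
with crossed random intercepts. Writing V₀ = I + γ_s Z_sZ_sᵀ + γ_t
Z_tZ_tᵀ (γ = variance ratios to σ_e²), the subject blocks make
D = I + γ_s Z_sZ_sᵀ block-diagonal with rank-one blocks invertible in
closed form, and the TMA factor enters through a T×T Woodbury
correction. One profiled-REML evaluation is O(n·T²); Nelder-Mead over
(log γ_s, log γ_t) converges in milliseconds at n ≈ 750, which is what
makes 200-replicate recovery studies routine. Estimates agree with
statsmodels MixedLM (crossed variance components) and lme4 to ~2×10⁻⁵
on small fixtures.

Choices, all recorded in the fit object:

- **REML**, not ML (the lme4 default), so variance components are
  unbiased to first order.
- **p-values** by the normal approximation on t = estimate/SE
  (the "p.z" convention); Satterthwaite degrees of freedom, computed
  from the numerical REML Hessian in (σ_s², σ_t², σ_e²), behind
  `df_method="satterthwaite"`.
- **Coding**: sex female = 0 / male = 1; disease as treatment contrasts
  against Control; age in years, untransformed; heart weight and BMI
  natural-log transformed; outcome √(percent/100), so an intercept of
  0.29 corresponds to (0.29)² ≈ 8.4% baseline positivity.
- **Degenerate designs**: a grouping factor with a single level is
  confounded with the intercept; its variance is fixed at 0 and the fit
  flagged singular (lme4 refuses such designs outright). Variance ratios
  estimated at the boundary are likewise flagged, never silently
  dropped.
- **Missing data**: listwise deletion within each model, with the drop
  count reported.

**Exclusions** (applied before modelling, all counts logged): subjects
under 18 years; rows missing sex or age; unevaluable cores. Counts
always sum back to the input row count.

**Residuals.** `compute_residuals` fits the adjustment model
(age + sex + both random intercepts). By default it returns the fully
conditional residual y − Xβ̂ − Z_sû − Z_tv̂ — the quantity that is
exactly orthogonal to the fixed-effect columns and vanishes on noiseless
data. For subject-level group comparisons (disease) this is the wrong
object: the subject BLUPs absorb most of a subject-level shift (a
planted 0.21 shift leaves ~0.03 in the conditional residual). The
pipeline therefore computes disease-comparison residuals with
`subtract_random=("tma_id",)`: subject intercepts still guard the fit
against pseudo-replication, but subject-level biology stays in the
residual, and the planted shift is recovered in full.

**Model suite.** Four standing specifications: age + sex on everything;
age + sex + disease on TMAs 1–2; age + sex + log heart weight (rows with
heart weight only); age + sex + an HCM indicator on everything. Failures
are isolated per model.

## 5. Problem sizes and numerical conventions

Tests and the acceptance script run synthetic cores at 256×256 px with
40 myocytes (~55 kpx of cell area) — large enough that every mask
operation, the 50-px filter, and the auto-selection rule are exercised
at realistic cell-to-image ratios while a full study stays in seconds.
Cohort simulations use 600 subjects across 5 TMAs (the cohort scale of
the motivating design) with 200 replicates for recovery studies. Otsu
histograms use 256 bins; ties break to the lowest canonical cut; Otsu
base thresholds are reported in optical-density units. All public
entry points are deterministic given their seed.

## 6. Known limitations

- The stain model is two-component Beer-Lambert with fixed vectors; no
  stain-vector estimation, scanner color profiles, or cross-slide
  normalization.
- The generator's bimodal per-cell intensity model favors the
  threshold-ladder approach by construction; continuous expression
  gradients would blur the blush/dark gap and degrade any fixed-ladder
  method, ours included.
- The auto-selection rule assumes separable object-mean distributions;
  on real cores with heavy-tailed intensities the manual index override
  remains the authoritative path, as it was in the original workflow.
- Percent mosaicism at exactly 100% (no negative cells at all) leaves
  every correction factor ≥ 1.5 above the positive population and the
  score collapses to 0; the observed biological range (<1%–92%) does not
  approach this regime, and such cores surface with QC flags.
- The REML fitter supports at most two crossed random intercepts (the
  study design); no random slopes.
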