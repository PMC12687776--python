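# Methods

This note documents the statistical model behind `bonescore`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the procedure left room.

## Harmonization model

Raw bone variables differ between cohorts for reasons unrelated to genotype:
background strain, scanner and calibration, analyst. The package treats the
mouse model (crossed with sex and age) as the harmonization stratum and
z-scores each variable against the pooled euploid + trisomic animals of that
stratum, using the sample (n−1) SD. Consequences worth keeping in mind:

* Genotype contrasts are preserved (both genotypes share the stratum mean),
  but each model's *pooled* mean is exactly zero per variable. Any linear
  composite therefore has mean zero per model, so in a balanced design the
  mouse-model main-effect sum of squares on composite scores is identically
  zero, and in unbalanced designs it is small and biologically empty. The
  model factor remains in the ANOVA only to support the interaction term,
  which is the scientifically meaningful comparison (do genotype effects
  differ between models?).
* Standardization is invariant to affine rescaling of a raw variable, so
  unit conventions cannot leak into the scores.
* Strata need n ≥ 2 and nonzero spread per variable; violations raise rather
  than propagate NaNs. Animals missing any variable of a compartment are
  dropped from that compartment (complete-case per compartment) because the
  composite needs the full vector; no imputation is attempted.
* When two cohorts measured a variable on incompatible scales (e.g. areal vs
  volumetric BMD), the variable is excluded from the harmonized panel via
  the `exclude_variables` config key rather than rescaled.

Standardization is computed on the μCT-complete animal set; animals missing
only mechanics data keep their z-scores.

## Composite scores

PCA is fitted per comparison set, per sex and per compartment on the pooled
z-scores — loadings are never reused across strata, because the loading
pattern is itself cohort-dependent. The decomposition uses the covariance
matrix of the z-scores (already near-correlation scale; a
`use_correlation=True` switch is provided), with explicit centering of the
pooled columns. Pooled means are exactly zero whenever all strata are scored
together, so centering matters only for partial pools; it is kept explicit
rather than assumed.

Eigenvector sign is not identified, so the component is oriented by an
anchor variable forced positive: BV/TV (trabecular) and Ct.Ar (cortical) by
default, making "higher score = more/denser bone" and letting deficits read
as decreased scores. An anchor with an exactly zero loading is rejected with
a request for a different anchor. Scoring applies the loading vector to the
z-scores as given (no re-centering), which is the composite's definition;
only PC1 is ever scored, later components appear in diagnostics only.

Why a composite helps: with a panel of p correlated variables carrying a
diffuse deficit δ in every coordinate, the composite's standardized effect is
δ·(Σw)/√(wᵀRw), which exceeds δ whenever the variables share variance along
the deficit direction, while the univariate alternative pays a 1/p Sidak
penalty. The acceptance suite quantifies this at the study's scale (p = 5,
n = 12/group, δ = 0.4 SD): composite power ≈ 0.15 vs ≈ 0.11 for the best
corrected univariate test.

## Factorial statistics

* Normality gate: Shapiro–Wilk at α = 0.05 on the residuals of the
  full-interaction model. Testing residuals (not raw cell values) is the
  defensible reading for factorial designs; a per-cell switch exists. On
  failure, the response is natural-log transformed (base does not affect
  decisions) and re-tested; non-positive responses are recorded as
  untransformable and analyzed raw, flagged.
* Variance gate: Levene's test with mean centering across the full factorial
  cells.
* ANOVA: full-interaction OLS with sum-to-zero coding; Type III
  (each-term-last) sums of squares, which reduce to Type I on balanced data
  and are the appropriate marginal tests when cell ns differ. Empty cells
  raise a named inestimability error instead of silently dropping terms.
* Welch fallback: when Levene and a term are both significant, a one-way
  Welch F across that term's marginal groups is computed as a side-check
  (recorded beside, not replacing, the ANOVA row); the term is reported
  significant only if Welch agrees. The one-way-marginal reading is a
  documented choice — a heteroscedastic factorial model is deliberately out
  of scope.
* Multiplicity: Sidak p_adj = 1−(1−p)^m for the pairwise family actually
  performed within the stated slicing (e.g. genotype within each sex × age
  cell), m recorded in the output; Bonferroni p_adj = min(1, m·p) for
  planned cell-mean contrasts. Pairwise comparisons and contrasts use the
  full model's residual mean square and cell ns.
* Transmission ratios: chi-square goodness of fit of observed genotype
  counts against Mendelian ratios. Group-level correlations: Pearson r over
  group means weighted by group n, tested two-tailed on t with k−2 df (the
  group is the unit of analysis).

## Mechanical property extraction

Beam equations for a three-point bend with span L, centroid-to-surface
distance c and second moment I: σ = FLc/4I, ε = 6cd/L², E = kL³/48I. The c
used is the distance from the section centroid to the surface along the
anterior-posterior loading direction (tensile-side by convention, switchable)
and I is I_min. Note the reported modulus comes from the beam deflection
formula while the 0.2%-offset construction needs the slope of the σ–ε curve
itself; the two differ by a fixed geometric factor under these equations, so
the offset line is built from the exact image of the fitted stiffness under
the σ/ε transforms — this keeps the offset line parallel to the elastic
branch of the curve it intersects, which is what the offset method requires.

Decisions the procedure leaves open, fixed here and exposed as parameters:

* Preload trimming: samples before force first reaches 0.2 N are discarded
  and displacement is re-zeroed at the linearly interpolated crossing.
* Stiffness window: among contiguous windows lying between 10% and 90% of
  the ultimate force, ending at or before the ultimate point and spanning at
  least 15% of the pre-ultimate samples, the one maximizing regression R² is
  chosen — ties to the larger window, then the earlier start, making the
  search deterministic. Best R² < 0.9 flags low linearity. Note that on a
  bilinear curve whose post-yield branch is long and shallow, the longest
  perfectly linear in-band window can lie post-yield; validation fixtures
  therefore use geometries whose elastic band dominates, which is also the
  physical regime of real bone tests (post-yield data are short or excluded
  by the 90% bound).
* Yield: first intersection of the σ–ε curve with the offset line
  (0.2% = 2000 µε), located by linear interpolation between bracketing
  samples; a curve with no intersection before failure gets the no-yield
  flag with yield collapsed onto the ultimate point.
* Ultimate/failure: ultimate is the first force maximum; failure is the
  first post-ultimate sample below 10% of ultimate (threshold
  configurable — "where the bone broke" needs an operational rule). A curve
  that never drops is flagged no-failure and excluded from group analysis,
  mirroring the exclusion of specimens that never fail within machine
  travel.
* Works are trapezoidal integrals of F over d (mJ = N·mm) split at the
  interpolated yield point; resilience and toughness are the corresponding
  σ–ε areas (MPa). On piecewise-linear input whose kinks are sample points,
  these integrals are exact, which is what makes the generator's
  machine-precision recovery targets meaningful.

## Cortical geometry

Segmentation labels cortex (8-connected, must be a single component),
marrow (background enclosed by cortex; exactly one cavity) and outside
(background reaching the border, 4-connected); broken-cortex masks fail loudly
because marrow leaks to the border. The centroid is of the total section
(cortex + marrow; cortex-only switchable — the upstream convention is not
observable from masks alone). Radial profiles cast 720 rays (every 0.5°,
counterclockwise from the recorded anterior direction): the cortex indicator
is sampled bilinearly every 0.25 px and the 0.5-crossings are located by
linear interpolation, giving subpixel endocortical (first entry) and
periosteal (last exit) radii. Areas are pixel-center counts × pixel area, so
Ct.Ar + Ma.Ar = Tt.Ar exactly. Perimeters are marching-squares contour
lengths of a Gaussian band-limited indicator (σ = 1.5 px): contouring the raw
binary mask leaves a ~5% staircase bias on circles, while the smoothed
contour tracks the true boundary with sub-pixel error for the curvatures of
murine cortices. Ct.Th is the mean over angles of (periosteal −
endocortical) radius — consistent with the radial machinery and equal to the
geometric thickness on annuli, rather than a 3D sphere-fitting definition.
Second moments are pixel sums about the cortex centroid including each
pixel's own a²/12 term; I_max/I_min are the eigenvalues of the 2×2 tensor.
Group-average cross-sections average radii per angle across animals after
per-animal averaging.

On a rasterized annulus (outer 1 mm, inner 0.5 mm, 10 µm pixels) every
metric lands within 0.4% of its closed form; tolerances in the tests are 2%.

## Synthetic cohort generator

The generator is the package's stand-in for study data and defines the
conditions under which the pipeline is validated:

* Variable panels are multivariate normal per factorial cell: mean =
  model-specific baseline + Σ(effect shifts) × baseline SD, covariance =
  D·R·D. Effects are additive in within-model SD units, which makes recovery
  targets analytic after standardization.
* Correlation matrices default to a single-factor structure R = λλᵀ +
  diag(1−λ²) — positive-definite by construction — with trabecular loadings
  (0.93, 0.97, 0.88, −0.93, 0.95) and cortical loadings placing the five
  size variables high, Ct.Th/Ct.Ar:Tt.Ar intermediate and Ct.TMD near zero.
  The source study does not report correlation magnitudes; these are
  assumptions chosen to reproduce the qualitative regime (trabecular PC1
  ~85–93% variance explained, cortical ~60–70%, Tb.Sp anticorrelated), not
  estimates.
* Baselines are plausible murine distal-femur values with small
  between-model offsets emulating background-strain differences; the default
  trisomic effect is a diffuse deficit (−0.3 to −0.8 SD, +0.7 on Tb.Sp).
  Default n = 12/group, within the 9–21 range typical of such studies;
  unbalanced designs are configured per cell. Missing-data injection is an
  explicit option.
* Bend curves are piecewise linear (toe, elastic, post-yield, cliff) with
  kink displacements inserted into the sample grid and every derived
  property recorded analytically, so noiseless recovery is exact to float
  precision. Annulus masks are rasterized by pixel-center membership with
  known closed forms.
* All randomness flows through NumPy's PCG64 `default_rng`; replicate
  experiments spawn per-replicate seeds from one `SeedSequence`.

What the generator does **not** emulate: non-normal biological variation,
heteroscedasticity across genotypes, measurement drift within a scanning
session, litter effects, 3D image content, or longitudinal growth. Passing
tests therefore establish the correctness and calibration of the
computations under the stated model, not the robustness of the biology-side
assumptions on real data.

## Operating characteristics computed by the acceptance script

With the defaults above (problem sizes chosen to keep each run in seconds to
a few minutes): type-I error of the genotype test over 1000 null replicate
cohorts at n = 10/group ≈ 0.05; PC1 sign structure recovered in ≥ 95% of 200
replicates; composite-score power strictly above the best Sidak-corrected
univariate power over 500 replicates at a 0.4 SD uniform deficit; balanced
model-effect SS at float zero; geometry within 0.4% and mechanics within
1e-13 of closed forms. `scripts/acceptance.py --seed N --out results.json`
recomputes all of these from scratch.

## Known limitations

* The Welch fallback is one-way marginal, not a heteroscedastic factorial
  model; repeated-measures designs (longitudinal body weights) are out of
  scope.
* PCA is classical: no sparsity, robustness or rotation; a single component
  is scored.
* The stiffness window search assumes the elastic region dominates the
  10–90% force band (see above).
* Per-slice masks only; the 3D cortical stack is reduced upstream. Ct.TMD
  enters as tabular input — density calibration from attenuation is not
  implemented.
* Machine-compliance correction, four-point bending and viscoelastic
  analysis are out of scope.
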