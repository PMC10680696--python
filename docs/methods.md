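# Methods

## Model

`mgpp` implements the saturated pairwise interaction multitype Gibbs point
process as a joint model of all cell types in one image. The unnormalized
log density is the sum of per-point first-order terms
`β₀,t + Σ_k β_{k,t} X_k(x)` and, for every unordered pair of types and each
of two spatial scales, an interaction coefficient (α short-range, γ
medium-range) times a *saturated pair statistic*. The statistic for the
ordered pair (a → b) is `Σ_{z∈x_a} u(z, x_b∖{z})` where `u` is the sum of
the N largest potential values z has with points of type b; the coefficient
of α_{t1,t2} in the log density is the symmetrized sum T_{t1→t2} + T_{t2→t1}
(T_{t,t} once for within-type pairs). A point never interacts with itself.
The normalizing constant is never computed; all inference and prediction go
through the Papangelou conditional intensity λ(y | x) = f(x∪{y})/f(x).

Assumptions worth stating explicitly: the window is a closed rectangle;
interactions are isotropic and depend only on inter-point distance;
coefficient matrices are symmetric; covariates are piecewise-constant
rasters (nearest-pixel lookup, no interpolation — a binary mask stays
binary); and the model is exchangeable within type, so the pattern is a set,
not a sequence.

## Potentials and normalization

Two families per scale:

| scale  | family      | form                                | default radii |
|--------|-------------|-------------------------------------|---------------|
| short  | exponential | `2^(−d/R)`                          | R = 30 µm     |
| short  | step        | `1{d ≤ R}`                          | R = 30 µm     |
| medium | exponential | `2^(−|d−m|/h)`, m, h = band mid/half | (70, 150) µm  |
| medium | step        | `1{R_in ≤ d ≤ R_out}`               | (70, 150) µm  |

The exponential families are normalized so the potential equals **1/2 at
the interaction radius** (and 1 at its maximum). This convention matters:
fitted α, γ scale inversely with the potential's magnitude, so absolute
coefficient values are comparable across families and radii only under a
fixed convention. The three conventional radii 30/70/150 µm are mapped to
a short radius of 30 µm and a medium *band* (70, 150) µm. Radii may be
scalar or full symmetric per-pair matrices.

## Saturation and incremental evaluation

Default saturation N = 2 (configurable). Small N is the regime where the
model genuinely departs from plain pairwise interaction, and it is where the
implementation is most easily wrong: adding a point y changes not only y's
own potentials but may push a weaker partner out of an *existing* point's
top-N set. `PatternState` therefore stores, per point, per partner type and
per scale, the **N+1 largest** potential values (sorted, zero-padded). The
exact change of every pair statistic under insertion is then
`max(0, q − L[N−1])` per existing point (its N-th largest is the displacement
threshold) plus the newcomer's own top-N sum; under deletion it is
`max(0, q − L[N])` (the (N+1)-th value steps in as replacement). This makes
conditional-intensity evaluation O(n) per location and is shared verbatim by
the design-matrix builder, the AUC and top-contributor diagnostics, and the
MCMC sampler, so fitting, prediction and simulation cannot drift apart.
Correctness is enforced by tests against the literal subset-enumeration
definition and against the density-ratio definition of λ (1e-10 relative
tolerance). Two numerical details: top-N sums are accumulated in descending
order so they are reproducible bit for bit, and the deletion bookkeeping
uses a 1e-12 slack when deciding whether a value sat in a top list, because
distances computed by different BLAS paths can differ in the last ulp
(recomputing too often is harmless; the recomputation itself is exact).
Ties among potential values need no tie-breaking: only sums of values enter
the model.

## Fitting

Estimation is the logistic composite likelihood: data rows (response 1)
and, per modeled type, `n_dummy` stratified-uniform dummy rows (response 0,
one uniform draw per cell of a jittered grid — lower variance than i.i.d.
uniform, and seeded for determinism). With dummy intensity
ρ_t = n_dummy/|W|, the success probability at location u is
λ(u)/(λ(u)+ρ_t), i.e. a Bernoulli GLM with offset −log ρ_t whose linear
predictor is exactly log λ. Data rows condition on the pattern minus the
point itself (the deletion deltas above); interaction columns are the exact
per-pair statistic changes. Defaults: 5,000 dummies per type, minimum 20
cells per type per image (types below the threshold are removed before
fitting, so their parameters are *absent*, not zero), 95% Wald intervals,
significance flag ⇔ CI excludes zero.

Standard errors are observed-information GLM errors. A corrected
composite-likelihood (Godambe) variance would be larger under strong
interaction; the naive intervals can therefore be anti-conservative in that
regime. This is a known limitation, accepted to keep the estimator a plain
GLM; the Poisson-limit coverage test verifies calibration where the naive
variance is valid. Columns whose statistic is identically zero (a pair
never within potential range) are unidentifiable and reported with estimate
0 and infinite SE; separation and non-convergence are flagged on the
returned object rather than raised.

Standard spatial covariates are built by `assemble_covariates`: the
distance-to-vasculature raster (the vasculature type then becomes an
environmental variable and is removed from the modeled types) and a binary
empty-region mask — pixels farther than a threshold from every cell. How
"regions devoid of cells" should be delineated is not canonical; the
thresholded distance transform is this package's choice, with the threshold
tied to the short-range radius (30 µm) and exposed as a parameter. Both
rasters default to 128×128 (64×64 in the bundled pipelines), a resolution
at which brute-force verification stays cheap and lookup error is far below
the interaction radii.

## Simulation

`mh_sample` runs a birth–death–move Metropolis–Hastings chain on the
unnormalized density restricted to at most `max_points` points. The
truncation (default 4× the Poisson-limit expected count) makes the target
well-defined even for attractive coefficients, where the untruncated density
need not be integrable; if the cap blocks more than 10% of birth proposals a
warning reports that the configured density is effectively explosive.
Proposals: birth (uniform location, uniform type; probability 0.4), death
(uniform point; 0.4), move (Gaussian jitter, σ = 10 µm, reflected at the
boundary; 0.2). Acceptance ratios are computed from the conditional
intensity via `PatternState`. The chain starts from a Poisson draw of the
first-order intensities, runs a default burn-in of 10⁴ steps, and returns
the single final state (a trajectory mode returns every k-th post-burn-in
state). Calibration is tested two ways: interaction-free chains reproduce
Poisson counts, and a two-site discretized chain driven by the same
conditional intensity matches the exactly enumerable four-state Gibbs
distribution within 2%.

## Synthetic cohorts

`generate_cohort` emulates the structure of a two-group multiplexed imaging
study: groups CLR and DII, several images per patient, a vasculature type
scattered as a Poisson process per image (the distance covariate is built
from it and is active during generation), the remaining types drawn from
the Gibbs model with patient-specific parameters (group base + Gaussian
noise on the interaction coefficients), and exponential survival times with
hazard `λ₀·exp(b·θ + b_age·(age−62.5) + b_sex·sex)`, censored at a horizon,
where θ is the patient's true designated interaction parameter. Ages are
uniform on 40–85, sex is Bernoulli(1/2), the baseline hazard is
exponential — the simplest specification compatible with the survival model
being tested.

Default scale is roughly an order of magnitude below a real cohort —
6 patients per group × 4 images, 4 modeled types + vasculature, a
500×500 µm window at 4×10⁻⁴ cells/µm² per type (~100 cells/type/image) —
so the full pipeline runs in minutes; the bundled pipelines use 4×3 and the
sampler at 5,000 burn-in + 2,500 steps, and everything scales up through
`CohortConfig`. The designated ground-truth contrast is tumor–CD8:
α = −0.2 in CLR (mild immune exclusion) versus +0.1 in DII (mild
infiltration), patient noise SD 0.1. These magnitudes are deliberately
moderate: with exponential (infinite-support) potentials the first point of
a rare type accumulates *unsaturated* potential gains from the entire
partner population, so coefficients of magnitude ≳1 in a dense window do
not model strong thinning — they drive the type extinct, which would both
break the ≥20-cell filter and put the designated pair below the ≥10-image
survival screen the cohort is supposed to exercise.

What the generator does **not** emulate: tissue morphology (glands, TLS
structures), marker-level data and cell-type calling, inhomogeneous
vasculature, non-exponential survival, and informative censoring. Passing
tests on these cohorts therefore validates the statistical machinery —
recovery, calibration, plumbing — not biological realism of any particular
dataset.

`synthesize_estimate_table` is a metadata-level shortcut (patient truth +
per-image Gaussian estimation noise, no images) used for survival-stage
simulation studies that need hundreds of replicate cohorts; the Cox stage
only ever sees the estimate table, so its calibration can be studied
without the imaging pipeline.

## Cohort analyses

- **Group median difference**: per pair, median of per-image estimates in
  group A minus group B; NaN when either group lacks estimates. Pairs are
  keyed by lexicographically sorted labels so images with different type
  orderings aggregate correctly.
- **MAD heterogeneity**: raw median absolute deviation about the median —
  no 1.4826 normal-consistency factor, since the maps are comparative;
  cells with fewer than two estimates are missing.
- **Top-contributor map**: per pixel, the interaction part of the log
  conditional intensity of a target type is decomposed into per-type terms
  `α_{t,t2}·Δshort + γ_{t,t2}·Δmedium`; the label is the argmax of the
  absolute value over t2 ≠ target (the within-type term is excluded — the
  map is about *other* types' influence; the signed winning value is
  emitted alongside). Ties break toward the earlier type in `type_set`; an
  all-zero pixel gets the sentinel `"none"`.
- **AUC**: Mann–Whitney probability that the log conditional intensity at
  an observed point of the type (pattern minus that point) exceeds its
  value at a stratified-uniform reference location (default 10,000,
  seeded), with half credit for ties — a constant-intensity model scores
  exactly 0.5, and any strictly increasing transform of the scores leaves
  the AUC unchanged. AUC–abundance correlations are Pearson, requiring ≥3
  paired images and nonzero variance.

## Survival stage

Per eligible (pair, scale): a Cox proportional hazards model with one
observation per image (the image's estimate, plus the patient's age, sex,
time, event), cluster-robust sandwich variance with patients as clusters —
no averaging of estimates within patients. Pairs with estimates from fewer
than 10 images are screened out (boundary inclusive). P-values are Wald;
FDR control is Benjamini–Hochberg, by default jointly across all α and γ
tests (a per-scale family is available). The partial likelihood uses
lifelines' Efron tie handling; simulated survival times are continuous, so
ties — the only place Efron and Breslow differ — do not arise in the
bundled studies. Zero-event data or non-convergence yield a flagged result
with missing p-value rather than an exception.

## Problem sizes used in the bundled studies

Chosen as the package's own defaults for its validation studies: saturation
oracle 200 random configurations (≤8 points, N ≤ 3, exact equality);
conditional-intensity consistency 100 random patterns at N = 1 (1e-10
relative); Poisson recovery 50 patterns at 2×10⁻⁴/µm² in 1 mm²; sign
recovery 20 replicates per scenario (α = −1.5 and +0.8, hundreds of points
per type); sampler calibration 50 chains + a 10⁵-step two-site chain;
survival calibration 50 null cohorts of 50 patients and log-HR recovery at
200 patients; end-to-end cohort 4 patients/group × 3 images. The
acceptance script uses 12 replicates for the sign-recovery scenarios.

## Known limitations

- Naive GLM variance (see above); no Godambe correction.
- No hyperparameter selection (radii, N, n_dummy are user choices).
- Rectangular windows only; no edge correction beyond the model's own
  conditioning; no 3-D support.
- MCMC output is a single equilibrated state per call; no convergence
  diagnostics beyond the calibration tests, and strongly attractive
  regimes mix slowly and lean on the max_points truncation.
- The absolute scale of α, γ is convention-dependent (half-at-radius
  normalization); compare coefficients only across fits sharing the same
  potentials and radii.
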