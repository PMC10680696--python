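# mgpp — multitype Gibbs point process models for tissue imaging

Multiplexed tissue imaging (CODEX/PhenoCycler and kin) reduces a tissue
section to a *multitype point pattern*: the coordinates of every cell plus a
cell-type label. `mgpp` models such patterns jointly across all cell types
with a **saturated pairwise interaction multitype Gibbs point process** — a
joint species distribution model for the tumor microenvironment — and carries
the analysis through the full cohort workflow: spatial-covariate
construction, pseudo-likelihood fitting, interaction interpretation,
heterogeneity mapping, survival association, and goodness-of-fit. A
synthetic-cohort generator makes every stage testable end to end without any
imaging data.

## The model

A pattern **x** with p cell types has unnormalized density

```
log f(x) =  Σ_t Σ_{x∈x_t} [ β₀,t + Σ_k β_{k,t} X_k(x) ]
          + Σ_{t1≤t2} α_{t1,t2} · S^S_{t1,t2}(x)
          + Σ_{t1≤t2} γ_{t1,t2} · S^M_{t1,t2}(x)        (+ const.)
```

where `X_k` are spatial covariates (e.g. distance to the nearest blood
vessel, an empty-region mask) and `S^S`, `S^M` are **saturated pair
statistics**: each point accumulates the sum of its **N largest** potential
values φ(d) (short range) or ψ(d) (medium range) with points of the partner
type. Capping at N — the saturation parameter — lets the model express both
clustering (α > 0) and repulsion (α < 0) while staying well-defined.
Potentials are bounded, isotropic functions of distance, normalized so the
interaction radius is the half-value distance: by default
`φ(d) = 2^(−d/30 µm)` and ψ peaks at the midpoint of a 70–150 µm band
(radii 30 / 70 / 150 µm; step-function variants are available).

Everything operates through the **Papangelou conditional intensity**
λ(y | x) = f(x ∪ {y}) / f(x) — the expected rate of type-t points at y given
the rest of the pattern — which cancels the intractable normalizing
constant. Fitting is a logistic composite likelihood: data points against
stratified-uniform dummy points (5,000 per type by default), a Bernoulli GLM
whose linear predictor is exactly log λ. Simulation is a birth–death–move
Metropolis–Hastings chain driven by the same conditional intensity. Per-image
interaction estimates feed Cox proportional-hazards models (one observation
per image, cluster-robust sandwich variance with patients as clusters,
Benjamini–Hochberg FDR across all pair × scale tests).

## Worked example

`examples/fit_single_image.py` simulates a two-type image with mild
within-type clustering of A (α_AA = 0.4) and cross-type avoidance
(α_AB = −0.4), then fits the model:

```
simulated pattern: {'A': 310, 'B': 115} cells in a 800 x 800 um window

interaction estimates (truth: alpha(A,A)=0.4, alpha(A,B)=-0.4):
 kind type1 type2  estimate     se  ci_low  ci_high  significant
alpha     A     A     0.312  0.142   0.034    0.590         True
alpha     A     B    -0.291  0.093  -0.473   -0.110         True
alpha     B     B     0.216  0.192  -0.161    0.593        False
gamma     A     A    -0.092  0.436  -0.946    0.762        False
gamma     A     B    -0.101  0.188  -0.469    0.267        False
gamma     B     B    -0.204  0.291  -0.774    0.366        False
AUC for type A: 0.569
AUC for type B: 0.596
```

Both true interactions are recovered with the right sign and flagged
significant at 0.05 (CI excluding zero); the null medium-range coefficients
are not. The AUC is the probability that the fitted log conditional
intensity at an observed cell of that type exceeds its value at a random
reference location (0.5 = no discrimination).

The other examples follow the same pattern:

- `examples/simulate_patterns.py` — repulsive / Poisson / attractive
  realizations at one intensity, with nearest-neighbour summaries;
- `examples/cohort_pipeline.py` — a full two-group synthetic cohort:
  per-image fits, group median-difference and MAD heterogeneity matrices,
  and the FDR-adjusted Cox survival screen;
- `examples/survival_calibration.py` — type-I error and log-HR recovery of
  the survival stage on metadata-level cohorts.

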