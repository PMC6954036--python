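# Methods

## Model and scope

A matrix population model projects stage abundances one year forward,
`n(t+1) = A n(t)` with `A = U + F + C` (column = source stage, row =
destination; this orientation is asserted on file read because published
matrices vary). All downstream quantities assume a time-invariant annual
model: the dominant eigenvalue λ of A is the asymptotic growth rate, its
right eigenvector **w** (normalized to sum 1) the stable stage distribution,
and `N = (I − U)⁻¹` the matrix of expected stage residence times, defined
whenever the spectral radius of U is below 1 (otherwise the life cycle is
"immortal" and an error is raised rather than a number returned).

Where several eigenvalues share the spectral radius (imprimitive life
cycles, e.g. strict age chains with one reproductive age) the real positive
Perron root is selected explicitly; relying on `argmax |λ|` alone picks an
arbitrary rotation and yields complex eigenvectors.

## Age from stage

A recruit cohort `c0 ∝ (F + C) w` (seed-bank entries zeroed, renormalized —
"age 0" is active establishment, so residence in a seed bank is
left-truncated) is pushed through U: with `n_x = Uˣ c0`,
`l_x = Σ_active n_x`, `m_x = (1ᵀF n_x)/l_x`, `c_x = (1ᵀC n_x)/l_x`.
Projection stops at age 1000 or when `l_x < 1e−7`, whichever comes first; a
cohort that dies out completely is flagged as extinct, which matters for the
truncation bookkeeping below.

**Right truncation.** Stage models parameterized with a terminal stasis loop
produce artefactual mortality/fertility plateaus once the surviving cohort's
composition stops changing. Trajectories are therefore cut at QSD₉₀ — the
first age at which Keyfitz's Δ (half the L1 distance) between the cohort's
active-stage composition and the quasi-stationary distribution falls to
0.10. The QSD is the dominant right eigenvector of U restricted to active
stages (not of A: the plateau is a property of the surviving cohort, which
reproduces through F/C but ages through U alone); this choice is switchable
in principle but is the default throughout. A species is *eligible* for
senescence metrics only if `l_x99 ≤ QSD₉₀`, i.e. 99% of the cohort dies
before the artefact sets in. Two special cases: a nilpotent U (pure age
chain) has no meaningful QSD and is treated as never converging; a cohort
that goes fully extinct before converging has a finished life course, so its
truncation point is the extinction age and it is eligible by construction.

**Entropies.** Keyfitz entropy uses trapezoidal quadrature on whatever grid
the survivorship lives on — yearly for empirical trajectories, arbitrarily
fine for analytic curves, where the continuous limit (H = 1 for exponential
survivorship) is met to 1e−3. Demetrius entropy renormalizes
`p_x ∝ λ^{−x} l_x r_x` over the truncated window (the Euler–Lotka
normalization only holds for complete schedules) and is therefore invariant
to rescaling the reproduction schedule. The default schedule is
`r_x = m_x + c_x` — first/last reproduction whether clonal or sexual — with
a sexual-only variant switchable. Mature life expectancy defaults to the
`η_e − L_α` form (the one the trait matrix uses); the `L_ω − L_α` variant is
available because both definitions are in circulation.

## Selection and traits

The eleven selection criteria are pure per-species predicates (validity,
≥ 3 study years and ≥ 2 annual matrices, unmanipulated, annual time step and
non-annual growth form, growth form in {epiphyte, herbaceous perennial,
succulent, shrub}, n > 2, column survival < 1, some sexual reproduction),
with replicate averaging (element-wise means) and a deterministic
best-study preference (quantified clonality > study years > matrix count >
dimension > first occurrence; no total order is standard, this one is
recorded here). Mode classification: ΣC > 0 → sexual-and-clonal; otherwise
an external botanical-knowledge flag splits strictly-sexual from
clonal-but-unquantified.

Trait columns are natural-log transformed; γ, ρ and S may legitimately be 0
and use `log(x + ε)` with ε = half the smallest positive observed value in
the column (recorded per run). Values outside the 2.5th–97.5th percentiles
of the logged column are masked per value, not per species; the bounds are
stored so re-application is idempotent. Columns are standardized to mean 0,
sample variance 1, and the parameters kept so the transform round-trips.
Keyfitz's H is the response variable of the inference stage and is carried
alongside untransformed.

## Imputation and ordination

Missing trait values are completed by chained equations with predictive
mean matching: each incomplete column is OLS-regressed on all others over
its observed rows, and each missing entry receives the observed value of one
of 5 donors whose predictions are nearest (10 sweeps, single completed
dataset, one seeded RNG). Imputed values are always observed values, so
bounded traits stay in range.

The PCA is phylogenetically corrected: `Cmat[i,j]` is the shared
root-to-MRCA branch length under Brownian motion, the ancestral mean is the
GLS estimate `a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X`, and the evolutionary covariance
`R = (X−1a)ᵀC⁻¹(X−1a)/(N−1)` is eigendecomposed; scores are `(X−1a)·V`.
BM scaling is fixed (no Pagel's-λ optimization). On a star tree with equal
branch lengths this is exactly ordinary covariance PCA, which the tests
assert to 1e−8. Covariance-on-standardized-traits is used (equivalent to a
correlation PCA only without phylogenetic weighting). Axes are retained by
the strict Kaiser rule (eigenvalue > 1). Eigenvector signs are fixed by
making each column's largest-magnitude loading positive.

Inference mirrors a comparative senescence analysis: `H ~ PC1 + PC2 +
PC1:PC2` for all species and per mode (subsets under 10 species are
skipped); three clonality-covariate models (full two-axis model with
clonality main effect and interactions; each axis × clonality separately);
per-mode one-sample t-tests of mean H against 1 (a zero-variance group
returns t = 0 when its mean is exactly at the threshold); Tukey HSD over
modes with a compact letter display built from maximal cliques of the
not-significantly-different graph. P-values are unadjusted across the model
family — no multiple-testing correction is applied, matching common practice
for this table layout. Plain Tukey HSD is used; a phylogenetic variant of
the group contrasts is out of scope.

## Synthetic data: what it emulates, what it does not

Species are generated from three hazard families chosen as the standard
monotone representatives of the three survivorship types: Gompertz
`μ(x) = a·e^{bx}` (Type I, a ∈ [0.03, 0.08], b ∈ [0.15, 0.25]), constant μ
(Type II, μ ∈ [0.15, 0.30]), declining `μ(x) = a/(1+bx)` (Type III,
a ∈ [0.55, 0.80], b ∈ [0.25, 0.35] — parameters set so 99% mortality falls
near age 30, comparable to the other regimes). Yearly survival is
`p_x = e^{−μ(x)}`; the age axis is trimmed where survivorship falls below
1e−9. Fertility (iteroparous from a maturity age of 2–5, or semelparous with
fatal reproduction at age 5–8) is solved from Euler–Lotka so each species
hits a target λ drawn log-normally around 1.02 (σ = 0.04) — λ exactly 1
would leave generation time undefined for every species. Clonal species
route 10–50% of recruitment through C. A seed-bank stage (stasis 0.2,
germination 0.4, 30% of seeds banked) is prepended for a quarter of species.

Age models are pooled into 10–16 contiguous stage bins using the stable age
distribution as within-bin weights, which preserves column survival as a
within-bin weighted mean, SSD-weighted reproductive output exactly, and λ to
within a few percent. The bin count matters: with very few stages the pooled
stasis loops dominate U's spectrum and a recruit cohort converges to the QSD
almost immediately, making nearly every species ineligible under the
truncation rule; 10+ stages keep convergence slower than mortality for the
large majority of species, as in empirical datasets where eligible models
are the progression-dominated ones. A small share of stasis (0.5–4%) is
redirected one stage backwards so shrinkage ρ is realized rather than
structurally zero; this leaves column survival, hence `l_x`, unchanged.
Semelparous species are planted only in the Type I cell because fatal
single-age reproduction clusters deaths regardless of the hazard family,
which would contaminate the per-regime H-side ground truth. Pooled
semelparous models usually fail the eligibility rule (their stasis plateau
is exactly the artefact it screens for) — that is treated as correct
behavior, not a defect.

Phylogenies are Yule trees (birth rate 1); tip edges are extended by the
expected waiting time to the next speciation because the simulator stops at
the n-th birth, which would otherwise leave a zero-length cherry and a
singular Brownian covariance. Traits evolve by multivariate BM with a chosen
rate matrix.

The "reference" scenario plants 124 strictly sexual (100 Type I + 24
Type III), 35 clonal-but-unquantified (all Type I) and 22 sexual-and-clonal
species (21 Type I + 1 Type III), plus three labelled filter failures
(annual growth form, no reproduction, survival ≥ 1). What passing tests on
these data do **not** show: real MPMs have observation error, non-monotone
(bathtub) hazards, density dependence, and stage classifications that mix
size and age; none of these are emulated, so ground-truth recovery here
demonstrates correctness of the machinery, not robustness to real-world
model misspecification.

## Numerical choices and degenerate inputs

- λ within 1e−10 of 1 → generation time reported missing (imputable), not a
  crash.
- Primitivity is decided on the boolean adjacency of A raised to
  `(n−1)·n + 1` via semiring exponentiation (no integer overflow);
  irreducibility by strong connectivity of the directed life-cycle graph of
  A, reproduction arcs included.
- `(I−U)` singular (column survival 1) → explicit immortal-life-cycle error.
- A trait column that is entirely missing, constant, or has no positive
  values to anchor the shifted log → named error.
- Tied candidates in best-study selection resolve to first occurrence;
  filtering outcomes are independent of collection order.
- All randomness flows from one integer seed per run; stage-local seeds are
  derived deterministically, and regeneration is bit-identical.

## Problem sizes

Default test and pipeline runs use collections of ~180 species with 45-year
age grids pooled to 10–16 stages, 64-tip trees for subspace-recovery checks,
100-replicate coverage simulations, and 10⁵-individual cohort simulations
for the Monte-Carlo oracle — sizes at which every ground-truth property is
measurable with comfortable margins while the full suite stays fast.

## Known limitations

- Transient dynamics, damping ratios and sensitivity/elasticity analysis are
  out of scope.
- Single imputation only; between-imputation variance is not propagated into
  the inference tables.
- The phylogenetic correction assumes plain Brownian motion; no λ/OU
  transformations.
- Group contrasts are non-phylogenetic Tukey HSD.
- The generation-time definition `T = log R0 / log λ` counts clonal recruits
  in R0 by default; whether ramet recruits should count toward "population
  replacement" is a modelling decision, so the sexual-only variant is a
  switch away.
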