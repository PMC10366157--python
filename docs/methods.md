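# Methods

## Pedigree representation and kinship

Pedigrees are read from PLINK `.fam`-style files (FID, IID, PAT, MAT, SEX;
whitespace or comma delimited, `0`/empty for a missing parent). Validation
enforces a DAG (no individual its own ancestor), unique individual ids, and
sex-consistent parent links; a parent referenced by id but absent from the
rows is materialized as a founder, and an individual with one missing
parent is treated as a half-founder (the missing side contributes nothing
to kinship). Generation indices come from a topological sort with
lexicographic tie-breaking, which makes every derived object independent of
input row order.

Kinship uses the classical recursive tabular method in generation order:
founders have self-kinship 1/2 and zero kinship with everyone processed
before them; for an individual with parents (p, q), the off-diagonal
recursion is the parental average and the diagonal is
`0.5*(1 + phi_pq)`, so inbreeding propagates exactly (a child of first
cousins gets f = 1/16, self-kinship 0.53125). The additive relationship
matrix is A = 2Φ; before any factorization a jitter of 1e-8 is added to
the diagonal for Cholesky/eigendecomposition robustness. The test suite
checks the recursion against a 100,000-replicate gene-dropping Monte-Carlo
estimate.

Relative pairs are classified by ancestor-path rules rather than kinship
thresholds, so inbreeding cannot mislabel a class. Rules are applied in
closeness priority (parent–offspring, full siblings, half-siblings,
grandparent, avuncular, first cousins, spouses), giving each pair exactly
one class. Spouses are defined as two individuals sharing at least one
common offspring — the only definition derivable from a pedigree file with
no marriage field. Cousins are grouped with the second-degree classes for
reporting, following the field's cohort-table convention, although their
kinship (1/16) is third-degree.

## Phenotype preparation

The preparation chain mirrors FFQ practice:

1. **Energy filter** — rows with energy strictly below 800 or strictly
   above 4200 kcal/d are excluded (boundary values retained); non-positive
   or missing energy is excluded with its own reason code. The exclusion
   report is a first-class output so participant flow is auditable.
2. **Energy adjustment** — servings/day are expressed per 1000 kcal:
   `x / (energy/1000)`.
3. **Food-group aggregation** — groups are row-wise sums of member items
   and may overlap (total meat contains red meat).
4. **Age adjustment and normalization** — each trait is regressed on age
   (simple linear fit, pooled across sexes by default since sex enters the
   mixed model as a fixed effect; a per-sex option exists) and the
   residuals are normalized. The default transform is rank-based
   inverse-normal with the Blom offset `(r - 3/8)/(n + 1/4)` and average
   ranks on ties, followed by exact z-scoring so prepared traits have
   sample mean 0 and variance 1 to machine precision. The alternative is
   Box–Cox (λ by profile maximum likelihood, values shifted positive
   first) followed by z-scoring. The inverse-normal route is invariant to
   any strictly monotone pre-transform of the trait, which is what makes
   the exponential serving-scale of the generator harmless downstream.

## Familial correlations

For role-distinguishable classes (parent–offspring by sex, brother–sister,
spouse, grandparent, avuncular) the interclass estimator is the
product-moment correlation over ordered pairs, role A against role B (the
parent, the male spouse, the elder, the aunt/uncle first). For
exchangeable classes (sister–sister, brother–brother, half-sibling,
cousin) the intraclass estimator is computed by double entry: each pair
contributes both orderings to a single product-moment correlation with a
common mean and variance.

Pairs are equally weighted and an individual appearing in many pairs is
retained in all of them, so pairs within a family are dependent; standard
errors therefore come from a leave-one-family-out jackknife rather than a
pair-level formula. The p-value is two-sided normal on icc/se; no
multiple-testing correction is applied (each trait × class test stands at
α = 0.05, with a report-significant-only switch for compatibility with
cohort reporting conventions). Estimates with fewer than 3 usable pairs,
fewer than 2 families, or degenerate variance are suppressed with an
explicit reason rather than reported as numbers.

## Heritability model

The Gaussian mixed model is `y = Xβ + g + e` with `g ~ N(0, σ_g² A)` and
`e ~ N(0, σ_e² I)`; `h² = σ_g²/(σ_g² + σ_e²)`. Two deliberate modelling
choices:

* **A = 2Φ, not Φ.** With the relationship matrix as covariance, σ_g² is
  the additive genetic variance and h² has its standard meaning. A config
  switch (`relationship(jitter=...)` on the kinship object returns 2Φ; the
  fit accepts any PSD matrix) lets a user fit the literal `K = Φ`
  covariance instead — this rescales σ_g² by 2 and, importantly, changes
  h², so the choice is surfaced prominently rather than buried.
* **No household component.** The model has genetic and residual variance
  only; a shared-household/couple component exists in the simulator but
  not in the fit, so estimated h² absorbs shared environment. This is the
  standard limitation of family-based heritability and is visible in the
  worked example (fitted 27% vs generative 25%).

**Gibbs sampler.** A is eigendecomposed once (A = UDUᵀ, after the 1e-8
jitter); in the rotated basis the genetic effects are independent,
`a_j ~ N(0, σ_g² d_j)`, and every sweep costs O(n): β from its
multivariate-normal conditional, the rotated effects elementwise, and the
variance components from scaled-inverse-chi-square conditionals. h² is a
deterministic transform of each draw, so draws lie in [0,1] by
construction and the retained count is exactly
`floor((n_iter − n_burnin)/thin)` — the reference schedule of 400,000
sweeps, 200,000 burn-in, thinning 40 retains exactly 5000 draws. Chains are
seeded independently and a fixed (seed, settings) pair reproduces draws
bit-for-bit.

**Priors.** Default: scaled-inverse-chi-square with df = 5 on both
variance components, scales set so each prior mode is half the phenotypic
variance (a 50:50 split — the common default of Bayesian whole-genome
regression software). This prior is deliberately proper and mildly
informative; on weakly identified family data (small sibships, no twins)
it dominates: the null-data posterior mean of h² stays near 0.2 — a fact
verified against dense 2-D numerical integration of the marginal
posterior, so it is prior geometry, not sampler error. Calibration
experiments (null calibration, coverage, cross-arm agreement) therefore
use the exposed weak option `FLAT_VARIANCE_PRIOR`: a flat prior on both
variance components (df = −2, scale 0), the classical weakly-informative
choice for variance-component Gibbs samplers. The scale-invariant σ⁻²
prior (df = 0) is rejected because it makes the posterior improper at
σ_g² = 0 and the chain collapses there.

**Probit arm.** Binary traits are fitted by truncated-normal data
augmentation of a latent liability with σ_e² ≡ 1; h² is reported on the
liability scale σ_g²/(σ_g² + 1). Degenerate (all-0/all-1) responses are
rejected.

**ML arm.** Maximum likelihood profiles a single parameter,
ρ = σ_g²/(σ_g² + σ_e²): at each ρ the GLS β and the total variance have
closed forms in the eigenbasis, and a bounded 1-D optimizer (with endpoint
checks) finds ρ̂. The likelihood-ratio test of σ_g² = 0 uses the 50:50
chi-square boundary mixture. An identity-like relationship matrix leaves ρ
unidentified and is reported with a `flat_likelihood` flag; optima at 0 or
1 get boundary flags. The ML arm doubles as an independent cross-check of
the Bayesian arm (agreement within 0.05 on simulated data with the weak
prior) and is itself checked against a dense-MVN 200-point grid oracle.

**Convergence.** Split Gelman–Rubin R̂ (each chain halved; constant chains
return 1.0 by convention) on h², σ_g², σ_e²; R̂ ≥ 1.03 sets a warning flag
on the fit, never an exception. The implementation is cross-checked
against arviz's split R̂ in the tests.

## Synthetic-data generator

The generator emulates the cohort envelope the analyses were designed for:
28% singletons, founder couples with sibships drawn from a distribution
over 1–6 children (default mean ≈ 1.66, matching a reported 1.60 ± 0.85),
and per-child probability 0.15 of a third-generation extension by a
married-in founder — together giving mean family size ≈ 3.2 (reported
3.20 ± 2.89, max 32). Phenotypes decompose a unit-variance latent trait
into additive-genetic (h²_true, drawn per family through the Cholesky
factor of the within-family A), couple-shared environment (c², shared by
spouses and inherited by nobody — the device that makes spouse ICCs exceed
parent–offspring ICCs, as the cohort reports), and residual variance, plus
linear age and sex effects. Assortative mating correlates founder-couple
residuals via a bivariate-normal (Gaussian-copula) draw at the configured
spousal r — a phenotypic-rank mechanism, deliberately agnostic about any
genetic pathway. Reported servings/day are
`exp(0.5·latent) · energy/1000`, so the per-1000-kcal trait is a positive,
skewed, monotone transform of the latent value and the inverse-normal
preparation is exercised non-trivially. Energy is drawn inside the
plausibility window except for a configurable misreport fraction (default
6.4%, matching 668/10,468 exclusions) pushed outside it.

For any pair with kinship φ the generator satisfies
`cov(latent) = 2φ·σ_g²` (plus the couple term within spouse pairs), which
the tests verify empirically — this closed form is what every recovery
test is anchored to.

What the generator does **not** emulate: item-level FFQ structure and
nutrient composition, measurement error and reporting bias beyond the
energy-misreport device, genotypes, dominance/epistasis, age-varying
genetic effects, household clusters larger than a couple, and non-random
mating beyond phenotypic assortment. Passing recovery tests therefore
show the estimators are correct under the stated generative model, not
that real dietary data meet that model's assumptions.

## Problem sizes and numerical choices

Recovery experiments use sibship mixes over 2–6 children (mean ≈ 3.6)
rather than the cohort's small default sibships: with ~1.6 children per
family h² is weakly identified and posterior summaries are prior-driven;
the larger sibships are the "well-identified" condition the calibration
claims are about. Test and acceptance runs use scaled-down Gibbs schedules
(thousands of sweeps, 1–2 chains) chosen as the package's standard quick
settings, with `--preset reference` exposing the full 400,000-sweep reference
schedule. Ties in ranks get average ranks; degenerate traits (zero
variance after age adjustment), empty responses, non-PSD relationship
matrices and single-chain R̂ requests all raise typed errors with the
offending quantity named.

## Known limitations

* Estimated h² conflates additive genetics with shared household
  environment (no household variance component, by design parity with the
  modelled analysis).
* The jackknife SE for ICCs is a documented substitute for the original
  S.A.G.E. FCOR variance formulas, which are not public; output metadata
  flags this.
* The George–Elston transform, the S.A.G.E. ecosystem's alternative to
  Box–Cox for trait normalization, has no published closed form and is
  not implemented; Box–Cox is the supported alternative.
* Interclass/intraclass estimator choice per class is fixed by role
  structure; no weighting menu (FCOR offers several) is provided.
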