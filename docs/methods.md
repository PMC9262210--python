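# Methods

## The model

Each individual carries a standardized polygenic score (PGS). Within a
family the scores of mother (M), father (P) and offspring (O1..On) are
jointly Gaussian with a correlation matrix determined by the mating regime:

- **random mating**: spousal correlation 0, parent–offspring and
  sibling–sibling correlations 0.5;
- **assortative mating**: spousal 0.2, parent–offspring and sibling 0.6.

Scores are drawn as exact multivariate normals through the Cholesky factor
of the correlation matrix; there is no locus-level meiosis, no
multi-generation assortment dynamics, and the assortative matrix is taken
as a given scenario rather than derived from an assortment strength (its
internal consistency is not asserted).

The index individual is offspring O1. Their phenotype is

    y = (k_I + C)·G_O1 + k_M·G_M + k_P·G_P + k_S·Σ_sibs G_sib + ε,
    ε ~ N(0, σ_ε²),

with the per-sibling effect k_S **summing** over siblings (the linear
multi-sibling extension). Confounding enters as the additive slope shift
C·G_O1, not as a separate confounder variable. Under random mating the
population OLS slope of y on G_O1 is

    β = k_I + ½k_M + ½k_P + n_sibs·½·k_S + C,

because every relative's score regresses on G_O1 with coefficient equal to
their PGS correlation (0.5). The difference estimator 2(β_NS − β_S)
therefore identifies k_S when direct effects, parental IGEs and
confounding are homogeneous across strata; heterogeneity biases it by
(ΔkI) + ½ΔkM + ½ΔkP + ΔC, and assortative mating biases it upward (every
0.5 weight becomes 0.6).

Error variance is assumed equal across strata (σ_ε = 1 by default, in
phenotype SD units); nothing in the estimators depends on that choice
beyond the Monte-Carlo noise level.

## Estimators

- **Stratified association**: OLS of phenotype on PGS plus covariates
  (default: sex, birth year, 10 PCs), classical homoskedastic SEs,
  complete-case. Classical rather than robust SEs match the delta-method
  algebra used downstream.
- **Difference / attenuation**: Δ = β_A − β_B with SE √(se_A²+se_B²)
  (non-overlapping strata, zero covariance); 95% intervals use 1.96
  throughout (normal, appropriate at the intended n). % attenuation divides
  Δ and its CI bounds by the *fixed* reference point estimate, ignoring
  denominator uncertainty — deliberately, and anti-conservatively.
- **Interaction route**: trait ~ PGS + N + N·PGS (+ N² + N²·PGS) +
  covariates, N = number of siblings; the 6+ exclusion drops N ≥ 6 before
  fitting. The N·PGS coefficient estimates ½k_S under a constant
  per-sibling effect.
- **×2 scaling**: point, SE and CI bounds of either route are doubled to a
  sibling IGE; it is an exact affine map, never re-derived from rounded
  inputs.
- The two routes differ when sibships vary in size: 2(β_NS − β_S) assumes
  one sibling each and over-counts when non-singletons average more; the
  interaction route is the sibship-size-aware estimator. The package
  reports both.

## The synthetic cohort

The generator emulates the *statistical structure* the analyses need, not
any particular dataset: sibship size is categorical (defaults matched to
~13% singletons and ~4.9% with six or more siblings, other masses a
design choice falling off roughly geometrically); birth order is uniform
among sibship positions; sibling counts are reported as brothers/sisters
(binomial split) with independent item non-response per question (default
1%); ~1.6% adoption; sex, birth year and PCs independent of the PGS unless
the PC-confounded mode is enabled (a user-chosen magnitude — the real
covariance of sibship size with parental characteristics is unknown here).
Stratum rules are applied literally: both questions zero → singleton, one
zero and the other unanswered → status missing, any positive count →
non-singleton; adopted individuals are excluded before analysis. With
`older_sib_only_ige`, only siblings occupying earlier birth positions
contribute k_S, which makes firstborns behave like singletons — the
birth-order signature.

Relatives' scores are discarded after phenotype generation, so the cohort
is a sample of unrelateds. What passing tests therefore show is that the
estimators recover the generating parameters *under the model's own
assumptions*; they cannot show robustness to half-siblings, participation
bias, real LD between causal and scored variants, generational effect
drift (available as an option, off by default) or genuine gene–environment
interplay, none of which the generator emulates.

## PGS construction stage

Clumping is the standard greedy rule: take the smallest-p variant below
the threshold, remove unselected variants within ±window on the same
chromosome with dosage r² at or above the threshold, repeat. Ties on p
break by chromosome, position, then id, for determinism. r² is the squared
sample correlation of dosages (no haplotypes exist here); positions are
1-based and the window comparison uses kb without rounding. Effect-allele
mismatches are errors, not auto-flips. The LD reference is synthetic:
two latent AR(1) haplotypes per individual thresholded at the allele
frequency — adequate for exercising the rule, not a model of real LD.

## Numerical and design choices

- Seeds are explicit everywhere; a run-level seed expands to per-call
  seeds via `numpy.random.SeedSequence` (children kept < 2³¹).
- Monte-Carlo assertions use 5 standard errors of the relevant sampling
  distribution at the generated n.
- Weight-recovery sweeps reuse one family draw and one error vector across
  the swept parameter values (common random numbers); the recovered weight
  then equals a single realized within-sample regression coefficient, so
  its noise is ~(1−r²)/√n rather than a difference of independent slopes.
  The maternal-bias sweep goes further: the trio stratum reuses the
  (M, P, O1) columns of the quad draw — a valid marginalization, since the
  3×3 sub-matrix of the random-mating quad structure *is* the trio
  structure — and the same error vector, so everything except the maternal
  difference cancels exactly.
- Study sizes: expectation-recovery and weight sweeps use 100,000 families
  per point; the difference-estimator calibration uses 200 replicates of
  20,000 families per stratum, and the assortative-mating inflation check
  200 replicates of 50,000 — sizes at which each check's Monte-Carlo error
  is several times smaller than the effect it measures.
- Non-PSD correlation matrices are rejected naming the offending
  eigenvalue; a PSD-but-singular matrix falls back to an eigendecomposition
  factor.
- Rank-deficient regression designs are rejected naming the first
  linearly dependent column rather than silently pseudo-inverted.
- Firstborn/non-firstborn analysis strata are restricted to non-singletons
  so they remain disjoint from (and comparable with) the singleton
  stratum, although the firstborn *flag* itself is simply "no older
  siblings".

## Known limitations

Half-sibling IGEs, non-random participation, geographic structure beyond a
generic group-difference test, within-family GWAS re-estimation and
imputation are out of scope. The attenuation CI is anti-conservative by
construction. The headline empirical magnitudes of the original study
design (attenuation percentages in real biobank data) are not identifiable
from synthetic data; the package targets parameter recovery and pattern
reproduction instead.
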