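# Methods

`pedeval` implements the quantitative-genetic evaluation chain of a closed
family breeding program for a farmed fish (the motivating system is Asian
seabass grown in sea cages and tanks, measured repeatedly between 105 and
570 days post-hatch): pedigree relationships, sire–dam REML variance
components, liability-threshold models for binary survival, between-trait
and between-environment genetic correlations, BLUP breeding values, and
mate allocation under strict inbreeding avoidance. This note records the
models, the estimation choices, and what the simulation-based validation
does and does not demonstrate.

## Pedigree and relationships

Pedigrees are validated (unique ids, parents present or coded 0, acyclic)
and recoded to consecutive integers in a stable parents-first topological
order. The numerator relationship matrix **A** is built by the tabular
method; the diagonal is `1 + F` and the inbreeding coefficient of any
*hypothetical* mating's progeny is half the candidates' relationship,
evaluated without mutating the pedigree. The matrix is stored dense: the
target scale (a few thousand animals per evaluation) makes sparse-inverse
machinery unnecessary. Founders are treated as unrelated and non-inbred;
nothing in the founder molecular data enters the pipeline.

Correctness is established against an independent memoized coancestry
recursion on random pedigrees and against the textbook identities (full
sibs 0.5, half sibs 0.25, full-sib-mating progeny F = 0.25).

## Sire–dam linear mixed model

For a continuous trait the model is

    y = mu + year + environment + sire + dam + family + e

with independent random effects. By default the sire and dam variances are
constrained equal (`equate_sire_dam`), reflecting that each parent
transmits half its genome, and the *separate* full-sib family term absorbs
the maternal/common-environment excess created by rearing each family in
its own tank until tagging. Under that parameterization

    sigmaP^2 = 2 sigmaS^2 + sigmaC^2 + sigmaE^2,
    h^2 = 4 sigmaS^2 / sigmaP^2,   c^2 = sigmaC^2 / sigmaP^2.

An unconstrained sire/dam option exists for sensitivity analysis; it still
derives h² from 4·sigmaS² (the dam line then carries the dam–sire excess).
Sire, dam and family effects use identity covariance within term — a
family-based sire–dam model, not an animal model; the pedigree enters at
the EBV stage. Nested single-pair matings alone cannot separate the family
term from the parental terms; identification comes from half-sib families
(parents used in more than one mating), which is why the simulator's
default design mates every sire to two dams.

Estimation maximizes the restricted likelihood with ten
expectation–maximization steps (guaranteed uphill; asserted in tests)
followed by average-information (AI) Newton updates with step halving.
All solves use the Woodbury identity, so cost scales with the number of
random-effect levels rather than records. Convergence requires a relative
log-likelihood change below 1e-8 and relative parameter changes below
1e-6; components heading negative are pinned at 1e-8 times the sample
variance and flagged. On balanced designs the REML estimates reproduce the
expected-mean-squares (ANOVA) estimators to 1e-6 relative, and on nested
designs they match lme4's `lmer` — an independent implementation — to well
under 2% of the residual variance. Heritability standard errors use the
delta method on the inverse AI matrix.

The common full-sib term is tested with a likelihood-ratio statistic
referred to the 50:50 mixture of a point mass at zero and chi-square with
one degree of freedom, the correct reference when the null value sits on
the boundary; at the convention adopted here a zero statistic reports
p = 1. Simulated type-I error at the 5% level is verified to be nominal.

## Bivariate model and G×E

Two traits are fitted jointly with trait-specific fixed effects; sire and
dam share one 2×2 genetic covariance block, the family term carries its own
2×2 block (its cross-trait covariance is estimated by default and can be
fixed at zero), and the residual block is estimated only where animals
carry both traits. Correlations are the off-diagonal over the geometric
mean of the diagonals; the phenotypic correlation sums 2×sire + family +
residual (co)variances.

The optimizer is the same AI machinery generalized to covariance
structures, with three safeguards that matter in practice: a per-iteration
trust region (no parameter moves more than half its own scale, preventing
a Newton overshoot from pinning a variance at the boundary), an active set
that freezes parameters pressed against a boundary with outward-pointing
gradients, and a *boundary-face search* — when a correlation ends near
|1|, all covariances are pinned to the cap |r| = 1 − 1e-7, the variances
are re-optimized on that face, the pins are released, and the mode with
the higher restricted likelihood wins. The face search is what lets a
degenerate fit (e.g. a trait against its own copy) reach r = 1 instead of
stalling on the nearly singular ridge below it. Correlations are capped at
1 − 1e-7 in magnitude so covariance blocks remain invertible; delta-method
SEs degenerate near ±1, so the G×E report also carries the estimate and SE
on the unbounded Fisher-z scale.

For genotype-by-environment interaction the trait's expression in tank and
in sea cage are treated as two traits. Every animal is tested in exactly
one environment, so the residual covariance is structurally zero and is
fixed there, and no phenotypic cross-environment correlation exists or is
reported. The environment fixed effect is excluded (the trait-specific
means absorb it), and the trait is square-root transformed first to even
out the variance difference between environments; the transform is applied
to the raw trait before any centering. The family (common-rearing) effect
is shared across environments — families are reared together before the
split — so its cross-environment covariance is estimated by default
(`common_cov=False` fixes it at zero). The sire-level correlation of the
two expressions is the between-environment genetic correlation; values
below one mean families re-rank across environments.

## Survival: threshold models and scale transformations

Survival is 1 if the animal is alive at the final measurement. The
sire–dam generalized mixed model uses a logit or probit link with the
residual fixed by the link; liability heritability is

    logit:  hL^2 = 4 sigma_s^2 / (sigma_s^2 + sigma_d^2 + pi^2/3)
    probit: hL^2 = 4 sigma_s^2 / (sigma_s^2 + sigma_d^2 + 1).

Estimation warm-starts with Schall-type penalized quasi-likelihood
(working-variate) updates and then maximizes the Laplace-approximated
marginal likelihood over the variance parameters — the inner joint mode is
found by penalized Newton iterations using the *observed* second
derivative of the data log-likelihood (for the probit the observed and
expected information differ, and using the expected one biases the
variances upward by several percent at 100-sire scale). The resulting
estimates agree with lme4's `glmer` probit fits to three decimals on the
same data, and recover a generating hL² = 0.2 without measurable bias at
200 families × 50 offspring. PQL alone attenuates binary variance
components at small family sizes; the validation experiments therefore use
families of 50.

A heritability estimated by the *linear* model on 0/1 data is converted to
the liability scale by the classical incidence correction
`hL^2 = hO^2 * p(1-p)/z^2`, where `z` is the standard-normal ordinate at
the threshold cutting off alive proportion p. The factor is symmetric in
p ↔ 1−p, minimized at p = 1/2 where it equals pi/2 exactly, and is checked
against a quadrature-based inversion of the normal tail integral.

## BLUP and mate allocation

Breeding values come from an animal model that reuses the sire–dam fit's
components: genetic variance 4·sigmaS² with covariance structure **A**,
the family variance as estimated, residual the remainder of sigmaP² (if
h² + c² ≥ 1 leaves no residual, a floor of 5% of sigmaP² keeps the
equations positive definite and the result is flagged). Solving the
mixed-model equations gives EBVs for every pedigree member including
non-phenotyped parents; a progeny without records predicts exactly at its
parent average (tested), and accuracy is `sqrt(1 - PEV/((1+F) sigmaA^2))`.

Mate allocation is the three-step greedy rule: (1) rank families by the
mean EBV of their candidate members (ties by family label for determinism)
and individuals within family by EBV; (2) take the best unused male and
assign the best-ranked unused female; (3) accept only if the prospective
progeny inbreeding is zero (enforced exactly, F < 1e-12 — the rule is
absolute, not a threshold), otherwise walk down the female ranking and log
each exclusion. One mating per selected animal (single-pair design). The
F = 0 rule alone excludes parent–offspring, full-sib and half-sib pairs;
tests double-check every emitted pair against **A** (a < 0.25) and verify
against an exhaustive ranked scan that no higher-ranked feasible female is
ever skipped. A closed-loop experiment (simulate → fit → BLUP → allocate →
breed from the selected parents' true transmitting effects) shows a
positive realized genetic trend over three generations whenever h² > 0.

## The simulator

`simulate.SimulationConfig` generates one cohort under the transmitting
model: per trait with phenotypic variance sigmaP², sire and dam effects
have variance (h²/4)·sigmaP² each, the within-family Mendelian deviation
(h²/2)·sigmaP², the family common effect c²·sigmaP² (one draw per family,
shared across environments), and an environmental residual with the
remainder — hence the feasibility constraint h² + c² ≤ 1. True breeding
values (sire + dam + Mendelian) are recorded for recovery scoring.
Cross-trait structure enters through genetic and residual correlation
matrices; common effects are independent across traits. Survival is a
thresholded standard-normal liability with its own heritability, threshold
at the quantile giving the target alive fraction, independent of the
growth traits. G×E is generated by drawing each parent's tank and cage
transmitting effects from a bivariate normal with the configured
correlation (separable environment × trait covariance). Fixed structure:
additive year effects (families assigned round-robin to year labels) and
additive environment shifts, per level or per level and trait. Attrition
(`degrade`) removes later-age measurements monotonically per animal and
rewrites survival as presence at the final age.

Defaults describe a realistic cohort of the motivating program: ~45
matings arranged as 22–23 sires × 2 dams (half-sib pairs for
identifiability), 30 tagged offspring per family, harvest-size weight
(mean 1073 g, SD 131 g), alive fraction 0.481, a quarter of each family
tested in tanks with markedly slower growth there, h² = 0.4, c² = 0.15.
Validation sizes: heritability recovery at the ~45-family scale;
G×E recovery at the same scale for generating correlations 0, 0.6 and 1;
survival recovery at 200 families × 50; LRT calibration at a reduced
30-family × 10 size chosen so 500 replicates run quickly while the
asymptotic boundary mixture still applies.

What the simulator does *not* emulate: non-normal trait distributions and
the mean–variance coupling of real growth data, a growth-curve process
linking ages (cross-age correlations are induced directly, not through a
trajectory model), cause-specific mortality, cannibalism or tagging loss
as distinct processes, and founder relatedness. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
Gaussian sire–dam generative model at realistic sizes — not robustness to
the ways field data violate it.

## Numerical conventions

Variance floors at 1e-8 of the sample variance mark boundary estimates;
correlation caps at 1 − 1e-7; REML convergence at 1e-8 relative
log-likelihood change (the bivariate engine additionally stops when ten
successive steps buy less than 1e-5 relative — progress on a flat boundary
ridge that no longer changes any reported quantity). Fixed effects use
reference coding with the first observed level as reference; estimates are
invariant to that choice, to row order, and transform correctly under
affine changes of the trait scale (all tested). Degenerate inputs (single
family, one outcome class, an animal measured in both environments,
confounded fixed effects) are refused with named errors rather than fitted.
No fitting routine uses random numbers; all stochastic tests and
experiments take explicit seeds.
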