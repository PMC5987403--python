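# pedeval

Pedigree-based genetic evaluation for family breeding programs in
aquaculture — written for the geneticist running a closed nucleus of
full- and half-sib fish families (the motivating system is Asian seabass
grown in sea cages and tanks) who needs, from a pedigree and a phenotype
table: heritabilities, common full-sib effects, genetic correlations
including genotype-by-environment (G×E) correlations, survival
heritability on the liability scale, BLUP breeding values, and a mating
list that avoids inbreeding.

## The models

**Growth traits** (body weight, total length at ages 105–570 dph) follow
the sire–dam linear mixed model

```
y_ijklm = mu + Y_i + E_j + s_k + d_l + c_kl + e_ijklm
```

with fixed spawning-year (Y) and environment (E) effects and random sire
(s), dam (d) and full-sib family (c) effects. Sire and dam variances are
constrained equal by default, so

```
sigmaP^2 = 2 sigmaS^2 + sigmaC^2 + sigmaE^2,
h^2  = 4 sigmaS^2 / sigmaP^2,       c^2 = sigmaC^2 / sigmaP^2,
```

where c² is the variance fraction full sibs share beyond additive genetics
(separate family rearing before tagging). Fitting is REML —
expectation–maximization warm start, then average-information updates.

**Binary survival** is modelled on a latent liability with logit/probit
threshold sire–dam models (`hL² = 4 sigma_s² / (sigma_s² + sigma_d² +
pi²/3)` for the logit, with 1 in place of pi²/3 for the probit), estimated
by penalized quasi-likelihood with a Laplace refinement; the classical
incidence correction `hL² = hO² · p(1-p)/z²` converts a linear-model
estimate to the same scale.

**Correlations** come from two-trait sire–dam REML
(`r = sigma_12 / sqrt(sigma_1² sigma_2²)`); for G×E the trait's tank and
cage expressions are treated as two traits measured on disjoint animals
(residual covariance fixed at 0, square-root transform), and the sire-level
correlation between them quantifies family re-ranking across environments.

**Breeding values** solve the animal-model mixed-model equations with the
pedigree numerator relationship matrix; **mate allocation** is the
three-step greedy rule — rank families and individuals on merit, pair best
with best, reject any pair whose prospective progeny inbreeding F exceeds
zero (full- and half-sib matings are thereby excluded).

A simulator generates cohorts with the exact family structure these models
assume (nested full-/half-sib families, common rearing effects, tank/cage
split, liability-scale survival, configurable G×E), with all generating
parameters and true breeding values recorded — every estimator in the
package is validated by parameter recovery against it.

## Worked example

```python
from pedeval.reml import ModelSpec, fit, heritability, lrt_common_env
from pedeval.simulate import SimulationConfig, simulate

ds = simulate(SimulationConfig(seed=42))   # ~46 families x 30 offspring,
                                           # truth: h2 = 0.4, c2 = 0.15
vc = fit(ds.phenotypes, ModelSpec(trait="weight"))
gp = heritability(vc)
stat, p = lrt_common_env(vc, fit(ds.phenotypes,
                                 ModelSpec(trait="weight").without_common()))
```

prints (see `examples/02_heritability_from_simulated_cohort.py`):

```
sire variance          1929.0
common full-sib         691.6
residual              11826.5
phenotypic            16376.2
h2 = 0.471 +- 0.254   c2 = 0.042 +- 0.104
LRT for the common full-sib term: chi2 = 0.17, p = 0.3393
```

The sire variance is a quarter of the additive variance, so h² = 4·1929 /
16376 ≈ 0.47 — within one SE of the generating 0.4; at a single cohort of
46 families the SE is honest about how little one cohort pins down. The
LRT p-value comes from the boundary 50:50 chi-square mixture; here one
cohort cannot separate the (true, c² = 0.15) common-rearing signal from
the parental terms, which is exactly why such programs accumulate
generations.

The other scripts in `examples/` each demonstrate one capability:
pedigree relationships and prospective inbreeding, G×E correlations,
survival threshold models, BLUP + mating lists, and the one-config
end-to-end pipeline (also available as a CLI: `pedeval pipeline --config
run.yaml --out reports/`).

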