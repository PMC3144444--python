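# Methods

`persistgs` studies how the accuracy of estimated breeding values persists
across generations in a closed breeding population when predictions come
from pedigree relationships versus dense SNP markers. This note records the
models, the simulator's assumptions, the numerical choices, and what the
package's tests do and do not demonstrate.

## The population simulator

The simulator emulates a closed layer-type breeding line with discrete
generations:

- **Founder LD.** Haplotypes start as independent Bernoulli draws with
  per-SNP allele frequencies uniform on (0.1, 0.9) and are passed through a
  burn-in of random mating at constant size (default effective size 100 for
  100 generations). Drift during burn-in builds the linkage disequilibrium
  and allele-frequency spectrum that marker-based prediction exploits;
  without it, markers could only capture pedigree relationships.
- **Genome.** Default 10 chromosomes of 1 Morgan with equally spaced SNP
  (default panel 2,000; a desk-scale stand-in for a commercial high-density
  panel). Meiosis uses the Haldane map: crossover counts are Poisson with
  mean equal to the chromosome length in Morgans, positions uniform, no
  interference.
- **Breeding structure.** Each generation is bred from a limited parent set
  (default 60 sires and 310 dams, matching the structure of a commercial
  layer line). Each dam is mated to one random sire and litters are as
  equal as possible, so full-sib families exist. Parents may be chosen at
  random, by truncation on phenotype, or by truncation on pedigree-BLUP EBV
  (ties broken by id). Progeny count defaults to 2,400 per generation with
  two hatches; founders carry generation label -1.
- **Trait.** A proportion `pi` of the panel has zero effect; the remaining
  `round((1 - pi) * m)` SNP are QTL with normal effects rescaled so the
  additive variance at founder frequencies equals `sigma2_a` exactly
  (deterministic QTL count keeps small examples exact). Phenotype = hatch
  effect + true breeding value + normal residual with
  `sigma2_e = sigma2_a (1 - h2) / h2`. Hatch effects are normal with SD
  equal to a quarter of the residual SD by default (their magnitude is a
  free choice; nothing downstream is sensitive to it because hatch is
  always fitted or corrected for).
- **Genotyping.** All parents plus a configurable fraction of progeny
  (default 13%, giving validation sets of roughly 300 genotyped,
  phenotyped birds per generation at the default scale). Missing calls are
  introduced at 1% so the QC filters are exercised.

What the simulator does **not** model: mutation, dominance and epistasis,
overlapping generations, genotyping error beyond missingness, selection on
multiple traits, and a realistic site-frequency spectrum or LD decay
profile fitted to a real line. Passing tests therefore demonstrate internal
consistency of the estimation machinery under an idealised additive model,
not performance on any particular real population.

## Quality control

Per-SNP filters, all strict inequalities: minor allele frequency > 0.025,
missing-call proportion < 0.05, and parent-offspring opposing-homozygote
rate < 0.05 (computed per SNP over genotyped pairs with both calls
observed; the statistic is symmetric in the two pair members). Phenotype
records beyond 3 SD of their within-hatch-within-generation mean are
removed; groups smaller than two records, or with zero SD, pass untouched.
Missing genotypes are mean-imputed (twice the allele frequency) before any
matrix algebra — adequate at 1% missingness, not a substitute for
LD-aware imputation at higher rates.

## Relationship matrices

The numerator relationship matrix A uses the tabular method; its sparse
inverse uses Henderson's rules with inbreeding coefficients taken from the
tabular diagonal. G follows VanRaden's first method,
`G = ZZ' / (2 sum p_k (1 - p_k))` with dosages centered at twice the
allele frequency. Centering frequencies default to the pooled genotyped
set (training and validation generations together); this is exposed as an
argument because the choice of base population is a modelling decision.
When frequencies are the observed column means, the ones vector is in the
null space of Z, so G is singular; the G-based mixed model therefore
blends `G* = 0.99 G + 0.01 I` by default (`blend=1` disables this where an
exact equivalence is wanted and G is full rank).

## BLUP machinery

**PBLUP** solves Henderson's mixed-model equations with hatch-within-
generation fixed effects and `A^{-1} * sigma2_e / sigma2_a`, sparse
throughout, returning EBV for every pedigree member including unphenotyped
validation animals.

**Variance components** come from EM-REML. A one-time generalized
eigendecomposition of (Z'SZ, A^{-1}), with S the projection orthogonal to
the fixed design, reduces each EM step to vector operations, so the
default cap of 500 iterations at relative tolerance 1e-8 is cheap even at
a few thousand animals. EM guarantees a non-decreasing REML likelihood
(verified against a dense-likelihood oracle in the tests) but converges
slowly near the `sigma2_a = 0` boundary; non-convergence is flagged on the
result, not raised.

**GBLUP** is a reduced animal model: only genotyped animals carry
breeding-value unknowns. A record on a non-genotyped progeny of two
genotyped parents enters through the row 0.5/0.5 on its parents with
residual variance inflated by the Mendelian-sampling term
`0.5 * sigma2_a` (parents treated as non-inbred); records with a
non-genotyped parent are dropped with a warning. With every phenotyped
animal genotyped the model reduces to the ordinary G-based animal model,
and its GEBV equal ridge-regression (SNP-BLUP) predictions with
`lambda = sigma2_e * 2 sum p(1-p) / sigma2_a` — both equivalences are
enforced in the test suite at 1e-6.

## Bayesian whole-genome regression

BayesA and BayesCpi regress pre-corrected records on centered dosages with
an intercept, by single-site Gibbs sampling with the residual-update trick
(O(nm) per sweep; the locus loop is numba-compiled). Records are the own
phenotypes of genotyped animals, pre-corrected by the training PBLUP hatch
solutions, plus full-sib family means of non-genotyped progeny of
genotyped parents. A family mean stands at the parent-average genotype and
carries weight `n * sigma2_e / (0.5 * sigma2_a + sigma2_e)`: each sib
deviates from the parent average by an independent Mendelian-sampling term
plus residual, and both average down with family size.

- **BayesA**: locus-specific variances, scaled-inverse-chi-square prior
  with `nu_a = 4.2` degrees of freedom and scale
  `S = (sigma2_a / sum 2p(1-p)) (nu_a - 2) / nu_a`, so the prior mean of
  each locus variance equals the per-locus share of the additive variance.
- **BayesCpi**: per-SNP inclusion indicators, one common variance for
  included effects (same prior family; the scale spreads `sigma2_a` over
  the expected included fraction `1 - pi0`, `pi0 = 0.95` by default and
  overridable), and `pi` sampled from Beta(m - m+ + 1, m+ + 1) under a
  uniform prior, where m+ is the number of currently included SNP. Large
  log-odds are clamped at +/-35 before the logistic to avoid overflow;
  monomorphic columns are skipped and flagged.
- Residual variance is sampled from its conditional under a
  scale-invariant prior; the intercept is updated like an unpenalized
  covariate. Chains are initialised at zero effects, `pi = 0.5`, variances
  at prior means. Defaults are 160,000 iterations with 50,000 burn-in and
  thinning 10, the protocol of the motivating study; the tests use short
  chains (1,500-5,000 sweeps) at desk-scale problem sizes, where pilot
  runs showed posterior summaries are already stable enough for the
  qualitative checks being made.

## Validation designs and the accuracy statistic

Accuracy is `cor(EBV, hatch-corrected phenotype) / sqrt(h2)` over the
genotyped, phenotyped validation animals. The heritability in the
denominator and the hatch corrections come from a PBLUP fit on all data —
the single permitted use of full-data information, affecting only the
evaluation statistic; training fits never see validation phenotypes, and a
leakage assertion enforces this on every emitted record. Degenerate
correlations (constant EBV or phenotypes) are returned as missing with a
reason code and excluded from averages.

*Accumulate* mode retrains on all data through generation g and validates
on generation g+1; *persist* mode trains once on data through generation 1
and validates on every later generation. With information flowing only
through pedigree relationships, which halve at each meiosis, persist-mode
accuracy is expected to decay by `sqrt(0.5)` per generation
(`expected_decay`).

The packaged decay experiment (`persistgs.experiments`) runs 30 replicate
populations (20 sires x 100 dams, 400 phenotyped and genotyped offspring
per generation, h2 = 0.4, random selection, 6 generations, 600-SNP panel)
and summarises the decay as the mean over lags of the squared ratio of
consecutive-generation accuracies. Accuracies are averaged over replicates
*before* taking ratios: a per-replicate ratio of two noisy correlations
with a small denominator is badly upward-biased (pilot runs gave means
near 3 where the theoretical value is 0.5), while the ratio of replicate
means is stable. The true h2 is used in the accuracy denominator here;
the consecutive-generation ratio is invariant to that denominator, so
re-estimating it by REML per replicate would only add compute. Random
selection is used because the sqrt(0.5) expectation assumes no selection.

## Accuracy meta-regression

Accuracy records are modelled by ordinary least squares on
`h2, pi, generation, generation^2, h2*generation, pi*generation` plus an
intercept — seven coefficients. The variant without pi terms (equivalent
to fitting the average pi) is the form to use when pedigree-based methods
are included, since their accuracy is not expected to depend on pi; an
optional method factor is off by default. Least-squares means are model
predictions on a user grid (for example pi in {0.88, 0.99} at h2 = 0.5)
with the remaining regressors held at their data means; grid values
outside the observed range warn.

## Known limitations

- EM-REML is robust but slow near variance boundaries; no AI-REML.
- Mean imputation and the absence of phasing limit realism at high
  missingness.
- The reduced animal model treats parents as non-inbred when inflating
  progeny residuals; with substantial inbreeding the Mendelian-sampling
  variance is overstated.
- Single trait only; the bivariate analyses of the motivating study are
  out of scope, as is any attempt to reproduce its proprietary-data
  results.
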