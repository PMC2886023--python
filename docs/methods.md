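# Methods

## Normalization model

Every background-corrected, log2-transformed intensity reading from a
two-colour hybridisation is decomposed as

    Y = mu + C + G + AG + DG + FG + TG + e

* `C` — fixed *comparison group*: one level per (array slide, printing
  block, dye channel). It captures slide, spatial-block and channel
  artefacts without assuming anything about their form, which is what makes
  the model a normalization.
* `G` — random gene abundance; `AG`, `DG`, `FG`, `TG` — random
  interactions of gene with array, dye, flock and treatment. Treatment is
  breed line x time point. All random effects are independent zero-mean
  Gaussians with one variance component each; `e` is the within-gene
  residual.

The BLUPs of `TG` are the normalized mean expression per gene and
condition: all nuisance structure has been soaked up by `C`, `G`, `AG`,
`DG` and `FG`, so between-condition biology lives in `TG`.

Two treatment codings are meaningful: ten levels (high/low sub-line within
each breed line by time: RH0 … SH2), which the downstream contrasts
require, and six levels (line x time). The fitter accepts whatever labels
the observation table carries; the sub-line coding is the default used by
the simulator and contrasts, and a six-level analysis is obtained simply by
labelling samples with line x time.

### REML/BLUP computation

Estimation is REML. The iteration is expectation-maximisation with
average-information (AI) acceleration: after three EM warm-up steps, an AI
step (Newton step on the variance components with the average-information
matrix) is attempted and accepted only if the restricted likelihood does
not decrease, with step-halving; otherwise the EM update — which provably
increases the likelihood — is taken. The reported likelihood trace is
therefore non-decreasing.

The comparison-group effect has many nuisance levels and is absorbed
exactly. Because every random term is gene-crossed, the absorbed
coefficient matrix is block-diagonal by gene up to a correction of rank
equal to the number of comparison-group cells; Woodbury's identity reduces
each iteration to batched dense factorizations of per-gene blocks (a few
dozen unknowns each) plus one small capacity-matrix solve. The restricted
log-likelihood, its gradient, the trace terms of the EM update and the AI
matrix are all computed exactly in this representation; the test suite
verifies logL, gradient and BLUPs against dense textbook formulas
(`ln|V| + ln|W'V⁻¹W| + y'Py` with `V = Σ σ²_k Z_k Z_k' + σ²_e I`) to
near machine precision.

Numerical choices:

* components are floored at `1e-8 × var(y)`; variances are parameters of a
  generative model here, so negative estimates are not meaningful;
* an AI step may shrink a component by at most a factor of 10 per
  iteration, because the floor is a spurious fixed point of the EM map — a
  single overshoot onto the floor could otherwise trap the iteration;
* a component sitting on the floor whose likelihood gradient is positive is
  "unpinned" (reset into the interior) rather than accepted as converged,
  at most three times;
* convergence requires a relative change below 1e-8 in every component and
  below 1e-10 in the restricted log-likelihood, within 500 iterations;
  components pinned at the floor count as unchanged. Non-convergence
  returns the last iterate with a warning flag.

One deliberate deviation from the elementwise intuition: inflating the
residual variance shrinks the `TG` solution *vector* toward zero in norm,
but individual entries can transiently grow as signal redistributes among
the crossed terms, so the shrinkage property is stated and tested
norm-wise.

## Differential expression

The DE measure per gene and time is the weighted difference of normalized
solutions, double-weighting the high sub-lines (the selection signal is
concentrated there): `(2·RH + RL)/3 − (2·SH + SL)/3` at T0 and T1, and the
plain `RH2 − SH2` at T2, where no low sub-line samples exist. Measures are
standardized by the empirical mean and SD over genes, by default within
each time point (a pooled flag standardizes across the three measures
jointly); |z| > 2.58 — the two-sided normal critical value at P = 0.01,
rounded to two decimals — is called significant. Fold changes are reported
as `2^de` with the negative-reciprocal convention for negative measures.

Chance-call accounting: with `n` tests at level `alpha`, the expected
number of chance calls is `round(n·alpha)`, and the false-positive rate
among the `n_de` calls actually made at a time point is
`100·expected/n_de` percent, rounded and capped at 100. These are upper
bounds — genes co-express, so the effective number of independent tests is
smaller than the gene count.

## Enrichment

Over-representation of a flat gene→term annotation in the DE set against
the fixed background of analysed genes, by the upper-tail hypergeometric
probability `P[X ≥ k]` with `X ~ Hypergeom(N, K, n)`. No ontology-graph
propagation and no ranked-list statistic: with a fixed DE list and a fixed
background the problem reduces to the one-sided Fisher/hypergeometric
test. Raw p-values at alpha = 0.01 are the primary output; a
Benjamini–Hochberg column is emitted alongside.

## Fleece-rot phenotypes and the animal model

An animal's fleece-rot score is the maximum of its four site scores (back
of neck, wither, loin, rump), each 0–5. Three traits are analysed: the
pre-wetting score, the post-wetting score, and their change, defined as
post − pre by default (a flag gives the opposite sign convention; the
change trait is the one most directly expressing induced susceptibility).
Scores are treated as numeric, consistent with interpreting the
allelic-substitution effect in score units.

The mixed animal model has fixed flock, sex, birth type and rear type
(factors with a single level are dropped automatically), a centred
date-of-birth covariate, and a polygenic animal effect with covariance
`σ²_a A`. `A` is built by the tabular method; `A⁻¹` directly by
Henderson's rules with inbreeding-aware Mendelian-sampling variances
(Quaas), so `A·A⁻¹ = I` exactly even for inbred pedigrees — random-mating
simulated pedigrees are inbred, and the simplified rules would silently
violate the identity there. The simplified rules remain available as an
option. Parents referenced but never listed are treated as founders;
cycles raise an error naming an animal involved.

REML again uses EM with AI acceleration, made cheap by absorbing the fixed
effects and taking one generalized eigendecomposition of `(Z'SZ, A⁻¹)` per
fit: every iteration is then O(n) for the traces and O(n²) for solutions,
so a 1,000-animal fit converges in about ten iterations in well under a
second, and the result is exact REML (verified against the dense criterion
in the tests). A variance heading for zero (e.g. σ²_a for the change
trait, whose polygenic part cancels) is detected by a flat restricted
likelihood over three consecutive iterations and reported as a boundary
estimate rather than thrashing against the floor; a boundary estimate
whose gradient points back into the interior is unpinned before
convergence is accepted. Only if REML genuinely fails within 500
iterations does the fit fall back to a user-supplied h² (default 0.3) with
a loud warning.

Wald chi-square tests of each fixed factor are reported; optional
screening drops factors non-significant at 0.05 and refits, but the
default keeps all factors (conservative and order-independent).

The *residual fleece-rot score* is `y − Xb̂ − Zû` — observed score minus
the model's correction — and may fall outside 0–5.

## SNP quality control and association

Per SNP and population: the minor-allele frequency from non-missing calls
(monomorphic SNPs get MAF 0, a flag, and no association estimate); the
exact conditional Hardy–Weinberg test — enumerate every heterozygote count
compatible with the observed allele counts, compute each configuration's
probability under random union of gametes, and sum the probabilities of
configurations no more probable than the observed one (the plain sum, not
the mid-p variant, which is available behind a flag); and ordinary least
squares of the residual score on minor-allele dosage with an intercept.
The slope is β (score units per allele copy), its two-sided p-value uses
the t distribution with n − 2 degrees of freedom, and
`R² = 100·(model SS)/(total SS)`. Missing genotypes are deleted pairwise
per SNP; no imputation. Which physical allele was counted in the original
assays is unrecoverable, so signs are relative to the minor allele —
recoding flips β and leaves p and R² unchanged (tested). Reporting flags
tests at P < 0.05 per test, with a Benjamini–Hochberg column alongside.

## Synthetic data

The intensity simulator draws directly from the normalization model's
generative law. The default layout mirrors the study design: a circular
alternate dye-swap loop over the ten sub-line x time samples — each RNA
sample labelled once with each dye, appearing on exactly two arrays — with
three biological replicates (two Trangie Merino, one CSIRO crossbred
flock), giving 30 arrays; genes are assigned to printing blocks
round-robin, fixed across slides as printed arrays are. Default components
(log2 scale) are σ²_G = 4.0 (gene abundance dominates, as in real
arrays), σ²_AG = 0.3, σ²_DG = 0.1, σ²_FG = 0.1, σ²_TG = 0.2, σ²_e = 0.25,
with mu = 8.2 and comparison-group offsets of SD 0.5 — intensities
averaging ~8 with SD ~2 on the log2 scale, matching the magnitudes typical
of background-corrected two-colour scans. Planted DE is an additive log2
shift per gene and treatment, returned in the ground truth.

The population simulator builds discrete generations from a founder cohort
(random sire per dam, a configurable number of offspring per mating),
breeding values by the mid-parent plus Mendelian-sampling rule, genotypes
at exact Hardy–Weinberg proportions, and a latent liability on the score
scale: fixed effects + Σ dosage·β + polygenic value + residual, with
var(polygenic)/(var(polygenic)+var(residual)) = h². Pre- and post-wetting
liabilities share the genetic and SNP effects (means 1.5 and 3.0 — wetting
induces rot) and have independent residuals; each of four sites adds
N(0, 0.25²) site noise before clamping and rounding to 0–5, and the trait
is the max over sites.

What this emulates and what it does not: the generators reproduce the
*statistical structure* the estimators assume (crossed random effects, the
loop topology, pedigree covariance, HWE, additive dosage effects), so
recovery tests validate the estimation machinery. They do not emulate
probe-level image artefacts, spatial trends, ordinal-scale distributional
quirks of real scores, genotyping error, or selection in the pedigree —
passing tests say nothing about robustness to those.

Two consequences of the score discretisation are worth naming. First,
clamping, rounding and the max-over-sites step attenuate observed-scale
heritability below the latent-scale parameter; recovery tests therefore
assert the mean estimate over seeds within ±0.1 of the latent value.
Second, the polygenic BLUP absorbs part of a planted SNP effect (relatives
share dosages), so residual-score regression under-estimates β in heritable
populations; the β-recovery experiment uses an h² = 0 population, where
the estimator's target equals the planted value. Both behaviours are
properties of the residual-score design itself, not implementation
artefacts.

A single global seed expands through a seed sequence into independent
child seeds per stage, so any stage is reproducible in isolation; all
derived seeds stay below 2³¹.

## Problem sizes in the tests

The test-suite experiments run at desk scale, chosen so the whole suite
finishes in well under a minute of REML work: variance-component recovery
at 200 genes on a single 8-array loop over 20 seeds, heritability recovery
at ~1,000 animals over 20 seeds, exact-test calibration over 10,000
simulated SNPs at n = 100, the null-association rate over 50 replicates of
16 SNPs x 3 traits on ~250-animal populations, and dense-oracle
equivalence on instances of at most a few hundred observations, where the
dense covariance algebra is exact and fast.

## Known limitations

* Single-trait animal model only; no maternal effects, no genomic
  relationship matrices, no multi-trait covariances.
* Gaussian likelihood for an ordinal 0–5 score; a threshold model is out
  of scope, matching the additive interpretation of β.
* The normalization model assumes homogeneous residual variance across
  genes.
* The enrichment test takes annotations as flat pairs; no GO-DAG
  propagation.
* The chance-call false-positive rates assume independent tests and are
  upper bounds under co-expression.
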