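# Methods

## Design and assumptions

The sampling unit is a case-parent triad at a di-allelic X SNP outside
the pseudo-autosomal and X-transposed regions, so fathers are
hemizygous.  Copy counts are `M ∈ {0,1,2}` (mother), `F ∈ {0,1}`
(father), `C ∈ {0,1}` for affected sons and `{0,1,2}` for affected
daughters; a son's X is maternal, a daughter carries the paternal X plus
one maternal X.  That leaves 8 Mendelian-admissible `(M,F,C)` cells per
offspring sex; `validate_mendelian` classifies records (including
partial ones, checked only on observed members) against this table.

Two assumptions underpin the tests:

1. **Mendelian transmission** at the locus, and no effect of the variant
   on fetal survival or fertility.
2. **Parental allelic exchangeability** (for the parent-informed parts
   only): conditional on the mating sum `S = M + F`, the variant alleles
   are placed at random across the parents' three X chromosomes, i.e.
   Pr(mother carries the single variant | S=1) = 2/3 and
   Pr(M=1,F=1 | S=2) = 2/3.  This holds under random mating within
   (possibly unknown) subpopulations and is far weaker than HWE.  It is
   testable: `exchangeability_test` sums the two binomial LRTs against
   2/3 (2 df; df degrades with empty strata and is reported).

## The likelihoods

All tests are conditional multinomial likelihoods over the admissible
cells, parameterized by genotype relative risks `R_B` (carrier sons),
`R_G1`, `R_G2` (het/hom daughters):

* **SSX-LRT** conditions on `(M, F, sex)`.  Only heterozygous-mother
  strata are informative; for sons the likelihood is a binomial in the
  transmission odds `R_B : 1`, and under the girls-log-additive
  constraint (`R_G2 = R_G1²`) both daughter strata pool into a single
  binomial with odds `R_G1 : 1`.
* **Parent-only LRT** conditions on `(M+F, sex)` and discards `C`: the
  exchangeability prior over `(M, F)` given the sum is tilted by the
  average offspring risk of each configuration.
* **PIX-LRT** conditions on `(M+F, sex)` and keeps the full triad: its
  cell probabilities are the product of the exchangeability prior, the
  Mendelian transmission probability and the risk factor, normalized
  within each mating-sum stratum.  Strata `S ∈ {0, 3}` are
  deterministic; informative families are those with `S ∈ {1, 2}`, which
  strictly contains the heterozygous-mother families.

The stratum nuisance masses (`γ_{M,F,sex}` or `μ_{S,sex}`) are free per
stratum, which is what confers robustness to population stratification:
on admixed null expected counts all three statistics are identically
zero.  With complete data the nuisance estimates coincide under null and
alternative and cancel from the LRT, so only the conditional factors are
maximized.

**Combined statistic.**  Per-sex 1-df statistics with direction signs
combine as `Z = (S_B√(N_B X_B) + S_G√(N_G X_G)) / √(N_B+N_G)`, where `N`
is the method's informative-family count (heterozygous mothers for SSX,
mating-sum-1-or-2 families for PIX).  The squared weights sum to one, so
Z is standard normal under the null; `Z²` is referred to chi-squared(1).
The sign is +1 at a numerically zero statistic (the signed root is zero
there anyway).  Combination requires 1-df inputs: for codominant girls
(2 df) no direction is defined, so `combine_z` rejects such inputs.

**Constraint modes.**  Girls may be fitted codominant (2 parameters) or
log-additive (`R_G2 = R_G1²`, 1 parameter; the default for combined
scans).  `fit_joint_model` additionally offers cross-sex constraints:
an X-inactivation alternative (`R_G2 = R_B`, 2-df test), a joint
log-additive alternative (`R_G1² = R_G2 = R_B`, 1-df test), and a 1-df
test of the X-inactivation constraint itself against the codominant
model.

## Numerical choices

All maximum-likelihood fits in the exact tests are numeric, on the
log-relative-risk scale, bounded to `R ∈ [1e-6, 1e6]`: 1-parameter fits
use bounded scalar minimization (absolute tolerance 1e-12 on log R),
2–3-parameter fits use Nelder–Mead from the null.  The test suite
verifies the maximizers against brute-force log-spaced grid searches.
Zero cells follow `0·log 0 = 0`; estimates that hit the bound are
reported with a `boundary` flag.  LRTs are clipped at zero.  P-values
are chi-squared upper tails (two-sided via `z²` for combined scores,
matching Bonferroni usage); exchangeability strata with fewer than 10
families are flagged because the asymptotics get crude there.

## EM for missing members

Families with at least one genotyped member contribute through the
observed-data likelihood, summing each family over its
Mendelian-consistent completions weighted by stratum mass × conditional
cell probability.  The E-step distributes fractional counts; the M-step
re-maximizes the risk parameters (shared) and stratum masses (free, and
per subpopulation label under `strata_mode="by_stratum"`).  Missingness
is assumed MAR given subpopulation and offspring sex, so missingness
probabilities cancel and are not estimated.  Defaults: relative
log-likelihood tolerance 1e-8, at most 500 iterations (the parameter
space is tiny; convergence is typically < 50 iterations), initialization
at `R = 1` with stratum masses from add-one-smoothed proportions of
families whose stratum is determined by their observed members (the
smoothing keeps every stratum reachable by completions).  Null and full
fits share the E-step machinery, differing only in whether the risk
parameters move, so the LRT is internally consistent; on complete data
it reproduces the exact statistics to numerical precision.

With informative missingness — subpopulations differing in both allele
frequency and missingness rate — the pooled EM is biased; fitting
stratum masses per subpopulation removes the bias (checked directionally
on expected counts in the tests).  `count_informative` defines the
combined-score weights under missingness: PIX counts a family unless its
observed members force `M+F ∈ {0,3}`; SSX counts only *observed*
heterozygous mothers (a configurable, documented convention — partially
observed families that merely might have a heterozygous mother are not
counted).

## Expected counts, NCPs, power

`PopulationScenario` mixes HWE subpopulations (weight, MAF, sex-specific
baseline risks) with a relative-risk model and an ascertained family
count.  Expected counts multiply genotype probabilities, Mendelian
transmission, and affection probability, then normalize to the design:
single-sex designs scale to `n_families`; `both_proportional` assumes a
1:1 sex ratio at birth and splits the total proportionally to each
sex's marginal affection probability.  A test's non-centrality parameter
is its statistic evaluated on these expected counts; power is the
noncentral chi-squared upper tail beyond the central critical value (at
alpha = 0.05 the same mapping gives the actual Type-I error of a
miscalibrated test).  The combined-score NCP uses `√NCP_sex` as the
expected signed root — the standard plug-in approximation, documented as
approximate.  Missingness NCPs distribute expected complete counts over
observation patterns (complete / mother-missing / father-missing; at
most one parent missing by design, mixed settings fix the
father:mother missing ratio at 2:1) and evaluate the EM likelihood ratio
on the expected pattern counts.

## Comparators

The **XTDT** is the McNemar statistic `(b−c)²/(b+c)` on
heterozygous-mother transmissions (a daughter's paternal allele is
obligatory and excluded).  It is the score test of the SSX model; across
the power grid the two NCPs agree to within 5%, the gap growing with
effect size (at `R = 2` it is 1.9%).

The **X-LRT** is reconstructed as a Poisson log-linear model on all 16
cells with six mating-type parameters *shared* across offspring sexes, a
single sex offset, and sex-specific risk terms, fitted with statsmodels
GLM (deviance differences give the LRTs; 3/1/2 df for the overall,
male-only and female-only nulls under codominant girls).  Sharing the
mating-type parameters is exactly what makes the model sensitive to
admixture in which subpopulations differ in allele frequency and in the
male:female ratio of baseline risk — its null NCPs are positive on such
expected counts while the sex-stratified tests stay at zero.  The same
sharing also means its male-null test uses cross-sex parental contrasts
and is *not* equivalent to the boys' SSX statistic even when correctly
specified.

One admixture scenario used in the reference computations is stated in
prose ambiguously in the source material; the baseline-risk assignment
adopted here (subpopulation 1: male 0.02 / female 0.03; subpopulation 2:
male 0.03 / female 0.02) is the unique one, up to relabeling, consistent
with all three of that scenario's reference null NCPs.  Likewise the
daughter design with `R_G2 = 2` is read as log-additive with
`R_G1 = √2`, the only reading consistent with its reference value and
with son triads being the more powerful design there.

## Simulator

`sample_triads` mirrors the ascertainment directly: draw a
subpopulation, parental genotypes under HWE, offspring sex and
Mendelian transmission, and accept the family with probability equal to
the child's disease risk until the design count is reached — so the
conditional law of accepted triads equals the expected-count
distribution exactly (verified by goodness of fit).  A single integer
seed drives a `SeedSequence` with per-marker spawned streams, making
replicate markers independent and output byte-reproducible.
`apply_missingness` partitions one uniform draw per family, enforcing
the at-most-one-missing-parent constraint by construction; children are
never masked.

What the simulator does *not* emulate: linkage disequilibrium between
markers, genotyping error, sibship structure beyond one affected child,
assortative mating (exchangeability violations), or
genotype-dependent missingness (only stratum-differential missingness,
used in the bias checks, is provided).  Passing tests therefore speak to
the statistical machinery under the stated model, not to data-quality
pathologies — which is why the scan flags, rather than drops,
exchangeability violations (default flag threshold p < 1e-4) and
reports Mendelian-inconsistency counts per SNP.

## Scan

`run_scan` filters on parent-based MAF (mothers count two chromosomes,
fathers one; copy counts are re-oriented to the parent-based minor
allele at read time, ties broken lexicographically by allele name) and
on user-supplied excluded coordinate intervals (no PAR/XTR coordinates
are bundled — they are build-specific), then runs the per-sex tests
(exact on complete triads, or EM including partial ones), combines the
sexes, and reports the Bonferroni threshold computed from the number of
SNPs actually tested.  Subpopulation labels are family-level; families
whose parents belong to different groups are assumed resolved upstream
when labels are assigned.  Duplicate family ids within a SNP keep the
first record by file order, or a seeded random choice on request.

## Problem sizes in the checks

The stochastic checks run at: 1000 replicate markers of 150 families
for null calibration of the complete-data tests, 400 for the EM under
20% missing parents; 200 replicates of 500 son triads with 30% missing
fathers for EM risk recovery; 300 replicates for the
independence-of-components correlation check; 50 random tables per
method for the grid-search oracle.  All deterministic reference
quantities (NCPs, informative-family masses, power mappings) are exact
computations on expected counts and are asserted to two printed
decimals.

## Known limitations

* No maternal-genotype effects; a maternally acting variant can bias
  the parental component of the PIX-LRT.
* Exchangeability violations (assortative mating, genotyping artifacts,
  survival effects) bias the parent-informed parts; the transmission
  SSX-LRT is the fallback, and the exchangeability test is run per SNP.
* Only triads (one affected child, both parents); no extended pedigrees,
  unaffected siblings, VCF input, or haplotype/multi-SNP models.
* Families with no genotyped member are rejected rather than carried.
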