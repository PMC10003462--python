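# Methods

This note documents the statistical procedures, the modeling choices made
where the design was genuinely open, the synthetic-data generator's scope,
and the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are unordered biallelic allele pairs per (sample, SNP); phenotype
is binary (1 = case). Two text dialects are read and written: PLINK
.ped/.map (phenotype 1 = control / 2 = case by default, `pheno_01` for 0/1
coding; allele code "0" = missing; a half-missing call is treated as fully
missing) and a TSV matrix (header of SNP ids, cells like "AG" or "NA").
SNP identity is the marker-id string; positions are 1-based. Strand is
assumed consistent within a dataset; no flipping is attempted.

Dosage space uses NaN as the missing sentinel — never -1 or 3 — so
accidental arithmetic on missing entries propagates visibly instead of
producing silently wrong sums.

## Association statistics

* **Risk-allele orientation.** Per SNP, the risk allele is the allele with
  the higher frequency in cases than in controls; exact ties go to
  `allele_b`. All genotype triples are then reported as (NN, NR, RR) and
  every allelic OR is ≥ 1 up to ties.
* **Fisher's exact test (allelic).** The 2x2 table is risk/non-risk allele
  counts by case/control. The two-sided p sums the conditional
  hypergeometric probabilities of every table with the observed margins
  whose point probability does not exceed the observed one (the minimum-
  likelihood convention, not the "central" doubling convention). Tables
  with total ≤ 500 use exact integer arithmetic so tie comparisons are
  exact; larger tables use the scipy routine (same convention, float
  weights). The allelic model was adopted because it reproduces the
  published ORs and CIs from the published genotype counts exactly.
* **Odds ratio and CI.** Sample (cross-product) OR from the allele counts
  with Woolf's log-normal 95% CI, z = 1.96. A zero cell triggers the
  Haldane-Anscombe +0.5 correction on all four cells for OR/CI (the Fisher
  p is still computed on the uncorrected integer table) and flags the
  result.
* **Hardy-Weinberg exact test.** Conditional on the observed allele counts,
  the probability of each attainable heterozygote count follows the
  standard ratio recurrence; the two-sided p sums configurations no more
  probable than the observed one. Monomorphic markers (one attainable
  configuration) return 1.0. The QC default tests controls only — the
  published per-SNP HWE column is consistent with control-only testing —
  and a `hwe_group="all"` switch covers the pooled variant.
* **Quality control.** SNP filters first (call rate ≥ 0.95, MAF > 0.01,
  HWE p > 0.01), then sample call-rate filtering (≥ 0.95) on the retained
  SNPs. Every exclusion is reported with its reason, value and threshold.
* **LD r².** Two-locus haplotype frequencies are estimated from unphased
  genotypes by EM (phase is ambiguous only for double heterozygotes;
  convergence at max frequency change < 1e-8 or 1000 iterations), then
  r² = D²/(p_A p_a p_B p_b). Controls only by default. Monomorphic SNPs
  yield r² = 0 with a flag.
* **Pruning and subsets.** Greedy pruning visits SNPs by ascending Fisher p
  (ties by snp_id) and keeps a SNP iff r² ≤ 0.8 with everything already
  kept — strictly greater values are excluded, so a pair at exactly 0.80 is
  retained, and the lower-p member of a tight pair survives. Pruning runs
  once over all SNPs; the p < 0.01 / 0.05 / 0.1 subsets filter the pruned
  list (hence are nested). The "all" subset is neither pruned nor
  thresholded.

## Missing-genotype imputation

The source pipeline imputed missing calls "considering the calculated LD"
without specifying the algorithm. The rule implemented here is a
deterministic stand-in that uses the computed r² directly: a missing value
at SNP *s* in sample *i* becomes the modal genotype of *s* among samples
that share sample *i*'s genotype at *s*'s highest-r² partner (partner
r² ≥ 0.3, a cutoff chosen to avoid conditioning on noise); if no partner
qualifies or the stratum is empty, the overall mode of *s*; ties break
toward the smaller dosage. Observed entries are never altered. On simulated
LD-structured data with masked entries, the conditional mode is at least as
accurate as the unconditional mode (asserted in the tests).

## Polygenic risk score

PRS_j = Σ_i logOR_i x_ij with natural-log allelic ORs as weights. Weights
are re-estimated on the training samples only by default (a leakage guard;
whole-sample estimation is available by passing no training ids, mimicking
the likely original behavior). SNPs monomorphic in training get weight 0
with a warning. Scores require a fully imputed matrix — there is no
per-sample renormalization by non-missing count. A one-feature logistic
regression (near-unpenalized, C = 1e6) maps score to case probability.

## Data splits

For N total samples, a class-balanced train+validation pool of
round(N·200/262) samples (floor-halved per class) is drawn; 10% per class
is held out for validation; the remainder is the test set. At the study's
262 samples (143 cases / 119 controls) this yields exactly 180 train / 20
validation / 62 test with 43 cases and 19 controls in the test set. Splits
are seeded and reproducible. Whether the original validation 20 were
class-balanced is unknown; stratified draws were chosen.

## The network

Two dense hidden layers, each ReLU-activated, at equal width — the width
rule maps input sizes 3/10/16/92 to widths 8/16/32/64; unlisted sizes take
the nearest listed size's width, ties toward the larger. ("Two dense layers
followed by a ReLU" admits other readings; the equal-width two-hidden-layer
interpretation is frozen by a parameter-count assertion: 3 inputs at width
8 give exactly 8·4 + 8·9 + 9 = 113 trainable parameters.) A single sigmoid
output unit; binary cross-entropy loss; Adam with initial step size 5e-3
and the classic per-update decay lr_t = lr0/(1 + 1e-5·t); 100 epochs;
batch size 32 (unstated in the source; the conventional default, and
configurable). After each epoch the validation loss is evaluated; the
restored checkpoint minimizes validation loss, with ties broken toward
higher training accuracy and then the earlier epoch. Training is pure
NumPy float64 with a single seeded generator for initialization and batch
shuffling, so a (seed, data) pair is bit-reproducible. A non-finite loss
aborts with the epoch and step size in the message.

Baselines: SVM (RBF, Platt probabilities), random forest, XGBoost,
logistic regression, LightGBM, AdaBoost — all at their library defaults,
seeded. No tuning is attempted (the source reports none).

## GA subset search and ensemble

A chromosome is a fixed-size k-subset of the QC-passed SNP pool; every
operator preserves |subset| = k. Fitness = training BCE + validation BCE of
the network trained on the subset's dosage columns at the restored
checkpoint (lower is better), memoized per subset; one fixed network seed
per GA run so fitness differences reflect subsets, not initialization
noise. A failed training maps to fitness +inf.

Defaults: population 30, cycles 30 (the published budget); tournament size
2, crossover rate 0.9, per-gene replacement mutation 0.05, elitism 1 — the
genetic operators themselves are unstated in the source, so common fixed-
size-subset GA practice is used, all configurable. Crossover keeps the
parents' shared SNPs and fills to size k uniformly from their symmetric
difference; mutation replaces a gene with a uniform draw from the unused
pool. One population member is seeded with the association top-k; the rest
are uniform random k-subsets. Duplicates are allowed (memoization makes
them cheap). Best-ever fitness is non-increasing by elitism.

"Five sets from GA" is read as five independent GA runs (seed offsets
0..4), one best-ever subset each, rather than the top 5 of a single final
population — independent runs give the ensemble the subset diversity the
method reports. The association top-k subset is always member six. One
network is trained per member subset; the ensemble prediction is the
unweighted mean of the six case probabilities, classified at ≥ 0.5. By
Jensen's inequality the ensemble's Brier score never exceeds the mean of
the members' Brier scores (asserted numerically on every harness run).

## Evaluation

Accuracy thresholds probabilities at 0.5 with ties classified as case (the
source states no threshold). Weighted F1 weights per-class F1 by true-class
support. AUC is the rank statistic with ties counted 0.5 (equivalent to
all-pairs enumeration, asserted against it). The repeated-run protocol
executes a seedable pipeline n times (100 by convention) with consecutive
seeds, reports per-metric means with empirical 2.5th/97.5th percentile
intervals (percentile rather than normal intervals, because the published
intervals are asymmetric about their means), flags the best iteration by
test AUC, and tallies — but excludes — crashed runs.

## Synthetic data generator

The generator emulates the statistical structure of the study panel, not
its biology:

* **Retrospective parameterization.** Controls are HWE draws at the
  specified control risk-allele frequency p; cases are HWE draws at
  p_case = OR·p / (1 + p·(OR − 1)), the case frequency implied by an
  allelic OR under retrospective (case-control) sampling. This is a
  simplification: under a multiplicative risk model true case genotypes
  deviate slightly from HWE. Realized ORs converge to the target as n
  grows (within 5% relative error at n = 10⁴, asserted).
* **LD blocks** are realized by latent-haplotype copying: within a block
  each chromosome copies a shared latent allele with probability 1 − s,
  else redraws from the marginal frequency. Two sites sharing the latent
  draw correlate with r = (1 − s)², so s = 1 − (r²)^¼ hits a target r².
  This construction requires equal allele frequencies within a block, so
  block members inherit the anchor SNP's control RAF and OR; targets
  outside [0, 1] raise with the feasible range. There is no recombination
  map and no inter-block LD.
* **Defaults** mirror the study conditions: 92 SNPs, 143 cases / 119
  controls, control RAFs spanning ~5-95% (the observed panel spans 4-94%),
  causal ORs 1.5-2.3, tight blocks at r² 0.80 and 0.98, 2% missingness.
  The recovery benchmark plants 5 causal SNPs (OR 3.0, control RAF 0.3)
  among 92 at 500+500 samples with no LD or missingness.
* **Not modeled:** population structure, relatedness, genotyping error,
  sex chromosomes, covariates. Passing tests on this generator show the
  pipeline recovers planted signal under clean assumptions; they do not
  certify performance on real genotypes.

## Problem sizes in the test suite

The stochastic acceptance harness runs twenty seeded reduced-budget
ensemble runs (population 10, cycles 10, 50 training epochs, k = 10) on
the recovery benchmark; each seed simulates its own dataset and drives the
split, the GA and the network initializations. The GA-versus-random-search
property uses 20 seeds at 300+300 samples, population 8, cycles 8, 25
epochs, with random search granted the same number of network trainings.
The published real-data performance table is not reproduced: the study
genotypes are available only on request, so those numbers are replaced by
the property suite above.

## Known limitations

* The conditional-mode imputation is a documented stand-in; the original
  pipeline's imputation algorithm is unspecified.
* Fitness (train + validation loss) can favor subsets that allow training-
  set memorization when the validation set is very small; this is a
  property of the method, visible in the tests at toy scale.
* One published CI cell (rs2284791 upper bound) prints 2.11 where the
  stated formula on the printed counts gives 2.1049; tests therefore
  accept CI bounds within one unit of the last printed digit.
* Genotypic/dominant/recessive association models, covariate adjustment,
  epistasis scans, shrinkage PRS estimators, and GO/PPI enrichment are out
  of scope.
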