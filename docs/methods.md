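# Methods

## The classification model

`ethnopred` infers a subject's population of origin from a panel of SNP
genotypes using an ensemble of **disjoint** CART-style decision trees.  The
training loop is:

1. learn a classification tree on the current candidate SNP pool;
2. remove the SNPs that tree uses from the pool;
3. repeat until the requested number of trees N is reached.

Because no SNP appears in two trees, a failed genotype measurement (NoCall)
silences only the trees that consult it.  At prediction time each tree either
votes for a class — when **all** of its SNPs are called for the subject — or
abstains.  The vote vector over the T' voting trees yields a population
inclusion probability vector `votes_c / T'` (e.g. votes 15/4/8 with 2
abstentions among 29 trees give (15/27, 4/27, 8/27)); the reported label is
the argmax, and a subject on which every tree abstains receives `NO_CALL`.
No imputation is ever performed.

Abstention is deliberately whole-tree rather than path-only: a tree whose
off-path SNP is missing might have routed the subject differently had the
value been observed, so the conservative reading is to withhold the vote.  A
`path_only` mode exists for comparison and is off by default.

### Trees

Trees are binary CART over the 3-level genotype factor.  Candidate splits at
a node are the three bipartitions of {A_A, A_B, B_B} that isolate one
genotype ({A_A} vs rest = dominant, {A_B} vs rest = heterozygote-specific,
{B_B} vs rest = recessive), per candidate SNP.  The split maximizing the
weighted Gini impurity decrease is chosen; ties are broken deterministically
(earliest SNP in matrix column order, then the bipartition listing order
above).  An impure node is allowed to split on a zero-gain candidate: a
greedy learner restricted to strictly positive gains cannot descend through
parity-structured (XOR-like) interactions whose first split is gain-neutral,
and growth still terminates because both children are strictly smaller.
Pure nodes, nodes smaller than twice `min_leaf_size` (default 5), and nodes
with no valid bipartition become leaves.  Leaf labels are the majority class,
ties toward the earlier class in the fixed class order.

Pruning follows classical cost-complexity pruning with the 1-SE rule: the
weakest-link critical-alpha path is computed on the full tree, candidate
alphas are the geometric means of consecutive critical values, each is scored
by an internal stratified cross-validation (default 10-fold, seeded), and the
largest alpha within one standard error of the minimum CV error is applied.
`prune="none"` is available for small exact constructions.

### Genotype semantics

"Major"/"minor" allele designations are dataset-relative, so trained models
store each SNP's (major, minor) allele *characters*.  When a model is applied
to a new dataset, each SNP's alleles are matched as an unordered pair; if the
new dataset designates the alleles in the opposite order, the homozygote
codes are flipped before traversal, and a character mismatch is an error.
This prevents silent code inversion in cross-dataset prediction.

## Pre-processing

A SNP is excluded when (a) its call rate is below 100%, (b) it lies on X, Y,
MT or an unknown chromosome, or (c) its genotype counts deviate from
Hardy–Weinberg proportions by Pearson's chi-squared test (1 df, no
continuity correction) at nominal p < 0.05.  Criteria are flagged
independently and the union removed, and the filter report gives both.

HWE is tested **within each labeled population** by default and a SNP is
flagged if it deviates in any population.  On stratified data a pooled test
exhibits the Wahlund effect — a heterozygote deficit proportional to the
between-population allele-frequency variance — and would preferentially
discard exactly the ancestry-informative SNPs the classifier needs; pooled
testing is therefore only available as an explicit option.  Monomorphic SNPs
fit HWE trivially (chi2 = 0, p = 1) and are never HWE-flagged; they carry no
information and the tree learner ignores them as zero-variance features.

## Robustness sizing

Let `u` be the per-SNP NoCall probability (assumed independent across SNPs;
the default working value is u = 0.1, a conservative array-platform rate)
and `n` the average SNPs per tree.  Then each tree is fully observed with
probability `p = (1-u)^n`.  Given out-of-fold per-tree predictions from
cross-validation, the minimal sub-ensemble size `m` is the smallest s whose
average majority-vote accuracy over size-s tree subsets reaches the accuracy
target (subsets enumerated exhaustively when `choose(T, s) <= 1e5`, else
sampled with a seeded generator, 1e5 draws by default).  The probability of
retaining at least m clean trees among N is the exact binomial upper tail

    C(N, m, p) = 100 * (1 - sum_{i=0}^{m-1} choose(N, i) p^i (1-p)^(N-i)),

and the recommended ensemble size is the smallest N with C >= the confidence
target.  The summation necessarily starts at i = 0: an ensemble with zero
clean trees has failed just as surely as one with fewer than m.  With the
reference constants p = 0.59049 and m = 9 the column runs 0.873% (N = 9),
4.09% (N = 10), 58.013% (N = 15), 99.892% (N = 28), 99.94% (N = 29), making
N = 29 the smallest size meeting a 99.9% target.  (Note 0.59049 = 0.9^5
exactly; with a fractional n = 5.13 the same chain gives p ≈ 0.5825 and the
identical search structure — the replay API accepts an explicit `p` for
reproducing fixed constants.)

The subset-accuracy search pools out-of-fold predictions across all samples
(the per-tree prediction table is its input; fold structure is not needed at
that point), whereas the cross-validation report itself aggregates per fold
and then unweighted across folds.

## Evaluation

`kfold_cv` uses stratified seeded folds (per-fold class proportions within
one sample of global).  Per fold, a fresh disjoint ensemble is trained on the
remaining folds; the held-out fold is scored per tree and for cumulative
majority votes over the first j trees.  Accuracies are mean ± sd (ddof = 1)
over the k fold values.  An ensemble `NO_CALL` on a held-out sample counts
as incorrect — the conservative convention.

The genomic-control inflation factor is `lambda = median(chi2) / 0.4549364`,
the denominator being the median of the chi-squared distribution with 1 df.
The per-SNP statistic is the Cochran–Armitage trend test with scores
(0, 1, 2) — the GWAS standard 1-df choice — computed as the score test
`N * r^2`; an allelic 2x2 Pearson test is available as an option.  NoCalls
are excluded per SNP.  The stratification-correction experiment reports
lambda on the full cohort and again on the subset retained by a
classifier-based inclusion cutoff.

## Synthetic data

The generator implements the Balding–Nichols model: ancestral minor-allele
frequency `pi ~ Uniform(0.1, 0.9)` per SNP, population frequency
`~ Beta(pi(1-F)/F, (1-pi)(1-F)/F)` (mean pi, divergence governed by F, the
model's F_ST; F = 0 degenerates to no divergence), genotypes as minor-allele
dosage `Binomial(2, freq)`, NoCalls masked independently at rate u.  Default
conditions are three populations of 200 samples at F = 0.15 over 1000
autosomal SNPs — divergence of continental scale and a sample size typical of
reference panels.  `simulate_from_truth` redraws cohorts from the same
per-population frequencies so train and test cohorts share populations, and
the case–control variant assigns phenotypes purely by population-specific
prevalence, so any association signal downstream is stratification by
construction.

What the generator does **not** emulate: linkage disequilibrium (sites are
independent), admixed individuals, correlated or batch-structured
missingness, genotyping error beyond NoCall, and realistic allele-frequency
spectra.  Passing tests on this data demonstrate the machinery —
disjointness, abstention arithmetic, filter behaviour, sizing mathematics,
stratification correction — not performance on real panels, where LD and
admixture make per-SNP information redundant and class boundaries soft.

## Numerical and design choices

- Binomial tails use `scipy.stats.binom.sf` (exact summation, no normal
  approximation).
- The null chi-squared median is fixed at 0.4549364.
- Gain comparisons use an absolute tolerance of 1e-12 for tie detection.
- Vote ties set a `tie` flag and resolve to the earliest class in
  `class_order`; the same rule applies to leaf labels and cumulative-vote
  scoring, so every tie-break in the package is the one deterministic rule.
- Single-class training input yields a single-leaf tree with a warning, so
  CV folds that lose a rare class entirely still run.
- `train_ensemble` raises (reporting the completed count) when a learned
  tree uses no SNPs — the pool is exhausted of informative features.
- Model files are JSON with a `format_version` field; all payload values are
  integers and strings, so the save/load round trip is bit-exact.
- The CLI derives per-stage seeds as SHA-256(`"{seed}:{stage}"`) mod 2^31,
  so a single seed reproduces any stage independently.

## Test-scale choices

The test suite exercises the full pipeline at desk scale: 3 populations x
200 samples x 1000 SNPs for parameter recovery, 2 x 200 x 2000 for the
stratification demonstration, 1e4 SNPs for null-lambda calibration, and 1e6
Monte-Carlo draws for the binomial-tail cross-check.  These sizes make the
statistical assertions sharp (binomial standard errors well below the
asserted margins) while the whole suite runs in well under a minute of
compute plus the heavier end-to-end cases.

## Known limitations

- No surrogate splits or imputation: heavy missingness concentrated on a few
  trees' SNPs degrades gracefully (abstention), but missingness above ~30%
  per SNP leaves few voting trees unless N is sized accordingly.
- The greedy learner with zero-gain splitting can grow bushy trees on pure
  noise; cost-complexity pruning is the counterweight and is on by default.
- Sub-ensemble accuracy search is exponential in the exhaustive regime by
  design; the enumeration cap and seeded sampling bound the work.
- VCF support is read-only and biallelic-SNP-only; multi-allelic records and
  half-calls become NoCall with a warning.
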