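# ethnopred

Ancestry classification from SNP genotypes with ensembles of **disjoint**
decision trees, for geneticists who need a cheap, interpretable ancestry
covariate — typically to detect and correct population stratification in
case–control association studies.

## The method

Genome-wide association studies are confounded when cases and controls are
drawn unevenly from populations with different allele frequencies.  A
standard diagnostic is the genomic-control inflation factor

    lambda = median(chi2_1) / 0.4549,

the median per-SNP 1-df association statistic over its theoretical null
median; lambda ≈ 1 indicates no stratification.

`ethnopred` learns a small SNP panel that classifies ancestry directly.
After quality filtering (call rate < 100%, non-autosomal location, and
Hardy–Weinberg disequilibrium at p < 0.05, tested per population), it learns
a sequence of CART trees, each on the SNP pool minus the SNPs used by earlier
trees.  The trees therefore share no SNPs, and a failed genotype (NoCall)
silences only the trees that use it: each tree votes for a population iff
all of its SNPs are called, otherwise it abstains.  For a subject with votes
v = (v_1, …, v_C) over the voting trees the classifier reports the
population-inclusion probability vector v / Σv — e.g. votes 15/4/8 with 2
abstaining trees out of 29 give (15/27, 4/27, 8/27) — and the majority label.
No imputation is involved at any point.

How many trees are enough?  If each SNP is missing independently with
probability u and a tree uses n SNPs on average, a tree is fully observed
with probability p = (1−u)^n.  The probability that at least m of N trees
are fully observed is the binomial tail

    C(N, m, p) = 100 · (1 − Σ_{i=0}^{m−1} (N choose i) p^i (1−p)^{N−i}) %,

so after finding the smallest sub-ensemble size m whose cross-validated
majority-vote accuracy meets a target, the package recommends the smallest N
with C(N, m, p) above a confidence target.  At the reference working point
(u = 0.1, p = 0.59049, m = 9) this search returns N = 29 trees for 99.9%
confidence.

A Balding–Nichols generator (beta-distributed population allele frequencies
around a shared ancestral frequency, divergence parameter F_ST) produces
structured genotype data with known truth, so the whole pipeline is testable
without any external download.

## Worked example

Simulate three populations (200 per population would be typical; 100 here),
filter, train a 5-tree ensemble, cross-validate, size for robustness, and
classify:

    $ ethnopred simulate --pops 3 --n 100 --snps 500 --fst 0.15 --seed 7 \
          --out g.tsv --labels l.tsv
    simulated 300 samples x 500 SNPs -> g.tsv

    $ ethnopred filter --in g.tsv --labels l.tsv --report report.tsv --out filtered.tsv
    kept 433 of 500 SNPs (67 filtered)

    $ ethnopred train --in filtered.tsv --labels l.tsv --n-trees 5 --seed 7 \
          --out model.json
    trained 5 disjoint trees over 29 SNPs -> model.json

    $ ethnopred cv --in filtered.tsv --labels l.tsv --k 10 --n-trees 5 --seed 7 \
          --out cv.json
    10-fold CV, 5 trees: ensemble accuracy 99.0% +/- 2.2%

    $ ethnopred size --model model.json --cv cv.json --u 0.1 \
          --acc-target 99.0 --conf-target 99.9 --out plan.json
    n=5.80 p=0.54276 m=5 -> recommend N=22

    $ ethnopred predict --model model.json --in filtered.tsv --out calls.tsv
    wrote 300 predictions -> calls.tsv

    $ head -3 calls.tsv | cut -f1-5,9
    sample_id   votes_POP1  votes_POP2  votes_POP3  abstained  label
    POP1_S0000  4           1           0           0          POP1
    POP1_S0001  5           0           0           0          POP1

Reading the output: the 67 filtered SNPs failed at least one quality
criterion (at F = 0.15 a handful of SNPs also fail the within-population HWE
test by chance, as expected at alpha = 0.05).  The 5 trees use 29 distinct
SNPs (~5.8 each), so under 10% missingness a tree survives with probability
0.9^5.8 ≈ 0.543; holding the cross-validated 99.0% accuracy with 99.9%
confidence would take 22 such trees.  The first subject got 4 of 5 votes for
POP1 (inclusion probability 0.8), the second was unanimous.

The same operations are available as library functions
(`ethnopred.train_ensemble`, `ethnopred.predict_batch`,
`ethnopred.build_plan`, `ethnopred.kfold_cv`, …); see `docs/methods.md` for
the model details and design rationale.

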