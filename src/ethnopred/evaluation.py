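"""Cross-validation, agreement statistics and genomic-control assessment.

``kfold_cv`` estimates classifier quality exactly the way the modelling
pipeline is used: the samples are split into k stratified folds, a fresh
disjoint ensemble is trained on k-1 folds, and the held-out fold is scored
per tree and for cumulative majority-vote ensembles over the first j trees.
Accuracies are aggregated as mean +/- sd over the k fold values.  A held-out
sample on which the ensemble returns NO_CALL counts as incorrect.

The association layer implements the genomic-control diagnostic for
population stratification: per-SNP 1-df chi-squared association statistics
(Cochran–Armitage trend by default, allelic 2x2 optionally) whose median,
divided by the theoretical null median 0.4549364, is the inflation factor
lambda.  Lambda near 1 indicates an unstratified cohort; classifier-based
sample exclusion should pull an inflated lambda back toward 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cart import TreeParams, _stratified_folds
from .ensemble import (
    NO_CALL, DisjointEnsemble, apply_inclusion_cutoff, predict_batch,
    train_ensemble,
)
from .genotype_io import (
    GenotypeMatrix, HET, HOM_MAJOR, HOM_MINOR, PopulationLabels,
)

__all__ = [
    "CHI2_NULL_MEDIAN", "CVReport",
    "kfold_cv", "percent_agreement", "trend_chi2", "allelic_chi2",
    "association_scan", "genomic_lambda", "stratification_correction_experiment",
]

#: median of the chi-squared distribution with 1 degree of freedom
CHI2_NULL_MEDIAN = 0.4549364


@dataclass(frozen=True)
class CVReport:
    """Outcome of :func:`kfold_cv`.

    ``per_tree_acc[j]`` and ``cumulative_acc[j]`` are (mean %, sd %) pairs
    over folds for tree j and for the majority vote over trees 0..j.
    ``oof_predictions`` holds each sample's out-of-fold predicted class index
    per tree (-1 = abstained), suitable for the robustness sizing search.
    """

    k: int
    fold_assignment: dict[str, int]
    per_tree_acc: tuple[tuple[float, float], ...]
    cumulative_acc: tuple[tuple[float, float], ...]
    oof_predictions: np.ndarray
    y_true: np.ndarray
    class_order: tuple[str, ...]


def kfold_cv(matrix: GenotypeMatrix, labels: PopulationLabels, k: int = 10,
             n_trees: int = 3, params: TreeParams | None = None,
             seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation of a disjoint ensemble.

    Folds are a seeded stratified partition (per-fold class proportions
    within one sample of global).  Classes with fewer than ``k`` members
    trigger a warning inside the single-class tree path if a fold loses the
    class entirely; the run still completes.
    """
    import warnings

    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.n_samples:
        raise ValueError("k exceeds the number of samples")
    params = params or TreeParams()
    y = labels.encoded(matrix.samples)
    n_classes = len(labels.class_order)
    counts = np.bincount(y, minlength=n_classes)
    if (counts[counts > 0] < k).any():
        warnings.warn("some classes have fewer members than folds", stacklevel=2)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, k, rng)

    n = matrix.n_samples
    oof = np.full((n_trees, n), -1, dtype=np.intp)
    tree_acc = np.zeros((n_trees, k))
    cum_acc = np.zeros((n_trees, k))
    cls_index = {c: i for i, c in enumerate(labels.class_order)}
    for f in range(k):
        train_ids = [s for i, s in enumerate(matrix.samples) if fold[i] != f]
        test_idx = np.flatnonzero(fold == f)
        test_ids = [matrix.samples[i] for i in test_idx]
        ens = train_ensemble(matrix.subset_samples(train_ids), labels, n_trees,
                             TreeParams(**{**params.__dict__,
                                           "seed": params.seed + 104729 * f}))
        test_matrix = matrix.subset_samples(test_ids)
        # per-tree votes on the held-out fold
        votes = np.full((n_trees, len(test_ids)), -1, dtype=np.intp)
        for j, tree in enumerate(ens.trees):
            sub = DisjointEnsemble(trees=(tree,), class_order=ens.class_order,
                                   snp_alleles=ens.snp_alleles, meta={})
            preds = predict_batch(sub, test_matrix)
            for t, sid in enumerate(test_ids):
                label = preds[sid].label
                votes[j, t] = cls_index[label] if label != NO_CALL else -1
        oof[:, test_idx] = votes
        y_test = y[test_idx]
        for j in range(n_trees):
            tree_acc[j, f] = 100.0 * float(
                np.mean((votes[j] == y_test) & (votes[j] >= 0)))
            head = votes[: j + 1]
            tallies = np.stack([(head == c).sum(axis=0)
                                for c in range(n_classes)])
            pred = tallies.argmax(axis=0)
            ok = (pred == y_test) & (tallies.sum(axis=0) > 0)
            cum_acc[j, f] = 100.0 * float(np.mean(ok))

    def agg(a: np.ndarray) -> tuple[tuple[float, float], ...]:
        sd = a.std(axis=1, ddof=1) if k > 1 else np.zeros(a.shape[0])
        return tuple((float(m), float(s)) for m, s in zip(a.mean(axis=1), sd))

    return CVReport(
        k=k,
        fold_assignment={s: int(fold[i]) for i, s in enumerate(matrix.samples)},
        per_tree_acc=agg(tree_acc),
        cumulative_acc=agg(cum_acc),
        oof_predictions=oof,
        y_true=y,
        class_order=tuple(labels.class_order),
    )


def percent_agreement(confusion) -> float:
    """Percent of counts on the diagonal of a C x C confusion table."""
    table = np.asarray(confusion, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("confusion table must be square")
    if (table < 0).any():
        raise ValueError("negative counts")
    total = table.sum()
    if total < 1:
        raise ValueError("empty confusion table")
    return float(100.0 * np.trace(table) / total)


def trend_chi2(case_counts, control_counts) -> float:
    """Cochran–Armitage trend statistic (1 df) with scores (0, 1, 2).

    ``case_counts`` and ``control_counts`` are (n_AA, n_AB, n_BB) genotype
    counts.  Returns 0.0 for zero-variance input (all samples carry one
    genotype, or one group is empty of information).
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if r.shape != (3,) or s.shape != (3,):
        raise ValueError("expected (n_AA, n_AB, n_BB) per group")
    if (r < 0).any() or (s < 0).any():
        raise ValueError("negative counts")
    if r.sum() < 1 or s.sum() < 1:
        raise ValueError("each group needs at least one observation")
    return float(_trend_chi2_vec(r[None, :], s[None, :])[0])


def _trend_chi2_vec(r: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Vectorized trend statistic over rows of case/control count triples."""
    t = np.array([0.0, 1.0, 2.0])
    n = r + s
    N = n.sum(axis=1)
    R = r.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        U = (t * r).sum(axis=1) - R / N * (t * n).sum(axis=1)
        V = (R / N) * (1.0 - R / N) * ((t * t * n).sum(axis=1)
                                       - (t * n).sum(axis=1) ** 2 / N)
        chi2 = np.where(V > 0, U * U / np.where(V > 0, V, 1.0), 0.0)
    return chi2


def allelic_chi2(case_counts, control_counts) -> float:
    """Pearson chi-squared (1 df) on the 2x2 allele-count table."""
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    a_case = np.array([2 * r[0] + r[1], 2 * r[2] + r[1]])
    a_ctrl = np.array([2 * s[0] + s[1], 2 * s[2] + s[1]])
    table = np.stack([a_case, a_ctrl])
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = rowsum * colsum / total
    if (expected == 0).any():
        return 0.0
    return float((((table - expected) ** 2) / expected).sum())


def association_scan(matrix: GenotypeMatrix,
                     phenotypes: Mapping[str, int],
                     statistic: str = "trend") -> np.ndarray:
    """Per-SNP 1-df association statistics for a case/control phenotype.

    NoCall genotypes are excluded per SNP.  ``statistic`` is ``"trend"``
    (Cochran–Armitage, the GWAS standard) or ``"allelic"``.
    """
    pheno = np.array([phenotypes[s] for s in matrix.samples], dtype=int)
    if set(np.unique(pheno)) - {0, 1}:
        raise ValueError("phenotypes must be 0 (control) or 1 (case)")
    if (pheno == 1).sum() == 0 or (pheno == 0).sum() == 0:
        raise ValueError("need at least one case and one control")
    case_counts = np.stack(
        [(matrix.calls[pheno == 1] == g).sum(axis=0)
         for g in (HOM_MAJOR, HET, HOM_MINOR)], axis=1).astype(float)
    ctrl_counts = np.stack(
        [(matrix.calls[pheno == 0] == g).sum(axis=0)
         for g in (HOM_MAJOR, HET, HOM_MINOR)], axis=1).astype(float)
    if statistic == "trend":
        return _trend_chi2_vec(case_counts, ctrl_counts)
    if statistic == "allelic":
        return np.array([allelic_chi2(case_counts[j], ctrl_counts[j])
                         for j in range(matrix.n_snps)])
    raise ValueError(f"unknown statistic {statistic!r}")


def genomic_lambda(chi2_values) -> float:
    """Genomic-control inflation factor: median statistic over the
    theoretical 1-df chi-squared median."""
    values = np.asarray(chi2_values, dtype=float)
    if values.size == 0:
        raise ValueError("no association statistics")
    return float(np.median(values) / CHI2_NULL_MEDIAN)


def stratification_correction_experiment(
        matrix: GenotypeMatrix, phenotypes: Mapping[str, int],
        ensemble: DisjointEnsemble, target_class: str,
        cutoff: float = 0.5, statistic: str = "trend",
        ) -> tuple[float, float]:
    """Inflation factor before and after classifier-based sample exclusion.

    Computes lambda over the full cohort, then classifies every sample with
    the ensemble, retains those whose inclusion probability for
    ``target_class`` reaches ``cutoff``, and recomputes lambda on the
    retained subset.
    """
    lambda_before = genomic_lambda(
        association_scan(matrix, phenotypes, statistic))
    predictions = predict_batch(ensemble, matrix)
    kept = apply_inclusion_cutoff(predictions, target_class, cutoff)
    if not kept:
        raise ValueError("no samples retained at the given cutoff")
    sub = matrix.subset_samples(kept)
    lambda_after = genomic_lambda(association_scan(sub, phenotypes, statistic))
    return lambda_before, lambda_after
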