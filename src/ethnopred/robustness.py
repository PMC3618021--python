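"""Sizing an ensemble to be robust against missing genotype values.

The argument proceeds in four steps, each a function here:

1. A tree with all its SNPs called votes; an average of ``n`` SNPs per tree
   and an independent per-SNP NoCall probability ``u`` give a per-tree
   coverage probability ``p = (1 - u)^n`` (:func:`coverage_prob`).
2. From cross-validated per-tree predictions, find the smallest sub-ensemble
   size ``m`` whose average majority-vote accuracy reaches the target
   (:func:`min_ensemble_size_for_accuracy`).
3. With ``N`` independent trees, the probability that at least ``m`` of them
   are fully observed is the binomial upper tail
   ``C(N, m, p) = 100 * (1 - sum_{i=0}^{m-1} choose(N,i) p^i (1-p)^(N-i))``
   (:func:`ensemble_confidence`; note the sum starts at i = 0 — an ensemble
   with zero clean trees is also a failure).
4. The recommended ensemble size is the smallest ``N`` whose confidence
   reaches the target (:func:`min_trees_for_confidence`).

With the reference constants p = 0.59049 and m = 9 the confidence column is
0.873% at N = 9, 58.013% at N = 15 and 99.94% at N = 29, making N = 29 the
smallest size with 99.9% confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .ensemble import DisjointEnsemble

__all__ = [
    "RobustnessPlan", "SubsetAccuracyResult",
    "coverage_prob", "avg_snps_per_tree", "ensemble_confidence",
    "min_trees_for_confidence", "min_ensemble_size_for_accuracy", "build_plan",
]


def coverage_prob(n: float, u: float) -> float:
    """Probability ``(1-u)^n`` that a tree with ``n`` SNPs is fully called.

    ``n`` may be fractional (an ensemble-average SNPs-per-tree); ``u`` is the
    per-SNP NoCall probability, assumed independent across SNPs.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be in [0, 1]")
    return float((1.0 - u) ** n)


def avg_snps_per_tree(ensemble: DisjointEnsemble) -> float:
    """Mean number of SNPs consulted per tree."""
    if ensemble.n_trees == 0:
        raise ValueError("empty ensemble")
    return sum(len(t.snp_set) for t in ensemble.trees) / ensemble.n_trees


def ensemble_confidence(N: int, m: int, p: float) -> float:
    """Percent probability that at least ``m`` of ``N`` trees are clean.

    Exact binomial upper tail, ``100 * P[Binomial(N, p) >= m]``.  ``m = 0``
    returns 100; ``N < m`` returns 0.
    """
    if N < 0 or m < 0:
        raise ValueError("N and m must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m == 0:
        return 100.0
    return float(100.0 * stats.binom.sf(m - 1, N, p))


def min_trees_for_confidence(m: int, p: float, conf_target: float,
                             n_max: int = 10**6) -> int:
    """Smallest integer ``N >= m`` with ``ensemble_confidence >= conf_target``.

    ``conf_target`` is a percent (< 100).  For ``p = 0`` any positive target
    is unreachable and raises ``ValueError``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if conf_target >= 100.0:
        raise ValueError("conf_target must be < 100")
    if p == 0.0 and conf_target > 0.0 and m > 0:
        raise ValueError("p = 0: no ensemble size reaches a positive confidence")
    for N in range(max(m, 0), n_max + 1):
        if ensemble_confidence(N, m, p) >= conf_target:
            return N
    raise RuntimeError(f"no N <= {n_max} reaches {conf_target}% confidence")


@dataclass(frozen=True)
class SubsetAccuracyResult:
    """Size -> average-accuracy table and the minimal adequate size.

    ``table`` rows are ``(size, n_subsets_evaluated, mean_accuracy_percent)``.
    When no size reaches the target, ``reachable`` is False and ``m`` holds
    the best size found (the one with the highest average accuracy).
    """

    m: int
    reachable: bool
    acc_target: float
    table: tuple[tuple[int, int, float], ...]

    @property
    def best(self) -> tuple[int, int, float]:
        return max(self.table, key=lambda row: row[2])


def _majority_accuracy(oof: np.ndarray, y: np.ndarray, rows: tuple[int, ...],
                       n_classes: int) -> float:
    """Percent accuracy of the majority vote over the given tree rows.

    ``oof`` holds integer class indices with -1 for an abstention; a sample
    on which every selected tree abstains is counted as incorrect, and vote
    ties resolve to the earlier class index.
    """
    sub = oof[list(rows)]
    votes = np.stack([(sub == c).sum(axis=0) for c in range(n_classes)])
    total = votes.sum(axis=0)
    pred = votes.argmax(axis=0)
    correct = (pred == y) & (total > 0)
    return float(100.0 * correct.mean())


def min_ensemble_size_for_accuracy(oof_predictions: np.ndarray,
                                   y_true: np.ndarray,
                                   n_classes: int,
                                   acc_target: float,
                                   max_enumeration: int = 10**5,
                                   n_samples_mc: int = 10**5,
                                   seed: int = 0) -> SubsetAccuracyResult:
    """Smallest sub-ensemble size whose average CV accuracy reaches a target.

    Parameters
    ----------
    oof_predictions
        Array (n_trees, n_samples) of out-of-fold predicted class indices,
        -1 marking an abstention.
    y_true
        True class indices per sample.
    n_classes
        Number of classes (class indices run 0..n_classes-1).
    acc_target
        Percent accuracy required of the size-``m`` average.
    max_enumeration, n_samples_mc, seed
        For each candidate size ``s``, all ``choose(T, s)`` subsets are
        enumerated when that count is at most ``max_enumeration``; otherwise
        ``n_samples_mc`` subsets are drawn with a seeded generator.
    """
    oof = np.asarray(oof_predictions)
    y = np.asarray(y_true)
    T = oof.shape[0]
    if T < 1:
        raise ValueError("need at least one tree")
    if acc_target > 100.0:
        raise ValueError("acc_target must be <= 100")
    rng = np.random.default_rng(seed)
    table: list[tuple[int, int, float]] = []
    answer: int | None = None
    for s in range(1, T + 1):
        n_subsets = comb(T, s)
        if n_subsets <= max_enumeration:
            accs = [_majority_accuracy(oof, y, rows, n_classes)
                    for rows in combinations(range(T), s)]
        else:
            accs = [_majority_accuracy(
                        oof, y, tuple(rng.choice(T, size=s, replace=False)),
                        n_classes)
                    for _ in range(n_samples_mc)]
            n_subsets = n_samples_mc
        mean_acc = float(np.mean(accs))
        table.append((s, n_subsets, mean_acc))
        if answer is None and mean_acc >= acc_target:
            answer = s
    if answer is None:
        best = max(table, key=lambda row: row[2])
        return SubsetAccuracyResult(m=best[0], reachable=False,
                                    acc_target=acc_target, table=tuple(table))
    return SubsetAccuracyResult(m=answer, reachable=True,
                                acc_target=acc_target, table=tuple(table))


@dataclass(frozen=True)
class RobustnessPlan:
    """All symbols of the sizing chain, recorded for the report.

    u: per-SNP NoCall probability; n: average SNPs per tree;
    p = (1-u)^n and q = 1-p: per-tree coverage/failure probability;
    m: minimal voting trees for the accuracy target Acc (percent);
    C: the confidence target (percent); N: recommended tree count.
    """

    u: float
    n: float
    p: float
    q: float
    m: int
    acc_target: float
    conf_target: float
    N: int
    accuracy_table: tuple[tuple[int, int, float], ...] = field(default=())
    acc_reachable: bool = True


def build_plan(ensemble: DisjointEnsemble,
               oof_predictions: np.ndarray,
               y_true: np.ndarray,
               u: float,
               acc_target: float = 99.9,
               conf_target: float = 99.9,
               p_override: float | None = None,
               max_enumeration: int = 10**5,
               n_samples_mc: int = 10**5,
               seed: int = 0) -> RobustnessPlan:
    """Chain the sizing computations into a :class:`RobustnessPlan`.

    ``p_override`` replaces the computed coverage probability when replaying
    externally fixed constants.
    """
    n = avg_snps_per_tree(ensemble)
    p = coverage_prob(n, u) if p_override is None else float(p_override)
    sub = min_ensemble_size_for_accuracy(
        oof_predictions, y_true, len(ensemble.class_order), acc_target,
        max_enumeration=max_enumeration, n_samples_mc=n_samples_mc, seed=seed)
    N = min_trees_for_confidence(sub.m, p, conf_target)
    return RobustnessPlan(u=float(u), n=float(n), p=p, q=1.0 - p, m=sub.m,
                          acc_target=float(acc_target),
                          conf_target=float(conf_target), N=N,
                          accuracy_table=sub.table, acc_reachable=sub.reachable)
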