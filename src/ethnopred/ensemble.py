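"""Disjoint decision-tree ensembles with abstention-aware majority voting.

The ensemble is built sequentially: a tree is learned on the current feature
pool, its SNPs are removed from the pool, and the next tree is learned on the
remainder, so no SNP appears in two trees.  Disjointness is what makes
abstention well-behaved under missing data: a NoCall silences only the trees
that use that SNP, and the remaining trees vote independently.

A prediction is a vote vector: each tree either votes for a class or abstains
(whenever any of its SNPs is NoCall for the subject).  The population
inclusion probability vector divides each class's votes by the number of
*voting* trees — e.g. 15 votes for the first class, 4 and 8 for the others
and 2 silent trees out of 29 gives (15/27, 4/27, 8/27).  The returned label
is the class with the most votes; if every tree abstains the ensemble itself
returns NO_CALL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cart import ABSTAIN, DecisionTree, TreeParams, learn_tree, predict_tree
from .genotype_io import (
    GenotypeMatrix, HOM_MAJOR, HET, HOM_MINOR, NOCALL,
    PopulationLabels,
)

__all__ = [
    "NO_CALL", "EnsembleExhaustedError", "DisjointEnsemble", "VotePrediction",
    "train_ensemble", "predict", "predict_batch", "predictions_to_frame",
    "apply_inclusion_cutoff",
]

#: ensemble-level sentinel label: every tree abstained
NO_CALL = "NO_CALL"


class EnsembleExhaustedError(RuntimeError):
    """The feature pool ran out of informative SNPs before ``n_trees``."""

    def __init__(self, completed: int, requested: int):
        self.completed = completed
        self.requested = requested
        super().__init__(
            f"feature pool exhausted of informative SNPs after "
            f"{completed} of {requested} trees")


@dataclass(frozen=True)
class DisjointEnsemble:
    """An ordered list of trees with pairwise-disjoint SNP sets.

    ``snp_alleles`` maps every SNP used by any tree to its
    ``(allele_major, allele_minor)`` characters from the training data, which
    anchors genotype codes across datasets.
    """

    trees: tuple[DecisionTree, ...]
    class_order: tuple[str, ...]
    snp_alleles: dict[str, tuple[str, str]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trees", tuple(self.trees))
        object.__setattr__(self, "class_order", tuple(self.class_order))
        seen: set[str] = set()
        for k, tree in enumerate(self.trees):
            overlap = seen & tree.snp_set
            if overlap:
                raise ValueError(
                    f"tree {k} reuses SNPs of earlier trees: {sorted(overlap)[:5]}")
            seen |= tree.snp_set
        missing = seen - set(self.snp_alleles)
        if missing:
            raise ValueError(f"snp_alleles lacks used SNPs: {sorted(missing)[:5]}")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def snp_union(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.trees:
            out |= t.snp_set
        return frozenset(out)


@dataclass(frozen=True)
class VotePrediction:
    """Vote counts, abstentions and the derived probability vector.

    Invariants: votes sum plus ``n_abstained`` equals the ensemble size;
    ``prob`` divides by the number of voting trees (empty when all abstain,
    in which case ``label`` is :data:`NO_CALL`); ``tie`` flags a non-unique
    argmax (broken toward the earlier class in class order).
    """

    votes: dict[str, int]
    n_abstained: int
    prob: dict[str, float]
    label: str
    tie: bool


def train_ensemble(matrix: GenotypeMatrix, labels: PopulationLabels,
                   n_trees: int, params: TreeParams | None = None,
                   ) -> DisjointEnsemble:
    """Learn ``n_trees`` trees by iterative SNP removal.

    Each tree is learned on the full feature pool minus every SNP used by the
    earlier trees; pairwise disjointness holds by construction.  Raises
    :class:`EnsembleExhaustedError` (reporting how many trees were completed)
    if a learned tree uses no SNP at all — i.e. the remaining pool contains
    no informative feature.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    params = params or TreeParams()
    pool = list(matrix.snp_ids)
    trees: list[DecisionTree] = []
    for k in range(n_trees):
        if not pool:
            raise EnsembleExhaustedError(completed=k, requested=n_trees)
        tree = learn_tree(matrix, labels, allowed_snps=pool,
                          params=TreeParams(**{**asdict(params),
                                               "seed": params.seed + 7919 * k}))
        if not tree.snp_set:
            raise EnsembleExhaustedError(completed=k, requested=n_trees)
        trees.append(tree)
        used = tree.snp_set
        pool = [s for s in pool if s not in used]
    alleles = {}
    for t in trees:
        for sid in t.snp_set:
            rec = matrix.snps[matrix.snp_index(sid)]
            alleles[sid] = (rec.allele_major, rec.allele_minor)
    meta = {"params": asdict(params), "n_trees_requested": int(n_trees),
            "seed": int(params.seed)}
    return DisjointEnsemble(trees=tuple(trees),
                            class_order=tuple(labels.class_order),
                            snp_alleles=alleles, meta=meta)


def predict(ensemble: DisjointEnsemble, sample: Mapping[str, int],
            path_only: bool = False) -> VotePrediction:
    """Vote prediction for one sample (mapping ``snp_id -> genotype code``).

    The sample must supply a call — possibly NOCALL — for every SNP in the
    ensemble's union SNP set; entirely absent entries are a contract
    violation and raise ``KeyError`` listing the missing ids.
    """
    absent = sorted(s for s in ensemble.snp_union if s not in sample)
    if absent:
        raise KeyError(f"sample lacks entries for ensemble SNPs: {absent[:10]}")
    votes = {c: 0 for c in ensemble.class_order}
    n_abstained = 0
    for tree in ensemble.trees:
        out = predict_tree(tree, sample, path_only=path_only)
        if out == ABSTAIN:
            n_abstained += 1
        else:
            votes[out] += 1
    return _finish_votes(votes, n_abstained, ensemble.class_order)


def _finish_votes(votes: dict[str, int], n_abstained: int,
                  class_order) -> VotePrediction:
    total = sum(votes.values())
    if total == 0:
        return VotePrediction(votes=votes, n_abstained=n_abstained, prob={},
                              label=NO_CALL, tie=False)
    prob = {c: votes[c] / total for c in class_order}
    best = max(votes.values())
    winners = [c for c in class_order if votes[c] == best]
    return VotePrediction(votes=votes, n_abstained=n_abstained, prob=prob,
                          label=winners[0], tie=len(winners) > 1)


def _aligned_codes(ensemble: DisjointEnsemble,
                   matrix: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Extract the ensemble's SNP columns from ``matrix``, remapping genotype
    codes where the matrix's major/minor designation is flipped relative to
    the training data (matched as an unordered allele pair)."""
    order = sorted(ensemble.snp_union)
    absent = [s for s in order if s not in matrix._snp_index]
    if absent:
        raise KeyError(f"matrix lacks ensemble SNPs: {absent[:10]}")
    cols = np.empty((matrix.n_samples, len(order)), dtype=np.int8)
    for j, sid in enumerate(order):
        rec = matrix.snps[matrix.snp_index(sid)]
        col = matrix.calls[:, matrix.snp_index(sid)]
        maj, mnr = ensemble.snp_alleles[sid]
        if (rec.allele_major, rec.allele_minor) == (maj, mnr):
            cols[:, j] = col
        elif (rec.allele_major, rec.allele_minor) == (mnr, maj):
            flipped = col.copy()
            flipped[col == HOM_MAJOR] = HOM_MINOR
            flipped[col == HOM_MINOR] = HOM_MAJOR
            cols[:, j] = flipped
        else:
            raise ValueError(
                f"SNP {sid!r}: dataset alleles "
                f"{rec.allele_major}/{rec.allele_minor} do not match model "
                f"alleles {maj}/{mnr}")
    return order, cols


def predict_batch(ensemble: DisjointEnsemble, matrix: GenotypeMatrix,
                  path_only: bool = False) -> dict[str, VotePrediction]:
    """Per-sample :func:`predict` over a whole matrix (sample order kept)."""
    order, codes = _aligned_codes(ensemble, matrix)
    out: dict[str, VotePrediction] = {}
    for i, sample_id in enumerate(matrix.samples):
        sample = dict(zip(order, (int(c) for c in codes[i])))
        out[sample_id] = predict(ensemble, sample, path_only=path_only)
    return out


def predictions_to_frame(predictions: Mapping[str, VotePrediction],
                         class_order: Sequence[str]) -> pd.DataFrame:
    """Tabular export: one row per sample with votes, abstentions,
    probabilities, label and tie flag."""
    rows = []
    for sample_id, p in predictions.items():
        row: dict = {"sample_id": sample_id}
        for c in class_order:
            row[f"votes_{c}"] = p.votes.get(c, 0)
        row["abstained"] = p.n_abstained
        for c in class_order:
            row[f"prob_{c}"] = p.prob.get(c, float("nan"))
        row["label"] = p.label
        row["tie"] = p.tie
        rows.append(row)
    cols = (["sample_id"] + [f"votes_{c}" for c in class_order] + ["abstained"]
            + [f"prob_{c}" for c in class_order] + ["label", "tie"])
    return pd.DataFrame(rows, columns=cols)


def apply_inclusion_cutoff(predictions: Mapping[str, VotePrediction],
                           target_class: str, min_prob: float) -> list[str]:
    """Sample ids whose inclusion probability for ``target_class`` is at
    least ``min_prob`` (NO_CALL samples are never kept)."""
    if not 0.0 <= min_prob <= 1.0:
        raise ValueError("min_prob must be in [0, 1]")
    kept = []
    for sample_id, p in predictions.items():
        if p.label == NO_CALL:
            continue
        if target_class not in p.votes:
            raise KeyError(f"unknown class {target_class!r}")
        if p.prob[target_class] >= min_prob:
            kept.append(sample_id)
    return kept
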