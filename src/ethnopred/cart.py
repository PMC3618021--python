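"""Single CART-style classification trees over categorical genotype features.

A tree's internal nodes each test one SNP with a binary bipartition of the
three genotype categories ({A_A} vs rest, {A_B} vs rest, {B_B} vs rest, which
cover dominant, heterozygote-specific and recessive patterns); leaves carry a
population label.  Prediction abstains for a subject whenever *any* SNP used
anywhere in the tree is NoCall — not merely SNPs on the realized root-to-leaf
path — so a vote is only ever cast from fully observed evidence.  A
path-only mode exists for comparison but is off by default.

Splits are chosen greedily by Gini impurity decrease.  Ties (including the
all-zero-gain ties that arise in parity-structured data) are broken
deterministically: earliest SNP in matrix column order first, then the fixed
bipartition listing order.  An impure node may therefore split on a zero-gain
candidate, which is what lets the learner descend through XOR-like structure;
growth always terminates because both children are strictly smaller.

Pruning follows classical cost-complexity pruning with the 1-SE rule over an
internal stratified cross-validation.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype_io import (
    CODE_TO_TOKEN, GenotypeMatrix, HET, HOM_MAJOR, HOM_MINOR, NOCALL,
    PopulationLabels,
)

__all__ = [
    "ABSTAIN", "BIPARTITIONS", "TreeParams", "TreeNode", "DecisionTree",
    "gini_impurity", "learn_tree", "predict_tree", "tree_to_rules",
]

#: sentinel returned by :func:`predict_tree` when the tree declines to vote
ABSTAIN = "ABSTAIN"

#: the fixed listing order of candidate left-branch genotype sets
BIPARTITIONS: tuple[frozenset[int], ...] = (
    frozenset({HOM_MAJOR}), frozenset({HET}), frozenset({HOM_MINOR}),
)

_EPS = 1e-12


@dataclass(frozen=True)
class TreeParams:
    """Learning parameters; the defaults are classical CART choices."""

    min_leaf_size: int = 5
    max_leaves: int | None = None
    prune: str = "cost_complexity_1se"  # or "none"
    internal_cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")
        if self.prune not in ("cost_complexity_1se", "none"):
            raise ValueError(f"unknown prune mode {self.prune!r}")
        if self.prune == "cost_complexity_1se" and self.internal_cv_folds < 2:
            raise ValueError("internal_cv_folds must be >= 2 when pruning")


class TreeNode:
    """One node of a binary genotype decision tree.

    A node is either internal (``snp_id``, ``left_genotypes``, two children)
    or a leaf (``label``).  Both kinds carry ``class_counts``, the per-class
    training counts of the samples that reached the node, aligned to the
    tree's class order; a leaf's label is the argmax with ties broken toward
    the earlier class.
    """

    __slots__ = ("snp_id", "left_genotypes", "left", "right",
                 "label", "class_counts")

    def __init__(self, *, snp_id=None, left_genotypes=None, left=None,
                 right=None, label=None, class_counts=()):
        self.snp_id = snp_id
        self.left_genotypes = left_genotypes
        self.left = left
        self.right = right
        self.label = label
        self.class_counts = tuple(int(c) for c in class_counts)

    # -- constructors ------------------------------------------------------

    @classmethod
    def leaf(cls, class_counts, class_order, label=None) -> "TreeNode":
        counts = tuple(int(c) for c in class_counts)
        if sum(counts) < 1:
            raise ValueError("leaf class_counts must sum to >= 1")
        majority = class_order[int(np.argmax(counts))]
        if label is not None and label != majority:
            raise ValueError(f"leaf label {label!r} is not the majority class")
        return cls(label=majority, class_counts=counts)

    @classmethod
    def internal(cls, snp_id, left_genotypes, left, right,
                 class_counts) -> "TreeNode":
        gset = frozenset(left_genotypes)
        full = {HOM_MAJOR, HET, HOM_MINOR}
        if not gset or gset == full or not gset <= full:
            raise ValueError("left_genotypes must be a nonempty proper subset "
                             "of the three genotype codes")
        return cls(snp_id=snp_id, left_genotypes=gset, left=left, right=right,
                   class_counts=class_counts)

    @property
    def is_leaf(self) -> bool:
        return self.snp_id is None

    def __eq__(self, other) -> bool:
        if not isinstance(other, TreeNode):
            return NotImplemented
        if self.is_leaf != other.is_leaf:
            return False
        if self.is_leaf:
            return (self.label == other.label
                    and self.class_counts == other.class_counts)
        return (self.snp_id == other.snp_id
                and self.left_genotypes == other.left_genotypes
                and self.class_counts == other.class_counts
                and self.left == other.left and self.right == other.right)

    def __repr__(self) -> str:
        if self.is_leaf:
            return f"Leaf({self.label}, counts={self.class_counts})"
        toks = ",".join(CODE_TO_TOKEN[g] for g in sorted(self.left_genotypes))
        return f"Node({self.snp_id} in {{{toks}}})"


@dataclass(frozen=True)
class DecisionTree:
    """A learned tree plus its class order and the set of SNPs it consults."""

    root: TreeNode
    class_order: tuple[str, ...]
    snp_set: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_order", tuple(self.class_order))
        object.__setattr__(self, "snp_set", frozenset(_collect_snps(self.root)))

    @property
    def n_leaves(self) -> int:
        return _count_leaves(self.root)


def _collect_snps(node: TreeNode) -> set[str]:
    if node.is_leaf:
        return set()
    return {node.snp_id} | _collect_snps(node.left) | _collect_snps(node.right)


def _count_leaves(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


# ---------------------------------------------------------------------------
# impurity
# ---------------------------------------------------------------------------

def gini_impurity(class_counts) -> float:
    """Gini impurity ``1 - sum_c (n_c/n)^2`` of a count vector."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative class counts")
    n = counts.sum()
    if n < 1:
        raise ValueError("class counts sum to zero")
    p = counts / n
    return float(1.0 - (p * p).sum())


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _best_split(G: np.ndarray, y: np.ndarray, n_classes: int,
                min_leaf: int) -> tuple[float, int, int] | None:
    """Best (gain, column, bipartition) at a node, or None if unsplittable.

    ``G`` is the node's samples x candidate-SNPs call submatrix (codes 0..2),
    ``y`` the integer class labels.  Gain is the weighted Gini decrease; a
    candidate is valid when both children satisfy ``min_leaf``.  Among equal
    gains the smallest column index wins, then the bipartition listing order
    (argwhere returns candidates in exactly that row-major order).
    """
    n, L = G.shape
    if L == 0:
        return None
    span = 3 * n_classes
    flat = (np.arange(L, dtype=np.intp) * span + G.astype(np.intp) * n_classes
            + y[:, None]).ravel()
    cnt = np.bincount(flat, minlength=L * span).reshape(L, 3, n_classes).astype(float)
    parent = np.bincount(y, minlength=n_classes).astype(float)
    g_parent = 1.0 - ((parent / n) ** 2).sum()

    n_left = cnt.sum(axis=2)                      # (L, 3)
    n_right = n - n_left
    right_cnt = parent[None, None, :] - cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        g_left = 1.0 - (cnt ** 2).sum(axis=2) / np.maximum(n_left, 1.0) ** 2
        g_right = 1.0 - (right_cnt ** 2).sum(axis=2) / np.maximum(n_right, 1.0) ** 2
    gain = g_parent - (n_left * g_left + n_right * g_right) / n
    gain[(n_left < min_leaf) | (n_right < min_leaf)] = -np.inf
    best = gain.max()
    if not np.isfinite(best) or best < -_EPS:
        return None
    col, b = np.argwhere(gain >= best - _EPS)[0]
    return float(best), int(col), int(b)


def _grow(G: np.ndarray, y: np.ndarray, n_classes: int,
          params: TreeParams) -> TreeNode:
    """Best-first growth (matches depth-first when max_leaves is unbounded)."""
    def make_leaf(idx):
        counts = np.bincount(y[idx], minlength=n_classes)
        return TreeNode(label=None, class_counts=counts)

    root = make_leaf(np.arange(len(y)))
    heap: list[tuple[float, int, TreeNode, np.ndarray, int, int]] = []
    seq = 0

    def consider(node, idx):
        nonlocal seq
        counts = np.asarray(node.class_counts)
        if counts.max() == counts.sum():       # pure
            return
        if len(idx) < 2 * params.min_leaf_size:
            return
        found = _best_split(G[idx], y[idx], n_classes, params.min_leaf_size)
        if found is None:
            return
        gain, col, b = found
        heapq.heappush(heap, (-gain, seq, node, idx, col, b))
        seq += 1

    consider(root, np.arange(len(y)))
    n_leaves = 1
    while heap and (params.max_leaves is None or n_leaves < params.max_leaves):
        _, _, node, idx, col, b = heapq.heappop(heap)
        mask = np.isin(G[idx, col], tuple(BIPARTITIONS[b]))
        left_idx, right_idx = idx[mask], idx[~mask]
        node.snp_id = col                      # int column; mapped to id later
        node.left_genotypes = BIPARTITIONS[b]
        node.left = make_leaf(left_idx)
        node.right = make_leaf(right_idx)
        n_leaves += 1
        consider(node.left, left_idx)
        consider(node.right, right_idx)
    return root


def _node_error(node: TreeNode) -> int:
    c = node.class_counts
    return sum(c) - max(c)


def _subtree_stats(node: TreeNode) -> tuple[int, int]:
    """(number of leaves, summed leaf misclassification count)."""
    if node.is_leaf:
        return 1, _node_error(node)
    ll, le = _subtree_stats(node.left)
    rl, re = _subtree_stats(node.right)
    return ll + rl, le + re


def _prune_at_alpha(node: TreeNode, alpha: float, n_total: int) -> TreeNode:
    """Smallest optimal subtree for complexity parameter ``alpha`` (error-rate
    units), computed bottom-up; collapses every branch whose per-leaf error
    reduction is <= alpha."""
    if node.is_leaf:
        return node
    node.left = _prune_at_alpha(node.left, alpha, n_total)
    node.right = _prune_at_alpha(node.right, alpha, n_total)
    leaves, sub_err = _subtree_stats(node)
    if (_node_error(node) - sub_err) / n_total <= alpha * (leaves - 1) + _EPS:
        return TreeNode(label=None, class_counts=node.class_counts)
    return node


def _weakest_link_alphas(root: TreeNode, n_total: int) -> list[float]:
    """Increasing critical alphas of the cost-complexity path (starting at 0)."""
    import copy

    tree = copy.deepcopy(root)
    alphas = [0.0]
    while not tree.is_leaf:
        links: list[tuple[float, TreeNode]] = []

        def visit(node):
            if node.is_leaf:
                return
            leaves, sub_err = _subtree_stats(node)
            g = (_node_error(node) - sub_err) / (n_total * (leaves - 1))
            links.append((g, node))
            visit(node.left)
            visit(node.right)

        visit(tree)
        a = min(g for g, _ in links)
        if a > alphas[-1] + _EPS:
            alphas.append(a)
        tree = _prune_at_alpha(tree, a, n_total)
    return alphas


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per sample; classes dealt round-robin after a shuffle, so
    per-fold class proportions are within one sample of the global ones."""
    fold = np.empty(len(y), dtype=np.intp)
    start = 0
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        rng.shuffle(members)
        fold[members] = (np.arange(len(members)) + start) % k
        start += len(members)
    return fold


def _predict_cols(node: TreeNode, row: np.ndarray) -> int:
    """Class index for a row of codes, on a tree whose snp_id fields are
    still integer column indices (training-time internal form)."""
    while not node.is_leaf:
        node = node.left if int(row[node.snp_id]) in node.left_genotypes else node.right
    return int(np.argmax(node.class_counts))


def _prune_1se(root: TreeNode, G: np.ndarray, y: np.ndarray, n_classes: int,
               params: TreeParams) -> TreeNode:
    n = len(y)
    alphas = _weakest_link_alphas(root, n)
    if len(alphas) == 1:
        return root
    # representative alphas: geometric means of consecutive critical values,
    # plus the final critical value itself (the root-collapse end of the path)
    cand = [float(np.sqrt(alphas[i] * alphas[i + 1])) for i in range(len(alphas) - 1)]
    cand.append(alphas[-1])
    k = min(params.internal_cv_folds, n)
    rng = np.random.default_rng(params.seed)
    fold = _stratified_folds(y, k, rng)
    err = np.zeros((len(cand), k))
    for f in range(k):
        train = fold != f
        test = np.flatnonzero(~train)
        if len(test) == 0 or train.sum() == 0:
            continue
        sub = _grow(G[train], y[train], n_classes, replace(params, prune="none"))
        # alphas ascending: prune the same tree progressively
        for ci, a in enumerate(cand):
            sub = _prune_at_alpha(sub, a, int(train.sum()))
            wrong = sum(_predict_cols(sub, G[t]) != y[t] for t in test)
            err[ci, f] = wrong / len(test)
    mean = err.mean(axis=1)
    se = err.std(axis=1, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(len(cand))
    best = int(np.argmin(mean))
    threshold = mean[best] + se[best]
    chosen = max(ci for ci in range(len(cand)) if mean[ci] <= threshold + _EPS)
    return _prune_at_alpha(root, cand[chosen], n)


def _finalize(node: TreeNode, snp_ids: Sequence[str], class_order) -> TreeNode:
    """Map integer columns to SNP ids and set leaf labels."""
    if node.is_leaf:
        return TreeNode.leaf(node.class_counts, class_order)
    return TreeNode.internal(snp_ids[node.snp_id], node.left_genotypes,
                             _finalize(node.left, snp_ids, class_order),
                             _finalize(node.right, snp_ids, class_order),
                             node.class_counts)


def learn_tree(matrix: GenotypeMatrix, labels: PopulationLabels,
               allowed_snps: Iterable[str] | None = None,
               params: TreeParams | None = None) -> DecisionTree:
    """Learn one classification tree.

    Parameters
    ----------
    matrix
        Training genotypes; must contain no NoCall among ``allowed_snps``
        (the preprocessing filters guarantee this on filtered data).
    labels
        Population assignment for every training sample.
    allowed_snps
        Candidate feature pool; defaults to all SNPs.  Candidates are always
        considered in matrix column order regardless of the iterable's order,
        which fixes the tie-break.
    params
        :class:`TreeParams`; defaults to classical CART settings with
        cost-complexity 1-SE pruning.

    A single-class input yields a single-leaf tree (with a warning) rather
    than an error, so cross-validation folds with accidental class absence
    still run.
    """
    params = params or TreeParams()
    if allowed_snps is None:
        cols = list(range(matrix.n_snps))
    else:
        wanted = set(allowed_snps)
        if not wanted:
            raise ValueError("allowed_snps is empty")
        cols = [j for j in range(matrix.n_snps) if matrix.snps[j].snp_id in wanted]
        missing = wanted - {matrix.snps[j].snp_id for j in cols}
        if missing:
            raise KeyError(f"allowed_snps not in matrix: {sorted(missing)[:5]}")
    G = matrix.calls[:, cols]
    if (G == NOCALL).any():
        raise ValueError("training data contains NoCall among candidate SNPs; "
                         "run the call-rate filter first")
    if matrix.n_samples == 0:
        raise ValueError("empty training matrix")
    y = labels.encoded(matrix.samples)
    n_classes = len(labels.class_order)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class training input: returning a single-leaf tree",
                      stacklevel=2)
    root = _grow(G.astype(np.int8), y, n_classes, params)
    if params.prune == "cost_complexity_1se" and not root.is_leaf:
        root = _prune_1se(root, G, y, n_classes, params)
    ids = [matrix.snps[j].snp_id for j in cols]
    return DecisionTree(_finalize(root, ids, labels.class_order),
                        tuple(labels.class_order))


# ---------------------------------------------------------------------------
# prediction and rule export
# ---------------------------------------------------------------------------

def predict_tree(tree: DecisionTree, sample: Mapping[str, int],
                 path_only: bool = False) -> str:
    """Predict one sample's class, or :data:`ABSTAIN`.

    ``sample`` must supply a call (possibly NOCALL) for *every* SNP in
    ``tree.snp_set``; a missing entry is a contract violation, distinct from
    an observed NoCall.  By default the tree abstains if any of its SNPs is
    NoCall, even off the realized traversal path; ``path_only=True`` abstains
    only when a NoCall is actually encountered while descending.
    """
    absent = [s for s in tree.snp_set if s not in sample]
    if absent:
        raise KeyError(f"sample lacks entries for tree SNPs: {sorted(absent)}")
    if not path_only and any(sample[s] == NOCALL for s in tree.snp_set):
        return ABSTAIN
    node = tree.root
    while not node.is_leaf:
        code = sample[node.snp_id]
        if code == NOCALL:
            return ABSTAIN
        node = node.left if code in node.left_genotypes else node.right
    return node.label


def tree_to_rules(tree: DecisionTree) -> list[str]:
    """One human-readable ``IF ... THEN population = ...`` rule per leaf."""
    rules: list[str] = []

    def fmt(snp_id, gset, negate):
        codes = sorted(gset)
        if negate:
            codes = sorted({HOM_MAJOR, HET, HOM_MINOR} - set(gset))
        toks = ",".join(CODE_TO_TOKEN[g] for g in codes)
        return f"{snp_id} in {{{toks}}}"

    def walk(node, conds):
        if node.is_leaf:
            cond = " AND ".join(conds) if conds else "TRUE"
            rules.append(f"IF {cond} THEN population = {node.label}")
            return
        walk(node.left, conds + [fmt(node.snp_id, node.left_genotypes, False)])
        walk(node.right, conds + [fmt(node.snp_id, node.left_genotypes, True)])

    walk(tree.root, [])
    return rules
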