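"""Single-tree learning, prediction with abstention, rule export."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethnopred import (
    ABSTAIN, PopulationLabels, TreeParams,
    gini_impurity, learn_tree, predict_tree, tree_to_rules,
)
from ethnopred.cart import BIPARTITIONS, DecisionTree, TreeNode
from ethnopred.genotype_io import (
    GenotypeMatrix, HET, HOM_MAJOR, HOM_MINOR, NOCALL,
)

from conftest import make_matrix


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ((50, 50), 0.5),
        ((100, 0, 0), 0.0),
    ])
    def test_known_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_matches_direct_formula(self):
        counts = (90, 45, 135)
        n = sum(counts)
        oracle = 1.0 - sum((c / n) ** 2 for c in counts)
        assert gini_impurity(counts) == pytest.approx(oracle)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 500), min_size=2, max_size=5)
           .filter(lambda c: sum(c) > 0))
    def test_bounds_and_purity(self, counts):
        g = gini_impurity(counts)
        assert 0.0 <= g < 1.0
        if max(counts) == sum(counts):
            assert g == pytest.approx(0.0)


def _labels(matrix, classes):
    assignment = {s: classes[i] for i, s in enumerate(matrix.samples)}
    return PopulationLabels(tuple(dict.fromkeys(classes)), assignment)


class TestLearnTree:
    def test_perfectly_separable_single_split(self, separable_matrix):
        matrix, labels = separable_matrix
        tree = learn_tree(matrix, labels, params=TreeParams(prune="none",
                                                            min_leaf_size=1))
        assert tree.snp_set == {"rs0"}
        assert not tree.root.is_leaf and tree.root.left.is_leaf
        preds = [predict_tree(tree, matrix.sample_calls(s))
                 for s in matrix.samples]
        truth = [labels.assignment[s] for s in matrix.samples]
        assert preds == truth

    def test_uninformative_features_give_single_leaf(self):
        m = make_matrix([["A_A", "A_B"]] * 8)
        labels = _labels(m, ["X"] * 4 + ["Y"] * 4)
        tree = learn_tree(m, labels, params=TreeParams(prune="none"))
        assert tree.root.is_leaf
        assert tree.root.label == "X"  # tie broken toward earlier class

    def test_xor_structure_learned(self):
        # class = parity of two dominant-coded SNPs; 4 balanced cells; the
        # first split has zero gain yet the tree must still separate fully
        rows, classes = [], []
        for g1 in ("A_A", "B_B"):
            for g2 in ("A_A", "B_B"):
                for _ in range(5):
                    rows.append([g1, g2])
                    classes.append("X" if (g1 == "B_B") ^ (g2 == "B_B") else "Y")
        m = make_matrix(rows)
        labels = _labels(m, classes)
        tree = learn_tree(m, labels, params=TreeParams(prune="none",
                                                       min_leaf_size=1))
        internal = sum(1 for r in tree_to_rules(tree)) - 1  # leaves - 1
        assert internal >= 2
        preds = [predict_tree(tree, m.sample_calls(s)) for s in m.samples]
        assert preds == classes

    def test_training_labels_reproduced_when_consistent(self, three_pop):
        matrix, labels, _ = three_pop
        tree = learn_tree(matrix, labels,
                          params=TreeParams(prune="none", min_leaf_size=1))
        # genotype rows are unique with overwhelming probability at 300 SNPs
        preds = [predict_tree(tree, matrix.sample_calls(s))
                 for s in matrix.samples]
        truth = [labels.assignment[s] for s in matrix.samples]
        assert preds == truth

    def test_nocall_in_training_rejected(self):
        m = make_matrix([["NoCall"], ["A_A"]])
        labels = _labels(m, ["X", "Y"])
        with pytest.raises(ValueError, match="NoCall"):
            learn_tree(m, labels)

    def test_single_class_yields_leaf_with_warning(self):
        m = make_matrix([["A_A"], ["B_B"]])
        labels = PopulationLabels(("X", "Y"), {"S0": "X", "S1": "X"})
        with pytest.warns(UserWarning, match="single-class"):
            tree = learn_tree(m, labels, params=TreeParams(prune="none"))
        assert tree.root.is_leaf and tree.root.label == "X"

    def test_candidate_iteration_order_irrelevant(self, three_pop):
        # ties are broken by matrix column position, so the order in which
        # the candidate pool is supplied must not matter
        matrix, labels, _ = three_pop
        ids = list(matrix.snp_ids)
        rng = np.random.default_rng(0)
        shuffled = list(ids)
        rng.shuffle(shuffled)
        t1 = learn_tree(matrix, labels, allowed_snps=ids,
                        params=TreeParams(prune="none"))
        t2 = learn_tree(matrix, labels, allowed_snps=shuffled,
                        params=TreeParams(prune="none"))
        assert t1 == t2

    def test_column_permutation_preserves_fit_quality(self, three_pop):
        # permuting columns may swap gain-tied SNPs but never changes how
        # well the learned tree fits the training data
        matrix, labels, _ = three_pop
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_snps)
        permuted = GenotypeMatrix(matrix.samples,
                                  tuple(matrix.snps[j] for j in perm),
                                  matrix.calls[:, perm])
        t1 = learn_tree(matrix, labels, params=TreeParams(prune="none"))
        t2 = learn_tree(permuted, labels, params=TreeParams(prune="none"))
        truth = [labels.assignment[s] for s in matrix.samples]
        acc1 = np.mean([predict_tree(t1, matrix.sample_calls(s)) == c
                        for s, c in zip(matrix.samples, truth)])
        acc2 = np.mean([predict_tree(t2, permuted.sample_calls(s)) == c
                        for s, c in zip(matrix.samples, truth)])
        assert acc1 == pytest.approx(acc2)

    def test_no_split_increases_impurity(self, three_pop):
        # every internal node's split has nonnegative weighted Gini decrease,
        # and pure nodes are leaves
        matrix, labels, _ = three_pop
        tree = learn_tree(matrix, labels, params=TreeParams(prune="none"))

        def visit(node):
            counts = np.array(node.class_counts, dtype=float)
            if node.is_leaf:
                return
            parent_g = gini_impurity(counts)
            assert counts.max() < counts.sum()  # impure, else leaf
            lc = np.array(node.left.class_counts, dtype=float)
            rc = np.array(node.right.class_counts, dtype=float)
            child_g = (lc.sum() * gini_impurity(lc)
                       + rc.sum() * gini_impurity(rc)) / counts.sum()
            assert child_g <= parent_g + 1e-9
            visit(node.left)
            visit(node.right)

        visit(tree.root)

    def test_pruning_never_enlarges_tree(self, three_pop):
        matrix, labels, _ = three_pop
        full = learn_tree(matrix, labels, params=TreeParams(prune="none"))
        pruned = learn_tree(matrix, labels,
                            params=TreeParams(prune="cost_complexity_1se"))
        assert pruned.n_leaves <= full.n_leaves

    def test_matches_sklearn_on_separable_fixture(self, separable_matrix):
        # independent CART implementation reaches the same training accuracy
        sklearn = pytest.importorskip("sklearn.tree")
        matrix, labels = separable_matrix
        X = np.stack([(matrix.calls == g).astype(float)
                      for g in (HOM_MAJOR, HET, HOM_MINOR)], axis=2
                     ).reshape(matrix.n_samples, -1)
        y = labels.encoded(matrix.samples)
        clf = sklearn.DecisionTreeClassifier(random_state=0).fit(X, y)
        ours = learn_tree(matrix, labels,
                          params=TreeParams(prune="none", min_leaf_size=1))
        our_preds = [predict_tree(ours, matrix.sample_calls(s))
                     for s in matrix.samples]
        our_acc = np.mean([p == labels.assignment[s]
                           for p, s in zip(our_preds, matrix.samples)])
        assert our_acc == pytest.approx(clf.score(X, y)) == 1.0


def _fixture_tree():
    """Hand-built 3-SNP tree over classes (P, Q, R)."""
    order = ("P", "Q", "R")
    leaf = lambda c: TreeNode.leaf({"P": [5, 0, 0], "Q": [0, 5, 0],
                                    "R": [0, 0, 5]}[c], order)
    n2 = TreeNode.internal("s1", BIPARTITIONS[1], leaf("P"), leaf("Q"),
                           (5, 5, 0))
    n3 = TreeNode.internal("s2", BIPARTITIONS[2], leaf("R"), leaf("Q"),
                           (0, 5, 5))
    root = TreeNode.internal("s0", BIPARTITIONS[0], n2, n3, (5, 10, 5))
    return DecisionTree(root, order)


class TestPredictTree:
    def test_abstains_on_off_path_nocall(self):
        tree = _fixture_tree()
        # sample routes left at root (never touches s2), but s2 is NoCall:
        # the whole tree must abstain
        sample = {"s0": HOM_MAJOR, "s1": HET, "s2": NOCALL}
        assert predict_tree(tree, sample) == ABSTAIN
        # path-only mode answers, for comparison
        assert predict_tree(tree, sample, path_only=True) == "P"

    def test_single_node_bipartition_routing(self, separable_matrix):
        matrix, labels = separable_matrix
        tree = learn_tree(matrix, labels, params=TreeParams(prune="none",
                                                            min_leaf_size=1))
        assert predict_tree(tree, {"rs0": HOM_MAJOR, "rs1": HET}) == "X"
        assert predict_tree(tree, {"rs0": HOM_MINOR, "rs1": HET}) == "Y"

    def test_exhaustive_traversal_matches_manual_oracle(self):
        tree = _fixture_tree()

        def oracle(g0, g1, g2):
            # independent manual traversal of the fixture layout
            if g0 == HOM_MAJOR:
                return "P" if g1 == HET else "Q"
            return "R" if g2 == HOM_MINOR else "Q"

        for g0 in (0, 1, 2):
            for g1 in (0, 1, 2):
                for g2 in (0, 1, 2):
                    got = predict_tree(tree, {"s0": g0, "s1": g1, "s2": g2})
                    assert got == oracle(g0, g1, g2)

    def test_missing_entry_is_contract_violation(self):
        tree = _fixture_tree()
        with pytest.raises(KeyError, match="s2"):
            predict_tree(tree, {"s0": 0, "s1": 0})


class TestRules:
    def test_single_leaf_one_rule(self):
        order = ("X",)
        tree = DecisionTree(TreeNode.leaf((7,), order), order)
        rules = tree_to_rules(tree)
        assert len(rules) == 1 and "TRUE" in rules[0]

    def test_three_internal_nodes_four_rules(self):
        rules = tree_to_rules(_fixture_tree())
        assert len(rules) == 4
        assert all(r.startswith("IF ") and " THEN population = " in r
                   for r in rules)

    def test_rule_count_equals_leaf_count(self, three_pop):
        matrix, labels, _ = three_pop
        tree = learn_tree(matrix, labels, params=TreeParams(prune="none"))
        assert len(tree_to_rules(tree)) == tree.n_leaves
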