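import numpy as np
import pytest

from ethnopred import (
    GenotypeMatrix, PopulationLabels, SnpRecord,
    SyntheticSpec, simulate_populations,
)
from ethnopred.cart import BIPARTITIONS, DecisionTree, TreeNode
from ethnopred.ensemble import DisjointEnsemble
from ethnopred.genotype_io import GENOTYPE_TOKENS


def make_matrix(token_rows, samples=None, snp_ids=None, chromosomes=None,
                alleles=None):
    """Build a GenotypeMatrix from rows of genotype tokens."""
    n = len(token_rows)
    L = len(token_rows[0]) if n else 0
    samples = samples or [f"S{i}" for i in range(n)]
    snp_ids = snp_ids or [f"rs{j}" for j in range(L)]
    chromosomes = chromosomes or [str(j % 22 + 1) for j in range(L)]
    alleles = alleles or [("A", "G")] * L
    snps = tuple(SnpRecord(snp_ids[j], chromosomes[j], 100 * (j + 1),
                           alleles[j][0], alleles[j][1]) for j in range(L))
    calls = np.array([[GENOTYPE_TOKENS[t] for t in row] for row in token_rows],
                     dtype=np.int8).reshape(n, L)
    return GenotypeMatrix(tuple(samples), snps, calls)


def make_random_ensemble(n_trees, n_classes=3, seed=0):
    """A structurally valid synthetic ensemble with disjoint random trees."""
    rng = np.random.default_rng(seed)
    class_order = tuple(f"C{i}" for i in range(n_classes))
    trees, alleles = [], {}
    sid = 0
    for _ in range(n_trees):
        ids = []

        def leaf():
            counts = [0] * n_classes
            counts[int(rng.integers(n_classes))] = int(rng.integers(1, 20))
            return TreeNode.leaf(counts, class_order)

        def internal(depth):
            nonlocal sid
            if depth == 0 or rng.random() < 0.3:
                return leaf()
            name = f"rs{sid:05d}"
            sid += 1
            ids.append(name)
            left = internal(depth - 1)
            right = internal(depth - 1)
            counts = [a + b for a, b in zip(left.class_counts, right.class_counts)]
            b = BIPARTITIONS[int(rng.integers(3))]
            return TreeNode.internal(name, b, left, right, counts)

        root = internal(3)
        if root.is_leaf:  # ensure at least one internal node per tree
            name = f"rs{sid:05d}"
            sid += 1
            ids.append(name)
            other = leaf()
            counts = [a + b for a, b in zip(root.class_counts, other.class_counts)]
            root = TreeNode.internal(name, BIPARTITIONS[0], root, other, counts)
        trees.append(DecisionTree(root, class_order))
        for name in ids:
            alleles[name] = ("A", "G")
    return DisjointEnsemble(trees=tuple(trees), class_order=class_order,
                            snp_alleles=alleles, meta={"seed": seed})


@pytest.fixture(scope="session")
def three_pop():
    """Small three-population Balding-Nichols dataset, shared across tests."""
    spec = SyntheticSpec(n_populations=3, samples_per_population=60,
                         n_snps=300, fst=0.2, seed=7)
    matrix, labels, truth = simulate_populations(spec)
    return matrix, labels, truth


@pytest.fixture()
def separable_matrix():
    """One SNP fully determines the class."""
    rows = [["A_A", "A_B"]] * 10 + [["B_B", "A_B"]] * 10
    matrix = make_matrix(rows)
    labels = PopulationLabels(
        ("X", "Y"), {f"S{i}": ("X" if i < 10 else "Y") for i in range(20)})
    return matrix, labels
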