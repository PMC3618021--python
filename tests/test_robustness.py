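"""Missingness-robustness sizing mathematics."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from ethnopred import (
    TreeParams, avg_snps_per_tree, build_plan, coverage_prob,
    ensemble_confidence, min_ensemble_size_for_accuracy,
    min_trees_for_confidence, train_ensemble,
)

from conftest import make_random_ensemble

# the reference confidence column for m = 9 clean trees at per-tree coverage
# p = 0.59049, as printed (string form preserves the printed precision)
REFERENCE_CONFIDENCE = {
    1: "0", 2: "0", 3: "0", 4: "0", 5: "0", 6: "0", 7: "0", 8: "0",
    9: "0.873", 10: "4.09", 11: "10.676", 12: "20.566", 13: "32.716",
    14: "45.652", 15: "58.013", 16: "68.86", 17: "77.744", 18: "84.616",
    19: "89.682", 20: "93.265", 21: "95.71", 22: "97.328", 23: "98.369",
    24: "99.023", 25: "99.424", 26: "99.666", 27: "99.809", 28: "99.892",
    29: "99.94", 30: "99.967",
}


class TestCoverageProb:
    @pytest.mark.parametrize("n,u,expected", [
        (0, 0.1, 1.0),
        (1, 0.25, 0.75),
        (5, 0.1, 0.9 ** 5),
    ])
    def test_values(self, n, u, expected):
        assert coverage_prob(n, u) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            coverage_prob(-1, 0.1)
        with pytest.raises(ValueError):
            coverage_prob(2, 1.5)


class TestAvgSnpsPerTree:
    def test_recount_oracle(self):
        ens = make_random_ensemble(10, seed=5)
        brute = sum(len(t.snp_set) for t in ens.trees) / 10
        assert avg_snps_per_tree(ens) == pytest.approx(brute)

    def test_single_tree(self):
        ens = make_random_ensemble(1, seed=8)
        assert avg_snps_per_tree(ens) == len(ens.trees[0].snp_set)


class TestEnsembleConfidence:
    def test_reference_table_reproduced(self):
        for N, printed in REFERENCE_CONFIDENCE.items():
            c = ensemble_confidence(N, 9, 0.59049)
            if printed == "0":
                assert c == 0.0
            else:
                decimals = len(printed.split(".")[1])
                assert f"{c:.{decimals}f}" == printed, f"N={N}"

    def test_binomial_identities(self):
        p = 0.37
        assert ensemble_confidence(6, 6, p) == pytest.approx(100 * p ** 6)
        assert ensemble_confidence(17, 0, p) == 100.0
        assert ensemble_confidence(3, 9, p) == 0.0

    def test_monotone_in_N_p_and_m(self):
        grid_p = [0.2, 0.5, 0.8]
        for p in grid_p:
            cs = [ensemble_confidence(N, 4, p) for N in range(4, 25)]
            assert all(a <= b + 1e-9 for a, b in zip(cs, cs[1:]))
        for N in (10, 20):
            cs = [ensemble_confidence(N, m, 0.6) for m in range(0, N + 1)]
            assert all(a >= b - 1e-9 for a, b in zip(cs, cs[1:]))
        cs = [ensemble_confidence(12, 5, p) for p in np.linspace(0.05, 0.95, 10)]
        assert all(a <= b + 1e-9 for a, b in zip(cs, cs[1:]))

    def test_matches_monte_carlo_binomial_tails(self):
        rng = np.random.default_rng(42)
        for N, m, p in [(29, 9, 0.59049), (15, 9, 0.59049), (10, 3, 0.8),
                        (20, 5, 0.3)]:
            draws = rng.binomial(N, p, size=10**6)
            est = float(np.mean(draws >= m))
            se = float(np.sqrt(max(est * (1 - est), 1e-12) / 10**6))
            exact = ensemble_confidence(N, m, p) / 100.0
            assert abs(exact - est) <= 3 * se + 1e-9


class TestMinTrees:
    def test_reference_answer_is_29(self):
        assert min_trees_for_confidence(9, 0.59049, 99.9) == 29

    def test_certain_coverage(self):
        assert min_trees_for_confidence(1, 1.0, 99.9) == 1

    def test_scan_matches_exact_binomial_oracle(self):
        m, p, target = 3, 0.5, 95.0

        def tail(N):
            return 100 * sum(comb(N, i) * p**i * (1 - p)**(N - i)
                             for i in range(m, N + 1))

        N = m
        while tail(N) < target:
            N += 1
        assert min_trees_for_confidence(m, p, target) == N

    def test_zero_coverage_unreachable(self):
        with pytest.raises(ValueError):
            min_trees_for_confidence(2, 0.0, 50.0)


class TestMinEnsembleSize:
    def _oracle(self, oof, y, n_classes, size):
        accs = []
        for rows in combinations(range(oof.shape[0]), size):
            correct = 0
            for t in range(oof.shape[1]):
                tallies = [0] * n_classes
                for r in rows:
                    if oof[r, t] >= 0:
                        tallies[oof[r, t]] += 1
                if sum(tallies) == 0:
                    continue
                if tallies.index(max(tallies)) == y[t]:
                    correct += 1
            accs.append(100 * correct / oof.shape[1])
        return float(np.mean(accs))

    def test_all_perfect_trees(self):
        y = np.array([0, 1, 0, 1])
        oof = np.tile(y, (4, 1))
        res = min_ensemble_size_for_accuracy(oof, y, 2, 100.0)
        assert res.m == 1 and res.reachable

    def test_unreachable_target(self):
        y = np.zeros(4, dtype=int)
        oof = np.ones((3, 4), dtype=int)  # every tree always wrong
        res = min_ensemble_size_for_accuracy(oof, y, 2, 50.0)
        assert not res.reachable

    def test_exhaustive_enumeration_matches_oracle(self):
        # 5 trees with hand-fixed prediction tables over 8 samples
        rng = np.random.default_rng(11)
        y = rng.integers(0, 3, size=8)
        oof = rng.integers(-1, 3, size=(5, 8))
        res = min_ensemble_size_for_accuracy(oof, y, 3, 90.0,
                                             max_enumeration=100)
        for size, n_subsets, mean_acc in res.table:
            assert n_subsets == comb(5, size)
            assert mean_acc == pytest.approx(self._oracle(oof, y, 3, size))
        reachable_sizes = [s for s, _, a in res.table if a >= 90.0]
        if reachable_sizes:
            assert res.reachable and res.m == reachable_sizes[0]
        else:
            assert not res.reachable

    def test_sampling_mode_is_seeded(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=10)
        oof = rng.integers(-1, 2, size=(12, 10))
        a = min_ensemble_size_for_accuracy(oof, y, 2, 99.0, max_enumeration=5,
                                           n_samples_mc=50, seed=3)
        b = min_ensemble_size_for_accuracy(oof, y, 2, 99.0, max_enumeration=5,
                                           n_samples_mc=50, seed=3)
        assert a == b


class TestBuildPlan:
    def test_no_missingness_collapses_to_m(self):
        ens = make_random_ensemble(6, n_classes=2, seed=9)
        y = np.array([0, 1] * 5)
        oof = np.tile(y, (6, 1))
        plan = build_plan(ens, oof, y, u=0.0, acc_target=99.9,
                          conf_target=99.9)
        assert plan.p == 1.0 and plan.N == plan.m

    def test_perfect_trees_with_missingness(self):
        ens = make_random_ensemble(6, n_classes=2, seed=9)
        y = np.array([0, 1] * 5)
        oof = np.tile(y, (6, 1))
        plan = build_plan(ens, oof, y, u=0.1, acc_target=99.9,
                          conf_target=99.9)
        assert plan.m == 1
        p = coverage_prob(avg_snps_per_tree(ens), 0.1)
        assert plan.N == min_trees_for_confidence(1, p, 99.9)
        assert plan.p + plan.q == pytest.approx(1.0)

    def test_replaying_reference_constants(self):
        ens = make_random_ensemble(9, n_classes=3, seed=9)
        y = np.arange(9) % 3
        oof = np.tile(y, (9, 1))  # perfect trees; m=1 from accuracy...
        plan = build_plan(ens, oof, y, u=0.1, p_override=0.59049)
        # ...but the confidence search with the reference p and m=9 gives 29
        assert min_trees_for_confidence(9, plan.p, 99.9) == 29
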