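from itertools import combinations

import numpy as np
import pytest

from cytofp.diversity import Composition, DissimilarityMatrix
from cytofp.errors import AlignmentError, UndefinedStatisticError
from cytofp.evaluation import (
    bh_adjust,
    kendall_tau_b,
    lorenz_curve,
    mantel_test,
    mixture_strain_correlation,
    r_squared,
)
from cytofp.tables import CountTable


def tau_b_bruteforce(x, y):
    """Exhaustive pair enumeration of the tie-aware rank correlation."""
    nc = nd = nt = nu = 0
    for i, j in combinations(range(len(x)), 2):
        dx = np.sign(x[j] - x[i])
        dy = np.sign(y[j] - y[i])
        if dx == 0 and dy == 0:
            continue  # tied in both: counts in neither tie term
        if dx == 0:
            nt += 1
        elif dy == 0:
            nu += 1
        elif dx == dy:
            nc += 1
        else:
            nd += 1
    return (nc - nd) / np.sqrt((nc + nd + nt) * (nc + nd + nu))


class TestKendall:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = kendall_tau_b(x, x)
        assert res.tau_b == pytest.approx(1.0)

    def test_perfect_discordance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = kendall_tau_b(x, x[::-1])
        assert res.tau_b == pytest.approx(-1.0)

    def test_tied_example_vs_bruteforce(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 3.0])
        res = kendall_tau_b(x, y)
        assert res.tau_b == pytest.approx(tau_b_bruteforce(x, y), abs=1e-12)

    def test_random_tied_vectors_vs_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 25))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = kendall_tau_b(x, y)
            assert res.tau_b == pytest.approx(tau_b_bruteforce(x, y), abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(UndefinedStatisticError):
            kendall_tau_b([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_antisymmetric_in_negation(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = kendall_tau_b(x, y).tau_b
        b = kendall_tau_b(x, -y).tau_b
        assert a == pytest.approx(-b, abs=1e-12)

    def test_p_value_two_sided_in_range(self, rng):
        res = kendall_tau_b(rng.normal(size=30), rng.normal(size=30))
        assert 0 < res.p_value <= 1


class TestRSquared:
    def test_perfect(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_predictor(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_evaluation_negative(self):
        assert r_squared([1, 2, 3], [3, 2, 1]) == pytest.approx(-3.0)

    def test_constant_truth_error(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def random_dissimilarity(rng, n, ids=None):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.uniform(0.05, 1.0, size=len(iu[0]))
    m += m.T
    return DissimilarityMatrix(ids or [f"s{i}" for i in range(n)], m)


class TestMantel:
    def test_self_correlation(self, rng):
        m = random_dissimilarity(rng, 8)
        res = mantel_test(m, m, n_permutations=200, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 201)

    def test_statistic_is_uppertriangle_pearson(self, rng):
        m1 = random_dissimilarity(rng, 5)
        m2 = random_dissimilarity(rng, 5)
        res = mantel_test(m1, m2, n_permutations=10, seed=0)
        expected = np.corrcoef(m1.condensed(), m2.condensed())[0, 1]
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_raw_cross_product_reported(self, rng):
        m1 = random_dissimilarity(rng, 5)
        m2 = random_dissimilarity(rng, 5)
        res = mantel_test(m1, m2, n_permutations=10, seed=0)
        assert res.z_m == pytest.approx(np.sum(m1.values * m2.values), abs=1e-12)

    def test_joint_relabeling_invariance(self, rng):
        m1 = random_dissimilarity(rng, 7)
        m2 = random_dissimilarity(rng, 7)
        perm = rng.permutation(7)
        ids = [m1.sample_ids[i] for i in perm]
        m1p = DissimilarityMatrix(ids, m1.values[np.ix_(perm, perm)])
        m2p = DissimilarityMatrix(ids, m2.values[np.ix_(perm, perm)])
        a = mantel_test(m1, m2, n_permutations=10, seed=0).statistic
        b = mantel_test(m1p, m2p, n_permutations=10, seed=0).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_id_mismatch(self, rng):
        m1 = random_dissimilarity(rng, 4)
        m2 = random_dissimilarity(rng, 4, ids=["a", "b", "c", "d"])
        with pytest.raises(AlignmentError):
            mantel_test(m1, m2)

    def test_determinism(self, rng):
        m1 = random_dissimilarity(rng, 8)
        m2 = random_dissimilarity(rng, 8)
        a = mantel_test(m1, m2, n_permutations=100, seed=5)
        b = mantel_test(m1, m2, n_permutations=100, seed=5)
        assert a.p_value == b.p_value

    def test_p_value_floor(self, rng):
        m1 = random_dissimilarity(rng, 8)
        res = mantel_test(m1, m1, n_permutations=99, seed=0)
        assert res.p_value >= 1 / 100


class TestLorenz:
    def test_uniform_on_diagonal(self):
        c = Composition([f"u{i}" for i in range(4)], np.full(4, 0.25))
        curve = lorenz_curve(c)
        np.testing.assert_allclose(curve[:, 0], curve[:, 1], atol=1e-12)

    def test_hand_evaluation(self):
        c = Composition(["a", "b"], np.array([0.9, 0.1]))
        curve = lorenz_curve(c)
        np.testing.assert_allclose(
            curve, [[0.0, 0.0], [0.5, 0.1], [1.0, 1.0]], atol=1e-12
        )

    def test_endpoints_and_convexity(self, rng):
        for _ in range(10):
            p = rng.uniform(0.01, 1, size=8)
            c = Composition([f"u{i}" for i in range(8)], p / p.sum())
            curve = lorenz_curve(c)
            assert curve[0].tolist() == [0.0, 0.0]
            np.testing.assert_allclose(curve[-1], [1.0, 1.0], atol=1e-12)
            ys = curve[:, 1]
            assert np.all(np.diff(ys, 2) >= -1e-12)  # convex


class TestBH:
    def test_vs_bruteforce_stepup(self, rng):
        p = rng.uniform(size=10)
        got = bh_adjust(p)
        # brute-force step-up: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1
        order = np.argsort(p)
        m = len(p)
        expected = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            candidates = [
                p[order[j - 1]] * m / j for j in range(rank, m + 1)
            ]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_monotone_in_input_order(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


class TestMixtureStrainCorrelation:
    def make_tables(self, rng, n=20, k=4, s=3):
        truth_raw = rng.uniform(0.01, 1, size=(n, s))
        truth = CountTable.from_raw_counts(
            [f"s{i}" for i in range(n)], [f"strain{j}" for j in range(s)], truth_raw
        )
        # mixture 0 mirrors strain 0 exactly; the rest are noise
        fp_raw = rng.uniform(0.01, 1, size=(n, k))
        fp_raw[:, 0] = truth.counts[:, 0]
        fp = CountTable(
            [f"s{i}" for i in range(n)],
            [f"mix{j}" for j in range(k)],
            fp_raw,
            relative=False,
        )
        return fp, truth

    def test_identical_column_perfect_tau(self, rng):
        fp, truth = self.make_tables(rng)
        screen = mixture_strain_correlation(fp, truth)
        assert screen.tau[0, 0] == pytest.approx(1.0)
        assert screen.significant[0, 0]

    def test_constant_column_excluded(self, rng):
        fp, truth = self.make_tables(rng)
        fp.counts[:, 1] = 0.125
        screen = mixture_strain_correlation(fp, truth)
        assert np.all(np.isnan(screen.tau[1]))
        assert np.all(np.isnan(screen.p_adjusted[1]))

    def test_per_strain_counts(self, rng):
        fp, truth = self.make_tables(rng)
        screen = mixture_strain_correlation(fp, truth)
        counts = screen.significant_per_unit()
        assert counts["strain0"] >= 1
        assert (counts == screen.significant.sum(axis=0)).all()

    def test_false_discovery_control(self):
        # independent columns: any rejection is a false discovery
        rng = np.random.default_rng(123)
        sims_with_fd = 0
        n_sims = 40
        for _ in range(n_sims):
            fp = CountTable.from_raw_counts(
                [f"s{i}" for i in range(15)],
                [f"m{j}" for j in range(5)],
                rng.uniform(0.01, 1, size=(15, 5)),
            )
            truth = CountTable.from_raw_counts(
                [f"s{i}" for i in range(15)],
                [f"t{j}" for j in range(4)],
                rng.uniform(0.01, 1, size=(15, 4)),
            )
            screen = mixture_strain_correlation(fp, truth, alpha=0.05)
            if screen.significant.any():
                sims_with_fd += 1
        # under independence BH controls FDR (= FWER when all nulls) at 5%
        assert sims_with_fd / n_sims <= 0.15

    def test_sample_mismatch(self, rng):
        fp, truth = self.make_tables(rng)
        truth2 = CountTable(
            [f"x{i}" for i in range(truth.n_samples)],
            truth.component_ids,
            truth.counts,
            relative=truth.relative,
        )
        with pytest.raises(AlignmentError):
            mixture_strain_correlation(fp, truth2)
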