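"""MI/CMI estimation, QUBO construction, Ising mapping and solvers."""

import itertools

import numpy as np
import pytest

from qradbrain.qubo import (
    QuboProblem,
    build_q_matrix,
    estimate_cmi,
    estimate_mi,
    qubo_energy,
    select_features,
    solve_anneal,
    solve_exhaustive,
    to_ising,
    QuboFeatureSelector,
)


class TestMiEstimator:
    def test_identity_binary_one_bit(self, rng):
        x = rng.integers(0, 2, 1000)
        assert estimate_mi(x, x) == pytest.approx(1.0, abs=0.02)

    def test_independent_near_zero(self, rng):
        x = rng.standard_normal(10000)
        y = rng.integers(0, 2, 10000) * 2 - 1
        assert estimate_mi(x, y) < 0.01

    def test_hand_evaluated_joint_counts(self):
        # joint counts [[30, 10], [10, 30]] over (x, y)
        x = np.repeat([0, 0, 1, 1], [30, 10, 10, 30])
        y = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
        p = np.array([[30, 10], [10, 30]]) / 80.0
        px, py = p.sum(1), p.sum(0)
        expected = sum(
            p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
            for i in range(2) for j in range(2)
        )
        assert estimate_mi(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_y_is_zero(self, rng):
        assert estimate_mi(rng.standard_normal(100), np.zeros(100)) == 0.0

    def test_consistency_on_known_distribution(self, rng):
        # X binary, Y = X flipped w.p. 0.2 -> I = 1 - H(0.2) bits
        exact = 1.0 + 0.8 * np.log2(0.8) + 0.2 * np.log2(0.2)
        errs = []
        for n in (100, 1000, 10000):
            x = rng.integers(0, 2, n)
            flip = rng.random(n) < 0.2
            y = x ^ flip
            errs.append(abs(estimate_mi(x, y) - exact))
        assert errs[2] < errs[0] and errs[2] < 0.02


class TestCmiEstimator:
    def test_constant_z_reduces_to_mi(self, rng):
        x = rng.standard_normal(500)
        y = rng.integers(0, 2, 500)
        z = np.zeros(500)
        assert estimate_cmi(x, y, z) == pytest.approx(
            estimate_mi(x, y), abs=1e-12)

    def test_xor_truth_table_exactly_one_bit(self):
        tbl = np.array(list(itertools.product([0, 1], [0, 1])))
        x = np.repeat(tbl[:, 0], 10)
        z = np.repeat(tbl[:, 1], 10)
        y = x ^ z
        assert estimate_cmi(x, y, z) == pytest.approx(1.0, abs=1e-12)

    def test_independent_near_zero(self, rng):
        x = rng.standard_normal(10000)
        y = rng.integers(0, 2, 10000)
        z = rng.standard_normal(10000)
        assert estimate_cmi(x, y, z) < 0.02


class TestQMatrix:
    def test_single_feature_is_marginal_mi(self, rng):
        X = rng.standard_normal((200, 1))
        y = rng.integers(0, 2, 200)
        Q = build_q_matrix(X, y)
        assert Q.shape == (1, 1)
        assert Q[0, 0] == pytest.approx(estimate_mi(X[:, 0], y), abs=1e-12)

    def test_xor_pair_off_diagonal_dominates(self, rng):
        n = 4000
        a = rng.choice([-1.0, 1.0], n) * np.abs(rng.standard_normal(n))
        b = rng.choice([-1.0, 1.0], n) * np.abs(rng.standard_normal(n))
        y = (np.sign(a) * np.sign(b)).astype(int)
        noise = rng.standard_normal(n)
        Q = build_q_matrix(np.column_stack([a, b, noise]), y)
        assert Q[0, 1] > 0.8 and Q[1, 0] > 0.8
        assert Q[0, 0] < 0.05 and Q[1, 1] < 0.05

    def test_permutation_consistency(self, rng):
        X = rng.standard_normal((300, 4))
        y = rng.integers(0, 2, 300)
        Q = build_q_matrix(X, y)
        perm = [2, 0, 3, 1]
        Qp = build_q_matrix(X[:, perm], y)
        assert np.allclose(Qp, Q[np.ix_(perm, perm)], atol=1e-12)


class TestEnergyAndIsing:
    def test_zero_state_energy_is_penalty(self):
        prob = QuboProblem(np.eye(3), k=2, alpha=0.5)
        assert qubo_energy(prob, [0, 0, 0]) == pytest.approx(0.5 * 4)

    def test_hand_arithmetic_two_features(self):
        prob = QuboProblem(np.eye(2), k=2, alpha=0.0)
        assert qubo_energy(prob, [1, 1]) == pytest.approx(-2.0)

    def test_matches_naive_double_loop(self, rng):
        p = 7
        Q = np.abs(rng.standard_normal((p, p)))
        prob = QuboProblem(Q, k=3, alpha=0.7)
        for _ in range(10):
            x = rng.integers(0, 2, p)
            naive = (
                -sum(Q[i, i] * x[i] for i in range(p))
                - sum((Q[i, j] + Q[j, i]) * x[i] * x[j]
                      for i in range(p) for j in range(i + 1, p))
                + 0.7 * (x.sum() - 3) ** 2
            )
            assert qubo_energy(prob, x) == pytest.approx(naive, abs=1e-12)

    def test_ising_single_variable_closed_form(self):
        q = 0.8
        prob = QuboProblem([[q]], k=1, alpha=0.0)
        h, J, offset = to_ising(prob)
        assert h[0] == pytest.approx(q / 2.0)
        assert offset == pytest.approx(-q / 2.0)

    @pytest.mark.parametrize("alpha", [0.0, 1.3])
    def test_ising_equivalence_all_states(self, rng, alpha):
        p = 6
        Q = np.abs(rng.standard_normal((p, p)))
        prob = QuboProblem(Q, k=2, alpha=alpha)
        h, J, offset = to_ising(prob)
        for bits in itertools.product([0, 1], repeat=p):
            x = np.array(bits)
            s = 1 - 2 * x
            ising = h @ s + s @ J @ s + offset
            assert qubo_energy(prob, x) == pytest.approx(ising, abs=1e-10)


class TestSolvers:
    def test_diagonal_only_hard_constraint_picks_top_k(self):
        Q = np.diag([0.1, 0.9, 0.3, 0.7, 0.5])
        sol = solve_exhaustive(QuboProblem(Q, k=3, alpha=0.0),
                               hard_constraint=True)
        assert sol.indices == [1, 3, 4]
        assert sol.cardinality == 3

    def test_xor_pair_beats_noise_feature(self):
        # diagonal weak, strong coupling between features 0 and 1
        Q = np.array([[0.01, 0.9, 0.0],
                      [0.9, 0.01, 0.0],
                      [0.0, 0.0, 0.05]])
        sol = solve_exhaustive(QuboProblem(Q, k=2, alpha=10.0))
        assert sol.indices == [0, 1]

    def test_optimality_against_random_states(self, rng):
        p = 10
        Q = np.abs(rng.standard_normal((p, p)))
        prob = QuboProblem(Q, k=4, alpha=1.0)
        sol = solve_exhaustive(prob)
        for _ in range(1000):
            x = rng.integers(0, 2, p)
            assert sol.energy <= qubo_energy(prob, x) + 1e-12

    def test_energy_recomputable_from_configuration(self, rng):
        Q = np.abs(rng.standard_normal((8, 8)))
        prob = QuboProblem(Q, k=3, alpha=2.0)
        for sol in (solve_exhaustive(prob),
                    solve_anneal(prob, reads=20, sweeps=30, seed=0)):
            assert qubo_energy(prob, sol.x) == pytest.approx(
                sol.energy, abs=1e-10)

    def test_anneal_monotone_in_reads(self, rng):
        Q = np.abs(rng.standard_normal((12, 12)))
        prob = QuboProblem(Q, k=5, alpha=1.0)
        e1 = solve_anneal(prob, reads=10, sweeps=20, seed=3).energy
        e2 = solve_anneal(prob, reads=20, sweeps=20, seed=3).energy
        assert e2 <= e1 + 1e-12

    def test_single_frozen_read_bounded_by_oracle(self, rng):
        Q = np.abs(rng.standard_normal((8, 8)))
        prob = QuboProblem(Q, k=3, alpha=1.0)
        greedy = solve_anneal(prob, reads=1, sweeps=5,
                              schedule=(1e-9, 1e-12), seed=0)
        assert greedy.energy >= solve_exhaustive(prob).energy - 1e-12

    def test_exhaustive_rejects_large_p(self):
        with pytest.raises(ValueError, match="anneal"):
            solve_exhaustive(QuboProblem(np.eye(23), k=2, alpha=0.0))


class TestSelectFeatures:
    def test_k_equals_p_selects_all(self, rng):
        X = rng.standard_normal((100, 4))
        y = rng.integers(0, 2, 100)
        assert select_features(X, y, k=4) == [0, 1, 2, 3]

    def test_auto_alpha_enforces_cardinality(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((200, 8))
            y = r.integers(0, 2, 200)
            assert len(select_features(X, y, k=3)) == 3

    def test_optimal_energy_non_increasing_in_k(self, rng):
        X = rng.standard_normal((300, 6))
        y = rng.integers(0, 2, 300)
        Q = build_q_matrix(X, y)
        energies = [
            solve_exhaustive(QuboProblem(Q, k=k, alpha=0.0),
                             hard_constraint=True).energy
            for k in range(1, 7)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_sklearn_selector_interface(self, rng):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        X = rng.standard_normal((150, 6))
        y = rng.integers(0, 2, 150) * 2 - 1
        pipe = Pipeline([("scale", StandardScaler()),
                         ("select", QuboFeatureSelector(k=3))])
        Xt = pipe.fit_transform(X, y)
        assert Xt.shape == (150, 3)
        sel = pipe.named_steps["select"]
        assert sel.solution_.cardinality == 3
        assert sel.q_matrix_.shape == (6, 6)
        assert np.all(np.diag(sel.q_matrix_) >= 0)
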