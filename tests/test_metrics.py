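"""Growth distortion, transition matrices, Procrustes and migration."""

import numpy as np
import pytest

from stoat import (CellTypePartition, GrowthVector, true_growth,
                   growth_distortion, transition_matrix,
                   growth_distortion_with_transitions, procrustes,
                   migration_metric, transition_graph, growth_vector,
                   simulate_1d)
from oracles import migration_loop, procrustes_grid_best, procrustes_objective


def _partition(labels):
    return CellTypePartition.from_labels(labels)


def _random_feasible(rng, n1, n2):
    Pi = rng.random((n1, n2))
    return Pi / Pi.sum(axis=0, keepdims=True) / n1


class TestTrueGrowth:
    def test_1d_design_counts(self):
        """A 30->60, B 71->41 out of 101: gamma_A = 1/101,
        gamma_B = -30/7171."""
        p1 = _partition(["A"] * 30 + ["B"] * 71)
        p2 = _partition(["A"] * 60 + ["B"] * 41)
        g = true_growth(p1, p2)
        assert g["A"] == pytest.approx(30 / (30 * 101))
        assert g["B"] == pytest.approx(-30 / (71 * 101))

    def test_identical_partitions_zero(self):
        p = _partition(["A", "A", "B"])
        assert all(v == 0.0 for v in true_growth(p, p).values())

    def test_mass_weighted_sum_is_total_change(self):
        p1 = _partition(["A"] * 3 + ["B"] * 5)
        p2 = _partition(["A"] * 6 + ["B"] * 4)
        g = true_growth(p1, p2)
        total = 3 * g["A"] + 5 * g["B"]
        assert total == pytest.approx((10 - 8) / 8)


class TestGrowthDistortion:
    def test_perfect_inference_zero(self):
        p1 = _partition(["A", "A", "B"])
        p2 = _partition(["A", "A", "A", "B"])
        g = true_growth(p1, p2)
        xi = np.array([g["A"], g["A"], g["B"]])
        gv = GrowthVector(xi=xi, n1=3)
        assert growth_distortion(gv, p1, p2) < 1e-25

    def test_zero_flux_on_1d_design(self):
        p1 = _partition(["A"] * 30 + ["B"] * 71)
        p2 = _partition(["A"] * 60 + ["B"] * 41)
        gv = GrowthVector(xi=np.zeros(101), n1=101)
        expected = 30 * (1 / 101) ** 2 + 71 * (30 / 7171) ** 2
        assert growth_distortion(gv, p1, p2) == pytest.approx(expected)

    def test_matches_loop(self, rng):
        labels1 = ["A", "B", "A", "B", "A"]
        labels2 = ["A", "B", "B", "A", "A", "B"]
        p1, p2 = _partition(labels1), _partition(labels2)
        xi = rng.normal(0, 0.05, 5)
        xi = np.maximum(xi, -1 / 5 + 1e-3)
        gv = GrowthVector(xi=xi, n1=5)
        g = true_growth(p1, p2)
        expected = sum((xi[i] - g[labels1[i]]) ** 2 for i in range(5))
        assert growth_distortion(gv, p1, p2) == pytest.approx(expected)

    def test_new_type_at_t2_redirects(self):
        p1 = _partition(["A", "A", "B"])
        p2 = _partition(["A", "B", "C"])
        gv = GrowthVector(xi=np.zeros(3), n1=3)
        with pytest.raises(ValueError, match="with_transitions"):
            growth_distortion(gv, p1, p2)


class TestTransitionMatrix:
    def test_block_diagonal_identity(self):
        labels = ["A", "A", "B", "B"]
        Pi = np.zeros((4, 4))
        Pi[0, 0] = Pi[1, 1] = Pi[2, 2] = Pi[3, 3] = 0.25
        tm = transition_matrix(Pi, _partition(labels), _partition(labels))
        np.testing.assert_allclose(tm.T, np.eye(2), atol=1e-12)

    def test_uniform_coupling_hand_value(self):
        """Types (2,2) -> (1,3) under the uniform coupling: every column
        splits its ancestry evenly between the two t1 types."""
        p1 = _partition(["A", "A", "B", "B"])
        p2 = _partition(["A", "B", "B", "B"])
        Pi = np.full((4, 4), 1 / 16)
        tm = transition_matrix(Pi, p1, p2)
        np.testing.assert_allclose(tm.T, 0.5, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_columns_stochastic_for_feasible_coupling(self, seed):
        rng = np.random.default_rng(seed)
        labels1 = list(rng.choice(["A", "B", "C"], size=6))
        labels2 = list(rng.choice(["A", "B", "C"], size=8))
        Pi = _random_feasible(rng, 6, 8)
        tm = transition_matrix(Pi, _partition(labels1), _partition(labels2))
        np.testing.assert_allclose(tm.T.sum(axis=0), 1.0, atol=1e-8)


class TestDistortionWithTransitions:
    def test_constant_within_type_zero(self):
        """A coupling that spreads each descendant evenly over its
        ancestral type (new types over all ancestors) gives a growth
        vector constant within each type, hence zero distortion."""
        labels1 = ["A", "A", "B", "B", "B"]
        labels2 = ["A", "B", "C", "B", "A"]
        p1, p2 = _partition(labels1), _partition(labels2)
        n1 = 5
        arr1 = np.array(labels1)
        Pi = np.zeros((5, 5))
        for j, t in enumerate(labels2):
            anc = np.nonzero(arr1 == t)[0]
            if anc.size == 0:  # type new at t2: uniform ancestry
                anc = np.arange(5)
            Pi[anc, j] = 1.0 / (n1 * anc.size)
        gv = growth_vector(Pi)
        d, _ = growth_distortion_with_transitions(gv, Pi, p1, p2)
        assert d < 1e-20

    def test_equals_within_type_sum_of_squares(self, rng):
        labels1 = list(rng.choice(["A", "B"], size=6))
        labels2 = list(rng.choice(["A", "B", "C"], size=7))
        p1, p2 = _partition(labels1), _partition(labels2)
        Pi = _random_feasible(rng, 6, 7)
        gv = growth_vector(Pi)
        d, _ = growth_distortion_with_transitions(gv, Pi, p1, p2)
        arr = np.array(labels1)
        expected = sum(((gv.xi[arr == t] - gv.xi[arr == t].mean()) ** 2).sum()
                       for t in set(labels1))
        assert d == pytest.approx(expected, abs=1e-10)

    def test_never_above_plain_distortion(self, rng):
        labels1 = ["A", "A", "A", "B", "B"]
        labels2 = ["A", "A", "B", "B", "B", "A"]
        p1, p2 = _partition(labels1), _partition(labels2)
        Pi = _random_feasible(rng, 5, 6)
        gv = growth_vector(Pi)
        d_t, _ = growth_distortion_with_transitions(gv, Pi, p1, p2)
        d_plain = growth_distortion(gv, p1, p2)
        assert d_t <= d_plain + 1e-12

    def test_minimal_over_random_transitions(self, rng):
        """The coupling-induced transition matrix achieves the minimum
        distortion over random column-stochastic alternatives."""
        labels1 = ["A", "A", "B", "B", "B"]
        labels2 = ["A", "B", "A", "B", "B", "A"]
        p1, p2 = _partition(labels1), _partition(labels2)
        Pi = _random_feasible(rng, 5, 6)
        gv = growth_vector(Pi)
        d_opt, tm = growth_distortion_with_transitions(gv, Pi, p1, p2)
        m1 = {t: labels1.count(t) for t in tm.row_types}
        m2 = np.array([labels2.count(t) for t in tm.col_types], dtype=float)
        arr = np.array(labels1)
        for _ in range(200):
            T = rng.random(tm.T.shape)
            T /= T.sum(axis=0, keepdims=True)
            d = 0.0
            for pi_, t in enumerate(tm.row_types):
                gamma_p = ((T[pi_] @ m2) - m1[t]) / (m1[t] * 5)
                d += ((gv.xi[arr == t] - gamma_p) ** 2).sum()
            assert d_opt <= d + 1e-12


class TestProcrustes:
    def _rigid(self, th, flip=False):
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return R @ np.diag([1.0, -1.0]) if flip else R

    @pytest.mark.parametrize("flip", [False, True])
    def test_recovers_known_rigid_motion(self, rng, flip):
        S1 = rng.random((8, 2)) * 10
        Q_true = self._rigid(0.6, flip)
        t = np.array([2.0, -3.0])
        # S2 such that Q S2 - h == S1  =>  S2 = Q^-1 (S1 + h)
        h_true = t
        S2 = (S1 + h_true) @ Q_true  # Q^-1 = Q^T for orthogonal
        Pi = np.eye(8) / 8
        Q, h = procrustes(S1, S2, Pi)
        mapped = S2 @ Q.T - h
        assert np.abs(mapped - S1).max() < 1e-10

    def test_self_registration_identity(self, rng):
        S = rng.random((6, 2))
        Q, h = procrustes(S, S, np.eye(6) / 6)
        np.testing.assert_allclose(Q, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(h, 0.0, atol=1e-9)

    def test_beats_rotation_grid_search(self, rng):
        S1 = rng.random((6, 2)) * 4
        S2 = rng.random((6, 2)) * 4
        Pi = rng.random((6, 6))
        Q, h = procrustes(S1, S2, Pi)
        ours = procrustes_objective(S1, S2, Pi, Q, h)
        grid = procrustes_grid_best(S1, S2, Pi)
        assert ours <= grid + 1e-9

    def test_rotation_only_flag(self, rng):
        S1 = rng.random((6, 2))
        S2 = rng.random((6, 2))
        Pi = rng.random((6, 6))
        Q, _ = procrustes(S1, S2, Pi, allow_reflection=False)
        assert np.linalg.det(Q) == pytest.approx(1.0)

    def test_collinear_warns(self):
        S = np.stack([np.arange(5.0), np.zeros(5)], axis=1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            procrustes(S, S, np.eye(5) / 5)


class TestMigration:
    def test_identity_matching_zero(self, rng):
        S = rng.random((5, 2))
        Pi = np.eye(5) / 5
        assert migration_metric(S, S, Pi) < 1e-20

    def test_rigid_motion_removed_by_procrustes(self, rng):
        S1 = rng.random((7, 2)) * 5
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        S2 = (S1 + np.array([1.0, 2.0])) @ R
        Pi = np.eye(7) / 7
        assert migration_metric(S1, S2, Pi) < 1e-18

    def test_matches_double_loop(self, rng):
        S1 = rng.random((3, 2))
        S2 = rng.random((3, 2))
        Pi = _random_feasible(rng, 3, 3)
        Q, h = procrustes(S1, S2, Pi)
        got = migration_metric(S1, S2, Pi, transform=(Q, h))
        assert got == pytest.approx(migration_loop(S1, S2 @ Q.T - h, Pi),
                                    abs=1e-12)

    def test_invariant_to_rigid_motion_of_slice2(self, rng):
        S1 = rng.random((6, 2)) * 3
        S2 = rng.random((6, 2)) * 3
        Pi = _random_feasible(rng, 6, 6)
        base = migration_metric(S1, S2, Pi)
        th = 2.2
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = migration_metric(S1, S2 @ R.T + np.array([5.0, -2.0]), Pi)
        assert abs(base - moved) < 1e-8

    def test_zero_column_skipped_with_warning(self, rng):
        S1 = rng.random((3, 2))
        S2 = rng.random((4, 2))
        Pi = _random_feasible(rng, 3, 4)
        Pi[:, 1] = 0.0
        with pytest.warns(UserWarning, match="zero columns"):
            migration_metric(S1, S2, Pi)


class TestTransitionGraph:
    def _tm(self, T, row_types, col_types):
        from stoat import TransitionMatrix
        return TransitionMatrix(T=np.asarray(T, dtype=float),
                                row_types=tuple(row_types),
                                col_types=tuple(col_types))

    def test_identity_gives_empty_graph(self):
        tm = self._tm(np.eye(3), "ABC", "ABC")
        assert transition_graph(tm) == []

    def test_single_strong_transition(self):
        tm = self._tm([[0.4, 0.6], [0.6, 0.4]], "AB", "AB")
        edges = transition_graph(tm, threshold=0.5)
        assert edges == [("A", "B", 0.6), ("B", "A", 0.6)]

    def test_zero_threshold_keeps_all_off_diagonal(self, rng):
        P1, P2 = 3, 3
        T = rng.random((P1, P2)) + 0.01
        T /= T.sum(axis=0, keepdims=True)
        tm = self._tm(T, "ABC", "ABC")
        edges = transition_graph(tm, threshold=0.0)
        assert len(edges) == P1 * P2 - min(P1, P2)


def test_ground_truth_coupling_has_zero_distortion():
    """The within-type-uniform ground-truth coupling of the noiseless 1D
    design reproduces the equal-share growth exactly."""
    s1, s2, truth = simulate_1d(seed=0)
    Pi = truth.uniform_coupling()
    gv = growth_vector(Pi)
    p1 = CellTypePartition.from_labels(s1.labels)
    p2 = CellTypePartition.from_labels(s2.labels)
    assert growth_distortion(gv, p1, p2) < 1e-12
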