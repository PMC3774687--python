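import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from thermotrack import ThermalFrame
from thermotrack.matching import (
    HeatSignature,
    ShapeStatistics,
    distance_matrix,
    greedy_assign,
    shape_sanity_check,
    update_heat_signatures,
    heat_assign,
    heat_costs,
)
from test_temporal_watershed import make_pose


def brute_force_global_min(costs):
    """Independent re-implementation of iterative global-min selection.

    Scans the full matrix with explicit loops, masking used rows/columns with
    None, ties broken by (row, col) order.
    """
    n = len(costs)
    used_r, used_c = set(), set()
    perm = {}
    for _ in range(n):
        best = None
        for i in range(n):
            if i in used_r:
                continue
            for j in range(n):
                if j in used_c:
                    continue
                if best is None or costs[i][j] < best[0]:
                    best = (costs[i][j], i, j)
        _, i, j = best
        perm[i] = j
        used_r.add(i)
        used_c.add(j)
    return np.array([perm[i] for i in range(n)])


class TestDistanceMatrix:
    def test_identical_pose_sets_zero_diagonal(self):
        poses = [make_pose((10.0, 10.0)), make_pose((40.0, 40.0), mouse_id=1)]
        d = distance_matrix(poses, poses)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_rigid_translation_six_dim_arithmetic(self):
        a = make_pose((10.0, 10.0))
        b = make_pose((13.0, 14.0))  # each keypoint displaced by (3,4): 5 px
        d = distance_matrix([a], [b])
        assert d[0, 0] == pytest.approx(np.sqrt(3) * 5.0, abs=1e-9)

    def test_swapped_distant_mice_offdiagonal_smaller(self):
        prev = [make_pose((10.0, 10.0)), make_pose((60.0, 60.0), mouse_id=1)]
        cur = [make_pose((60.0, 60.0)), make_pose((10.0, 10.0), mouse_id=1)]
        d = distance_matrix(prev, cur)
        assert d[0, 1] < d[0, 0] and d[1, 0] < d[1, 1]

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix([make_pose((0.0, 0.0))], [])


class TestGreedyAssign:
    def test_zero_diagonal_gives_identity(self):
        c = np.array([[0.0, 5, 6], [7, 0.0, 8], [9, 10, 0.0]])
        np.testing.assert_array_equal(greedy_assign(c), [0, 1, 2])

    @pytest.mark.parametrize(
        "costs,expected",
        [([[1.0, 10.0], [10.0, 2.0]], [0, 1]), ([[5.0, 1.0], [2.0, 9.0]], [1, 0])],
    )
    def test_small_examples(self, costs, expected):
        np.testing.assert_array_equal(greedy_assign(np.array(costs)), expected)

    def test_matches_brute_force_on_seeded_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 5))
            c = rng.random((n, n))
            np.testing.assert_array_equal(greedy_assign(c), brute_force_global_min(c))

    def test_bijection_always_and_hungarian_agreement_on_tracking_matrices(self):
        """Greedy is a bijection on any input and recovers the optimal
        assignment on distance-structured matrices (small same-identity
        costs, large cross-identity costs), the regime tracking produces."""
        rng = np.random.default_rng(7)
        agree = 0
        n_trials = 500
        for _ in range(n_trials):
            c = rng.uniform(5.0, 50.0, size=(3, 3))
            np.fill_diagonal(c, rng.uniform(0.0, 4.0, size=3))
            shuffle = rng.permutation(3)
            c = c[:, shuffle]
            perm = greedy_assign(c)
            assert sorted(perm) == [0, 1, 2]  # bijection, always
            _, col = linear_sum_assignment(c)
            agree += np.array_equal(perm, col)
        assert agree / n_trials >= 0.90

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.integers(2, 5).flatmap(
            lambda n: st.lists(
                st.lists(st.integers(0, 10**6), min_size=n, max_size=n),
                min_size=n,
                max_size=n,
            )
        ),
        st.integers(-1000, 1000),
    )
    def test_bijection_and_shift_invariance(self, rows, shift):
        """Greedy output is always a bijection, and adding a constant to all
        costs never changes the assignment (exact for integer costs)."""
        c = np.asarray(rows, dtype=float)
        perm = greedy_assign(c)
        assert sorted(perm) == list(range(len(c)))
        np.testing.assert_array_equal(perm, greedy_assign(c + shift))

    def test_greedy_optimal_when_choices_consistent_with_optimum(self):
        """Whenever each greedily chosen entry belongs to the (unique) optimal
        assignment, greedy and Hungarian coincide exactly."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(500):
            c = rng.random((4, 4))
            perm = greedy_assign(c)
            row, col = linear_sum_assignment(c)
            optimal = dict(zip(row, col))
            if all(optimal[i] == j for i, j in enumerate(perm)):
                checked += 1
                assert np.array_equal(perm, col)
        assert checked > 100  # the condition holds often enough to be informative


class TestShapeSanity:
    def _stats(self, rng, n=300, loc=0.23, scale=0.005):
        s = ShapeStatistics(alpha=0.01, min_shapes=100, refit_every=100)
        s.add(rng.normal(loc, scale, size=n))
        return s

    def test_cold_start_all_false(self):
        s = ShapeStatistics(min_shapes=100)
        flags, glob = shape_sanity_check(s, [0.5, 0.9])
        assert not flags.any() and not glob

    def test_mean_value_not_flagged(self):
        s = self._stats(np.random.default_rng(0))
        flags, _ = shape_sanity_check(s, [0.23])
        assert not flags[0]

    def test_extreme_value_flagged_and_global_needs_two(self):
        s = self._stats(np.random.default_rng(1))
        flags, glob = shape_sanity_check(s, [0.8, 0.23])
        assert flags[0] and not flags[1]
        assert not glob  # exactly one deviating mouse does not raise the state
        flags, glob = shape_sanity_check(s, [0.8, 0.9])
        assert glob


class TestHeatSignatures:
    def test_buffer_spans_exactly_B_frames(self):
        sig = HeatSignature(mouse_id=0, buffer_frames=9)
        for i in range(10):
            sig.add(np.full(5, float(i)))
        assert sig.n_frames == 9
        assert sig.samples.min() == 1.0  # frame 0 evicted

    def test_constant_signature_step_ecdf(self):
        sig = HeatSignature(mouse_id=0, buffer_frames=3)
        sig.add(np.full(20, 25.0))
        assert set(np.unique(sig.samples)) == {25.0}

    def test_update_collects_in_shape_samples(self):
        frame = ThermalFrame(np.arange(16, dtype=float).reshape(4, 4), index=0)
        shape = np.zeros((4, 4), bool)
        shape[0, :2] = True
        sigs = [HeatSignature(mouse_id=0)]
        update_heat_signatures(sigs, frame, [shape])
        np.testing.assert_array_equal(np.sort(sigs[0].samples), [0.0, 1.0])

    def test_identical_samples_ks_zero_identity(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(25.0, 0.5, 200)
        sig = HeatSignature(mouse_id=0)
        sig.add(samples)
        costs = heat_costs([samples], [sig])
        assert costs[0, 0] == 0.0

    def test_disjoint_supports_undo_swap(self):
        rng = np.random.default_rng(4)
        a = rng.normal(25.0, 0.1, 500)
        b = rng.normal(35.0, 0.1, 500)
        sig_a = HeatSignature(mouse_id=0)
        sig_b = HeatSignature(mouse_id=1)
        sig_a.add(a)
        sig_b.add(b)
        # labels swapped upstream: current shape 0 carries b's temperatures
        perm = heat_assign([b[:100], a[:100]], [sig_a, sig_b])
        np.testing.assert_array_equal(perm, [1, 0])

    def test_same_distribution_identity_in_most_trials(self):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(100):
            a = rng.normal(25.0, 0.5, 400)
            b = rng.normal(26.0, 0.5, 400)
            sa, sb = HeatSignature(0), HeatSignature(1)
            sa.add(a)
            sb.add(b)
            perm = heat_assign(
                [rng.normal(25.0, 0.5, 150), rng.normal(26.0, 0.5, 150)], [sa, sb]
            )
            wins += np.array_equal(perm, [0, 1])
        assert wins >= 95

    def test_empty_shape_gets_sentinel_cost(self):
        sig = HeatSignature(mouse_id=0)
        sig.add(np.full(10, 25.0))
        costs = heat_costs([np.empty(0)], [sig])
        assert costs[0, 0] > 1.0
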