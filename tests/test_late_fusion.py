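"""Alternating-minimization consensus: exact update steps and convergence."""

import numpy as np
import pytest

import latefuse as lf
from latefuse.late_fusion import EmptyClusterWarning

from conftest import (
    enumerate_best_decision,
    masked_objective_bruteforce,
    random_fusion_instance,
)


def _agreeing_instance(n=6, k=2, p=2):
    labels = np.array([0, 0, 0, 1, 1, 1])
    mask = np.ones((n, p), dtype=int)
    assignments = [
        lf.ViewAssignment.from_labels(labels, mask[:, j] == 1, k, view_index=j)
        for j in range(p)
    ]
    decision = lf.ConsensusDecision.from_labels(labels, n_clusters=k)
    return labels, mask, assignments, decision


class TestObjective:
    def test_agreeing_views_with_own_partition_scores_zero(self):
        _, mask, assignments, decision = _agreeing_instance()
        centroids = lf.update_centroids(decision, assignments, mask)
        assert lf.objective(decision, centroids, assignments, mask) == 0.0

    def test_single_flipped_instance_costs_its_distance(self):
        labels, mask, assignments, decision = _agreeing_instance()
        flipped = labels.copy()
        flipped[0] = 1  # instance 0 disagrees in view 1 only
        assignments[1] = lf.ViewAssignment.from_labels(
            flipped, mask[:, 1] == 1, 2, view_index=1
        )
        centroids = lf.update_centroids(decision, assignments, mask)
        got = lf.objective(decision, centroids, assignments, mask)
        expected = masked_objective_bruteforce(labels, centroids, assignments, mask)
        assert got == pytest.approx(expected)
        assert got > 0

    def test_undefined_centroid_with_global_mean_fallback(self):
        # one view; sample 2 is masked out and is the only member of
        # consensus cluster 2, so that centroid has no visible members ->
        # fallback is the view's global mean e1, and the masked sample
        # contributes nothing to the objective
        mask = np.array([[1], [0]])
        z = lf.ViewAssignment.from_labels(np.array([0]), mask[:, 0] == 1, 2, 0)
        y = lf.ConsensusDecision.from_labels(np.array([0, 1]), n_clusters=2)
        m = lf.update_centroids(y, [z], mask, previous=None)
        assert m.defined[0, 0] and not m.defined[0, 1]
        np.testing.assert_allclose(m.centroids[0, 1], [1.0, 0.0])
        assert lf.objective(y, m, [z], mask) == pytest.approx(0.0)

    def test_masked_terms_contribute_exactly_zero(self, rng):
        for _ in range(10):
            assignments, mask, centroids, decision = random_fusion_instance(rng, 7, 3, 3)
            got = lf.objective(decision, centroids, assignments, mask)
            expected = masked_objective_bruteforce(
                decision.labels(), centroids, assignments, mask
            )
            assert got == pytest.approx(expected)


class TestUpdateDecision:
    def test_strict_argmin_assigns_lowest_cost_cluster(self):
        _, mask, assignments, decision = _agreeing_instance()
        centroids = lf.update_centroids(decision, assignments, mask)
        new, cost = lf.update_decision(centroids, assignments, mask, decision)
        np.testing.assert_array_equal(new.matrix, decision.matrix)
        assert (cost.matrix >= 0).all()

    def test_tied_costs_keep_previous_cluster(self):
        # two identical centroids -> every cost row tied; sticky keeps Y
        mask = np.ones((3, 1), dtype=int)
        z = lf.ViewAssignment.from_labels(np.array([0, 0, 0]), mask[:, 0] == 1, 2, 0)
        centroids = lf.CentroidSet(
            centroids=np.array([[[0.5, 0.5], [0.5, 0.5]]]),
            defined=np.ones((1, 2), dtype=bool),
        )
        prev = lf.ConsensusDecision.from_labels(np.array([1, 0, 1]), n_clusters=2)
        new, _ = lf.update_decision(centroids, [z], mask, prev)
        np.testing.assert_array_equal(new.matrix, prev.matrix)

    @pytest.mark.parametrize("trial", range(30))
    def test_attains_exhaustive_minimum(self, trial):
        rng = np.random.default_rng(2000 + trial)
        n, k, p = 5, 3, 2
        assignments, mask, centroids, decision = random_fusion_instance(rng, n, k, p)
        new, _ = lf.update_decision(centroids, assignments, mask, decision)
        got = lf.objective(new, centroids, assignments, mask)
        best, _ = enumerate_best_decision(centroids, assignments, mask, k)
        assert got == pytest.approx(best, abs=1e-9)

    def test_never_increases_objective(self, rng):
        for _ in range(10):
            assignments, mask, centroids, decision = random_fusion_instance(rng, 8, 3, 3)
            before = lf.objective(decision, centroids, assignments, mask)
            new, _ = lf.update_decision(centroids, assignments, mask, decision)
            after = lf.objective(new, centroids, assignments, mask)
            assert after <= before + 1e-12


class TestUpdateCentroids:
    def test_singleton_clusters_copy_their_rows(self):
        mask = np.ones((2, 1), dtype=int)
        z = lf.ViewAssignment.from_labels(np.array([0, 1]), mask[:, 0] == 1, 2, 0)
        y = lf.ConsensusDecision.from_labels(np.array([0, 1]), n_clusters=2)
        m = lf.update_centroids(y, [z], mask)
        np.testing.assert_allclose(m.centroids[0, 0], [1.0, 0.0])
        np.testing.assert_allclose(m.centroids[0, 1], [0.0, 1.0])
        assert m.defined.all()

    def test_masked_sample_leaves_centroid_undefined_and_retained(self):
        mask = np.array([[1], [0]])
        z = lf.ViewAssignment.from_labels(np.array([0]), mask[:, 0] == 1, 2, 0)
        y = lf.ConsensusDecision.from_labels(np.array([0, 1]), n_clusters=2)
        prev = lf.CentroidSet(
            centroids=np.array([[[0.2, 0.8], [0.7, 0.3]]]),
            defined=np.ones((1, 2), dtype=bool),
        )
        m = lf.update_centroids(y, [z], mask, previous=prev)
        assert not m.defined[0, 1]
        np.testing.assert_allclose(m.centroids[0, 1], [0.7, 0.3])

    def test_two_member_cluster_averages_one_hot_rows(self):
        mask = np.ones((4, 1), dtype=int)
        z = lf.ViewAssignment.from_labels(np.array([0, 1, 0, 1]), mask[:, 0] == 1, 2, 0)
        y = lf.ConsensusDecision.from_labels(np.array([0, 0, 1, 1]), n_clusters=2)
        m = lf.update_centroids(y, [z], mask)
        np.testing.assert_allclose(m.centroids[0, 0], [0.5, 0.5])

    def test_defined_centroids_are_convex_combinations(self, rng):
        for _ in range(10):
            assignments, mask, centroids, _ = random_fusion_instance(rng, 8, 3, 3)
            rows = centroids.centroids[centroids.defined]
            assert (rows >= -1e-12).all()
            np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("delta", [1e-3, 1e-1])
    def test_perturbing_any_defined_centroid_never_helps(self, rng, delta):
        for _ in range(5):
            assignments, mask, centroids, decision = random_fusion_instance(rng, 7, 3, 2)
            centroids = lf.update_centroids(decision, assignments, mask, previous=centroids)
            base = lf.objective(decision, centroids, assignments, mask)
            for j in range(centroids.n_views):
                for c in range(centroids.n_clusters):
                    if not centroids.defined[j, c]:
                        continue
                    for coord in range(centroids.n_clusters):
                        for sign in (+1, -1):
                            bumped = lf.CentroidSet(
                                centroids=centroids.centroids.copy(),
                                defined=centroids.defined.copy(),
                            )
                            bumped.centroids[j, c, coord] += sign * delta
                            assert (
                                lf.objective(decision, bumped, assignments, mask)
                                >= base - 1e-12
                            )


class TestFuse:
    def test_consistent_complete_views_are_a_fixed_point(self):
        _, mask, assignments, decision = _agreeing_instance()
        state = lf.fuse(assignments, mask, decision)
        assert state.converged
        assert state.n_iterations == 1
        assert state.objective_trace[-1] == 0.0
        np.testing.assert_array_equal(state.decision.matrix, decision.matrix)

    def test_objective_trace_is_non_increasing_and_converges(self, rng):
        for _ in range(10):
            assignments, mask, _, decision = random_fusion_instance(rng, 30, 3, 3)
            state = lf.fuse(assignments, mask, decision)
            trace = state.objective_trace
            assert state.converged and state.n_iterations < 200
            assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
            assert all(v >= 0 for v in trace)

    def test_permuting_one_views_columns_leaves_partition_unchanged(self, rng):
        assignments, mask, _, decision = random_fusion_instance(rng, 25, 3, 3)
        base = lf.fuse(assignments, mask, decision).decision
        permuted = list(assignments)
        perm = rng.permutation(3)
        permuted[1] = lf.ViewAssignment(
            matrix=assignments[1].matrix[:, perm], view_index=1
        )
        again = lf.fuse(permuted, mask, decision).decision
        np.testing.assert_array_equal(again.matrix, base.matrix)

    def test_fusion_improves_on_its_initialization_in_most_runs(self):
        wins = 0
        n_runs = 20
        for s in range(n_runs):
            data = lf.synthetic_multiview(
                lf.SyntheticSpec(n_samples=150, n_views=3, n_clusters=4, seed=s)
            )
            data.mask = lf.generate_mask(
                150, 3, lf.MissingnessSpec(epsilon=0.5, seed=s + 900)
            )
            assignments = lf.cluster_each_view(data, 4, seed=s)
            y0 = lf.build_initial_decision("zf", data, assignments, 4, seed=s)
            state = lf.fuse(assignments, data.mask, y0)
            if lf.nmi(state.decision.labels(), data.labels) >= lf.nmi(
                y0.labels(), data.labels
            ):
                wins += 1
        assert wins >= 0.9 * n_runs

    def test_invalid_max_iter_raises(self):
        _, mask, assignments, decision = _agreeing_instance()
        with pytest.raises(lf.DataValidationError):
            lf.fuse(assignments, mask, decision, max_iter=0)

    def test_empty_consensus_cluster_warns_but_persists(self):
        mask = np.ones((4, 1), dtype=int)
        z = lf.ViewAssignment.from_labels(np.array([0, 0, 0, 0]), mask[:, 0] == 1, 3, 0)
        y0 = lf.ConsensusDecision.from_labels(np.array([0, 0, 0, 0]), n_clusters=3)
        with pytest.warns(EmptyClusterWarning):
            state = lf.fuse([z], mask, y0)
        assert state.decision.n_clusters == 3
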