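"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive every quantity from first principles
(explicit loops, exhaustive enumeration) so they stay independent of the
vectorized implementation paths they check.
"""

import itertools

import numpy as np
import pytest

import latefuse as lf


def masked_objective_bruteforce(y_labels, centroids, assignments, mask):
    """Masked sum of per-view k-means objectives, by explicit triple loop.

    y_labels: per-sample consensus labels; centroids: CentroidSet;
    assignments: list of ViewAssignment; mask: N x P.
    """
    total = 0.0
    n, p = np.asarray(mask).shape
    for j in range(p):
        z = assignments[j].matrix
        for i in range(n):
            if mask[i][j] == 0:
                continue
            c = y_labels[i]
            diff = z[i].astype(float) - centroids.centroids[j, c]
            total += float(diff @ diff)
    return total


def enumerate_best_decision(centroids, assignments, mask, k):
    """Global minimum of the masked objective over all K^N assignments."""
    n = np.asarray(mask).shape[0]
    best = np.inf
    best_labels = None
    for combo in itertools.product(range(k), repeat=n):
        val = masked_objective_bruteforce(combo, centroids, assignments, mask)
        if val < best:
            best = val
            best_labels = combo
    return best, np.array(best_labels)


def kkm_objective_bruteforce(kernel, labels):
    """Discrete kernel k-means objective by per-point distance sums.

    sum_i ( K_ii - (2/N_c) sum_l K_il + (1/N_c^2) sum_{l,l'} K_ll' ) over
    each point's own cluster c, written without the trace shortcut.
    """
    kernel = np.asarray(kernel, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for c in set(labels.tolist()):
        idx = [i for i in range(len(labels)) if labels[i] == c]
        nc = len(idx)
        quad = sum(kernel[a, b] for a in idx for b in idx) / nc**2
        for i in idx:
            total += kernel[i, i] - 2.0 * sum(kernel[i, l] for l in idx) / nc + quad
    return total


def enumerate_best_2partition(kernel):
    """Global optimum of the discrete objective over all 2-partitions."""
    n = kernel.shape[0]
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        best = min(best, kkm_objective_bruteforce(kernel, labels))
    return best


def random_fusion_instance(rng, n, k, p):
    """Random (assignments, mask, centroids, decision) with valid invariants."""
    while True:
        mask = (rng.random((n, p)) > 0.3).astype(int)
        if (mask.sum(axis=1) > 0).all():
            break
    assignments = []
    for j in range(p):
        labels = rng.integers(0, k, size=int(mask[:, j].sum()))
        assignments.append(
            lf.ViewAssignment.from_labels(labels, mask[:, j] == 1, k, view_index=j)
        )
    decision = lf.ConsensusDecision.from_labels(rng.integers(0, k, size=n), n_clusters=k)
    centroids = lf.update_centroids(decision, assignments, mask, previous=None)
    return assignments, mask, centroids, decision


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_incomplete_data(rng):
    """3-view 4-cluster synthetic data with half the samples incomplete."""
    data = lf.synthetic_multiview(
        lf.SyntheticSpec(n_samples=120, n_views=3, n_clusters=4, seed=3)
    )
    data.mask = lf.generate_mask(
        data.n_samples, data.n_views, lf.MissingnessSpec(epsilon=0.5, seed=4)
    )
    return data
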