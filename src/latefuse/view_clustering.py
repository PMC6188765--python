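"""Spectral-relaxed kernel k-means on the visible instances of each view.

Kernel k-means minimizes the within-cluster sum of squares in the feature
space induced by a kernel K.  Dropping the discrete constraint and writing
U = Z L^{1/2} turns the problem into trace maximization max tr(U^T K U)
subject to U^T U = I, solved exactly by the top-K eigenvectors of K; plain
k-means on the rows of U then rounds the relaxation back to a partition.

Per-view clustering of incomplete data extracts the principal sub-kernel of
the visible instances, centers and scales it, clusters it, and scatters the
labels back into an N x K indicator whose missing rows are all-zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .data_model import (
    DataValidationError,
    DegenerateKernelWarning,
    MultiViewKernelData,
    ViewAssignment,
    _as_square_symmetric,
)


class TooFewVisibleInstancesError(DataValidationError):
    """A view has fewer visible instances than requested clusters."""


@dataclass
class KernelKMeansResult:
    """Labels + spectral embedding of one kernel k-means run.

    ``relaxed_objective`` is tr(U^T K U), i.e. the sum of the K largest
    eigenvalues of the kernel — the optimum of the relaxed problem, an upper
    bound on the discrete trace objective.  ``restart_inertias`` records the
    k-means inertia of every restart on the rows of U; labels come from the
    best restart.
    """

    labels: np.ndarray
    embedding: np.ndarray
    relaxed_objective: float
    restart_inertias: list[float]


def center_and_scale(kernel: np.ndarray) -> np.ndarray:
    """Double-center a kernel and scale its mean diagonal to 1.

    Computes H K H / s with H = I - 11^T/n and s = mean(diag(H K H)).
    Centering translates the implicit feature map to zero mean, so row sums
    of the output vanish; scaling fixes the mean squared feature norm at 1.
    If s <= 1e-12 the kernel collapsed under centering (constant features);
    scaling is skipped and a :class:`DegenerateKernelWarning` is emitted.
    """
    kernel = _as_square_symmetric(kernel)
    n = kernel.shape[0]
    row_mean = kernel.mean(axis=0, keepdims=True)
    total_mean = kernel.mean()
    centered = kernel - row_mean - row_mean.T + total_mean
    scale = np.trace(centered) / n
    if scale <= 1e-12:
        warnings.warn(
            "kernel collapses under centering (mean diagonal <= 1e-12); "
            "scaling skipped",
            DegenerateKernelWarning,
            stacklevel=2,
        )
        return centered
    return centered / scale


def _restart_seeds(seed: int, n_restarts: int) -> list[int]:
    """Decorrelated, reproducible per-restart k-means seeds."""
    ss = np.random.SeedSequence(seed & 0x7FFFFFFF)
    return [int(s) for s in ss.generate_state(n_restarts)]


def _lloyd_refine(
    kernel: np.ndarray, labels: np.ndarray, k: int, max_iter: int = 100
) -> np.ndarray:
    """Exact kernel-space Lloyd iterations from a given partition.

    Distance of point i to the implicit mean of cluster c:
    K_ii - (2/N_c) sum_{l in c} K_il + (1/N_c^2) sum_{l,l' in c} K_ll'.
    Empty clusters are repaired by seizing the point farthest from its
    current centroid.
    """
    labels = labels.copy()
    n = kernel.shape[0]
    diag = np.diag(kernel)
    for _ in range(max_iter):
        dist = np.empty((n, k))
        for c in range(k):
            idx = np.flatnonzero(labels == c)
            if idx.size == 0:
                dist[:, c] = np.inf
                continue
            dist[:, c] = (
                diag - 2.0 * kernel[:, idx].mean(axis=1) + kernel[np.ix_(idx, idx)].mean()
            )
        new = dist.argmin(axis=1)
        for c in range(k):
            if not (new == c).any():
                far = int(np.argmax(dist[np.arange(n), new]))
                new[far] = c
        if (new == labels).all():
            break
        labels = new
    return labels


def _single_move_refine(
    kernel: np.ndarray, labels: np.ndarray, k: int, max_sweeps: int = 50, tol: float = 1e-12
) -> np.ndarray:
    """First-improvement single-point move descent on the exact objective.

    Repeatedly moves any point whose relocation strictly decreases the
    discrete kernel k-means objective (Hartigan-style), never emptying a
    cluster; terminates at a single-move local optimum.
    """
    labels = labels.copy()
    n = kernel.shape[0]
    diag = np.diag(kernel)
    sums = np.array(
        [kernel[np.ix_(labels == c, labels == c)].sum() for c in range(k)]
    )
    counts = np.bincount(labels, minlength=k).astype(float)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            a = labels[i]
            if counts[a] <= 1:
                continue
            s = np.bincount(labels, weights=kernel[i], minlength=k)
            sum_a_without = sums[a] - 2.0 * s[a] + diag[i]
            # objective = tr(K) - sum_c sums_c / counts_c; a move improves it
            # iff it increases the subtracted total
            old_part = sums[a] / counts[a] + sums / counts
            new_part = sum_a_without / (counts[a] - 1.0) + (
                sums + 2.0 * s + diag[i]
            ) / (counts + 1.0)
            delta = new_part - old_part
            delta[a] = -np.inf
            b = int(np.argmax(delta))
            if delta[b] > tol:
                sums[a] = sum_a_without
                counts[a] -= 1.0
                sums[b] += 2.0 * s[b] + diag[i]
                counts[b] += 1.0
                labels[i] = b
                improved = True
        if not improved:
            break
    return labels


def _swap_refine(
    kernel: np.ndarray, labels: np.ndarray, k: int, max_steps: int = 100, tol: float = 1e-12
) -> np.ndarray:
    """Best-improvement pairwise-swap descent on the exact objective.

    Exchanges two points between clusters when the swap strictly decreases
    the discrete kernel k-means objective; escapes local optima that no
    single-point move can leave.  Each step costs one n x k matrix product
    plus an n x n delta evaluation.
    """
    labels = labels.copy()
    n = kernel.shape[0]
    diag = np.diag(kernel)
    for _ in range(max_steps):
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels] = 1.0
        s = kernel @ onehot  # s[i, c] = sum_{m in c} K_im
        counts = onehot.sum(axis=0)
        na = counts[labels]
        own = s[np.arange(n), labels]
        # delta_a[i, l]: change in the subtracted total for cluster A[i]
        # when i leaves and l enters; full swap gain = delta_a + delta_a.T
        m = s[:, labels].T  # m[i, l] = s[l, A[i]]
        delta_a = (
            diag[:, None] - 2.0 * own[:, None] + 2.0 * m - 2.0 * kernel + diag[None, :]
        ) / na[:, None]
        gain = delta_a + delta_a.T
        same = labels[:, None] == labels[None, :]
        gain[same] = -np.inf
        flat = int(np.argmax(gain))
        i, l = divmod(flat, n)
        if gain[i, l] <= tol:
            break
        labels[i], labels[l] = labels[l], labels[i]
    return labels


def _pair_move_refine(
    kernel: np.ndarray, labels: np.ndarray, k: int, max_steps: int = 100, tol: float = 1e-12
) -> np.ndarray:
    """Best-improvement descent over joint relocations of two same-cluster points.

    Moves a pair (i, l) sharing a cluster into a common target cluster when
    that strictly decreases the exact objective; covers coordinated escapes
    that neither single moves nor swaps can make.
    """
    labels = labels.copy()
    n = kernel.shape[0]
    diag = np.diag(kernel)
    for _ in range(max_steps):
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels] = 1.0
        s = kernel @ onehot
        counts = onehot.sum(axis=0)
        quads = (onehot * s).sum(axis=0)  # quads[c] = sum_{m,m' in c} K_mm'
        na = counts[labels]
        sa = quads[labels]
        own = s[np.arange(n), labels]
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        pair_quad = diag[:, None] + diag[None, :] + 2.0 * kernel
        # S_a after removing both i and l (shared cluster a)
        sa_new = sa[:, None] - 2.0 * (own[:, None] + own[None, :]) + pair_quad
        src_ok = same & (na[:, None] > 2)
        src_term = np.where(
            src_ok,
            sa_new / np.maximum(na[:, None] - 2.0, 1.0) - (sa / na)[:, None],
            -np.inf,
        )
        best_gain = tol
        best_move = None
        for b in range(k):
            into_b = labels == b
            sb_new = quads[b] + 2.0 * (s[:, b][:, None] + s[:, b][None, :]) + pair_quad
            dst_term = sb_new / (counts[b] + 2.0) - (
                quads[b] / counts[b] if counts[b] > 0 else 0.0
            )
            gain = np.where(~into_b[:, None], src_term + dst_term, -np.inf)
            flat = int(np.argmax(gain))
            i, l = divmod(flat, n)
            if gain[i, l] > best_gain:
                best_gain = gain[i, l]
                best_move = (i, l, b)
        if best_move is None:
            break
        i, l, b = best_move
        labels[i] = b
        labels[l] = b
    return labels


def _refine_partition(kernel: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Alternate the descent moves (Lloyd, single, swap, pair) until stable."""
    for _ in range(20):
        before = labels
        labels = _lloyd_refine(kernel, labels, k)
        labels = _single_move_refine(kernel, labels, k)
        labels = _swap_refine(kernel, labels, k)
        labels = _pair_move_refine(kernel, labels, k)
        if (labels == before).all():
            break
    return labels


def kernel_kmeans(
    kernel: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> KernelKMeansResult:
    """Cluster one (already preprocessed) kernel into k groups.

    The top-k eigenvectors of the kernel (descending eigenvalue order from a
    deterministic symmetric solver) form the embedding U.  Each restart runs
    k-means++ on the rows of U and then polishes the rounded partition with
    exact kernel-space Lloyd iterations, single-point move descent and
    pairwise-swap descent; the restart with the lowest exact discrete
    objective supplies the labels.
    Deterministic in (kernel, k, n_restarts, seed).  Note U itself is
    basis-arbitrary under eigenvalue ties; only the labels are contractual
    downstream.
    """
    kernel = _as_square_symmetric(kernel)
    n = kernel.shape[0]
    if k < 1 or n < k:
        raise TooFewVisibleInstancesError(
            f"too few visible instances: n={n} < k={k}" if n < k else f"invalid k={k}"
        )
    eigvals, eigvecs = scipy.linalg.eigh(kernel, subset_by_index=[n - k, n - 1])
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    embedding = eigvecs[:, order]

    best_labels = None
    best_objective = np.inf
    inertias: list[float] = []
    for rs in _restart_seeds(seed, n_restarts):
        km = KMeans(n_clusters=k, n_init=1, init="k-means++", random_state=rs)
        labels = km.fit_predict(embedding)
        inertias.append(float(km.inertia_))
        labels = _refine_partition(kernel, labels, k)
        obj = kernel_kmeans_objective(kernel, labels)
        if obj < best_objective:
            best_objective = obj
            best_labels = labels
    assert best_labels is not None
    return KernelKMeansResult(
        labels=np.asarray(best_labels, dtype=int),
        embedding=embedding,
        relaxed_objective=float(eigvals.sum()),
        restart_inertias=inertias,
    )


def kernel_kmeans_objective(kernel: np.ndarray, labels: np.ndarray) -> float:
    """Exact discrete kernel k-means objective tr(K) - sum_c (1/N_c) 1^T K_c 1.

    Evaluates the within-cluster sum of squares of the partition in the
    kernel-induced feature space; empty clusters contribute nothing.  Used to
    score discrete partitions (e.g. against enumeration oracles).
    """
    kernel = np.asarray(kernel, dtype=float)
    labels = np.asarray(labels, dtype=int)
    obj = float(np.trace(kernel))
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        obj -= kernel[np.ix_(idx, idx)].sum() / len(idx)
    return obj


def cluster_each_view(
    data: MultiViewKernelData,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> list[ViewAssignment]:
    """Kernel k-means per view on visible instances only.

    For each view j: extract the principal sub-kernel of visible instances,
    center and scale it, cluster with :func:`kernel_kmeans` under the derived
    seed ``seed + j``, and scatter labels back into an N x K indicator with
    all-zero rows at missing instances.
    """
    assignments: list[ViewAssignment] = []
    for j in range(data.n_views):
        visible = data.mask[:, j] == 1
        n_vis = int(visible.sum())
        if n_vis < k:
            raise TooFewVisibleInstancesError(
                f"view {j} has {n_vis} visible instances, fewer than k={k}"
            )
        sub = data.kernels[j][np.ix_(visible, visible)]
        result = kernel_kmeans(center_and_scale(sub), k, n_restarts=n_restarts, seed=seed + j)
        assignments.append(
            ViewAssignment.from_labels(result.labels, visible, k, view_index=j)
        )
    return assignments
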