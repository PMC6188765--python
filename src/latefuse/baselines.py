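"""Kernel-imputation baselines and initialization strategies.

Five standard ways to obtain a complete clustering of incomplete multiview
kernel data, used both as comparison methods and as sources of the initial
consensus decision Y^0 for late fusion:

* ``zero_fill`` (ZF) — missing kernel entries set to 0;
* ``mean_fill`` (MF) — missing entries set to the per-entry mean of the
  corresponding visible entries in the other views;
* ``knn_fill`` (KNN) — missing rows/columns rebuilt from the view's k most
  similar visible samples;
* ``af_fill`` (AF) — missing entries copied from the average of the
  zero-filled kernels (`af-copy`: the consensus-copy reading of
  alignment-maximization filling);
* ``best_single_view`` (BS) — the best view's visible partition, completed
  with random labels (an oracle baseline: it needs ground truth to pick the
  view).

The imputation baselines feed a uniform-average multiple kernel k-means:
each completed kernel is centered and scaled, the kernels are averaged with
equal weights, and the combined kernel is clustered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import (
    ConsensusDecision,
    DataValidationError,
    MultiViewKernelData,
    ViewAssignment,
)
from .evaluate import nmi
from .view_clustering import KernelKMeansResult, center_and_scale, kernel_kmeans


@dataclass
class CompletedKernelSet:
    """P symmetric kernels with no missing entries, plus imputation provenance.

    ``provenance[j]`` counts the entries of view j that were imputed (cells
    (i, l) where sample i or sample l is missing in view j); visible-visible
    entries are always carried over unchanged.
    """

    kernels: list[np.ndarray]
    fill_method: str
    provenance: list[int]


def _missing_cells(mask: np.ndarray, view: int) -> np.ndarray:
    """Boolean N x N matrix: True where entry (i, l) of the view is missing."""
    vis = mask[:, view].astype(bool)
    return ~(vis[:, None] & vis[None, :])


def zero_fill(data: MultiViewKernelData) -> CompletedKernelSet:
    """Set every kernel entry touching a missing instance to zero."""
    kernels = []
    counts = []
    for j in range(data.n_views):
        miss = _missing_cells(data.mask, j)
        k = data.kernels[j].copy()
        k[miss] = 0.0
        kernels.append(k)
        counts.append(int(miss.sum()))
    return CompletedKernelSet(kernels=kernels, fill_method="zero", provenance=counts)


def mean_fill(data: MultiViewKernelData) -> CompletedKernelSet:
    """Per-entry mean of the corresponding visible entries in other views.

    A cell visible in no view falls back to 0 (the zero-fill semantics for
    hopeless entries) with a warning.
    """
    n = data.n_samples
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(data.n_views):
        vis_cell = ~_missing_cells(data.mask, j)
        num += np.where(vis_cell, data.kernels[j], 0.0)
        den += vis_cell
    with np.errstate(invalid="ignore"):
        consensus = np.where(den > 0, num / np.maximum(den, 1), 0.0)

    kernels = []
    counts = []
    warned = False
    for j in range(data.n_views):
        miss = _missing_cells(data.mask, j)
        if not warned and bool((miss & (den == 0)).any()):
            warnings.warn(
                "some missing kernel entries are visible in no view; filled with 0",
                UserWarning,
                stacklevel=2,
            )
            warned = True
        k = np.where(miss, consensus, data.kernels[j])
        kernels.append((k + k.T) / 2.0)
        counts.append(int(miss.sum()))
    return CompletedKernelSet(kernels=kernels, fill_method="mean", provenance=counts)


def knn_fill(data: MultiViewKernelData, k_neighbors: int = 5) -> CompletedKernelSet:
    """Rebuild missing rows of each view from the k most similar visible samples.

    For sample i missing in view j, similarity to the candidates is the
    per-entry mean of kernel entries over the views where both samples are
    visible (the mean-filled consensus restricted to i's visible views).  The
    ``k_neighbors`` most similar samples among those visible in view j supply
    the fill: row and column i become the mean of their rows/columns in the
    zero-filled kernel, the diagonal entry the mean of their diagonal
    entries.  All fills are computed against the same zero-filled base (no
    order dependence) and the matrix is re-symmetrized.
    """
    if k_neighbors < 1:
        raise DataValidationError("k_neighbors must be >= 1")
    n = data.n_samples
    base = zero_fill(data)

    # consensus similarity restricted to visible-visible cells
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(data.n_views):
        vis_cell = ~_missing_cells(data.mask, j)
        num += np.where(vis_cell, data.kernels[j], 0.0)
        den += vis_cell

    kernels = []
    counts = []
    for j in range(data.n_views):
        vis = data.mask[:, j].astype(bool)
        if int(vis.sum()) <= k_neighbors:
            raise DataValidationError(
                f"view {j} has only {int(vis.sum())} visible samples; "
                f"needs more than k_neighbors={k_neighbors}"
            )
        k = base.kernels[j].copy()
        for i in np.flatnonzero(~vis):
            cand = np.flatnonzero(vis)
            with np.errstate(invalid="ignore"):
                sim = np.where(den[i, cand] > 0, num[i, cand] / np.maximum(den[i, cand], 1), -np.inf)
            if not np.isfinite(sim).any():
                raise DataValidationError(
                    f"sample {i} has no visible neighbors for view {j}"
                )
            order = np.argsort(-sim, kind="stable")[:k_neighbors]
            nb = cand[order]
            fill_row = base.kernels[j][nb].mean(axis=0)
            k[i, :] = fill_row
            k[:, i] = fill_row
            k[i, i] = base.kernels[j][nb, nb].mean()
        k = (k + k.T) / 2.0
        # visible-visible entries must survive untouched
        vis_cell = vis[:, None] & vis[None, :]
        k[vis_cell] = data.kernels[j][vis_cell]
        kernels.append(k)
        counts.append(int((~vis_cell).sum()))
    return CompletedKernelSet(kernels=kernels, fill_method="knn", provenance=counts)


def af_fill(data: MultiViewKernelData) -> CompletedKernelSet:
    """Copy entries of the averaged zero-filled consensus into missing cells."""
    zf = zero_fill(data)
    consensus = sum(zf.kernels) / data.n_views
    kernels = []
    counts = []
    for j in range(data.n_views):
        miss = _missing_cells(data.mask, j)
        k = np.where(miss, consensus, data.kernels[j])
        kernels.append((k + k.T) / 2.0)
        counts.append(int(miss.sum()))
    return CompletedKernelSet(kernels=kernels, fill_method="af", provenance=counts)


def multiple_kernel_kmeans(
    completed: CompletedKernelSet,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> ConsensusDecision:
    """Uniform-average multiple kernel k-means on a completed kernel set.

    Each kernel is centered and scaled, the kernels are averaged with equal
    weights, and the combined kernel is clustered with spectral-relaxed
    kernel k-means.
    """
    combined = sum(center_and_scale(kk) for kk in completed.kernels) / len(completed.kernels)
    result: KernelKMeansResult = kernel_kmeans(combined, k, n_restarts=n_restarts, seed=seed)
    return ConsensusDecision.from_labels(result.labels, n_clusters=k)


def best_single_view(
    data: MultiViewKernelData,
    assignments: list[ViewAssignment],
    truth: np.ndarray,
    seed: int = 0,
) -> ConsensusDecision:
    """Best view's visible partition, completed with seeded random labels.

    An oracle baseline: each view's visible-instance partition is scored by
    NMI against the ground truth on its visible indices, the best view is
    kept (ties to the lowest view index), and each of its missing instances
    receives a uniformly random cluster from the seeded generator.
    """
    if truth is None:
        raise DataValidationError("best_single_view requires ground-truth labels")
    truth = np.asarray(truth, dtype=int)
    scores = []
    for z in assignments:
        vis = z.visible
        scores.append(nmi(z.labels()[vis], truth[vis]))
    best = int(np.argmax(scores))
    z = assignments[best]
    k = z.n_clusters
    labels = z.labels()
    missing = np.flatnonzero(~z.visible)
    rng = np.random.default_rng(seed)
    labels[missing] = rng.integers(0, k, size=missing.size)
    return ConsensusDecision.from_labels(labels, n_clusters=k)


def build_initial_decision(
    method: str,
    data: MultiViewKernelData,
    assignments: list[ViewAssignment],
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    k_neighbors: int = 5,
) -> ConsensusDecision:
    """Dispatch an initialization method tag (bs/zf/mf/knn/af) to a decision."""
    method = method.lower()
    if method == "bs":
        return best_single_view(data, assignments, data.labels, seed=seed)
    fillers = {"zf": zero_fill, "mf": mean_fill, "af": af_fill}
    if method == "knn":
        completed = knn_fill(data, k_neighbors=k_neighbors)
    elif method in fillers:
        completed = fillers[method](data)
    else:
        raise DataValidationError(f"unknown initialization method {method!r}")
    return multiple_kernel_kmeans(completed, k, n_restarts=n_restarts, seed=seed)
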