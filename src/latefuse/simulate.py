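"""Synthetic multiview data, the random view-missingness process, and the
toy Gaussian stability study.

The missingness simulator mirrors the standard protocol for benchmarking
incomplete multiview methods: a fraction epsilon of the samples (the
incomplete-sample ratio) is selected; each selected sample draws a uniform
vector g in [0, 1]^P and loses view p when g_p < q0, redrawing until at
least one view survives.  With ``require_missing`` (the default) the redraw
also insists on at least one missing view, so exactly round(epsilon * N)
samples are genuinely incomplete.

The synthetic multiview generator emulates multi-omics-like layers: latent
cluster labels shared across views, per-view Gaussian blobs in independent
feature spaces, and linear or Gaussian kernels (Gaussian width = mean
pairwise distance of that view's features).

The toy study checks the premise of late fusion — under random missingness
the visible instances' cluster structure is stable — on three well-separated
2-D Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .data_model import DataValidationError, MultiViewKernelData
from .evaluate import acc
from .view_clustering import center_and_scale, kernel_kmeans

#: toy three-Gaussian defaults: well separated, unit covariance, so the
#: complete-data clustering is essentially perfect and the stability claim
#: is sharp.
TOY_MEANS = np.array([[0.0, 0.0], [4.0, 0.0], [2.0, 3.5]])


@dataclass
class MissingnessSpec:
    """Parameters of the random view-missingness process."""

    epsilon: float
    q0: float = 0.5
    seed: int = 0
    require_missing: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise DataValidationError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if not 0.0 < self.q0 < 1.0:
            raise DataValidationError(f"q0 must be in (0, 1), got {self.q0}")


@dataclass
class SyntheticSpec:
    """Recipe for shared-cluster multiview data with per-view kernels.

    Cluster centers in view j are drawn i.i.d. N(0, separation^2 / d_j) per
    coordinate, so the expected squared distance between two centers is
    2 * separation^2 regardless of the view's dimension; features add
    isotropic noise of scale ``noise``.  ``view_consistency`` is the fraction
    of samples whose latent label is respected in every view; the rest get an
    independently redrawn label per view (inconsistent views).
    """

    n_samples: int = 300
    n_views: int = 3
    n_clusters: int = 4
    feature_dims: Sequence[int] = (8, 8, 8)
    separation: float = 4.0
    noise: float = 1.0
    view_consistency: float = 1.0
    kernel_types: Sequence[str] = ("linear", "linear", "linear")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 * self.n_clusters:
            raise DataValidationError("need n_samples >= 2 * n_clusters")
        if len(self.feature_dims) != self.n_views or min(self.feature_dims) < 1:
            raise DataValidationError("feature_dims must list a positive dim per view")
        if len(self.kernel_types) != self.n_views or not set(self.kernel_types) <= {
            "linear",
            "gaussian",
        }:
            raise DataValidationError("kernel_types must be 'linear'/'gaussian' per view")
        if not 0.0 <= self.view_consistency <= 1.0:
            raise DataValidationError("view_consistency must be in [0, 1]")


def generate_mask(n_samples: int, n_views: int, spec: MissingnessSpec) -> np.ndarray:
    """Draw the zero-one N x P visibility mask of the missingness protocol.

    Exactly round(epsilon * N) samples are selected; unselected rows are
    all-ones.  Each selected sample rejects g-draws until at least one view
    is present (and, when ``require_missing``, at least one absent).
    """
    if n_views < 1:
        raise DataValidationError("need at least one view")
    if spec.require_missing and n_views < 2:
        raise DataValidationError(
            "require_missing needs >= 2 views (a sample cannot have both a "
            "visible and a missing view otherwise)"
        )
    rng = np.random.default_rng(spec.seed)
    n_selected = int(round(spec.epsilon * n_samples))
    selected = np.sort(rng.choice(n_samples, size=n_selected, replace=False))
    mask = np.ones((n_samples, n_views), dtype=int)
    for i in selected:
        while True:
            g = rng.random(n_views)
            missing = g < spec.q0
            if missing.all():
                continue
            if spec.require_missing and not missing.any():
                continue
            mask[i] = (~missing).astype(int)
            break
    return mask


def linear_kernel(features: np.ndarray) -> np.ndarray:
    return features @ features.T


def gaussian_kernel(features: np.ndarray) -> tuple[np.ndarray, float]:
    """RBF kernel with width set to the mean pairwise Euclidean distance.

    Returns (kernel, width); K[i, l] = exp(-||x_i - x_l||^2 / (2 width^2)).
    """
    dists = pdist(features)
    width = float(dists.mean()) if dists.size else 1.0
    if width <= 0:
        width = 1.0
    sq = squareform(dists) ** 2
    return np.exp(-sq / (2.0 * width**2)), width


def toy_gaussians(n_per_cluster: int = 100, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Three isotropic 2-D Gaussian clusters, shuffled, with labels."""
    if n_per_cluster < 2:
        raise DataValidationError("need n_per_cluster >= 2")
    rng = np.random.default_rng(seed)
    features = np.concatenate(
        [rng.normal(mean, 1.0, size=(n_per_cluster, 2)) for mean in TOY_MEANS]
    )
    labels = np.repeat(np.arange(len(TOY_MEANS)), n_per_cluster)
    perm = rng.permutation(labels.size)
    return features[perm], labels[perm]


def _cluster_features(
    features: np.ndarray, k: int, n_restarts: int, seed: int
) -> np.ndarray:
    """Kernel k-means (linear kernel, centered/scaled) on raw 2-D features."""
    result = kernel_kmeans(
        center_and_scale(linear_kernel(features)), k, n_restarts=n_restarts, seed=seed
    )
    return result.labels


def _matched_centroid_drift(
    centroids: np.ndarray, reference: np.ndarray
) -> float:
    """Max distance between optimally matched centroid pairs."""
    d = np.linalg.norm(centroids[:, None, :] - reference[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(d)
    return float(d[rows, cols].max())


def random_missing_study(
    n_per_cluster: int = 100,
    ratios: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    n_repeats: int = 100,
    seed: int = 0,
    n_restarts: int = 10,
) -> dict:
    """Stability of visible-instance clustering under random deletion.

    For each missing ratio, instances are deleted uniformly at random
    ``n_repeats`` times; each time, kernel k-means runs on the visible set
    and records the visible-instance ACC and the maximum drift of the
    visible-data cluster centroids from the complete-data centroids (after
    optimal matching).  Returns per-ratio means plus the complete-data
    baseline.
    """
    if any(not 0.0 < r < 1.0 for r in ratios):
        raise DataValidationError("ratios must lie in (0, 1)")
    features, labels = toy_gaussians(n_per_cluster, seed=seed)
    n = labels.size
    k = len(TOY_MEANS)
    complete_pred = _cluster_features(features, k, n_restarts, seed)
    complete_acc = acc(complete_pred, labels)
    complete_centroids = np.stack(
        [features[complete_pred == c].mean(axis=0) for c in range(k)]
    )
    rng = np.random.default_rng(seed + 1)
    per_ratio = {}
    for ratio in ratios:
        n_delete = int(round(ratio * n))
        if n - n_delete < k:
            raise DataValidationError(f"ratio {ratio} leaves fewer than {k} points")
        accs = np.empty(n_repeats)
        drifts = np.empty(n_repeats)
        for r in range(n_repeats):
            deleted = rng.choice(n, size=n_delete, replace=False)
            visible = np.setdiff1d(np.arange(n), deleted)
            pred = _cluster_features(
                features[visible], k, n_restarts, seed + 7 * r + 1
            )
            accs[r] = acc(pred, labels[visible])
            centroids = np.stack(
                [
                    features[visible][pred == c].mean(axis=0)
                    if (pred == c).any()
                    else np.full(2, np.nan)
                    for c in range(k)
                ]
            )
            drifts[r] = (
                _matched_centroid_drift(centroids, complete_centroids)
                if np.isfinite(centroids).all()
                else np.nan
            )
        per_ratio[float(ratio)] = {
            "mean_acc": float(accs.mean()),
            "mean_drift": float(np.nanmean(drifts)),
            "max_drift": float(np.nanmax(drifts)),
        }
    return {
        "complete_acc": float(complete_acc),
        "complete_centroids": complete_centroids,
        "per_ratio": per_ratio,
    }


def synthetic_multiview(spec: SyntheticSpec) -> MultiViewKernelData:
    """Shared-cluster multiview kernel data (fully visible) with true labels.

    Latent labels are balanced; each view gets its own cluster centers,
    features, and kernel.  The returned container carries an all-ones mask
    (impose missingness with :func:`generate_mask`) and the ground-truth
    labels in ``.labels``.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_clusters
    labels = rng.permutation(np.resize(np.arange(k), n))
    kernels = []
    for j in range(spec.n_views):
        d = int(spec.feature_dims[j])
        centers = rng.normal(0.0, spec.separation / np.sqrt(d), size=(k, d))
        view_labels = labels.copy()
        if spec.view_consistency < 1.0:
            flip = rng.random(n) > spec.view_consistency
            view_labels[flip] = rng.integers(0, k, size=int(flip.sum()))
        features = centers[view_labels] + rng.normal(0.0, spec.noise, size=(n, d))
        if spec.kernel_types[j] == "linear":
            kernels.append(linear_kernel(features))
        else:
            kernels.append(gaussian_kernel(features)[0])
    return MultiViewKernelData(
        kernels=kernels, mask=np.ones((n, spec.n_views), dtype=int), labels=labels
    )


def identifiability_example(
    n_per_cluster: int = 30,
    separation: float = 6.0,
    noise: float = 0.5,
    seed: int = 0,
) -> MultiViewKernelData:
    """Four clusters, three views, each view blind to a different cluster pair.

    View v gives the two clusters of its merged pair the same center, so no
    single view can resolve all four clusters; the pairs (0,1), (2,3), (1,2)
    jointly separate every cluster, so the views together identify the full
    partition.  Linear kernels; labels attached as ground truth.
    """
    merged_pairs = [(0, 1), (2, 3), (1, 2)]
    k = 4
    rng = np.random.default_rng(seed)
    n = k * n_per_cluster
    labels = rng.permutation(np.repeat(np.arange(k), n_per_cluster))
    d = 4
    kernels = []
    for a, b in merged_pairs:
        # orthogonal, well-separated base centers; merge one pair
        centers = separation * np.eye(k)[:, :d]
        centers[b] = centers[a]
        features = centers[labels] + rng.normal(0.0, noise, size=(n, d))
        kernels.append(linear_kernel(features))
    return MultiViewKernelData(
        kernels=kernels, mask=np.ones((n, len(merged_pairs)), dtype=int), labels=labels
    )
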