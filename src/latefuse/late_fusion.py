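"""Late fusion: consensus clustering of per-view partitions by masked k-means.

Each view's partition is a zero-one indicator Z^j whose rows act as
K-dimensional compressed representations of the instances (all-zero where
missing).  The consensus decision Y minimizes the masked sum of per-view
k-means objectives

    min_{Y, M}  sum_j sum_c sum_i  Y_ic * S_ij * || Z_i^j - M_c^j ||^2

over one-hot rows of Y and per-(view, cluster) centroids M_c^j in R^K.
Alternating minimization solves it: the Y-update assigns each sample to the
cluster with the smallest mask-weighted total squared distance, and the
M-update sets each centroid to the mean of the visible compressed
representations assigned to it.  Both half-steps are exact minimizers of
their subproblems, so the objective is non-increasing and, being bounded
below by zero and piecewise constant in the finite set of decisions, the
alternation converges in finitely many iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    CentroidSet,
    ConsensusDecision,
    DataValidationError,
    ViewAssignment,
)

#: near-tie width for the sticky Y-update tie-break
TIE_TOL = 1e-12


class EmptyClusterWarning(UserWarning):
    """A consensus cluster has no members (K is fixed prior knowledge)."""


@dataclass
class AssignmentCost:
    """N x K matrix G with G[i, c] = sum_j S_ij ||Z_i^j - M_c^j||^2."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or not np.isfinite(m).all() or (m < -TIE_TOL).any():
            raise DataValidationError("assignment costs must be finite and nonnegative")
        self.matrix = np.maximum(m, 0.0)


@dataclass
class FusionState:
    """Outcome of one alternating-minimization run."""

    decision: ConsensusDecision
    centroids: CentroidSet
    objective_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    init_method: str = ""


def _check_shapes(
    assignments: list[ViewAssignment], mask: np.ndarray, n_clusters: int
) -> tuple[int, int]:
    mask = np.asarray(mask)
    n, p = mask.shape
    if len(assignments) != p:
        raise DataValidationError(f"{len(assignments)} assignments for {p} mask columns")
    for z in assignments:
        if z.matrix.shape != (n, n_clusters):
            raise DataValidationError(
                f"view {z.view_index} assignment shape {z.matrix.shape} != ({n}, {n_clusters})"
            )
    return n, p


def assignment_cost(
    centroids: CentroidSet,
    assignments: list[ViewAssignment],
    mask: np.ndarray,
) -> AssignmentCost:
    """Mask-weighted squared distances of every sample to every cluster."""
    k = centroids.n_clusters
    n, p = _check_shapes(assignments, mask, k)
    mask = np.asarray(mask, dtype=float)
    g = np.zeros((n, k))
    for j in range(p):
        z = assignments[j].matrix.astype(float)  # (N, K)
        m = centroids.centroids[j]  # (K, K): row c is M_c^j
        # ||z_i - m_c||^2 = |z_i|^2 - 2 z_i.m_c + |m_c|^2
        d = (
            (z * z).sum(axis=1, keepdims=True)
            - 2.0 * z @ m.T
            + (m * m).sum(axis=1)[None, :]
        )
        g += mask[:, j : j + 1] * d
    return AssignmentCost(matrix=g)


def objective(
    decision: ConsensusDecision,
    centroids: CentroidSet,
    assignments: list[ViewAssignment],
    mask: np.ndarray,
) -> float:
    """Masked sum of per-view k-means objectives for a given (Y, M).

    Terms with S_ij = 0 contribute exactly zero.  A sample assigned against
    an undefined centroid is scored against the retained/fallback value that
    the centroid slot stores.
    """
    if decision.n_clusters != centroids.n_clusters:
        raise DataValidationError("decision and centroids disagree on K")
    g = assignment_cost(centroids, assignments, mask).matrix
    return float((decision.matrix * g).sum())


def update_decision(
    centroids: CentroidSet,
    assignments: list[ViewAssignment],
    mask: np.ndarray,
    previous: ConsensusDecision,
) -> tuple[ConsensusDecision, AssignmentCost]:
    """Exact Y-update: each sample joins the cluster minimizing its cost.

    Ties (within :data:`TIE_TOL`) are sticky: the previous cluster wins if it
    is among the minimizers, otherwise the lowest index does.  Stickiness
    guarantees Y only changes when the objective strictly decreases, which
    makes convergence by Y-stability well-defined.
    """
    cost = assignment_cost(centroids, assignments, mask)
    g = cost.matrix
    n, k = g.shape
    row_min = g.min(axis=1)
    minimal = g <= (row_min + TIE_TOL)[:, None]
    prev_labels = previous.labels()
    new_labels = np.argmax(minimal, axis=1)  # lowest minimizing index
    keep = minimal[np.arange(n), prev_labels]
    new_labels[keep] = prev_labels[keep]
    return ConsensusDecision.from_labels(new_labels, n_clusters=k), cost


def update_centroids(
    decision: ConsensusDecision,
    assignments: list[ViewAssignment],
    mask: np.ndarray,
    previous: CentroidSet | None = None,
) -> CentroidSet:
    """Exact M-update: per-(view, cluster) mean of visible member rows.

    M_c^j = sum_i Y_ic S_ij Z_i^j / sum_i Y_ic S_ij where the denominator is
    positive (defined=True; the result is a convex combination of one-hot
    rows, so entries are >= 0 and sum to 1).  A zero denominator leaves the
    objective independent of that centroid: the previous value is retained
    with defined=False, or, with no previous set (initialization), the global
    mean of the view's visible rows is used as the fallback.
    """
    k = decision.n_clusters
    n, p = _check_shapes(assignments, mask, k)
    mask = np.asarray(mask, dtype=float)
    y = decision.matrix.astype(float)
    centroids = np.zeros((p, k, k))
    defined = np.zeros((p, k), dtype=bool)
    for j in range(p):
        z = assignments[j].matrix.astype(float)
        w = y * mask[:, j : j + 1]  # (N, K): membership weights in view j
        denom = w.sum(axis=0)  # (K,)
        num = w.T @ z  # (K, K)
        ok = denom > 0
        defined[j] = ok
        centroids[j][ok] = num[ok] / denom[ok, None]
        if (~ok).any():
            if previous is not None:
                centroids[j][~ok] = previous.centroids[j][~ok]
            else:
                vis = mask[:, j] > 0
                fallback = (
                    z[vis].mean(axis=0) if vis.any() else np.full(k, 1.0 / k)
                )
                centroids[j][~ok] = fallback
    return CentroidSet(centroids=centroids, defined=defined)


def fuse(
    assignments: list[ViewAssignment],
    mask: np.ndarray,
    initial_decision: ConsensusDecision,
    max_iter: int = 200,
    init_method: str = "",
) -> FusionState:
    """Alternating minimization of the late-fusion objective.

    Centroids are first computed from the initial decision Y^0; each
    iteration then updates Y (exact assignment step) and M (exact mean step)
    and records the objective.  The loop stops when Y is unchanged over a
    full iteration — an exact fixed point — or at ``max_iter``.  The recorded
    trace (initial value plus one value per iteration) is non-increasing.
    """
    if max_iter < 1:
        raise DataValidationError(f"max_iter must be >= 1, got {max_iter}")
    centroids = update_centroids(initial_decision, assignments, mask, previous=None)
    decision = initial_decision
    trace = [objective(decision, centroids, assignments, mask)]
    converged = False
    iterations = 0
    for _ in range(max_iter):
        new_decision, _ = update_decision(centroids, assignments, mask, decision)
        centroids = update_centroids(new_decision, assignments, mask, previous=centroids)
        iterations += 1
        trace.append(objective(new_decision, centroids, assignments, mask))
        if np.array_equal(new_decision.matrix, decision.matrix):
            decision = new_decision
            converged = True
            break
        decision = new_decision
    if (decision.matrix.sum(axis=0) == 0).any():
        warnings.warn(
            "consensus partition has empty clusters (K is fixed prior knowledge)",
            EmptyClusterWarning,
            stacklevel=2,
        )
    return FusionState(
        decision=decision,
        centroids=centroids,
        objective_trace=trace,
        n_iterations=iterations,
        converged=converged,
        init_method=init_method,
    )
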