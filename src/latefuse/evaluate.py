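"""Clustering metrics (NMI, ACC) and the initialization-vs-fusion harness.

NMI is normalized mutual information with square-root normalization,
I(a; b) / sqrt(H(a) H(b)) in natural logs, with the 0/0 -> 0 convention when
either partition is a single cluster.  ACC is clustering accuracy under the
best one-to-one cluster-label matching, solved by the Hungarian algorithm on
the contingency table.  Both are invariant to relabeling either partition.

``run_comparison`` reproduces, on synthetic data, the design of the
initialization-vs-late-fusion experiments: for each (method, epsilon, seed)
it simulates incomplete multiview data, builds an initial decision, runs the
fusion, and records initial and fused NMI against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .data_model import DataValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SyntheticSpec


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise DataValidationError("label vectors must be 1-D and equal length")
    if a.size == 0:
        raise DataValidationError("empty label vectors")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=int)
    np.add.at(table, (ai, bi), 1)
    return table


def nmi(labels_a: np.ndarray, labels_b: np.ndarray, normalization: str = "sqrt") -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    ``normalization`` selects the denominator: "sqrt" (the contract),
    "max", or "mean" of the two entropies.  Returns 0 when either partition
    is a single cluster (0/0 convention).
    """
    table = _contingency(labels_a, labels_b).astype(float)
    n = table.sum()
    pij = table / n
    pa = pij.sum(axis=1)
    pb = pij.sum(axis=0)
    nz = pij > 0
    outer = pa[:, None] * pb[None, :]
    mi = float((pij[nz] * np.log(pij[nz] / outer[nz])).sum())
    ha = float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = float(-(pb[pb > 0] * np.log(pb[pb > 0])).sum())
    if normalization == "sqrt":
        denom = np.sqrt(ha * hb)
    elif normalization == "max":
        denom = max(ha, hb)
    elif normalization == "mean":
        denom = (ha + hb) / 2.0
    else:
        raise DataValidationError(f"unknown normalization {normalization!r}")
    if denom <= 0:
        return 0.0
    return float(np.clip(mi / denom, 0.0, 1.0))


def acc(labels_pred: np.ndarray, labels_true: np.ndarray) -> float:
    """Clustering accuracy: best one-to-one label matching (Hungarian)."""
    table = _contingency(labels_pred, labels_true)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / table.sum())


def visible_metrics(
    labels_pred: np.ndarray,
    labels_true: np.ndarray,
    visible: np.ndarray,
) -> tuple[float, float]:
    """(NMI, ACC) restricted to the visible positions.

    ``visible`` is a boolean mask or an integer index set over the samples.
    A single visible instance yields ACC 1.0 and NMI 0.0 (single-class
    conventions).
    """
    visible = np.asarray(visible)
    if visible.dtype == bool:
        idx = np.flatnonzero(visible)
    else:
        idx = visible.astype(int)
    if idx.size == 0:
        raise DataValidationError("empty visible set")
    pred = np.asarray(labels_pred, dtype=int)
    true = np.asarray(labels_true, dtype=int)
    # labels_pred may already be restricted to the visible subset
    pred_sub = pred if pred.size == idx.size else pred[idx]
    return nmi(pred_sub, true[idx]), acc(pred_sub, true[idx])


@dataclass
class ComparisonReport:
    """Per-run records + per-(method, epsilon) aggregates + method ranks.

    ``records`` has one row per (method, epsilon, seed) with initial NMI,
    fused NMI, and delta = fused - initial.  ``summary`` aggregates means
    over seeds.  ``ranks`` holds, per epsilon, each method's rank (1 = best)
    by mean fused NMI and by mean delta.
    """

    records: pd.DataFrame
    summary: pd.DataFrame
    ranks: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def run_comparison(
    spec: "SyntheticSpec",
    epsilons: Sequence[float],
    init_methods: Sequence[str],
    n_seeds: int,
    k: int | None = None,
    q0: float = 0.5,
    n_restarts: int = 10,
    max_iter: int = 200,
) -> ComparisonReport:
    """Initialization-vs-late-fusion comparison on simulated incomplete data.

    For every (method, epsilon, seed): draw a fresh multiview dataset from
    ``spec`` (re-seeded with ``spec.seed + seed``), draw a missingness mask at
    incomplete-sample ratio epsilon, cluster each view's visible instances,
    build Y^0 with the method, fuse, and score initial and fused partitions
    by NMI against the ground truth.
    """
    from .baselines import build_initial_decision
    from .late_fusion import fuse
    from .simulate import MissingnessSpec, generate_mask, synthetic_multiview
    from .view_clustering import cluster_each_view
    from dataclasses import replace

    allowed = {"bs", "zf", "mf", "knn", "af"}
    bad = set(m.lower() for m in init_methods) - allowed
    if bad:
        raise DataValidationError(f"unknown init methods {sorted(bad)}")
    if k is None:
        k = spec.n_clusters

    rows = []
    for eps in epsilons:
        for run in range(n_seeds):
            run_seed = spec.seed + run
            data = synthetic_multiview(replace(spec, seed=run_seed))
            mspec = MissingnessSpec(epsilon=eps, q0=q0, seed=run_seed + 10_000)
            data.mask = generate_mask(data.n_samples, data.n_views, mspec)
            assignments = cluster_each_view(data, k, n_restarts=n_restarts, seed=run_seed)
            for method in init_methods:
                method = method.lower()
                y0 = build_initial_decision(
                    method, data, assignments, k, n_restarts=n_restarts, seed=run_seed
                )
                state = fuse(
                    assignments, data.mask, y0, max_iter=max_iter, init_method=method
                )
                initial = nmi(y0.labels(), data.labels)
                fused = nmi(state.decision.labels(), data.labels)
                rows.append(
                    {
                        "method": method,
                        "epsilon": eps,
                        "seed": run_seed,
                        "initial_nmi": initial,
                        "fused_nmi": fused,
                        "delta": fused - initial,
                        "iterations": state.n_iterations,
                        "converged": state.converged,
                    }
                )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby(["method", "epsilon"], as_index=False)[
            ["initial_nmi", "fused_nmi", "delta"]
        ]
        .mean()
        .sort_values(["epsilon", "method"], ignore_index=True)
    )
    ranks = summary.copy()
    ranks["fused_rank"] = (
        summary.groupby("epsilon")["fused_nmi"].rank(ascending=False, method="first").astype(int)
    )
    ranks["delta_rank"] = (
        summary.groupby("epsilon")["delta"].rank(ascending=False, method="first").astype(int)
    )
    metadata = {
        "q0": q0,
        "n_seeds": n_seeds,
        "base_seed": spec.seed,
        "epsilons": list(epsilons),
        "methods": [m.lower() for m in init_methods],
    }
    return ComparisonReport(records=records, summary=summary, ranks=ranks, metadata=metadata)
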