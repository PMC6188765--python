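"""Core data types and file I/O for incomplete multiview kernel data.

The universe every stage of the pipeline consumes is a set of P symmetric
N x N kernel (similarity) matrices over the same N samples, together with a
zero-one N x P visibility mask S: S[i, j] = 1 means sample i has an instance
in view j, S[i, j] = 0 means that instance is missing.  Every sample must be
visible in at least one view.

Partitions are carried internally as zero-one indicator matrices (one-hot
rows); externally, cluster labels are 0-based integers, one per line.
Matrices travel as dense tab-separated text with no header, or as a raw
little-endian float64 row-major dump prefixed by a two-int64 (rows, cols)
header.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

#: maximum tolerated |K - K.T| before a kernel is rejected; below it the
#: kernel is silently symmetrized via (K + K.T) / 2.
SYMMETRY_TOL = 1e-8


class DataValidationError(ValueError):
    """Base class for all validation failures on multiview inputs."""


class DimensionMismatchError(DataValidationError):
    """Kernels are not square, or views disagree on the number of samples."""


class AsymmetricKernelError(DataValidationError):
    """A kernel's asymmetry exceeds :data:`SYMMETRY_TOL`."""


class MaskError(DataValidationError):
    """The visibility mask is malformed, e.g. a sample has no visible view."""


class DegenerateKernelWarning(UserWarning):
    """Raised when centering collapses a kernel or a kernel is not PSD."""


def _as_square_symmetric(kernel: np.ndarray, *, name: str = "kernel") -> np.ndarray:
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise DimensionMismatchError(f"{name} must be square, got shape {kernel.shape}")
    asym = np.max(np.abs(kernel - kernel.T)) if kernel.size else 0.0
    if asym > SYMMETRY_TOL:
        raise AsymmetricKernelError(
            f"{name} asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
        )
    return (kernel + kernel.T) / 2.0


@dataclass
class MultiViewKernelData:
    """P symmetric N x N kernels + N x P visibility mask + optional labels.

    Invariants enforced at construction: each kernel square, symmetric within
    :data:`SYMMETRY_TOL` (then symmetrized), all sharing one N; mask entries
    in {0, 1} with every row containing at least one 1.
    """

    kernels: list[np.ndarray]
    mask: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.kernels:
            raise DataValidationError("need at least one view")
        self.kernels = [
            _as_square_symmetric(k, name=f"kernel[{j}]") for j, k in enumerate(self.kernels)
        ]
        n = self.kernels[0].shape[0]
        for j, k in enumerate(self.kernels):
            if k.shape[0] != n:
                raise DimensionMismatchError(
                    f"kernel[{j}] has {k.shape[0]} samples, kernel[0] has {n}"
                )
        mask = np.asarray(self.mask)
        if mask.ndim != 2 or mask.shape != (n, len(self.kernels)):
            raise MaskError(
                f"mask shape {mask.shape} does not match (n_samples={n}, "
                f"n_views={len(self.kernels)})"
            )
        if not np.isin(mask, (0, 1)).all():
            raise MaskError("mask entries must be 0 or 1")
        self.mask = mask.astype(int)
        if (self.mask.sum(axis=1) == 0).any():
            bad = int(np.flatnonzero(self.mask.sum(axis=1) == 0)[0])
            raise MaskError(f"sample {bad} has no visible view")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise DimensionMismatchError("sample_ids length does not match n_samples")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise DimensionMismatchError("labels length does not match n_samples")

    @property
    def n_samples(self) -> int:
        return self.kernels[0].shape[0]

    @property
    def n_views(self) -> int:
        return len(self.kernels)

    def check_psd(self, tol: float = 1e-8) -> float:
        """Smallest eigenvalue across views; warns (never raises) below -tol.

        Positive semidefiniteness is not required by the fusion machinery
        (only symmetry is), so indefinite kernels are admissible but flagged.
        """
        smallest = np.inf
        for j, k in enumerate(self.kernels):
            lam = scipy.linalg.eigvalsh(k, subset_by_index=[0, 0])[0]
            smallest = min(smallest, lam)
            if lam < -tol:
                warnings.warn(
                    f"kernel[{j}] is not PSD (smallest eigenvalue {lam:.3g})",
                    DegenerateKernelWarning,
                    stacklevel=2,
                )
        return float(smallest)


@dataclass
class ViewAssignment:
    """Zero-one N x K partition of one view; all-zero rows mark missing instances."""

    matrix: np.ndarray
    view_index: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or not np.isin(m, (0, 1)).all():
            raise DataValidationError("assignment matrix must be zero-one N x K")
        sums = m.sum(axis=1)
        if not np.isin(sums, (0, 1)).all():
            raise DataValidationError("each row must sum to 0 (missing) or 1")
        self.matrix = m.astype(int)

    @property
    def n_clusters(self) -> int:
        return self.matrix.shape[1]

    @property
    def visible(self) -> np.ndarray:
        """Boolean vector: rows that carry an assignment."""
        return self.matrix.sum(axis=1) == 1

    def labels(self, missing: int = -1) -> np.ndarray:
        """Per-sample labels; missing instances get ``missing``."""
        lab = np.full(self.matrix.shape[0], missing, dtype=int)
        vis = self.visible
        lab[vis] = np.argmax(self.matrix[vis], axis=1)
        return lab

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        visible: np.ndarray,
        n_clusters: int,
        view_index: int,
    ) -> "ViewAssignment":
        """Scatter labels of the visible instances into an N x K indicator.

        ``labels`` is given in visible-index order; ``visible`` is the boolean
        mask column for the view.
        """
        visible = np.asarray(visible, dtype=bool)
        m = np.zeros((visible.size, n_clusters), dtype=int)
        idx = np.flatnonzero(visible)
        if len(idx) != len(labels):
            raise DimensionMismatchError("labels do not match the visible count")
        m[idx, np.asarray(labels, dtype=int)] = 1
        return cls(matrix=m, view_index=view_index)


@dataclass
class ConsensusDecision:
    """Zero-one N x K consensus partition Y; every row sums to exactly 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or not np.isin(m, (0, 1)).all():
            raise DataValidationError("decision matrix must be zero-one N x K")
        if m.shape[0] == 0:
            raise DataValidationError("empty decision")
        if not (m.sum(axis=1) == 1).all():
            raise DataValidationError("every decision row must sum to exactly 1")
        self.matrix = m.astype(int)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.matrix.shape[1]

    def labels(self) -> np.ndarray:
        return np.argmax(self.matrix, axis=1)

    @classmethod
    def from_labels(cls, labels: np.ndarray, n_clusters: int | None = None) -> "ConsensusDecision":
        labels = np.asarray(labels, dtype=int)
        if n_clusters is None:
            n_clusters = int(labels.max()) + 1 if labels.size else 0
        m = np.zeros((labels.size, n_clusters), dtype=int)
        m[np.arange(labels.size), labels] = 1
        return cls(matrix=m)


@dataclass
class CentroidSet:
    """Per-(view, cluster) centroids M[j, c] in R^K with definedness flags.

    ``defined[j, c]`` is False when the (view, cluster) pair had no visible
    member at the last update; the stored value is then the retained previous
    centroid (or the initialization fallback) and contributes nothing to the
    fusion objective unless a sample is actually assigned against it.
    """

    centroids: np.ndarray  # (P, K, K) float
    defined: np.ndarray  # (P, K) bool

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        d = np.asarray(self.defined, dtype=bool)
        if c.ndim != 3 or d.shape != c.shape[:2]:
            raise DataValidationError("centroids must be (P, K, K) with (P, K) flags")
        if not np.isfinite(c).all():
            raise DataValidationError("centroid entries must be finite")
        self.centroids = c
        self.defined = d

    @property
    def n_views(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[1]


# ---------------------------------------------------------------------------
# Text / binary matrix dialects
# ---------------------------------------------------------------------------

#: suffixes that select the raw binary dialect instead of TSV
_BINARY_SUFFIXES = {".bin", ".raw"}


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a dense matrix: TSV (no header) or, for .bin/.raw, raw float64.

    The binary layout is two little-endian int64 (rows, cols) followed by the
    row-major little-endian float64 payload.  TSV uses %.17g so float64
    round-trips bit-exactly.
    """
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if path.suffix in _BINARY_SUFFIXES:
        with open(path, "wb") as fh:
            np.array(matrix.shape, dtype="<i8").tofile(fh)
            matrix.astype("<f8").tofile(fh)
    else:
        np.savetxt(path, matrix, fmt="%.17g", delimiter="\t")


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in _BINARY_SUFFIXES:
        with open(path, "rb") as fh:
            rows, cols = np.fromfile(fh, dtype="<i8", count=2)
            data = np.fromfile(fh, dtype="<f8", count=rows * cols)
        if data.size != rows * cols:
            raise DataValidationError(f"{path}: truncated binary matrix")
        return data.reshape(int(rows), int(cols))
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=float, ndmin=2))


def read_mask(path: str | Path) -> np.ndarray:
    mask = read_matrix(path)
    if not np.isin(mask, (0, 1)).all():
        raise MaskError(f"{path}: mask entries must be 0 or 1")
    return mask.astype(int)


def read_labels(path: str | Path) -> np.ndarray:
    labels = np.loadtxt(path, dtype=int, ndmin=1)
    return labels


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int)[:, None], fmt="%d")


def read_kernel_set(
    paths: Sequence[str | Path],
    mask_path: str | Path,
    labels_path: str | Path | None = None,
) -> MultiViewKernelData:
    """Load kernels + mask (+ labels) from disk into a validated container.

    Kernels with asymmetry at or below :data:`SYMMETRY_TOL` are symmetrized
    silently; larger asymmetry raises :class:`AsymmetricKernelError`.
    """
    kernels = [read_matrix(p) for p in paths]
    mask = read_mask(mask_path)
    labels = read_labels(labels_path) if labels_path is not None else None
    return MultiViewKernelData(kernels=kernels, mask=mask, labels=labels)


def write_partition(
    decision: ConsensusDecision,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write one 0-based label per line plus a JSON sidecar (``path + .json``).

    The sidecar records N, K and any caller-supplied metadata (e.g. the final
    objective value and iteration count of a fusion run).
    """
    path = Path(path)
    write_labels(decision.labels(), path)
    side = {"n_samples": decision.n_samples, "n_clusters": decision.n_clusters}
    if metadata:
        side.update(metadata)
    with open(path.with_name(path.name + ".json"), "w") as fh:
        json.dump(side, fh, indent=2, default=float)
        fh.write("\n")


def read_partition(path: str | Path) -> ConsensusDecision:
    """Inverse of :func:`write_partition` (the sidecar supplies K)."""
    path = Path(path)
    labels = read_labels(path)
    k = None
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            k = json.load(fh).get("n_clusters")
    return ConsensusDecision.from_labels(labels, n_clusters=k)
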