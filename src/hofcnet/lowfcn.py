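"""Low-order functional connectivity estimation.

Full-correlation networks, sparse-representation (regularized partial
correlation) networks, sliding-window network sequences, and magnitude
thresholding.  All routines consume and return plain float arrays; rows are
time points, columns are ROIs.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import DegenerateSignalError, WindowError
from .types import WindowSpec, check_symmetric

__all__ = [
    "standardize_columns",
    "pearson_fcn",
    "sparse_representation_fcn",
    "sliding_windows",
    "windowed_fcns",
    "threshold_sparsify",
    "DEFAULT_THRESHOLD_LEVELS",
    "DEFAULT_REGULARIZER_GRID",
]

#: keep-fractions 1%, 10%, 20%, ..., 90%, 100% (11 sparsity levels)
DEFAULT_THRESHOLD_LEVELS: tuple[float, ...] = (0.01,) + tuple(
    round(0.1 * k, 1) for k in range(1, 11)
)

#: regularizer grid 2^-5, 2^-4, ..., 2^4, 2^5
DEFAULT_REGULARIZER_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 6))


def standardize_columns(x: np.ndarray, labels: Sequence[str] | None = None) -> np.ndarray:
    """Center each column to zero mean and scale it to unit Euclidean norm.

    Parameters
    ----------
    x
        V x P array of ROI signals.
    labels
        Optional ROI names, used only to make error messages informative.

    Raises
    ------
    DegenerateSignalError
        If any column is constant (zero norm after centering).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D array, got ndim={x.ndim}")
    centered = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    dead = np.flatnonzero(norms == 0.0)
    if dead.size:
        i = int(dead[0])
        name = labels[i] if labels is not None else f"column {i + 1}"
        raise DegenerateSignalError(f"constant signal in ROI {name!s}")
    return centered / norms


def pearson_fcn(x: np.ndarray, labels: Sequence[str] | None = None) -> np.ndarray:
    """Full-correlation network: W = X~^T X~ for the standardized series X~.

    Output is symmetric with unit diagonal and all entries clipped to [-1, 1]
    (clipping only absorbs floating-point overshoot).
    """
    xs = standardize_columns(x, labels)
    w = xs.T @ xs
    w = 0.5 * (w + w.T)
    np.clip(w, -1.0, 1.0, out=w)
    np.fill_diagonal(w, 1.0)
    return w


def _lasso_column(gram: np.ndarray, target: int, lam: float,
                  tol: float, max_sweeps: int) -> np.ndarray:
    """Cyclic coordinate descent for one reconstruction problem.

    Minimizes ``||x_t - sum_{j != t} w_j x_j||^2 + lam * sum |w_j|`` given the
    Gram matrix of unit-norm columns.  The target column is excluded from its
    own support by construction, not by penalty.
    """
    p = gram.shape[0]
    w = np.zeros(p)
    others = [j for j in range(p) if j != target]
    half = 0.5 * lam
    for _ in range(max_sweeps):
        delta = 0.0
        for j in others:
            # partial residual correlation with column j (unit norms => denom 1)
            cj = gram[j, target] - (gram[j] @ w - w[j])
            new = math.copysign(max(abs(cj) - half, 0.0), cj)
            delta = max(delta, abs(new - w[j]))
            w[j] = new
        if delta < tol:
            break
    return w


def sparse_representation_fcn(
    x: np.ndarray,
    lam: float,
    *,
    symmetrize: str | None = "avg",
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Sparse-representation network: each ROI regressed on all others with an
    l1 penalty and a zero self-weight constraint.

    Column *i* of the raw solution holds the coefficients reconstructing
    signal *i* from the remaining signals.  ``symmetrize`` controls the final
    projection: ``"avg"`` returns ``(W + W^T)/2``, ``"max"`` keeps the
    larger-magnitude entry of each pair, ``None`` returns the raw asymmetric
    solution.
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if symmetrize not in ("avg", "max", None):
        raise ValueError(f"unknown symmetrize mode {symmetrize!r}")
    xs = standardize_columns(x, labels)
    p = xs.shape[1]
    gram = xs.T @ xs
    w = np.zeros((p, p))
    for i in range(p):
        w[:, i] = _lasso_column(gram, i, lam, tol, max_sweeps)
    if symmetrize == "avg":
        w = 0.5 * (w + w.T)
    elif symmetrize == "max":
        pick = np.abs(w) >= np.abs(w.T)
        w = np.where(pick, w, w.T)
    np.fill_diagonal(w, 0.0)
    return w


def sliding_windows(n_volumes: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open, 0-based row ranges of every full sliding window.

    The k-th range (k = 0 .. K-1) is ``[k*step, k*step + width)`` with
    ``K = floor((V - width)/step) + 1``; trailing rows not covered by a full
    window are discarded.
    """
    k = spec.n_windows(n_volumes)  # raises WindowError when width > V
    return [(i * spec.step, i * spec.step + spec.width) for i in range(k)]


def windowed_fcns(
    x: np.ndarray,
    spec: WindowSpec,
    labels: Sequence[str] | None = None,
) -> list[np.ndarray]:
    """Full-correlation network of every sliding window, in window order.

    Each window slice is standardized independently before correlation.
    """
    x = np.asarray(x, dtype=float)
    out = []
    for k, (lo, hi) in enumerate(sliding_windows(x.shape[0], spec)):
        try:
            out.append(pearson_fcn(x[lo:hi], labels))
        except DegenerateSignalError as err:
            raise DegenerateSignalError(f"window {k + 1} [{lo}:{hi}): {err}") from err
    return out


def threshold_sparsify(w: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Keep only the strongest off-diagonal connections.

    Retains the ``ceil(keep_fraction * P(P-1)/2)`` upper-triangle entries with
    the largest absolute value (ties broken by (row, col) lexicographic order),
    zeroes the rest, and mirrors the result to the lower triangle.  The
    diagonal is preserved.  ``keep_fraction = 1`` keeps every edge.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    w = check_symmetric(w)
    p = w.shape[0]
    rows, cols = np.triu_indices(p, k=1)
    n_edges = rows.size
    n_keep = math.ceil(keep_fraction * n_edges)
    vals = w[rows, cols]
    # sort by (-|w|, row, col); lexsort keys are applied last-first
    order = np.lexsort((cols, rows, -np.abs(vals)))
    keep = order[:n_keep]
    out = np.zeros_like(w)
    out[np.diag_indices(p)] = np.diag(w)
    out[rows[keep], cols[keep]] = vals[keep]
    out[cols[keep], rows[keep]] = vals[keep]
    return out
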