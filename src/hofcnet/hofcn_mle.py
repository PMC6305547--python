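"""High-order network estimation by matrix-normal maximum likelihood.

A sequence of windowed low-order networks ``W_1 .. W_K`` is treated as a
sample from a matrix-variate normal with a single shared row/column
covariance Omega.  Omega is found by damped fixed-point iteration on

    Omega = (1 / (K P)) * sum_k (W_k - M) Omega^{-1} (W_k - M)^T

with M the entrywise mean of the sample and identity initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, SingularMatrixError

__all__ = ["HoFCNEstimate", "mean_network", "mle_step", "estimate_hofcn_mle"]

#: jitter escalation schedule applied before inversion (relative to tr/P scale)
_JITTER_LADDER = (1e-10, 1e-9, 1e-8, 1e-7, 1e-6)
_COND_LIMIT = 1e12


@dataclass
class HoFCNEstimate:
    """Converged (or capped) high-order network estimate.

    ``final_residual`` is the relative fixed-point defect
    ``||Omega - RHS(Omega)||_F / ||Omega||_F``.
    """

    omega: np.ndarray
    mean_network: np.ndarray
    n_windows: int
    iterations_run: int
    final_residual: float
    converged: bool


def mean_network(networks: Sequence[np.ndarray]) -> np.ndarray:
    """Entrywise mean of a non-empty, shape-consistent list of networks."""
    if len(networks) == 0:
        raise ValueError("cannot average an empty list of networks")
    stack = [np.asarray(w, dtype=float) for w in networks]
    shape = stack[0].shape
    for k, w in enumerate(stack):
        if w.shape != shape:
            raise ValueError(
                f"network {k + 1} has shape {w.shape}, expected {shape}"
            )
    return np.mean(stack, axis=0)


def _jittered_inverse(omega: np.ndarray) -> np.ndarray:
    """Invert *omega* after adding escalating diagonal jitter.

    The jitter is ``eps * (tr(Omega)/P) * I`` with eps escalating tenfold from
    1e-10 to 1e-6; if the conditioning never drops below 1e12 the matrix is
    declared singular.
    """
    p = omega.shape[0]
    scale = float(np.trace(omega)) / p
    if scale <= 0.0:
        scale = 1.0
    eye = np.eye(p)
    for eps in _JITTER_LADDER:
        candidate = omega + eps * scale * eye
        if np.linalg.cond(candidate) < _COND_LIMIT:
            return np.linalg.inv(candidate)
    raise SingularMatrixError(
        "matrix remained numerically singular after jitter up to 1e-6"
    )


def mle_step(
    networks: Sequence[np.ndarray],
    mean: np.ndarray,
    omega: np.ndarray,
) -> np.ndarray:
    """One application of the fixed-point map.

    Returns ``(1/(K P)) sum_k (W_k - mean) omega^{-1} (W_k - mean)^T``,
    symmetrized as ``(A + A^T)/2`` to absorb floating-point drift.
    """
    omega = np.asarray(omega, dtype=float)
    mean = np.asarray(mean, dtype=float)
    k = len(networks)
    p = omega.shape[0]
    inv = _jittered_inverse(omega)
    acc = np.zeros_like(omega)
    for w in networks:
        d = np.asarray(w, dtype=float) - mean
        acc += d @ inv @ d.T
    acc /= k * p
    return 0.5 * (acc + acc.T)


def estimate_hofcn_mle(
    networks: Sequence[np.ndarray],
    damping: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HoFCNEstimate:
    """Damped fixed-point iteration from the identity matrix.

    Parameters
    ----------
    networks
        K >= 2 windowed low-order networks of identical shape.
    damping
        Mixing weight eta in ``Omega <- (1 - eta) Omega + eta RHS(Omega)``.
        The undamped map can oscillate with period two; damping preserves its
        fixed points.
    tol
        Stop when the relative Frobenius change of the iterate drops below
        this value.
    max_iter
        Iteration cap; hitting it records ``converged=False`` and emits a
        warning rather than raising.
    """
    if not 0.0 < damping <= 1.0:
        raise ValueError(f"damping must be in (0, 1], got {damping}")
    if len(networks) < 2:
        raise ValueError(f"need at least 2 windowed networks, got {len(networks)}")
    stack = [np.asarray(w, dtype=float) for w in networks]
    m = mean_network(stack)
    spread = max(float(np.linalg.norm(w - m)) for w in stack)
    if spread <= 1e-12 * max(1.0, float(np.linalg.norm(m))):
        raise DegenerateInputError(
            "all windowed networks are identical; the scatter is zero"
        )
    p = m.shape[0]
    omega = np.eye(p)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        new = (1.0 - damping) * omega + damping * mle_step(stack, m, omega)
        denom = max(float(np.linalg.norm(omega)), np.finfo(float).tiny)
        change = float(np.linalg.norm(new - omega)) / denom
        omega = new
        if change < tol:
            converged = True
            break
    residual = float(
        np.linalg.norm(omega - mle_step(stack, m, omega))
        / max(float(np.linalg.norm(omega)), np.finfo(float).tiny)
    )
    if not converged:
        warnings.warn(
            f"fixed-point iteration did not converge in {max_iter} iterations "
            f"(relative residual {residual:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return HoFCNEstimate(
        omega=omega,
        mean_network=m,
        n_windows=len(stack),
        iterations_run=iterations,
        final_residual=residual,
        converged=converged,
    )
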