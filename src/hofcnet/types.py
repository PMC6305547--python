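"""Core domain containers: time-series matrices, connectivity matrices, window specs.

The numeric estimation routines in this package operate on plain ``numpy``
arrays; these thin dataclasses carry the arrays together with ROI labels across
the I/O and CLI layers.  Both expose ``__array__`` so they can be passed
directly wherever an array is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AsymmetricMatrixError, FormatError, WindowError

#: tolerance used everywhere a matrix is required to be symmetric
SYMMETRY_TOL = 1e-10


def default_roi_labels(p: int) -> list[str]:
    """Generate placeholder ROI labels ``ROI_001 ... ROI_p``."""
    width = max(3, len(str(p)))
    return [f"ROI_{i + 1:0{width}d}" for i in range(p)]


def check_symmetric(w: np.ndarray, tol: float = SYMMETRY_TOL) -> np.ndarray:
    """Validate that *w* is a square symmetric float matrix.

    Raises
    ------
    AsymmetricMatrixError
        If the asymmetry exceeds *tol*; the message reports ``max |W - W^T|``.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise FormatError(f"expected a square matrix, got shape {w.shape}")
    gap = float(np.max(np.abs(w - w.T))) if w.size else 0.0
    if gap > tol:
        raise AsymmetricMatrixError(
            f"matrix is not symmetric: max |W - W^T| = {gap:.3e} exceeds tol {tol:.1e}"
        )
    return w


@dataclass
class TimeSeriesMatrix:
    """One subject's ROI signals: V volumes (rows) by P ROIs (columns)."""

    data: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(f"time series must be 2-D, got ndim={self.data.ndim}")
        v, p = self.data.shape
        if v < 2 or p < 2:
            raise FormatError(f"time series needs V >= 2 and P >= 2, got V={v}, P={p}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite entry at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        if not self.labels:
            self.labels = default_roi_labels(p)
        if len(self.labels) != p:
            raise FormatError(
                f"label count {len(self.labels)} does not match P={p}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted network over P ROIs."""

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = check_symmetric(self.weights)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("connectivity matrix contains non-finite entries")
        p = self.weights.shape[0]
        if not self.labels:
            self.labels = default_roi_labels(p)
        if len(self.labels) != p:
            raise FormatError(
                f"label count {len(self.labels)} does not match P={p}"
            )

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.weights, dtype=dtype)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window scheme: width in volumes and step between window starts."""

    width: int
    step: int

    def __post_init__(self) -> None:
        if self.width < 2:
            raise WindowError(f"window width must be >= 2, got {self.width}")
        if self.step < 1:
            raise WindowError(f"window step must be >= 1, got {self.step}")

    def n_windows(self, n_volumes: int) -> int:
        """Number of full windows fitting in a series of *n_volumes* rows."""
        if self.width > n_volumes:
            raise WindowError(
                f"window width {self.width} exceeds series length {n_volumes}"
            )
        return (n_volumes - self.width) // self.step + 1
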