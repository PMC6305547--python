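"""Seeded generators for every input the pipeline consumes.

Three families:

* multivariate Gaussian BOLD surrogates with a block (modular) correlation
  structure, optionally AR(1)-filtered in time;
* matrix-normal samples of connectivity matrices with a known shared
  row/column covariance;
* two-class cohorts whose groups differ by a correlation shift planted on a
  chosen set of edges.

Sub-seeding scheme: subject ``k`` of a cohort draws from
``numpy.random.default_rng([seed, k])`` — a counter-based derivation that is
stable across platforms and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SpecError
from .types import TimeSeriesMatrix, default_roi_labels

__all__ = [
    "ModularCovSpec",
    "CohortSpec",
    "CohortDataset",
    "make_modular_cov",
    "sample_bold",
    "sample_matrix_normal",
    "make_cohort",
]

_PD_EIG_FLOOR = 1e-8  # smallest eigenvalue accepted as "positive definite"
_CLIP_FLOOR = 1e-6  # eigenvalue floor used when projecting perturbed matrices


@dataclass(frozen=True)
class ModularCovSpec:
    """Block-structured correlation model scaled by a common noise variance."""

    n_rois: int
    n_modules: int = 1
    within_corr: float = 0.5
    between_corr: float = 0.1
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise SpecError(f"need at least 2 ROIs, got {self.n_rois}")
        if not 1 <= self.n_modules <= self.n_rois:
            raise SpecError(f"n_modules must be in [1, {self.n_rois}]")
        if not 0.0 < self.within_corr < 1.0:
            raise SpecError(f"within_corr must be in (0, 1), got {self.within_corr}")
        if not 0.0 <= self.between_corr <= self.within_corr:
            raise SpecError(
                "between_corr must satisfy 0 <= between_corr <= within_corr, "
                f"got {self.between_corr} vs {self.within_corr}"
            )
        if self.noise_sd <= 0:
            raise SpecError(f"noise_sd must be positive, got {self.noise_sd}")

    def module_of(self) -> np.ndarray:
        """Module index of every ROI (sizes as equal as possible, in order)."""
        chunks = np.array_split(np.arange(self.n_rois), self.n_modules)
        return np.concatenate([np.full(len(c), m) for m, c in enumerate(chunks)])


@dataclass(frozen=True)
class CohortSpec:
    """Two-class cohort with a correlation effect planted on selected edges."""

    n_pos: int
    n_neg: int
    n_volumes: int
    base: ModularCovSpec
    affected_edges: tuple[tuple[int, int], ...] = ()
    effect_size: float = 0.0
    seed: int = 0
    ar_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise SpecError("both groups need at least one subject")
        if self.n_volumes < 2:
            raise SpecError(f"need at least 2 volumes, got {self.n_volumes}")
        if not 0.0 <= self.ar_coef < 1.0:
            raise SpecError(f"ar_coef must be in [0, 1), got {self.ar_coef}")
        p = self.base.n_rois
        for i, j in self.affected_edges:
            if not (0 <= i < j < p):
                raise SpecError(f"affected edge ({i}, {j}) invalid for P={p}: need 0 <= i < j < P")


@dataclass
class CohortDataset:
    """In-memory cohort: parallel lists of ids, time series and string labels."""

    subject_ids: list[str]
    series: list[TimeSeriesMatrix]
    labels: list[str]
    spec: CohortSpec | None = None
    positive_label: str = "positive"

    def numeric_labels(self) -> np.ndarray:
        return np.where(np.asarray(self.labels) == self.positive_label, 1, -1)

    def __len__(self) -> int:
        return len(self.subject_ids)


def _assert_pd(cov: np.ndarray, context: str) -> None:
    eigmin = float(np.linalg.eigvalsh(cov)[0])
    if eigmin <= _PD_EIG_FLOOR:
        raise SpecError(
            f"{context}: smallest eigenvalue {eigmin:.3e} <= {_PD_EIG_FLOOR:.0e}; "
            "use smaller correlation contrasts or effects"
        )


def make_modular_cov(spec: ModularCovSpec) -> np.ndarray:
    """Block correlation matrix scaled by noise_sd^2.

    Within-module entries equal ``within_corr``, between-module entries
    ``between_corr``, unit diagonal (before scaling).  Positive definiteness
    is verified by eigensolve before returning.
    """
    modules = spec.module_of()
    same = modules[:, None] == modules[None, :]
    r = np.where(same, spec.within_corr, spec.between_corr)
    np.fill_diagonal(r, 1.0)
    _assert_pd(r, "modular covariance spec")
    return spec.noise_sd**2 * r


def sample_bold(
    cov: np.ndarray,
    n_volumes: int,
    seed: int | Sequence[int],
    *,
    ar_coef: float = 0.0,
    labels: Sequence[str] | None = None,
) -> TimeSeriesMatrix:
    """Draw Gaussian BOLD surrogate rows with the given spatial covariance.

    Rows are i.i.d. by default; with ``ar_coef = rho > 0`` an AR(1) filter
    ``x_t = rho x_{t-1} + sqrt(1 - rho^2) e_t`` is applied along time, which
    preserves the stationary spatial covariance.
    """
    cov = np.asarray(cov, dtype=float)
    if n_volumes < 2:
        raise ValueError(f"need at least 2 volumes, got {n_volumes}")
    _assert_pd(cov, "sampling covariance")
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_volumes, cov.shape[0]))
    x = z @ chol.T
    if ar_coef > 0.0:
        scale = np.sqrt(1.0 - ar_coef**2)
        for t in range(1, n_volumes):
            x[t] = ar_coef * x[t - 1] + scale * x[t]
    lab = list(labels) if labels is not None else default_roi_labels(cov.shape[0])
    return TimeSeriesMatrix(x, lab)


def sample_matrix_normal(
    mean: np.ndarray,
    sigma: np.ndarray,
    n_samples: int,
    seed: int,
) -> list[np.ndarray]:
    """Draw ``W_k = M + A Z_k A^T`` with ``A A^T = Sigma`` and Z_k i.i.d. standard normal.

    Sigma acts as both the row and the column covariance, matching the
    single-shared-covariance matrix-normal model the MLE iteration assumes.
    """
    mean = np.asarray(mean, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if n_samples < 0:
        raise ValueError(f"n_samples must be non-negative, got {n_samples}")
    _assert_pd(sigma, "matrix-normal covariance")
    a = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(seed)
    p = sigma.shape[0]
    return [mean + a @ rng.standard_normal((p, p)) @ a.T for _ in range(n_samples)]


def _perturbed_correlation(spec: CohortSpec) -> np.ndarray:
    """Base correlation with the effect added on affected edges, projected PD.

    The effect is planted on correlations; if any perturbed entry leaves
    [-1, 1] the spec is rejected.  The result is projected to the nearest
    positive-definite matrix by clipping eigenvalues at 1e-6.
    """
    r = make_modular_cov(spec.base) / spec.base.noise_sd**2
    for i, j in spec.affected_edges:
        r[i, j] += spec.effect_size
        r[j, i] += spec.effect_size
    off = r - np.diag(np.diag(r))
    if np.any(np.abs(off) > 1.0):
        raise SpecError(
            "effect pushes a correlation outside [-1, 1]; reduce effect_size"
        )
    evals, evecs = np.linalg.eigh(r)
    if evals[0] <= _PD_EIG_FLOOR:
        r = (evecs * np.clip(evals, _CLIP_FLOOR, None)) @ evecs.T
        _assert_pd(r, "perturbed covariance after projection")
    return spec.base.noise_sd**2 * r


def make_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate the full two-class cohort deterministically from spec.seed.

    Negative subjects draw from the base covariance; positive subjects from
    the edge-perturbed covariance.  Subject ``k`` (0-based, positives first)
    uses the sub-seed ``[seed, k]``.
    """
    cov_neg = make_modular_cov(spec.base)
    cov_pos = _perturbed_correlation(spec)
    n = spec.n_pos + spec.n_neg
    width = max(3, len(str(n)))
    ids, series, labels = [], [], []
    roi_labels = default_roi_labels(spec.base.n_rois)
    for k in range(n):
        positive = k < spec.n_pos
        ts = sample_bold(
            cov_pos if positive else cov_neg,
            spec.n_volumes,
            [spec.seed, k],
            ar_coef=spec.ar_coef,
            labels=roi_labels,
        )
        ids.append(f"sub_{k + 1:0{width}d}")
        series.append(ts)
        labels.append("positive" if positive else "negative")
    return CohortDataset(ids, series, labels, spec=spec)
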