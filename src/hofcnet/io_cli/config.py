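"""Run configuration: validated estimator / CV parameters and a flat-file loader."""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from ..errors import ConfigError
from ..lowfcn import DEFAULT_REGULARIZER_GRID, DEFAULT_THRESHOLD_LEVELS

__all__ = ["RunConfig", "load_config", "ESTIMATORS"]

ESTIMATORS = ("pc", "sr", "hofcn_mle", "s_hofcn", "m_hofcn")


@dataclass
class RunConfig:
    """Everything a classification or estimation run needs, in one place.

    ``grid`` holds regularizer strengths for sr / s_hofcn / m_hofcn (for
    m_hofcn it is expanded to the (mu1, mu2) product grid unless explicit
    pairs are given); ``threshold_levels`` are the keep-fractions used as the
    grid for pc / hofcn_mle.
    """

    estimator: str = "pc"
    window_width: int = 70
    window_step: int = 1
    grid: tuple = tuple(DEFAULT_REGULARIZER_GRID)
    threshold_levels: tuple = tuple(DEFAULT_THRESHOLD_LEVELS)
    svm_c: float = 1.0
    ttest_p: float = 0.05
    seed: int = 0
    positive_label: str = "positive"
    alpha: float = 0.5
    damping: float = 0.5
    mle_tol: float = 1e-6
    mle_max_iter: int = 500
    prox_tol: float = 1e-6
    prox_max_iter: int = 1000
    sr_tol: float = 1e-8
    sr_max_sweeps: int = 10_000
    ista_scaling: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ConfigError(
                f"unknown estimator {self.estimator!r}; expected one of {ESTIMATORS}"
            )
        if self.window_width < 2:
            raise ConfigError(f"window_width must be >= 2, got {self.window_width}")
        if self.window_step < 1:
            raise ConfigError(f"window_step must be >= 1, got {self.window_step}")
        self.grid = tuple(self.grid)
        if len(self.grid) == 0:
            raise ConfigError("grid must be non-empty")
        flat = [g for g in self.grid if not isinstance(g, (tuple, list))]
        if flat == list(self.grid) and list(self.grid) != sorted(self.grid):
            raise ConfigError("grid values must be ascending")
        self.threshold_levels = tuple(self.threshold_levels)
        if not self.threshold_levels or not all(
            0.0 < t <= 1.0 for t in self.threshold_levels
        ):
            raise ConfigError("threshold_levels must be non-empty and lie in (0, 1]")
        if self.svm_c <= 0:
            raise ConfigError(f"svm_c must be positive, got {self.svm_c}")
        if not 0.0 < self.ttest_p < 1.0:
            raise ConfigError(f"ttest_p must be in (0, 1), got {self.ttest_p}")

    def resolved(self) -> dict:
        """JSON-serializable record of the full configuration."""
        d = asdict(self)
        d["grid"] = [list(g) if isinstance(g, (tuple, list)) else g for g in self.grid]
        d["threshold_levels"] = list(self.threshold_levels)
        return d


def _coerce(raw: str):
    try:
        return json.loads(raw)
    except json.JSONDecodeError:
        return raw


def load_config(path: os.PathLike | str, **overrides) -> RunConfig:
    """Parse a flat ``key = value`` file (values in JSON syntax where needed).

    Lines starting with ``#`` are comments.  Unknown keys raise; keys missing
    from the file fall back to defaults, with *overrides* taking precedence.
    """
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}: line {i + 1} is not 'key = value': {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ConfigError(f"{path}: unknown config key {key!r}")
        values[key] = _coerce(raw.strip())
    values.update(overrides)
    return RunConfig(**values)
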