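"""Glue between the estimators and the CLI: per-method recipes and runners.

A "recipe" is the deterministic per-subject map ``(data, grid value) ->
network`` that :func:`hofcnet.classify.nested_loocv` evaluates; ``data`` is
whatever per-subject intermediate the method needs (the raw time series for
pc/sr, the converged MLE network for the high-order methods).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from ..classify import EvalResult, nested_loocv
from ..hofcn_mle import estimate_hofcn_mle
from ..hofcn_prox import ProxConfig, refine_m_hofcn, refine_s_hofcn
from ..lowfcn import (
    pearson_fcn,
    sparse_representation_fcn,
    threshold_sparsify,
    windowed_fcns,
)
from ..types import ConnectivityMatrix, TimeSeriesMatrix, WindowSpec
from .config import RunConfig

__all__ = [
    "prepare_subject",
    "make_recipe",
    "method_grid",
    "estimate_network",
    "run_classification",
    "result_table",
]

EVAL_COLUMNS = [
    "method", "N", "s", "param", "fold", "subject_id",
    "TP", "TN", "FP", "FN", "ACC", "SEN", "SPE",
]


def _window_spec(cfg: RunConfig) -> WindowSpec:
    return WindowSpec(cfg.window_width, cfg.window_step)


def prepare_subject(ts: TimeSeriesMatrix, cfg: RunConfig) -> Any:
    """Per-subject precomputation done once, before any grid search.

    High-order methods compute the windowed networks and the MLE fixed point
    here; low-order methods pass the raw series through.
    """
    if cfg.estimator in ("hofcn_mle", "s_hofcn", "m_hofcn"):
        windows = windowed_fcns(ts.data, _window_spec(cfg), ts.labels)
        est = estimate_hofcn_mle(
            windows, damping=cfg.damping, tol=cfg.mle_tol, max_iter=cfg.mle_max_iter
        )
        return est.omega
    return ts


def make_recipe(cfg: RunConfig) -> Callable[[Any, Any], np.ndarray]:
    """Map a prepared subject and one grid value to a network matrix."""
    est = cfg.estimator
    if est == "pc":
        return lambda ts, keep: threshold_sparsify(pearson_fcn(ts.data, ts.labels), keep)
    if est == "sr":
        return lambda ts, lam: sparse_representation_fcn(
            ts.data, lam, tol=cfg.sr_tol, max_sweeps=cfg.sr_max_sweeps, labels=ts.labels
        )
    if est == "hofcn_mle":
        return lambda omega, keep: threshold_sparsify(omega, keep)
    if est == "s_hofcn":
        return lambda omega, mu: refine_s_hofcn(
            omega,
            ProxConfig(mu=mu, alpha=cfg.alpha, tol=cfg.prox_tol,
                       max_iter=cfg.prox_max_iter, ista_scaling=cfg.ista_scaling),
        )
    if est == "m_hofcn":
        return lambda omega, mus: refine_m_hofcn(
            omega,
            ProxConfig(mu1=mus[0], mu2=mus[1], alpha=cfg.alpha, tol=cfg.prox_tol,
                       max_iter=cfg.prox_max_iter, ista_scaling=cfg.ista_scaling),
        )
    raise ValueError(f"unknown estimator {est!r}")


def method_grid(cfg: RunConfig) -> list:
    """Hyperparameter grid searched for the configured estimator.

    pc / hofcn_mle use the keep-fraction levels; sr / s_hofcn use the scalar
    regularizer grid; m_hofcn uses explicit (mu1, mu2) pairs when provided,
    otherwise the full product of the scalar grid with itself.
    """
    if cfg.estimator in ("pc", "hofcn_mle"):
        return list(cfg.threshold_levels)
    if cfg.estimator == "m_hofcn":
        if cfg.grid and isinstance(cfg.grid[0], (tuple, list)):
            return [tuple(g) for g in cfg.grid]
        return [(m1, m2) for m1 in cfg.grid for m2 in cfg.grid]
    return list(cfg.grid)


def estimate_network(ts: TimeSeriesMatrix, cfg: RunConfig, param=None) -> ConnectivityMatrix:
    """One subject's network for a fixed hyperparameter (no thresholding
    for pc / hofcn_mle unless a keep-fraction is given)."""
    prepared = prepare_subject(ts, cfg)
    if cfg.estimator in ("pc", "hofcn_mle") and param is None:
        w = pearson_fcn(ts.data, ts.labels) if cfg.estimator == "pc" else prepared
        return ConnectivityMatrix(np.asarray(w), list(ts.labels))
    if param is None:
        param = method_grid(cfg)[0]
    w = make_recipe(cfg)(prepared, param)
    return ConnectivityMatrix(np.asarray(w), list(ts.labels))


@dataclass
class ClassificationRun:
    """One nested-LOOCV evaluation plus the context needed to report it."""

    cfg: RunConfig
    result: EvalResult
    subject_ids: list[str]


def run_classification(
    subjects: Sequence[tuple[str, TimeSeriesMatrix, int]],
    cfg: RunConfig,
    *,
    log=sys.stderr,
) -> ClassificationRun:
    """Prepare every subject, then run the nested LOOCV for ``cfg.estimator``."""
    cohort = []
    for sid, ts, label in subjects:
        cohort.append((sid, prepare_subject(ts, cfg), label))
        if log is not None:
            print(f"prepared {sid}", file=log)
    result = nested_loocv(
        cohort, make_recipe(cfg), method_grid(cfg),
        p_thresh=cfg.ttest_p, c=cfg.svm_c,
    )
    if log is not None:
        for (sid, truth, pred), param in zip(result.predictions, result.fold_params):
            print(f"fold {sid}: true={truth:+d} pred={pred:+d} param={param!r}", file=log)
    return ClassificationRun(cfg=cfg, result=result, subject_ids=[s[0] for s in subjects])


def result_table(run: ClassificationRun) -> pd.DataFrame:
    """Per-fold rows plus one summary row, in the documented column order."""
    cfg, res = run.cfg, run.result
    rows = []
    for (sid, truth, pred), param in zip(res.predictions, res.fold_params):
        rows.append({
            "method": cfg.estimator, "N": cfg.window_width, "s": cfg.window_step,
            "param": repr(param), "fold": sid, "subject_id": sid,
            "TP": int(truth > 0 and pred > 0), "TN": int(truth < 0 and pred < 0),
            "FP": int(truth < 0 and pred > 0), "FN": int(truth > 0 and pred < 0),
            "ACC": "", "SEN": "", "SPE": "",
        })
    rows.append({
        "method": cfg.estimator, "N": cfg.window_width, "s": cfg.window_step,
        "param": "", "fold": "ALL", "subject_id": "",
        "TP": res.tp, "TN": res.tn, "FP": res.fp, "FN": res.fn,
        "ACC": repr(res.acc), "SEN": repr(res.sen), "SPE": repr(res.spe),
    })
    return pd.DataFrame(rows, columns=EVAL_COLUMNS)
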