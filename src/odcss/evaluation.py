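"""Evaluation metrics and the moving-window / just-in-time GPR baselines.

Metrics follow the standard soft-sensor conventions: RMSE and MAE for
closeness, MAPE in percent (undefined when any true value is zero), and
the coefficient of determination R^2 = 1 - SSE/SST.  ``cumulative_rmse``
tracks the prequential RMSE from the first labeled prediction to the
current one, the usual way drifting-stream performance is visualized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import KernelConfig
from .gpr import fit_gpr, predict_gpr
from .pipeline import RunResult
from .predictor import PredictionResult, rank_labeled_by_similarity
from .stream import SemiSupervisedStream, StreamSample, apply_scaler, fit_scaler

__all__ = [
    "MetricReport",
    "compute_metrics",
    "cumulative_rmse",
    "run_mwgpr",
    "run_jitgpr",
    "run_static_gpr",
]


@dataclass(frozen=True)
class MetricReport:
    rmse: float
    mae: float
    mape_percent: Optional[float]  # None when a zero true value makes it undefined
    r2: float
    n_test: int


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricReport:
    """RMSE, MAE, MAPE (percent) and R^2 of a prediction vector."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mape = (
        float(np.mean(np.abs(err / y_true)) * 100.0) if np.all(y_true != 0) else None
    )
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return MetricReport(rmse=rmse, mae=mae, mape_percent=mape, r2=r2, n_test=y_true.size)


def cumulative_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Element k is the RMSE over the first k+1 prediction pairs."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    se = (y_pred - y_true) ** 2
    return np.sqrt(np.cumsum(se) / np.arange(1, se.size + 1))


def _finalize(predictions, truth, config=None) -> RunResult:
    result = RunResult(predictions=predictions, truth=truth, events=[], config=config)
    y_true, y_pred = result.labeled_pairs()
    if y_true.size >= 1:
        result.metrics = compute_metrics(y_true, y_pred)
    return result


def run_mwgpr(
    stream: SemiSupervisedStream | Sequence[StreamSample],
    init_labeled: Sequence[StreamSample],
    window_width: int = 50,
    kernel: KernelConfig | None = None,
    seed: int = 0,
) -> RunResult:
    """Moving-window GPR baseline.

    A GP is fitted on the most recent ``window_width`` labeled samples;
    every tick is predicted with the current window model, and the window
    slides when a new label arrives (after that tick's prediction, keeping
    the protocol prequential).  The window ranges over labeled samples
    only — a window over mostly-unlabeled ticks would starve the model.
    """
    if window_width < 2:
        raise ValueError("window_width must be >= 2")
    kernel = kernel or KernelConfig()
    scaler = fit_scaler(list(init_labeled))
    window = [
        StreamSample(t=s.t, x=apply_scaler(scaler, s.x), y=s.y) for s in init_labeled
    ]
    model = None
    predictions, truth = [], {}
    for sample in stream:
        z = apply_scaler(scaler, sample.x)
        if model is None:
            tail = window[-window_width:]
            model = fit_gpr(
                np.vstack([s.x for s in tail]),
                np.array([s.y for s in tail], dtype=float),
                kernel,
                seed=seed,
            )
        y_hat, _ = predict_gpr(model, z)
        predictions.append(
            (sample.t, PredictionResult(y_hat=y_hat, route="ensemble",
                                        contributors=[s.t for s in window[-window_width:]],
                                        per_model=[y_hat]))
        )
        if sample.is_labeled:
            truth[sample.t] = float(sample.y)
            window.append(StreamSample(t=sample.t, x=z, y=sample.y))
            model = None  # refit on the slid window at next use
    return _finalize(predictions, truth)


def run_jitgpr(
    stream: SemiSupervisedStream | Sequence[StreamSample],
    init_labeled: Sequence[StreamSample],
    k: int = 50,
    measure: str = "euclidean",
    kernel: KernelConfig | None = None,
    seed: int = 0,
) -> RunResult:
    """Just-in-time GPR baseline: every tick gets a disposable local GP
    fitted on the ``k`` labeled samples most similar to the query, drawn
    from the growing labeled database."""
    if k < 2:
        raise ValueError("k must be >= 2")
    kernel = kernel or KernelConfig()
    scaler = fit_scaler(list(init_labeled))
    db = [StreamSample(t=s.t, x=apply_scaler(scaler, s.x), y=s.y) for s in init_labeled]
    predictions, truth = [], {}
    for sample in stream:
        z = apply_scaler(scaler, sample.x)
        ranked = rank_labeled_by_similarity(db, z, measure)
        chosen = ranked[: min(k, len(ranked))]
        model = fit_gpr(
            np.vstack([s.x for s in chosen]),
            np.array([s.y for s in chosen], dtype=float),
            kernel,
            seed=seed,
        )
        y_hat, _ = predict_gpr(model, z)
        predictions.append(
            (sample.t, PredictionResult(y_hat=y_hat, route="jit",
                                        contributors=[s.t for s in chosen],
                                        per_model=[y_hat]))
        )
        if sample.is_labeled:
            truth[sample.t] = float(sample.y)
            db.append(StreamSample(t=sample.t, x=z, y=sample.y))
    return _finalize(predictions, truth)


def run_static_gpr(
    stream: SemiSupervisedStream | Sequence[StreamSample],
    init_labeled: Sequence[StreamSample],
    kernel: KernelConfig | None = None,
    seed: int = 0,
) -> RunResult:
    """Static reference: one GP fitted on the initial training set and never
    updated.  Quantifies what adaptation buys under drift."""
    kernel = kernel or KernelConfig()
    scaler = fit_scaler(list(init_labeled))
    model = fit_gpr(
        np.vstack([apply_scaler(scaler, s.x) for s in init_labeled]),
        np.array([s.y for s in init_labeled], dtype=float),
        kernel,
        seed=seed,
    )
    predictions, truth = [], {}
    for sample in stream:
        y_hat, _ = predict_gpr(model, apply_scaler(scaler, sample.x))
        predictions.append(
            (sample.t, PredictionResult(y_hat=y_hat, route="ensemble",
                                        contributors=[0], per_model=[y_hat]))
        )
        if sample.is_labeled:
            truth[sample.t] = float(sample.y)
    return _finalize(predictions, truth)
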