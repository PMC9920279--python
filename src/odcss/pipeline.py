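"""Top-level orchestration: the streaming soft-sensor estimator.

The method is prequential (test-then-train): every arriving sample is
first clustered on features alone, then predicted, and only afterwards is
its label — true or self-training pseudo — allowed to update any model
state.  A sample's own label therefore never leaks into its own
prediction.

:class:`ODCSSRegressor` packages the whole method as a scikit-learn style
estimator: ``fit`` consumes the initial labeled training set, ``predict``
gives non-mutating point predictions, and ``run`` / ``process_sample``
expose the streaming protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .clustering import ODCState, AssignmentEvent, distances_to_centers, odc_step
from .config import KernelConfig, RunConfig
from .predictor import ColdStartError, PredictionResult, predict
from .self_training import IRDecision, maybe_augment, on_true_label
from .stream import (
    LABELED,
    ScalingStats,
    SemiSupervisedStream,
    StreamSample,
    apply_scaler,
    fit_scaler,
)

__all__ = ["RunResult", "ODCSSRegressor", "initialize", "run_stream", "run_odcss_s"]


@dataclass
class RunResult:
    """Everything one prequential run produced."""

    predictions: list[tuple[int, Optional[PredictionResult]]]
    truth: dict[int, float]
    events: list[AssignmentEvent]
    config: Optional[RunConfig] = None
    metrics: object = None
    decisions: list[tuple[int, IRDecision]] = field(default_factory=list)
    state: Optional[ODCState] = None  # final clustering state, when available

    def labeled_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(y_true, y_pred) on labeled ticks that received a prediction."""
        yt, yp = [], []
        for tick, pred in self.predictions:
            if pred is not None and tick in self.truth:
                yt.append(self.truth[tick])
                yp.append(pred.y_hat)
        return np.array(yt), np.array(yp)

    def prediction_at(self, tick: int) -> Optional[PredictionResult]:
        for t, pred in self.predictions:
            if t == tick:
                return pred
        raise KeyError(f"no prediction recorded for tick {tick}")


def initialize(
    init_labeled: Sequence[StreamSample], config: RunConfig
) -> tuple[ScalingStats, ODCState]:
    """Build the starting state from the initial labeled training set.

    The scaler is fitted on this set and held fixed; the samples are then
    replayed through the clustering engine in order, so initialization and
    streaming share one code path.  Per-cluster models are left dirty and
    built lazily on first use.
    """
    init_labeled = list(init_labeled)
    if len(init_labeled) < 4:
        raise ValueError("initial training set too small")
    if any(not s.is_labeled for s in init_labeled):
        raise ValueError("initial training set must be fully labeled")
    scaler = fit_scaler(init_labeled)
    state = ODCState(config=config)
    for s in init_labeled:
        z = StreamSample(t=s.t, x=apply_scaler(scaler, s.x), y=s.y)
        odc_step(state, z, provenance=LABELED, y=float(s.y))
        state.labeled_db.append(z)
    return scaler, state


def _tick_seed(config: RunConfig, tick: int) -> int:
    return (config.seed ^ (tick * 2654435761)) & 0x7FFFFFFF


def process_sample(
    scaler: ScalingStats,
    state: ODCState,
    sample: StreamSample,
    config: RunConfig,
) -> tuple[Optional[PredictionResult], Optional[IRDecision]]:
    """One prequential step: cluster, predict, then learn.

    Returns (prediction, IR decision); either may be None — the prediction
    during cold start, the decision for labeled ticks or when augmentation
    is off/skipped.
    """
    z = apply_scaler(scaler, sample.x)
    zsample = StreamSample(t=sample.t, x=z)  # label withheld from this tick's model state
    event = odc_step(state, zsample)
    joined = event.kind == "joined_clusters"

    try:
        pred = predict(state, z, config,
                       joined_cluster_ids=event.cluster_ids if joined else None,
                       seed=_tick_seed(config, sample.t))
    except ColdStartError:
        pred = None

    decision: Optional[IRDecision] = None
    if sample.is_labeled:
        on_true_label(state, StreamSample(t=sample.t, x=z, y=sample.y), config)
    elif config.augment and pred is not None:
        decision = maybe_augment(
            state, zsample, pred.y_hat, config,
            joined_cluster_ids=event.cluster_ids if joined else (),
        )
    return pred, decision


def run_stream(
    stream: SemiSupervisedStream | Sequence[StreamSample],
    init_labeled: Sequence[StreamSample],
    config: RunConfig,
) -> RunResult:
    """Initialize from the labeled training set, then fold the stream.

    Metrics are computed on labeled ticks only (cold-start ticks without a
    prediction are excluded).
    """
    scaler, state = initialize(init_labeled, config)
    predictions: list[tuple[int, Optional[PredictionResult]]] = []
    truth: dict[int, float] = {}
    decisions: list[tuple[int, IRDecision]] = []
    for sample in stream:
        pred, decision = process_sample(scaler, state, sample, config)
        predictions.append((sample.t, pred))
        if sample.is_labeled:
            truth[sample.t] = float(sample.y)
        if decision is not None:
            decisions.append((sample.t, decision))
    result = RunResult(
        predictions=predictions,
        truth=truth,
        events=state.events,
        config=config,
        decisions=decisions,
        state=state,
    )
    from .evaluation import compute_metrics  # local import avoids a cycle

    y_true, y_pred = result.labeled_pairs()
    if y_true.size >= 1:
        result.metrics = compute_metrics(y_true, y_pred)
    return result


def run_odcss_s(
    stream: SemiSupervisedStream | Sequence[StreamSample],
    init_labeled: Sequence[StreamSample],
    config: RunConfig,
) -> RunResult:
    """Supervised-only variant: the unlabeled ticks are dropped entirely
    and self-training is disabled."""
    labeled_only = [s for s in stream if s.is_labeled]
    cfg = RunConfig(**{**_config_dict(config), "augment": False})
    return run_stream(labeled_only, init_labeled, cfg)


def _config_dict(config: RunConfig) -> dict:
    return {name: getattr(config, name) for name in RunConfig.__dataclass_fields__}


class ODCSSRegressor(BaseEstimator, RegressorMixin):
    """Online dynamic-clustering soft sensor as a scikit-learn estimator.

    Parameters mirror :class:`~odcss.config.RunConfig`; see there for the
    scientific meaning of each knob.  ``fit(X, y)`` consumes the initial
    labeled training set; ``run(stream)`` performs the prequential
    test-then-train pass; ``predict(X)`` gives point predictions from the
    current state without updating it.

    Attributes
    ----------
    scaler_ : ScalingStats
        Standardization statistics fitted on the initial training set.
    state_ : ODCState
        The evolving cluster/outlier/labeled-database state.
    config_ : RunConfig
        The frozen run configuration assembled from the parameters.
    """

    def __init__(
        self,
        R: float = 3.0,
        M: int = 10,
        alpha: float = 0.4,
        P: float = 0.5,
        IR_th: float = 0.1,
        m_max: int = 2,
        k_jit: int = 50,
        similarity: str = "euclidean",
        val_fraction: float = 0.3,
        nu: float = 2.5,
        optimize_hyperparams: bool = True,
        augment: bool = True,
        spatial_inverse: bool = False,
        keep_rejected_unlabeled: bool = False,
        seed: int = 0,
    ):
        self.R = R
        self.M = M
        self.alpha = alpha
        self.P = P
        self.IR_th = IR_th
        self.m_max = m_max
        self.k_jit = k_jit
        self.similarity = similarity
        self.val_fraction = val_fraction
        self.nu = nu
        self.optimize_hyperparams = optimize_hyperparams
        self.augment = augment
        self.spatial_inverse = spatial_inverse
        self.keep_rejected_unlabeled = keep_rejected_unlabeled
        self.seed = seed

    # -- construction helpers -------------------------------------------------

    def _make_config(self) -> RunConfig:
        return RunConfig(
            R=self.R,
            M=self.M,
            alpha=self.alpha,
            P=self.P,
            IR_th=self.IR_th,
            m_max=self.m_max,
            k_jit=self.k_jit,
            similarity=self.similarity,
            val_fraction=self.val_fraction,
            kernel=KernelConfig(nu=self.nu, optimize=self.optimize_hyperparams),
            seed=self.seed,
            augment=self.augment,
            spatial_inverse=self.spatial_inverse,
            keep_rejected_unlabeled=self.keep_rejected_unlabeled,
        )

    # -- sklearn surface ------------------------------------------------------

    def fit(self, X, y, ticks=None):
        """Initialize from the labeled training set (rows of X with targets y)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if ticks is None:
            ticks = np.arange(X.shape[0])
        samples = [
            StreamSample(t=int(t), x=x, y=float(v)) for t, x, v in zip(ticks, X, y)
        ]
        return self.fit_samples(samples)

    def fit_samples(self, init_labeled: Sequence[StreamSample]):
        """Initialize from labeled :class:`StreamSample` objects directly."""
        self.config_ = self._make_config()
        self.scaler_, self.state_ = initialize(init_labeled, self.config_)
        self.n_features_in_ = self.scaler_.d
        self._next_tick = max(s.t for s in init_labeled) + 1
        self._predictions: list[tuple[int, Optional[PredictionResult]]] = []
        self._truth: dict[int, float] = {}
        self._decisions: list[tuple[int, IRDecision]] = []
        return self

    def predict(self, X) -> np.ndarray:
        """Point predictions from the current state; the state is not updated."""
        check_is_fitted(self, "state_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = np.empty(X.shape[0])
        for i, x in enumerate(X):
            z = apply_scaler(self.scaler_, x)
            dists = distances_to_centers(self.state_, z)
            joined_ids = [
                cl.id for cl, d in zip(self.state_.clusters, dists)
                if d <= self.config_.R
            ]
            out[i] = predict(self.state_, z, self.config_,
                             joined_cluster_ids=joined_ids or None).y_hat
        return out

    # -- streaming surface ----------------------------------------------------

    def process_sample(self, sample: StreamSample) -> Optional[PredictionResult]:
        """Prequential step on one sample; records prediction and truth."""
        check_is_fitted(self, "state_")
        pred, decision = process_sample(self.scaler_, self.state_, sample, self.config_)
        self._predictions.append((sample.t, pred))
        if sample.is_labeled:
            self._truth[sample.t] = float(sample.y)
        if decision is not None:
            self._decisions.append((sample.t, decision))
        return pred

    def run(self, stream: SemiSupervisedStream | Sequence[StreamSample]) -> RunResult:
        """Fold a whole stream prequentially and return the collected result."""
        check_is_fitted(self, "state_")
        for sample in stream:
            self.process_sample(sample)
        result = RunResult(
            predictions=list(self._predictions),
            truth=dict(self._truth),
            events=list(self.state_.events),
            config=self.config_,
            decisions=list(self._decisions),
            state=self.state_,
        )
        from .evaluation import compute_metrics

        y_true, y_pred = result.labeled_pairs()
        if y_true.size >= 1:
            result.metrics = compute_metrics(y_true, y_pred)
        return result

    def score(self, X, y):
        """Coefficient of determination of non-mutating predictions."""
        from .evaluation import compute_metrics

        return compute_metrics(np.asarray(y, dtype=float), self.predict(X)).r2
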