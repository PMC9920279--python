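"""Adaptive switching prediction.

A query that fell inside clusters is predicted by a selective ensemble:
the per-cluster GP models of the nearest (by center distance) buildable
clusters are averaged with equal weights.  A query flagged as an outlier —
or one for which no cluster model can be built — is predicted by a
just-in-time GP fitted on the labeled samples most similar to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import Cluster, ODCState, euclidean_distance
from .config import RunConfig
from .gpr import GPRModel, InsufficientDataError, fit_gpr, predict_gpr
from .similarity import regularized_covariance, similarity
from .stream import StreamSample

__all__ = [
    "ColdStartError",
    "NoBuildableModelError",
    "PredictionResult",
    "select_cluster_models",
    "ensemble_predict",
    "jit_predict",
    "predict",
    "rank_labeled_by_similarity",
]


class ColdStartError(RuntimeError):
    """Fewer than two labeled samples exist: no prediction is possible."""


class NoBuildableModelError(RuntimeError):
    """No cluster has enough labeled/pseudo members to fit a model."""


@dataclass
class PredictionResult:
    """One prediction with its route and provenance.

    ``contributors`` holds cluster ids on the ensemble route and the ticks
    of the selected labeled samples on the just-in-time route.
    """

    y_hat: float
    route: str  # "ensemble" | "jit"
    contributors: list[int] = field(default_factory=list)
    per_model: list[float] = field(default_factory=list)
    variance: float | None = None


def _cluster_train_key(cluster: Cluster) -> tuple:
    return tuple((m.tick, m.provenance, m.y) for m in cluster.trainable_members())


def _rebuild_if_needed(cluster: Cluster, config: RunConfig) -> GPRModel | None:
    """Lazily (re)fit a cluster's GP on its labeled + pseudo members.

    The dirty flag triggers the check; the actual refit happens only when
    the training subset changed, since the model is a pure function of it.
    Returns None when fewer than two trainable members exist.
    """
    train = cluster.trainable_members()
    if len(train) < 2:
        return None
    key = _cluster_train_key(cluster)
    if cluster.model is not None and not cluster.dirty:
        return cluster.model
    if cluster.model is not None and key == cluster.model_train_key:
        cluster.dirty = False
        return cluster.model
    X = np.vstack([m.x for m in train])
    y = np.array([m.y for m in train], dtype=float)
    seed = (config.seed ^ (cluster.id * 0x9E3779B1)) & 0x7FFFFFFF
    cluster.model = fit_gpr(X, y, config.kernel, seed=seed)
    cluster.model_train_key = key
    cluster.dirty = False
    return cluster.model


def select_cluster_models(
    state: ODCState,
    xq: np.ndarray,
    m_max: int,
    candidate_ids: list[int] | None = None,
) -> list[tuple[Cluster, GPRModel]]:
    """The nearest buildable cluster models, up to ``m_max`` of them.

    Candidates default to all clusters; the switching predictor restricts
    them to the clusters the query belongs to, so that the ensemble never
    averages in a model for a distant process state.  Candidates are
    ranked by ascending center distance (ties by lower id); clusters with
    fewer than two labeled/pseudo members are skipped.  Dirty models are
    rebuilt on demand.
    """
    pool = (
        state.clusters
        if candidate_ids is None
        else [cl for cl in state.clusters if cl.id in set(candidate_ids)]
    )
    order = sorted(pool, key=lambda cl: (euclidean_distance(xq, cl.c), cl.id))
    chosen: list[tuple[Cluster, GPRModel]] = []
    for cl in order:
        model = _rebuild_if_needed(cl, state.config)
        if model is None:
            continue
        chosen.append((cl, model))
        if len(chosen) == m_max:
            break
    if not chosen:
        raise NoBuildableModelError("no cluster model can be built")
    return chosen


def ensemble_predict(models: list[tuple[Cluster, GPRModel]], xq: np.ndarray) -> PredictionResult:
    """Simple (unweighted) average of the selected cluster-model predictions."""
    if not models:
        raise ValueError("empty model list")
    per_model = [predict_gpr(model, xq)[0] for _, model in models]
    return PredictionResult(
        y_hat=float(np.mean(per_model)),
        route="ensemble",
        contributors=[cl.id for cl, _ in models],
        per_model=per_model,
    )


def rank_labeled_by_similarity(
    labeled_db: list[StreamSample], xq: np.ndarray, measure: str
) -> list[StreamSample]:
    """Labeled samples ranked most-similar first; ties go to the older tick."""
    cov_inv = None
    if measure == "covariance_weighted":
        X = np.vstack([s.x for s in labeled_db])
        cov_inv = np.linalg.inv(regularized_covariance(X))
    scored = [(similarity(xq, s.x, measure, cov_inv=cov_inv), s) for s in labeled_db]
    scored.sort(key=lambda pair: (-pair[0], pair[1].t))
    return [s for _, s in scored]


def jit_predict(
    state: ODCState,
    xq: np.ndarray,
    k_jit: int,
    measure: str,
    kernel,
    seed: int,
) -> PredictionResult:
    """Just-in-time prediction: fit a fresh GP on the most similar labeled samples."""
    if len(state.labeled_db) < 2:
        raise ColdStartError("cold start: fewer than two labeled samples")
    ranked = rank_labeled_by_similarity(state.labeled_db, xq, measure)
    chosen = ranked[: min(k_jit, len(ranked))]
    X = np.vstack([s.x for s in chosen])
    y = np.array([s.y for s in chosen], dtype=float)
    model = fit_gpr(X, y, kernel, seed=seed)
    mean, var = predict_gpr(model, xq)
    return PredictionResult(
        y_hat=mean,
        route="jit",
        contributors=[s.t for s in chosen],
        per_model=[mean],
        variance=var,
    )


def predict(
    state: ODCState,
    xq: np.ndarray,
    config: RunConfig,
    joined_cluster_ids: list[int] | None,
    seed: int | None = None,
) -> PredictionResult:
    """Route one query: ensemble over the (nearest, buildable) clusters the
    query belongs to, just-in-time otherwise — including the fallback when
    none of those clusters can support a model."""
    seed = config.seed if seed is None else seed
    if joined_cluster_ids:
        try:
            models = select_cluster_models(
                state, xq, config.m_max, candidate_ids=joined_cluster_ids
            )
            return ensemble_predict(models, xq)
        except (NoBuildableModelError, InsufficientDataError):
            pass
    return jit_predict(state, xq, config.k_jit, config.similarity, config.kernel, seed)
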