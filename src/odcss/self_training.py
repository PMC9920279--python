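"""Improvement-rate-gated self-training and sample maintenance.

A pseudo-label (the model's own prediction for an unlabeled tick) is
accepted only if adding it to the online training set improves validation
RMSE by more than the confidence threshold:

    IR = (RMSE_before - RMSE_after) / RMSE_before,   accept iff IR > IR_th

where the validation set is the fraction of the labeled database most
similar to the query.  Accepted pseudo-labels become cluster training
data; rejected ones are removed from the clusters they had just joined.
When a true label arrives it supersedes any pseudo copy of the same tick
and triggers pruning of the affected clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import (
    PSEUDO,
    AssignmentEvent,
    ODCState,
    prune_pseudo_samples,
)
from .config import RunConfig
from .gpr import fit_gpr, predict_gpr_batch
from .predictor import rank_labeled_by_similarity
from .stream import LABELED, StreamSample

__all__ = [
    "IRDecision",
    "TooFewLabeledError",
    "split_validation",
    "improvement_rate",
    "maybe_augment",
    "on_true_label",
]


class TooFewLabeledError(ValueError):
    """Labeled database too small to carve out a validation set."""


@dataclass
class IRDecision:
    """Outcome of one pseudo-label confidence evaluation."""

    IR: float
    accepted: bool
    rmse_before: float
    rmse_after: float
    val_ticks: list[int] = field(default_factory=list)
    skipped: bool = False  # evaluation not run (too few labeled samples)


def split_validation(
    labeled_db: Sequence[StreamSample],
    xq: np.ndarray,
    val_fraction: float,
    measure: str,
) -> tuple[list[StreamSample], list[StreamSample]]:
    """Split the labeled database into online training and validation sets.

    The ceil(val_fraction * n) samples most similar to the query form the
    validation set; the rest train.  Both parts must be non-empty.
    """
    db = list(labeled_db)
    if len(db) < 4:
        raise TooFewLabeledError("too few labeled samples")
    n_val = int(np.ceil(val_fraction * len(db)))
    ranked = rank_labeled_by_similarity(db, xq, measure)
    val_set = ranked[:n_val]
    train_set = ranked[n_val:]
    if not train_set or not val_set:
        raise TooFewLabeledError("validation split left an empty partition")
    return train_set, val_set


def improvement_rate(
    train_set: Sequence[StreamSample],
    val_set: Sequence[StreamSample],
    pseudo: tuple[np.ndarray, float],
    kernel,
    seed: int,
    ir_th: float,
) -> IRDecision:
    """Validation-RMSE improvement from adding one pseudo-labeled sample.

    The before-model is fitted normally; the after-model reuses the
    before-model's fitted hyperparameters so the two fits differ only in
    the added sample, isolating its effect from hyperparameter jitter.
    """
    if len(train_set) < 2:
        raise ValueError("train_set needs at least 2 samples")
    if len(val_set) < 1:
        raise ValueError("val_set must be non-empty")
    Xtr = np.vstack([s.x for s in train_set])
    ytr = np.array([s.y for s in train_set], dtype=float)
    Xval = np.vstack([s.x for s in val_set])
    yval = np.array([s.y for s in val_set], dtype=float)
    xq, y_hat = pseudo

    before = fit_gpr(Xtr, ytr, kernel, seed=seed)
    rmse_before = float(np.sqrt(np.mean((predict_gpr_batch(before, Xval) - yval) ** 2)))

    Xaug = np.vstack([Xtr, np.asarray(xq, dtype=float)[None, :]])
    yaug = np.append(ytr, y_hat)
    after = fit_gpr(Xaug, yaug, kernel, seed=seed, fixed_kernel=before.kernel_)
    rmse_after = float(np.sqrt(np.mean((predict_gpr_batch(after, Xval) - yval) ** 2)))

    if rmse_before > 0:
        ir = (rmse_before - rmse_after) / rmse_before
        accepted = ir > ir_th
    else:  # nothing to improve on
        ir, accepted = 0.0, False
    return IRDecision(
        IR=ir,
        accepted=accepted,
        rmse_before=rmse_before,
        rmse_after=rmse_after,
        val_ticks=[s.t for s in val_set],
    )


def _ir_seed(config: RunConfig, tick: int) -> int:
    return (config.seed ^ tick) & 0x7FFFFFFF


def maybe_augment(
    state: ODCState,
    sample: StreamSample,
    y_hat: float,
    config: RunConfig,
    joined_cluster_ids: Sequence[int] = (),
) -> IRDecision:
    """Gate one pseudo-label and update cluster/outlier bookkeeping.

    Accepted: the sample's provenance flips to pseudo (with label
    ``y_hat``) in every cluster containing it and on any buffered outlier
    copy.  Rejected: the sample is removed from the clusters it joined
    this tick (unless ``keep_rejected_unlabeled``); outlier copies are
    untouched.  When the labeled database is too small the evaluation is
    skipped — treated as a rejection without removal.
    """
    try:
        train_set, val_set = split_validation(
            state.labeled_db, sample.x, config.val_fraction, config.similarity
        )
    except TooFewLabeledError:
        return IRDecision(
            IR=0.0, accepted=False, rmse_before=0.0, rmse_after=0.0, skipped=True
        )
    decision = improvement_rate(
        train_set,
        val_set,
        (sample.x, y_hat),
        config.kernel,
        seed=_ir_seed(config, sample.t),
        ir_th=config.IR_th,
    )
    if decision.accepted:
        for cl in state.clusters_containing(sample.t):
            for m in cl.members:
                if m.tick == sample.t:
                    m.provenance = PSEUDO
                    m.y = y_hat
            cl.mark_dirty()
        for rec in state.outliers:
            if rec.sample.t == sample.t:
                rec.provenance = PSEUDO
                rec.y = y_hat
    elif not config.keep_rejected_unlabeled:
        for cid in joined_cluster_ids:
            cl = state.cluster_by_id(cid)
            cl.members = [m for m in cl.members if m.tick != sample.t]
            cl.mark_dirty()
        state.clusters = [cl for cl in state.clusters if cl.n > 0]
    return decision


def on_true_label(
    state: ODCState,
    sample: StreamSample,
    config: RunConfig,
) -> AssignmentEvent:
    """Absorb a true label: update the database, supersede any pseudo copy,
    and prune the affected clusters.

    ``sample`` carries standardized features and the true label.  Pruning
    runs on exactly the clusters containing the sample, per the rule that
    sample deletion starts only when the latest true label is detected.
    """
    if sample.y is None:
        raise ValueError("on_true_label requires a labeled sample")
    state.labeled_db.append(sample)
    containing = state.clusters_containing(sample.t)
    for cl in containing:
        for m in cl.members:
            if m.tick == sample.t:
                m.provenance = LABELED
                m.y = float(sample.y)
        cl.mark_dirty()
    for rec in state.outliers:
        if rec.sample.t == sample.t:
            rec.provenance = LABELED
            rec.y = float(sample.y)
    return prune_pseudo_samples(state, [cl.id for cl in containing], sample.t)
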