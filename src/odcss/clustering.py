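"""Online dynamic clustering (ODC) of a process data stream.

Micro-clusters are maintained incrementally: an arriving sample joins every
cluster whose center lies within radius ``R`` (soft multi-membership across
fuzzy state boundaries), drags the center of any cluster it is deep inside
(distance <= 2R/3) via a running-mean update, or else lands in an outlier
buffer from which a new cluster is born once ``M`` mutually close outliers
have accumulated.  When a fresh true label arrives, the least influential
pseudo/unlabeled members of the affected clusters are pruned by ascending
spatio-temporal weight.

All features entering this module are standardized; ``R`` is in
standardized units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .stream import LABELED, UNLABELED, StreamSample

__all__ = [
    "PSEUDO",
    "ClusterMember",
    "Cluster",
    "OutlierRecord",
    "ODCState",
    "AssignmentEvent",
    "cluster_snapshot",
    "euclidean_distance",
    "cluster_center",
    "distances_to_centers",
    "assign_or_buffer",
    "try_form_cluster",
    "spatio_temporal_weights",
    "prune_pseudo_samples",
    "odc_step",
]

PSEUDO = "pseudo"

# fraction of R inside which an insertion drags the cluster center
CENTER_UPDATE_FRACTION = 2.0 / 3.0


@dataclass
class ClusterMember:
    """A sample stored in a cluster, with insertion metadata.

    ``provenance`` is ``labeled`` for true labels, ``pseudo`` for accepted
    self-training labels and ``unlabeled`` otherwise; ``y`` carries the
    (true or pseudo) label value when provenance is not ``unlabeled``.
    """

    sample: StreamSample
    insert_tick: int
    provenance: str = UNLABELED
    y: Optional[float] = None

    @property
    def tick(self) -> int:
        return self.sample.t

    @property
    def x(self) -> np.ndarray:
        return self.sample.x


@dataclass
class OutlierRecord:
    """A buffered outlier; keeps any label it acquires for later cluster birth."""

    sample: StreamSample
    insert_tick: int
    provenance: str = UNLABELED
    y: Optional[float] = None


@dataclass
class Cluster:
    id: int
    c: np.ndarray
    members: list[ClusterMember] = field(default_factory=list)
    dirty: bool = True
    model: object = None
    model_train_key: tuple = ()

    @property
    def n(self) -> int:
        return len(self.members)

    def trainable_members(self) -> list[ClusterMember]:
        """Members usable as GP training data (have a true or pseudo label)."""
        return [m for m in self.members if m.provenance in (LABELED, PSEUDO)]

    def mark_dirty(self) -> None:
        self.dirty = True


@dataclass
class AssignmentEvent:
    """Audit record of one clustering decision, sufficient for replay checks."""

    tick: int
    kind: str  # joined_clusters | became_outlier | new_cluster_formed | pruned
    cluster_ids: list[int] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    _KINDS = frozenset({"joined_clusters", "became_outlier", "new_cluster_formed", "pruned"})

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class ODCState:
    """Clusters + outlier buffer + labeled database for one run."""

    config: RunConfig
    clusters: list[Cluster] = field(default_factory=list)
    outliers: list[OutlierRecord] = field(default_factory=list)
    labeled_db: list[StreamSample] = field(default_factory=list)
    next_cluster_id: int = 0
    seeded: bool = False  # has the very first sample been absorbed?
    events: list[AssignmentEvent] = field(default_factory=list)

    def cluster_by_id(self, cid: int) -> Cluster:
        for cl in self.clusters:
            if cl.id == cid:
                return cl
        raise KeyError(f"no cluster with id {cid}")

    def clusters_containing(self, tick: int) -> list[Cluster]:
        return [cl for cl in self.clusters if any(m.tick == tick for m in cl.members)]

    def _new_cluster(self, center: np.ndarray, members: list[ClusterMember]) -> Cluster:
        cl = Cluster(id=self.next_cluster_id, c=np.asarray(center, dtype=float), members=members)
        self.next_cluster_id += 1
        self.clusters.append(cl)
        return cl


def cluster_snapshot(state: ODCState):
    """Tabular snapshot of the cluster structure: one row per cluster with
    id, center components and member counts by provenance."""
    import pandas as pd

    rows = []
    for cl in state.clusters:
        row = {"id": cl.id, "n": cl.n}
        row.update({f"c{i}": v for i, v in enumerate(cl.c)})
        for prov in (LABELED, PSEUDO, UNLABELED):
            row[f"n_{prov}"] = sum(1 for m in cl.members if m.provenance == prov)
        rows.append(row)
    return pd.DataFrame(rows)


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def cluster_center(members: Sequence[ClusterMember | StreamSample | np.ndarray]) -> np.ndarray:
    """Arithmetic mean of member feature vectors."""
    if len(members) == 0:
        raise ValueError("empty member set")
    xs = []
    for m in members:
        if isinstance(m, ClusterMember):
            xs.append(m.x)
        elif isinstance(m, (StreamSample, OutlierRecord)):
            xs.append(m.x if isinstance(m, StreamSample) else m.sample.x)
        else:
            xs.append(np.asarray(m, dtype=float))
    return np.mean(np.vstack(xs), axis=0)


def distances_to_centers(state: ODCState, x: np.ndarray) -> np.ndarray:
    """Distance from ``x`` to every cluster center, in cluster order."""
    if not state.clusters:
        return np.empty(0)
    return np.array([euclidean_distance(x, cl.c) for cl in state.clusters])


def assign_or_buffer(
    state: ODCState,
    sample: StreamSample,
    provenance: str = UNLABELED,
    y: Optional[float] = None,
) -> AssignmentEvent:
    """Insert one (standardized) sample: join clusters within R or buffer it.

    The sample joins every cluster whose center is within R; each joined
    cluster whose distance is also <= 2R/3 has its center updated by the
    running-mean recursion c' = (c*(n-1) + x)/n with n the member count
    after insertion.  Otherwise the sample becomes an outlier and cluster
    birth is attempted.
    """
    cfg = state.config
    dists = distances_to_centers(state, sample.x)
    within = np.flatnonzero(dists <= cfg.R) if dists.size else np.empty(0, dtype=int)

    if within.size > 0:
        joined, insert_dists = [], []
        for idx in within:
            cl = state.clusters[idx]
            cl.members.append(
                ClusterMember(sample=sample, insert_tick=sample.t, provenance=provenance, y=y)
            )
            cl.mark_dirty()
            if dists[idx] <= CENTER_UPDATE_FRACTION * cfg.R:
                n = cl.n  # count after insertion
                cl.c = (cl.c * (n - 1) + sample.x) / n
            joined.append(cl.id)
            insert_dists.append(float(dists[idx]))
        event = AssignmentEvent(
            tick=sample.t,
            kind="joined_clusters",
            cluster_ids=joined,
            details={"insert_distances": insert_dists},
        )
        state.events.append(event)
        return event

    # outlier path
    record = OutlierRecord(sample=sample, insert_tick=sample.t, provenance=provenance, y=y)
    state.outliers.append(record)
    if state.config.outlier_cap is not None and len(state.outliers) > state.config.outlier_cap:
        state.outliers.pop(0)
    born = try_form_cluster(state, sample)
    if born is not None:
        event = AssignmentEvent(
            tick=sample.t,
            kind="new_cluster_formed",
            cluster_ids=[born.id],
            details={
                "birth_size": born.n,
                "outlier_distances": [float(d) for d in dists],
            },
        )
    else:
        event = AssignmentEvent(
            tick=sample.t,
            kind="became_outlier",
            details={"outlier_distances": [float(d) for d in dists]},
        )
    state.events.append(event)
    return event


def try_form_cluster(state: ODCState, new_outlier: StreamSample) -> Optional[Cluster]:
    """Attempt cluster birth around the newest outlier.

    The seed group is the newest outlier plus every buffered outlier within
    R of it; a cluster is born iff the group reaches the density threshold
    M.  Outliers that do not form a cluster stay buffered.
    """
    cfg = state.config
    group, rest = [], []
    for rec in state.outliers:
        if euclidean_distance(rec.sample.x, new_outlier.x) <= cfg.R:
            group.append(rec)
        else:
            rest.append(rec)
    if len(group) < cfg.M:
        return None
    members = [
        ClusterMember(sample=r.sample, insert_tick=r.insert_tick, provenance=r.provenance, y=r.y)
        for r in group
    ]
    center = cluster_center(members)
    state.outliers = rest
    return state._new_cluster(center, members)


def spatio_temporal_weights(
    cluster: Cluster,
    query_tick: int,
    alpha: float,
    spatial_inverse: bool = False,
) -> np.ndarray:
    """Influence weight of each member: alpha*d_i/sum(d) + (1-alpha)*(t_i/sum(t))^-1.

    d_i is the member's distance to the current center and t_i its age at
    ``query_tick``.  Small weight = old and (under the literal spatial
    term) close to the center => pruned first.  ``spatial_inverse`` flips
    the spatial term to (d_i/sum(d))^-1 so that central samples are
    protected instead.

    Degenerate cases (the formula is undefined there): sum(d)=0 gives every
    member spatial term alpha/n; a member with age 0 takes the maximum
    temporal factor of the positive-age members (newest most protected);
    if no member has positive age the temporal factor is 1/n for all;
    a single-member cluster has weight 1.
    """
    n = cluster.n
    if n == 0:
        raise ValueError("empty cluster")
    if n == 1:
        return np.ones(1)

    d = np.array([euclidean_distance(m.x, cluster.c) for m in cluster.members])
    ages = np.array([float(query_tick - m.insert_tick) for m in cluster.members])
    if np.any(ages < 0):
        raise ValueError("query_tick precedes a member insert_tick")

    sum_d = d.sum()
    if sum_d == 0:
        spatial = np.full(n, 1.0 / n)
    else:
        frac = d / sum_d
        if spatial_inverse:
            spatial = np.empty(n)
            pos = frac > 0
            spatial[pos] = 1.0 / frac[pos]
            if (~pos).any():
                spatial[~pos] = spatial[pos].max() if pos.any() else 1.0 / n
        else:
            spatial = frac

    sum_t = ages.sum()
    if sum_t == 0:
        temporal = np.full(n, 1.0 / n)
    else:
        temporal = np.empty(n)
        pos = ages > 0
        temporal[pos] = sum_t / ages[pos]
        if (~pos).any():
            temporal[~pos] = temporal[pos].max()

    return alpha * spatial + (1.0 - alpha) * temporal


def prune_pseudo_samples(
    state: ODCState, cluster_ids: Sequence[int], query_tick: int
) -> AssignmentEvent:
    """Remove the floor(P * n_eligible) least-influential pseudo/unlabeled members.

    Only members whose provenance is pseudo or unlabeled are eligible; true
    labeled members are never pruned.  Ties in weight are broken by older
    insert_tick first.  Centers are not recomputed on deletion.
    """
    cfg = state.config
    removed: dict[int, list[int]] = {}
    removed_provenances: list[str] = []
    for cid in cluster_ids:
        cl = state.cluster_by_id(cid)
        eligible = [i for i, m in enumerate(cl.members) if m.provenance in (PSEUDO, UNLABELED)]
        n_remove = math.floor(cfg.P * len(eligible))
        if n_remove == 0:
            continue
        weights = spatio_temporal_weights(
            cl, query_tick, cfg.alpha, spatial_inverse=cfg.spatial_inverse
        )
        order = sorted(eligible, key=lambda i: (weights[i], cl.members[i].insert_tick))
        doomed = set(order[:n_remove])
        removed_provenances.extend(cl.members[i].provenance for i in doomed)
        removed[cid] = sorted(cl.members[i].tick for i in doomed)
        cl.members = [m for i, m in enumerate(cl.members) if i not in doomed]
        cl.mark_dirty()
    state.clusters = [cl for cl in state.clusters if cl.n > 0]
    event = AssignmentEvent(
        tick=query_tick,
        kind="pruned",
        cluster_ids=sorted(removed),
        details={"removed_ticks": removed, "removed_provenances": removed_provenances},
    )
    state.events.append(event)
    return event


def odc_step(
    state: ODCState,
    sample: StreamSample,
    provenance: str = UNLABELED,
    y: Optional[float] = None,
) -> AssignmentEvent:
    """Process one standardized sample through the clustering engine.

    The very first sample ever seen seeds the initial cluster directly
    (the density threshold applies only to clusters born from the outlier
    buffer).
    """
    if not state.seeded:
        state.seeded = True
        member = ClusterMember(sample=sample, insert_tick=sample.t, provenance=provenance, y=y)
        cl = state._new_cluster(sample.x.copy(), [member])
        event = AssignmentEvent(
            tick=sample.t,
            kind="new_cluster_formed",
            cluster_ids=[cl.id],
            details={"birth_size": 1, "initial": True},
        )
        state.events.append(event)
        return event
    return assign_or_buffer(state, sample, provenance=provenance, y=y)
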