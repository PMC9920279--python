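"""Core stream types, feature standardization and CSV stream I/O.

A semi-supervised data stream is a time-ordered sequence of process records
in which every tick carries a feature vector (online measurements) and only
a sparse subset carries the target value (offline laboratory analysis).
All downstream distance computations operate on standardized features, so
the scaler fitted on the initial labeled training set is part of the run
state and is held fixed for the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StreamSample",
    "SemiSupervisedStream",
    "ScalingStats",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "read_stream_csv",
    "write_stream_csv",
]

#: variance floor protecting constant features from division by zero
SD_FLOOR = 1e-8

LABELED = "labeled"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class StreamSample:
    """One tick of a semi-supervised stream.

    Parameters
    ----------
    t : int
        Non-negative stream index (tick). Strictly increasing along a stream.
    x : ndarray of shape (d,)
        Feature vector in raw engineering units (or standardized units once
        inside the pipeline).
    y : float, optional
        Target value (e.g. substrate concentration in g/L). ``None`` marks
        an unlabeled sample.
    """

    t: int
    x: np.ndarray
    y: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.t < 0:
            raise ValueError(f"tick must be non-negative, got {self.t}")

    @property
    def label_kind(self) -> str:
        return LABELED if self.y is not None else UNLABELED

    @property
    def is_labeled(self) -> bool:
        return self.y is not None

    def with_features(self, x: np.ndarray) -> "StreamSample":
        return replace(self, x=np.asarray(x, dtype=float))


@dataclass
class SemiSupervisedStream:
    """Ordered sequence of :class:`StreamSample` sharing one feature space."""

    samples: list[StreamSample]
    label_period: int = 1

    def __post_init__(self) -> None:
        ticks = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(ticks, ticks[1:])):
            raise ValueError("stream ticks must be strictly increasing")
        dims = {s.x.shape[0] for s in self.samples}
        if len(dims) > 1:
            raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")
        if self.label_period < 1:
            raise ValueError("label_period must be >= 1")

    @property
    def d(self) -> int:
        if not self.samples:
            raise ValueError("empty stream has no dimension")
        return self.samples[0].x.shape[0]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def labeled(self) -> list[StreamSample]:
        return [s for s in self.samples if s.is_labeled]

    def unlabeled(self) -> list[StreamSample]:
        return [s for s in self.samples if not s.is_labeled]


@dataclass(frozen=True)
class ScalingStats:
    """Per-dimension mean and standard deviation (population formula)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if np.any(self.sd <= 0):
            raise ValueError("sd components must be strictly positive")

    @property
    def d(self) -> int:
        return self.mean.shape[0]


def fit_scaler(samples: Sequence[StreamSample]) -> ScalingStats:
    """Fit per-dimension standardization statistics on a sample set.

    Uses the population standard deviation; components below :data:`SD_FLOOR`
    (constant features) are replaced by the floor so downstream divisions
    stay finite.
    """
    if len(samples) == 0:
        raise ValueError("no samples")
    X = np.vstack([s.x for s in samples])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population (ddof=0)
    sd = np.where(sd < SD_FLOOR, SD_FLOOR, sd)
    return ScalingStats(mean=mean, sd=sd)


def apply_scaler(stats: ScalingStats, x: np.ndarray) -> np.ndarray:
    """Standardize a feature vector: ``(x - mean) / sd`` componentwise."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != stats.d:
        raise ValueError(f"dimension mismatch: x has {x.shape[0]}, scaler has {stats.d}")
    return (x - stats.mean) / stats.sd


def invert_scaler(stats: ScalingStats, z: np.ndarray) -> np.ndarray:
    """Map a standardized vector back to engineering units."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] != stats.d:
        raise ValueError(f"dimension mismatch: z has {z.shape[0]}, scaler has {stats.d}")
    return z * stats.sd + stats.mean


def read_stream_csv(
    path,
    target_column: str = "y",
    index_column: Optional[str] = "tick",
) -> SemiSupervisedStream:
    """Read a semi-supervised stream from CSV.

    The file must have a header row. Every column except the target column
    and the optional tick column is taken as a feature, in file order. An
    empty target cell marks an unlabeled sample. When the tick column is
    absent, ticks are assigned from row order; when present, rows are
    re-ordered by tick.
    """
    df = pd.read_csv(path)
    if target_column not in df.columns:
        raise ValueError(f"missing target column {target_column!r}")
    has_ticks = index_column is not None and index_column in df.columns
    feature_cols = [c for c in df.columns if c != target_column and c != index_column]
    feats = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric feature cell at data row {row}")
    targets = pd.to_numeric(df[target_column], errors="coerce")
    ticks = (
        df[index_column].astype(int).to_numpy()
        if has_ticks
        else np.arange(len(df), dtype=int)
    )
    order = np.argsort(ticks, kind="stable")
    samples = [
        StreamSample(
            t=int(ticks[i]),
            x=feats.iloc[i].to_numpy(dtype=float),
            y=None if pd.isna(targets.iloc[i]) else float(targets.iloc[i]),
        )
        for i in order
    ]
    return SemiSupervisedStream(samples=samples, label_period=_infer_label_period(samples))


def write_stream_csv(stream: Iterable[StreamSample], path, feature_names=None,
                     target_column: str = "y") -> None:
    """Write a stream in the CSV format understood by :func:`read_stream_csv`."""
    samples = list(stream)
    if not samples:
        raise ValueError("cannot write an empty stream")
    d = samples[0].x.shape[0]
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(d)]
    rows = []
    for s in samples:
        row = {"tick": s.t}
        row.update({name: v for name, v in zip(feature_names, s.x)})
        row[target_column] = s.y if s.y is not None else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _infer_label_period(samples: Sequence[StreamSample]) -> int:
    labeled_ticks = [s.t for s in samples if s.is_labeled]
    if len(labeled_ticks) < 2:
        return 1
    gaps = np.diff(labeled_ticks)
    return int(max(1, np.min(gaps)))
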