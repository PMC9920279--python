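"""Run configuration for the streaming soft sensor.

All clustering-related lengths (the radius ``R`` in particular) are in
standardized-feature units because every distance computation downstream
of the scaler operates in standardized space.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["KernelConfig", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class KernelConfig:
    """Matérn-plus-noise covariance configuration shared by all GPR fits.

    ``nu`` controls smoothness (2.5 gives twice-differentiable sample
    paths, the usual default for process data); the ``*_init`` values seed
    hyperparameter optimization, which maximizes the log marginal
    likelihood when ``optimize`` is on.
    """

    nu: float = 2.5
    length_scale_init: float = 1.0
    signal_variance_init: float = 1.0
    noise_variance_init: float = 1e-2
    optimize: bool = True
    n_restarts: int = 0

    def __post_init__(self) -> None:
        for name in ("length_scale_init", "signal_variance_init", "noise_variance_init"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the full online method.

    Parameters
    ----------
    R : float
        Cluster radius in standardized-feature units.
    M : int
        Minimum density threshold: number of mutually close outliers needed
        to give birth to a new cluster.
    alpha : float
        Spatio-temporal mixing weight in [0, 1] for the pruning weights
        (1 = purely spatial, 0 = purely temporal).
    P : float
        Proportion of eligible (pseudo/unlabeled) members pruned from a
        cluster when a fresh true label arrives.
    IR_th : float
        Improvement-rate threshold a pseudo-label must exceed to be
        accepted into the training set.
    m_max : int
        Maximal number of cluster models averaged in the selective ensemble.
    k_jit : int
        Neighborhood size of the just-in-time model built for outliers.
    similarity : str
        Similarity measure used for JIT neighbor selection and for picking
        the online validation set.
    val_fraction : float
        Fraction of the labeled database held out as the online validation
        set when scoring a candidate pseudo-label.
    """

    R: float = 3.0
    M: int = 10
    alpha: float = 0.4
    P: float = 0.5
    IR_th: float = 0.1
    m_max: int = 2
    k_jit: int = 50
    similarity: str = "euclidean"
    val_fraction: float = 0.3
    kernel: KernelConfig = field(default_factory=KernelConfig)
    seed: int = 0
    augment: bool = True
    spatial_inverse: bool = False
    keep_rejected_unlabeled: bool = False
    outlier_cap: int | None = None

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must be in [0, 1]")
        if self.m_max < 1:
            raise ValueError("m_max must be >= 1")
        if self.k_jit < 3:
            raise ValueError("k_jit must be >= 3")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


_KERNEL_FIELDS = set(KernelConfig.__dataclass_fields__)


def load_config(path) -> RunConfig:
    """Load a flat key-value config file (TOML or YAML) into a RunConfig.

    Keys mirror the RunConfig field names; kernel fields may be given flat
    (``nu``, ``length_scale_init``, ...) or nested under ``kernel``.
    """
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat mapping")
    kernel_raw = dict(raw.pop("kernel", {}))
    for key in list(raw):
        if key in _KERNEL_FIELDS:
            kernel_raw[key] = raw.pop(key)
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(kernel=KernelConfig(**kernel_raw), **raw)


def save_config(config: RunConfig, path) -> None:
    """Write a RunConfig as a flat YAML mapping (kernel fields nested)."""
    data = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
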