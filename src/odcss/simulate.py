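"""Synthetic semi-supervised streams.

Two generators stand in for proprietary plant data:

* a fed-batch fermentation simulator built on Monod growth kinetics,
  emitting the nine auxiliary-variable roles typical of an industrial
  antibiotic fermentation (cultivation time, temperature, pH, dissolved
  oxygen, air flow and consumption, feed rate and consumptions) with
  substrate concentration as the sparse offline-analyzed target; and
* a generic drifting nonlinear stream with abrupt mode switches and
  gradual coefficient drift.

Both interleave high-frequency unlabeled samples with low-frequency
labeled ones, the structure that makes the stream semi-supervised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .stream import SemiSupervisedStream, StreamSample

__all__ = [
    "FermentationConfig",
    "Mode",
    "DriftStreamConfig",
    "simulate_fedbatch_batch",
    "make_fermentation_campaign",
    "make_drift_stream",
    "make_two_mode_campaign",
    "FEATURE_NAMES",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "time_min",
    "temperature_C",
    "pH",
    "DO_percent",
    "air_flow_m3h",
    "cum_air_m3",
    "feed_rate_Lh",
    "cum_feed_L",
    "cum_ammonia_L",
]

# nominal per-feature scales; measurement noise sd = noise_sd * scale
_NOISE_SCALES = np.array([0.0, 5.0, 0.5, 30.0, 10.0, 200.0, 0.5, 5.0, 20.0])


@dataclass(frozen=True)
class FermentationConfig:
    """Kinetic and scheduling parameters of the fed-batch generator.

    Kinetics follow the Monod law mu = mu_max * S / (Ks + S) with biomass
    yield Y_xs; after ``feed_start`` a constant feed dilutes the broth and
    supplies substrate.  ``dt_minutes`` is the online sampling interval and
    ``label_hours`` the offline analysis interval, so one labeled sample
    appears every label_hours*60/dt_minutes ticks.
    """

    mu_max: float = 0.25  # 1/h
    Ks: float = 1.5  # g/L
    Y_xs: float = 0.5  # g biomass per g substrate
    S0: float = 30.0  # g/L
    X0: float = 0.2  # g/L
    V0: float = 50.0  # L
    feed_start: float = 24.0  # h
    feed_rate: float = 0.25  # L/h
    feed_substrate: float = 300.0  # g/L
    batch_hours: float = 96.0
    dt_minutes: float = 15.0
    label_hours: float = 4.0
    noise_sd: float = 0.02  # relative measurement noise level
    batch_variability: float = 0.05  # relative sd of per-batch parameter jitter
    n_batches: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_max", "Ks", "Y_xs", "S0", "X0", "V0", "batch_hours",
                     "dt_minutes", "label_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if (self.label_hours * 60.0) % self.dt_minutes != 0:
            raise ValueError("dt_minutes must divide label_hours*60")

    @property
    def label_every(self) -> int:
        return int(round(self.label_hours * 60.0 / self.dt_minutes))

    @property
    def samples_per_batch(self) -> int:
        return int(round(self.batch_hours * 60.0 / self.dt_minutes)) + 1


def _rhs(state: np.ndarray, cfg: FermentationConfig, t_h: float) -> np.ndarray:
    X, S, V = state
    mu = cfg.mu_max * S / (cfg.Ks + S) if S > 0 else 0.0
    dX = mu * X
    dS = -mu * X / cfg.Y_xs
    dV = 0.0
    if t_h >= cfg.feed_start and cfg.feed_rate > 0:
        dX += -cfg.feed_rate * X / V
        dS += cfg.feed_rate * (cfg.feed_substrate - S) / V
        dV = cfg.feed_rate
    return np.array([dX, dS, dV])


def _rk4_step(state: np.ndarray, cfg: FermentationConfig, t_h: float, dt_h: float) -> np.ndarray:
    k1 = _rhs(state, cfg, t_h)
    k2 = _rhs(state + 0.5 * dt_h * k1, cfg, t_h + 0.5 * dt_h)
    k3 = _rhs(state + 0.5 * dt_h * k2, cfg, t_h + 0.5 * dt_h)
    k4 = _rhs(state + dt_h * k3, cfg, t_h + dt_h)
    return state + dt_h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def _jittered(cfg: FermentationConfig, rng: np.random.Generator) -> FermentationConfig:
    def j() -> float:
        return float(max(0.1, 1.0 + cfg.batch_variability * rng.standard_normal()))

    return replace(
        cfg,
        mu_max=cfg.mu_max * j(),
        Ks=cfg.Ks * j(),
        Y_xs=cfg.Y_xs * j(),
        S0=cfg.S0 * j(),
        X0=cfg.X0 * j(),
        feed_rate=cfg.feed_rate * j(),
    )


def simulate_fedbatch_batch(
    config: FermentationConfig, batch_index: int = 0
) -> SemiSupervisedStream:
    """Integrate one fermentation batch and emit its sampled stream.

    Fixed-step RK4 at the sampling resolution keeps the trajectory exactly
    reproducible.  Negative concentrations produced by a step are clamped
    to zero (and logged); emitted samples therefore satisfy S, X, V >= 0.
    The target is the true substrate concentration; measurement noise is
    applied to the auxiliary features only — offline analysis is treated
    as exact.
    """
    rng = np.random.default_rng([config.seed, batch_index])
    cfg = _jittered(config, rng)

    dt_h = config.dt_minutes / 60.0
    state = np.array([cfg.X0, cfg.S0, cfg.V0])
    cum_air = 0.0
    samples: list[StreamSample] = []
    for i in range(config.samples_per_batch):
        t_h = i * dt_h
        X, S, V = state
        mu = cfg.mu_max * S / (cfg.Ks + S)
        growth = mu * X  # volumetric growth activity, drives the surrogates
        feed_now = cfg.feed_rate if t_h >= cfg.feed_start else 0.0
        air_flow = 20.0 + 0.6 * growth * V / cfg.V0
        cum_air += air_flow * dt_h
        features = np.array([
            t_h * 60.0,
            30.0 + 2.0 * mu / cfg.mu_max,
            6.8 - 0.6 * (1.0 - S / (S + cfg.Ks)),
            np.clip(100.0 - 3.5 * growth, 0.0, 100.0),
            air_flow,
            cum_air,
            feed_now,
            V - cfg.V0,
            0.08 * (X * V - cfg.X0 * cfg.V0),
        ])
        noise = rng.standard_normal(9) * (config.noise_sd * _NOISE_SCALES)
        y = float(S) if i % config.label_every == 0 else None
        samples.append(StreamSample(t=i, x=features + noise, y=y))

        state = _rk4_step(state, cfg, t_h, dt_h)
        if np.any(state < 0):
            logger.debug("clamping negative state at batch %d step %d", batch_index, i)
            state = np.clip(state, 0.0, None)
    return SemiSupervisedStream(samples=samples, label_period=config.label_every)


def make_fermentation_campaign(
    config: FermentationConfig,
) -> tuple[SemiSupervisedStream, SemiSupervisedStream]:
    """Simulate a multi-batch campaign and split it for online soft sensing.

    The labeled samples of the first two batches form the initial training
    set; the remaining batches, concatenated with tick continuity, form
    the online stream.
    """
    if config.n_batches < 3:
        raise ValueError("campaign needs n_batches >= 3")
    spb = config.samples_per_batch
    init_samples: list[StreamSample] = []
    online_samples: list[StreamSample] = []
    for b in range(config.n_batches):
        batch = simulate_fedbatch_batch(config, b)
        offset = b * spb
        shifted = [replace(s, t=s.t + offset) for s in batch]
        if b < 2:
            init_samples.extend(s for s in shifted if s.is_labeled)
        else:
            online_samples.extend(shifted)
    return (
        SemiSupervisedStream(samples=init_samples, label_period=config.label_every),
        SemiSupervisedStream(samples=online_samples, label_period=config.label_every),
    )


@dataclass
class Mode:
    """One regime of the drifting stream: a feature distribution and a
    smooth nonlinear feature-target map y = b + w.x + amp*sin(freq*sum(x))."""

    center: np.ndarray
    w: np.ndarray
    b: float = 0.0
    scale: float = 1.0
    amp: float = 1.0
    freq: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.w = np.asarray(self.w, dtype=float)

    def sample_x(self, rng: np.random.Generator) -> np.ndarray:
        return self.center + self.scale * rng.standard_normal(self.center.shape[0])

    def target(self, x: np.ndarray) -> float:
        return float(self.b + self.w @ x + self.amp * np.sin(self.freq * x.sum()))


@dataclass
class DriftStreamConfig:
    """Configuration of the generic drifting stream.

    ``switch_ticks`` are the abrupt mode switches (the active mode cycles
    through ``modes``); ``drift_rate`` adds a per-tick linear creep to the
    active mode's coefficients (gradual drift).
    """

    modes: list[Mode]
    switch_ticks: tuple[int, ...] = ()
    drift_rate: float = 0.0
    noise_sd: float = 0.1
    label_period: int = 4
    n_ticks: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one mode required")
        if list(self.switch_ticks) != sorted(set(self.switch_ticks)):
            raise ValueError("switch_ticks must be strictly increasing")
        if self.label_period < 1:
            raise ValueError("label_period must be >= 1")

    @property
    def d(self) -> int:
        return self.modes[0].center.shape[0]


def make_drift_stream(config: DriftStreamConfig) -> SemiSupervisedStream:
    """Generate a drifting nonlinear stream with the configured labeling
    schedule.  Every ``label_period``-th tick (starting at tick 0) is
    labeled; the target of unlabeled ticks is withheld."""
    rng = np.random.default_rng(config.seed)
    modes = [
        Mode(center=m.center.copy(), w=m.w.copy(), b=m.b, scale=m.scale,
             amp=m.amp, freq=m.freq)
        for m in config.modes
    ]
    active = 0
    switches = set(config.switch_ticks)
    samples: list[StreamSample] = []
    for t in range(config.n_ticks):
        if t in switches:
            active = (active + 1) % len(modes)
        mode = modes[active]
        if config.drift_rate:
            mode.w = mode.w + config.drift_rate
            mode.b = mode.b + config.drift_rate
        x = mode.sample_x(rng)
        y = mode.target(x) + config.noise_sd * rng.standard_normal()
        samples.append(
            StreamSample(t=t, x=x, y=float(y) if t % config.label_period == 0 else None)
        )
    return SemiSupervisedStream(samples=samples, label_period=config.label_period)


def make_two_mode_campaign(
    seed: int = 0,
    n_init_ticks: int = 200,
    n_ticks: int = 800,
    switch_ticks: tuple[int, ...] = (300, 560),
    label_period: int = 4,
    noise_sd: float = 0.1,
) -> tuple[list[StreamSample], list[StreamSample]]:
    """Two-regime abrupt-drift scenario: a stationary warm-up whose labeled
    samples form the initial training set, then an online phase that
    switches abruptly to a well-separated second regime and, by default,
    back again (a recurring concept).  The away-phase is longer than a
    typical sliding-window turnover (50 labels), so the return exposes the
    difference between retaining per-state models and window forgetting.

    Returns (init_labeled, online_stream).
    """
    config = DriftStreamConfig(
        modes=[
            Mode(center=np.zeros(2), w=np.array([1.5, -1.0]), b=0.0),
            Mode(center=np.array([5.0, 5.0]), w=np.array([-1.0, 2.0]), b=8.0),
        ],
        switch_ticks=tuple(switch_ticks),
        noise_sd=noise_sd,
        label_period=label_period,
        n_ticks=n_ticks,
        seed=seed,
    )
    stream = make_drift_stream(config)
    init_labeled = [s for s in stream if s.t < n_init_ticks and s.is_labeled]
    online = [s for s in stream if s.t >= n_init_ticks]
    return init_labeled, online
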