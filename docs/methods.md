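# Methods

This note documents the model, its parameters, the numerical choices, and
what the synthetic generators do and do not establish.

## Problem setting

A semi-supervised process data stream delivers, at integer ticks
`t = 0, 1, 2, …`, a feature vector `x_t ∈ R^d` of online process
measurements; a sparse subset of ticks (one in `label_period`) additionally
carries the target `y_t` (an offline-analyzed quantity such as substrate
concentration). The task is prequential regression: predict `ŷ_t` from
`x_t` and strictly past information, then — and only then — consume `y_t`
(if present) for learning. Metrics are computed on labeled ticks only;
ticks predicted before any model exists (cold start) are excluded.

## Feature standardization

All distances, radii and similarities operate on standardized features
`z = (x − μ)/σ`, with `μ, σ` fitted once on the initial labeled training
set (population σ, floored at 1e-8 for constant features) and held fixed.
Rationale: distances over mixed engineering units (minutes, °C, %, L) are
meaningless, and re-estimating the scaler online would let the metric
itself drift. Consequence: the cluster radius `R` is expressed in
standardized units and is **not** comparable to radii quoted for
raw-unit data elsewhere.

## Online dynamic clustering

State: a list of micro-clusters (center `c`, member list with insertion
tick and provenance ∈ {labeled, pseudo, unlabeled}), an unbounded outlier
buffer, and the labeled database.

Per arriving (standardized) sample:

* **Join:** the sample is appended to *every* cluster with
  `d(z, c) ≤ R` — soft multi-membership across fuzzy state boundaries, no
  fractional weights. For each joined cluster with `d ≤ 2R/3` the center
  migrates by the running mean `c' = (c·(n−1) + z)/n`, `n` counted *after*
  insertion (this reading makes the update exactly the running-mean
  recursion).
* **Outlier / birth:** otherwise the sample is buffered; a new cluster is
  born from the newest outlier plus all buffered outliers within `R` of it
  once that group reaches `M`. The group leaves the buffer; stragglers
  remain. Chains beyond one hop are not merged. The very first sample of a
  run seeds the initial cluster directly (the density threshold applies
  only to buffer births).
* **Pruning** runs only when a true label arrives, and only in the
  clusters containing that sample. Members with provenance pseudo or
  unlabeled are ranked by the spatio-temporal weight

      w_i = α · d_i/Σd + (1−α) · (t_i/Σt)^{-1}

  (`d_i` = distance to the current center, `t_i` = age in ticks) and the
  `floor(P · n_eligible)` smallest-weight members are removed. True
  labeled members are never pruned; centers are not recomputed on
  deletion. Degenerate cases, where the formula is undefined: `Σd = 0`
  gives every member spatial term `α/n`; a zero-age member takes the
  maximum temporal factor among aged members (newest most protected); if
  no member has positive age the temporal factor is `1/n`; a
  single-member cluster has weight 1. As printed, the spatial term gives
  *distant* members *larger* (more protected) weights, which sits oddly
  with "least influential removed first"; the literal form is the default
  and a `spatial_inverse` switch inverts the spatial term for users who
  prefer the other reading. No further intent is guessed.

Ties in the pruning sort are broken by older insertion tick first; all
sorts are stable, so runs are exactly reproducible.

## Gaussian-process base learner

Every predictive component uses one GP wrapper (scikit-learn
`GaussianProcessRegressor`): kernel
`σ_f²·Matérn(ℓ, ν) + σ_n²·δ`, defaults ν = 2.5, ℓ init 1.0 (standardized
units), σ_f² init 1.0, σ_n² init 1e-2. Bounds: ℓ ∈ [1e-2, 1e3],
σ_f² ∈ [1e-3, 1e3], σ_n² ∈ [1e-8, 1e1]. Targets are centered by their
training mean inside the model (a zero-prior-mean GP on raw concentrations
is badly specified); the mean is restored at prediction. Hyperparameters
maximize the log marginal likelihood at every (re)fit, single L-BFGS start
by default. Cholesky failures escalate jitter 1e-10 → 1e-8 → 1e-6 before
giving up. Predictive variance includes the fitted noise term (the
variance of a new noisy observation — what a sensor reports). Fits require
≥ 2 rows; callers fall back (ensemble → JIT → no prediction) below that.

A cluster's model is a pure function of its labeled + pseudo members and
the kernel config, so although any membership change marks the cluster
dirty, the refit is skipped when that training subset is unchanged — a
cache with identical semantics that keeps per-tick cost bounded.

## Switching prediction

If the sample joined clusters: the (at most `m_max`) nearest *containing*
clusters with ≥ 2 labeled/pseudo members supply models, and the prediction
is their unweighted average. Restricting candidates to containing clusters
matters: averaging in the model of a cluster several radii away mixes an
unrelated process state into every prediction (measured on the two-regime
stream this alone quadruples post-switch error). If the sample is an
outlier — or no containing cluster can support a model — a just-in-time GP
is fitted on the `k_jit` most similar labeled samples. Similarity measures
(euclidean, manhattan, cosine, Pearson, covariance-weighted with ridge
`Σ̂ + 1e-6·tr(Σ̂)/d·I`) all return larger-is-more-similar scores;
ranking ties go to the older tick.

## Self-training

For every unlabeled prediction: the `ceil(val_fraction·n)` labeled samples
most similar to the query form the online validation set (same similarity
measure as JIT — one knob, the two roles are not distinguished), the rest
train. Two GPs are compared: fitted on the training set, and on the
training set plus the candidate `{x_t, ŷ_t}`. The improvement rate
`IR = (RMSE − RMSE′)/RMSE` must exceed `IR_th` for acceptance. The second
fit reuses the first fit's optimized hyperparameters, so the two models
differ only in the added sample — this isolates the candidate's effect
from hyperparameter jitter and halves the cost of the dominant per-tick
operation. `RMSE = 0` defines `IR = 0` (nothing to improve; rejected).

Accepted: the sample's provenance flips to pseudo (label `ŷ_t`) in every
cluster containing it, and on its buffered outlier copy. Rejected: the
sample is removed from the clusters it joined this tick (a
`keep_rejected_unlabeled` switch retains it as plain unlabeled); outlier
copies are untouched. With fewer than 4 labeled samples the evaluation is
skipped and treated as a rejection *without* removal. When the true label
of a tick later arrives, it supersedes any pseudo copy, the sample enters
the labeled database exactly once, and pruning fires. The IR evaluation
seed is derived per tick (`run_seed ⊕ tick`, masked below 2³¹), so each
decision is individually reproducible.

## Parameters and defaults

| name | default | meaning |
|---|---|---|
| `R` | 3.0 | cluster radius, standardized units |
| `M` | 10 | outlier count needed for cluster birth |
| `alpha` | 0.4 | spatial weight share in pruning, ∈ [0,1] |
| `P` | 0.5 | pruned proportion of eligible members per label arrival |
| `IR_th` | 0.1 | improvement-rate acceptance threshold |
| `m_max` | 2 | maximal ensemble size |
| `k_jit` | 50 | JIT neighborhood size |
| `val_fraction` | 0.3 | labeled fraction held out as online validation |
| `similarity` | euclidean | JIT / validation-selection measure |

`M, alpha, P, IR_th, m_max, k_jit` follow the operating point reported for
chemical-process benchmark data in the soft-sensing literature this method
comes from; `R` cannot be carried over (those radii are raw-unit-specific)
and 3.0 was chosen for standardized 9-variable data where within-state
distances concentrate around `√(2d) ≈ 4`. `val_fraction` 0.3 is a common
holdout share — the method's source only asks for "a certain proportion".

## Synthetic streams

**Fed-batch fermentation.** Monod kinetics
`μ = μ_max·S/(K_s + S)`, `dX/dt = μX`, `dS/dt = −μX/Y_xs`, with feed terms
`dS/dt += F(S_f − S)/V`, `dX/dt −= FX/V`, `dV/dt = F` after `feed_start`.
Defaults `μ_max = 0.25 h⁻¹`, `K_s = 1.5 g/L`, `Y_xs = 0.5`, `S₀ = 30 g/L`,
`X₀ = 0.2 g/L`, `V₀ = 50 L`, feed from 24 h at 0.25 L/h of 300 g/L
substrate, 96 h batches — a substrate fall-then-fed profile typical of an
antibiotic fed-batch. Integration is fixed-step RK4 at the sampling
resolution (reproducibility over adaptive stepping); negative states are
clamped to zero. Nine emitted features mirror the auxiliary-variable roles
of an industrial fermenter (cultivation time, temperature/pH/DO surrogates
driven by `μ` and `μX`, air flow and its integral, feed rate and
cumulative volumes, an ammonia-consumption surrogate proportional to
biomass formed); measurement noise (relative level `noise_sd`, default
0.02) is applied to features only — offline analysis is treated as exact.
Per-batch parameters are jittered by `batch_variability` (default 5%
relative). The default campaign is 5 batches at 15-minute sampling and
4-hour labeling: labeled samples of batches 1–2 (50) form the initial
training set, batches 3–5 stream online (1,155 ticks, 75 labels). The
15-minute default is a desk-scale choice: it preserves the paper-of-
record's 1:16-per-cycle label sparsity and initial-training-set size while
keeping a full campaign under a minute of compute; the finer 5-minute
schedule is one config field away.

**Drifting nonlinear stream.** Per regime ("mode"): features
`x ~ N(center, scale²I)` and target `y = b + w·x + amp·sin(freq·Σx)` plus
Gaussian noise. Abrupt drift cycles through modes at `switch_ticks`;
gradual drift creeps the active mode's coefficients by `drift_rate` per
tick. The packaged two-mode campaign warms up in regime A, switches to a
well-separated regime B, and returns (A→B→A) with the away-phase longer
than a 50-label sliding-window turnover — recurring regimes are the
condition where retaining per-state models is observably better than
window forgetting; under a single permanent switch, adaptive clustering
and a moving window recover through the same mechanism and are near-
equivalent.

**What a green test does and does not establish.** The generators
reproduce the *structure* of industrial semi-supervised streams (label
sparsity, nonlinearity, batch-to-batch variability, both drift kinds), not
the distributions of any real plant; passing thresholds here demonstrate
that the mechanisms work as specified, not plant-level accuracy. Real data
features the simulators lack include sensor faults and missing values,
auto-correlated measurement noise, irregular labeling delays, and
cross-batch autocorrelation beyond parameter jitter.

## Known limitations

* The outlier buffer is unbounded by default (a cap is available); streams
  consisting mostly of isolated outliers grow memory linearly.
* Clusters never merge; long gradual drift can leave a trail of
  overlapping clusters whose models are near-duplicates.
* MAPE is undefined whenever a true target is exactly zero (e.g. substrate
  depletion) and is reported as such rather than patched.
* Cold-start ticks (fewer than two labeled samples seen) yield no
  prediction and are excluded from metrics.
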