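"""Salient-change detection with dynamic decaying stochastic thresholds.

This is the model's clock substitute.  Each feature layer k keeps a
threshold on the inter-frame activation distance.  Between events the
threshold decays from its ceiling T_max towards a floor near T_min along a
noisy exponential:

    T[t+1] = T[t] - ((T_max - T_min)/tau) * exp(-D/tau) + N(0, (T_max - T_min)/alpha)

where D counts timesteps since the last reset.  Whenever the measured
distance exceeds the current threshold, a salient perceptual change is
registered — one unit of subjective time — the layer's accumulator is
incremented, and the threshold resets to T_max with D = 0.  Attention is a
single global factor C > 0 scaling both T_min and T_max: higher C (higher
thresholds, less attention to change) registers fewer events and yields
shorter duration estimates.

Without noise the trajectory from a reset is the partial sum of a geometric
series, converging to the closed-form floor

    T_max - (T_max - T_min) / (tau * (1 - exp(-1/tau))),

slightly below T_min; :func:`noiseless_threshold_floor` computes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import DistanceSeries

__all__ = [
    "ThresholdParams",
    "ThresholdState",
    "EventTrain",
    "AccumulatorVector",
    "DEFAULT_THRESHOLDS",
    "apply_attention_scaling",
    "threshold_step",
    "noiseless_threshold_floor",
    "detect_salient_events",
    "run_accumulators",
    "counts_to_frame",
    "cumulative_counts_to_frame",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Threshold dynamics for one layer.

    T_max / T_min are the ceiling and floor of the decay (in the layer's
    activation-distance units), tau the decay time constant in timesteps,
    and alpha the noise divisor: the per-step Gaussian noise has standard
    deviation (T_max - T_min)/alpha by default (``noise_interpretation=
    "variance"`` treats that quantity as the variance instead).
    ``attention_C`` records the cumulative attention scaling already baked
    into T_max/T_min.  ``static_mode`` freezes the threshold at T_max with
    no decay and no noise (control variant).
    """

    T_max: float
    T_min: float
    tau: float
    alpha: float
    attention_C: float = 1.0
    static_mode: bool = False
    noise_interpretation: str = "sd"
    clamp_at_zero: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.T_min < self.T_max):
            raise ValueError(f"need 0 < T_min < T_max; got {self.T_min}, {self.T_max}")
        if self.tau <= 0 or self.alpha <= 0:
            raise ValueError("tau and alpha must be positive")
        if self.attention_C <= 0:
            raise ValueError("attention_C must be positive")
        if self.noise_interpretation not in ("sd", "variance"):
            raise ValueError("noise_interpretation must be 'sd' or 'variance'")

    @property
    def noise_sd(self) -> float:
        """Standard deviation of the per-step threshold noise."""
        scale = (self.T_max - self.T_min) / self.alpha
        return scale if self.noise_interpretation == "sd" else math.sqrt(scale)


#: Per-layer threshold parameters for the canonical four read-out layers
#: (T_max, T_min, tau, alpha).  The fc7 reference lists only T_max = 355
#: explicitly; its tau and alpha follow the values shared by every other
#: layer (100 and 50).
DEFAULT_THRESHOLDS: Dict[str, ThresholdParams] = {
    "conv2": ThresholdParams(T_max=340.0, T_min=100.0, tau=100.0, alpha=50.0),
    "pool5": ThresholdParams(T_max=400.0, T_min=100.0, tau=100.0, alpha=50.0),
    "fc7": ThresholdParams(T_max=355.0, T_min=100.0, tau=100.0, alpha=50.0),
    "output": ThresholdParams(T_max=0.55, T_min=0.15, tau=100.0, alpha=50.0),
}


@dataclass
class ThresholdState:
    """Current threshold value and timesteps since the last reset."""

    T_current: float
    D: int = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")


def apply_attention_scaling(params: ThresholdParams, C: float) -> ThresholdParams:
    """Scale T_min and T_max (and hence the noise scale and floor) by C > 0."""
    if not C > 0:
        raise ValueError(f"attention scaling factor must be > 0, got {C}")
    return replace(
        params,
        T_max=C * params.T_max,
        T_min=C * params.T_min,
        attention_C=C * params.attention_C,
    )


def threshold_step(
    state: ThresholdState,
    params: ThresholdParams,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
) -> ThresholdState:
    """Advance the threshold one timestep (no event).

    Applies the exponential decrement for the current D, adds one Gaussian
    noise draw unless ``noiseless``, and increments D.  Attention scaling
    must already be baked into ``params``.  Noise can drive the value
    transiently outside [floor, T_max]; it is not clamped unless
    ``params.clamp_at_zero``.
    """
    if params.static_mode:
        return ThresholdState(T_current=params.T_max, D=state.D + 1)
    dec = ((params.T_max - params.T_min) / params.tau) * math.exp(-state.D / params.tau)
    noise = 0.0
    if not noiseless:
        if rng is None:
            raise ValueError("stochastic stepping needs an rng; or pass noiseless=True")
        noise = rng.normal(0.0, params.noise_sd)
    T_new = state.T_current - dec + noise
    if params.clamp_at_zero and T_new < 0:
        T_new = 0.0
    return ThresholdState(T_current=T_new, D=state.D + 1)


def noiseless_threshold_floor(params: ThresholdParams) -> float:
    """Asymptote of the noiseless decay from a reset (geometric series)."""
    span = params.T_max - params.T_min
    return params.T_max - span / (params.tau * (1.0 - math.exp(-1.0 / params.tau)))


@dataclass
class EventTrain:
    """Per-layer timestep indices of salient events for one trial."""

    events: Dict[str, np.ndarray]
    n_steps: int
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        for name, idx in self.events.items():
            idx = np.asarray(idx, dtype=np.int64)
            if len(idx) and (np.any(np.diff(idx) <= 0) or idx[-1] >= self.n_steps):
                raise ValueError(f"layer {name!r}: event indices invalid")
            self.events[name] = idx

    def counts(self) -> Dict[str, int]:
        return {name: int(len(idx)) for name, idx in self.events.items()}

    def cumulative(self, layer: str) -> np.ndarray:
        """Cumulative event count at each timestep (length n_steps)."""
        curve = np.zeros(self.n_steps, dtype=np.int64)
        if len(self.events[layer]):
            np.add.at(curve, self.events[layer], 1)
        return np.cumsum(curve)


@dataclass
class AccumulatorVector:
    """Per-layer salient-event counts for one trial — the model's abstract
    duration units, and the feature vector for calibration."""

    counts: Dict[str, int]
    trial_id: str = "trial"
    duration_s: float = float("nan")
    scene_type: str = "unlabelled"
    event_train: EventTrain | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    def as_array(self, layer_order: Sequence[str]) -> np.ndarray:
        return np.array([self.counts[name] for name in layer_order], dtype=np.float64)


def _detect_single_layer(
    d: np.ndarray,
    params: ThresholdParams,
    rng: np.random.Generator | None,
    noiseless: bool,
) -> np.ndarray:
    """Event indices for one layer's distance series (tight inner loop)."""
    n = len(d)
    if params.static_mode:
        return np.flatnonzero(d > params.T_max)
    span = params.T_max - params.T_min
    # decrement depends only on D; precompute the schedule once
    dec = (span / params.tau) * np.exp(-np.arange(n, dtype=np.float64) / params.tau)
    if noiseless:
        noise = np.zeros(n)
    else:
        noise = rng.normal(0.0, params.noise_sd, size=n)
    clamp = params.clamp_at_zero
    T = params.T_max
    T_max = params.T_max
    D = 0
    events = []
    d = np.asarray(d, dtype=np.float64)
    for t in range(n):
        if d[t] > T:  # strict: ties do not trigger
            events.append(t)
            T = T_max
            D = 0
        else:
            T = T - dec[D] + noise[t]
            if clamp and T < 0.0:
                T = 0.0
            D += 1
    return np.asarray(events, dtype=np.int64)


def detect_salient_events(
    distances: DistanceSeries,
    params: Mapping[str, ThresholdParams],
    seed: int | np.random.SeedSequence | None = 0,
    noiseless: bool = False,
    attention_C: float = 1.0,
) -> EventTrain:
    """Run the threshold mechanism over a trial's distance series.

    Per timestep and layer: compare the distance to the current threshold
    first; on an event, reset to (scaled) T_max with D = 0, otherwise apply
    one decay-plus-noise step.  The threshold starts at the scaled T_max
    with D = 0.  Each layer consumes an independent noise substream spawned
    from ``seed``, so results are reproducible bitwise.
    """
    missing = [name for name in distances.layer_names if name not in params]
    if missing:
        raise KeyError(f"no threshold parameters for layers {missing}")
    if noiseless:
        rngs = {name: None for name in distances.layer_names}
    else:
        ss = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        children = ss.spawn(len(distances.layer_names))
        rngs = {
            name: np.random.default_rng(child)
            for name, child in zip(distances.layer_names, children)
        }
    events: Dict[str, np.ndarray] = {}
    for name in distances.layer_names:
        p = params[name]
        if attention_C != 1.0:
            p = apply_attention_scaling(p, attention_C)
        events[name] = _detect_single_layer(
            distances.distances[name], p, rngs[name], noiseless
        )
    return EventTrain(events=events, n_steps=distances.n_steps, trial_id=distances.trial_id)


def run_accumulators(
    trials: Iterable[DistanceSeries],
    params: Mapping[str, ThresholdParams],
    seed: int = 0,
    noiseless: bool = False,
    attention_C: float = 1.0,
) -> list[AccumulatorVector]:
    """Detect and count salient events independently for every trial.

    Thresholds and accumulators are re-initialised per trial (no state
    leaks); each trial gets its own noise substream spawned from ``seed``.
    The returned vectors keep their event trains, so cumulative
    count-versus-time curves remain available per layer.
    """
    root = np.random.SeedSequence(seed)
    out: list[AccumulatorVector] = []
    for child, series in zip_spawn(root, trials):
        train = detect_salient_events(
            series, params, seed=child, noiseless=noiseless, attention_C=attention_C
        )
        out.append(
            AccumulatorVector(
                counts=train.counts(),
                trial_id=series.trial_id,
                duration_s=series.duration_s
                if not math.isnan(series.duration_s)
                else series.n_steps / series.frame_rate,
                scene_type=series.scene_type,
                event_train=train,
            )
        )
    return out


def zip_spawn(root: np.random.SeedSequence, items: Iterable):
    """Pair each item with a freshly spawned child SeedSequence."""
    for item in items:
        yield root.spawn(1)[0], item


def counts_to_frame(accumulators: Sequence[AccumulatorVector]) -> pd.DataFrame:
    """Long-format counts: trial_id, scene_type, duration_s, layer, count."""
    rows = [
        {
            "trial_id": a.trial_id,
            "scene_type": a.scene_type,
            "duration_s": a.duration_s,
            "layer": layer,
            "count": count,
        }
        for a in accumulators
        for layer, count in a.counts.items()
    ]
    return pd.DataFrame(rows)


def cumulative_counts_to_frame(
    accumulators: Sequence[AccumulatorVector],
) -> pd.DataFrame:
    """Per-timestep cumulative curves: trial_id, layer, t, cumulative_count."""
    rows = []
    for a in accumulators:
        if a.event_train is None:
            continue
        for layer in a.counts:
            curve = a.event_train.cumulative(layer)
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": a.trial_id,
                        "layer": layer,
                        "t": np.arange(len(curve)),
                        "cumulative_count": curve,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["trial_id", "layer", "t", "cumulative_count"]
    )
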