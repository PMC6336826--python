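"""Synthetic stimuli: trial designs, activation-change streams, videos, gaze.

Everything the pipeline consumes can be generated here so the full model is
exercisable without any video corpus, eye tracker or pretrained network.
Three scene archetypes mirror the change-richness ordering of natural
footage — busy city streets, a leafy campus walk, a quiet office/cafe —
through the rate of salient inter-frame change bursts (stream mode) and the
number and speed of moving objects (video mode).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import DistanceSeries, FrameSequence, LayerSpec
from .gating import GazeTrace
from .thresholds import DEFAULT_THRESHOLDS, ThresholdParams

__all__ = [
    "STANDARD_DURATIONS_S",
    "TrialDesign",
    "SceneSpec",
    "DEFAULT_SCENES",
    "generate_trial_list",
    "generate_synthetic_stream",
    "generate_synthetic_video",
    "generate_synthetic_gaze",
]

#: The 13 trial durations (seconds) of the reference design.
STANDARD_DURATIONS_S: tuple[float, ...] = (
    1, 1.5, 2, 3, 4, 6, 8, 12, 16, 24, 32, 48, 64,
)

#: Repetitions per duration in the reference design (13 x 330 = 4290 trials).
REFERENCE_REPETITIONS = 330

#: Desk-scale default: 13 durations x 20 repetitions = 260 trials.
DESK_REPETITIONS = 20


@dataclass(frozen=True)
class Trial:
    trial_id: str
    duration_s: float
    scene_type: str


@dataclass
class TrialDesign:
    """A pseudo-random list of (trial_id, duration_s, scene_type)."""

    trials: list[Trial]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def durations(self) -> np.ndarray:
        return np.sort(np.unique([t.duration_s for t in self.trials]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trials])


@dataclass(frozen=True)
class SceneSpec:
    """Change statistics of one scene archetype.

    Stream mode: per layer, inter-frame distances are a Gaussian baseline
    (mean ``baseline_frac * T_min``, sd ``noise_floor * T_min``) plus
    salient bursts of fixed magnitude ``burst_gain * T_max`` arriving as a
    Bernoulli process at ``change_rate`` Hz.  Magnitudes are expressed as
    fractions of each layer's threshold scale so one spec drives every
    layer, including the probability-scale output layer.

    Video mode: ``n_objects`` squares of side ``object_size`` move at
    ``object_speed`` px/frame over a static background.
    """

    scene_type: str
    change_rate: float
    baseline_frac: float = 0.6
    noise_floor: float = 0.1
    burst_gain: float = 1.25
    n_objects: int = 2
    object_speed: float = 2.0
    object_size: int = 12

    def __post_init__(self) -> None:
        if self.change_rate < 0:
            raise ValueError("change_rate must be >= 0")
        if self.noise_floor < 0 or self.baseline_frac < 0:
            raise ValueError("baseline parameters must be >= 0")

    def expected_mean_distance(
        self, layer_params: ThresholdParams, frame_rate: float
    ) -> float:
        """Configured marginal mean of the generated distance series."""
        p_burst = min(self.change_rate / frame_rate, 1.0)
        return (
            self.baseline_frac * layer_params.T_min
            + p_burst * self.burst_gain * layer_params.T_max
        )


#: Three archetypes ordered by change richness: city > campus > office/cafe.
DEFAULT_SCENES: Dict[str, SceneSpec] = {
    "city": SceneSpec("city", change_rate=1.2, n_objects=4, object_speed=4.0),
    "campus_outside": SceneSpec(
        "campus_outside", change_rate=0.6, n_objects=2, object_speed=2.0
    ),
    "office_cafe": SceneSpec(
        "office_cafe", change_rate=0.3, n_objects=1, object_speed=1.0
    ),
}


def generate_trial_list(
    durations: Sequence[float] = STANDARD_DURATIONS_S,
    repetitions: int = DESK_REPETITIONS,
    seed: int = 0,
    scene_types: Sequence[str] | None = None,
) -> TrialDesign:
    """Shuffled trial list with exactly ``repetitions`` trials per duration.

    Scene types rotate over the repetitions of each duration before the
    shuffle, so scenes stay near-balanced within every duration level.
    """
    if not durations:
        raise ValueError("need at least one duration")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if scene_types is None:
        scene_types = tuple(DEFAULT_SCENES)
    trials = [
        Trial(
            trial_id=f"d{dur:g}_r{rep:03d}",
            duration_s=float(dur),
            scene_type=scene_types[rep % len(scene_types)],
        )
        for dur in durations
        for rep in range(repetitions)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return TrialDesign(trials=[trials[i] for i in order], seed=seed)


def _stream_length(duration_s: float, frame_rate: float) -> int:
    """Distance-series length: one fewer than the frame count."""
    return max(int(round(duration_s * frame_rate)) - 1, 0)


def generate_synthetic_stream(
    design: TrialDesign,
    scenes: Mapping[str, SceneSpec] | None = None,
    layers: Sequence[LayerSpec] | Sequence[str] | None = None,
    frame_rate: float = 30.0,
    seed: int = 0,
    threshold_refs: Mapping[str, ThresholdParams] | None = None,
) -> list[DistanceSeries]:
    """Per-trial, per-layer distance series with scene-controlled statistics.

    Stands in for the change series a feature hierarchy would produce when
    driven by natural video of each scene type.  Higher ``change_rate``
    yields stochastically larger distances and more supra-threshold bursts.
    ``threshold_refs`` provides the per-layer magnitude scale (defaults to
    the canonical table).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    scenes = dict(scenes) if scenes is not None else DEFAULT_SCENES
    threshold_refs = dict(threshold_refs or DEFAULT_THRESHOLDS)
    if layers is None:
        layer_names = list(threshold_refs)
    else:
        layer_names = [sp.name if isinstance(sp, LayerSpec) else str(sp) for sp in layers]
    for name in layer_names:
        if name not in threshold_refs:
            raise KeyError(f"no threshold reference scale for layer {name!r}")
    root = np.random.SeedSequence(seed)
    out: list[DistanceSeries] = []
    for trial in design.trials:
        if trial.scene_type not in scenes:
            raise KeyError(f"no SceneSpec for scene {trial.scene_type!r}")
        sc = scenes[trial.scene_type]
        rng = np.random.default_rng(root.spawn(1)[0])
        n = _stream_length(trial.duration_s, frame_rate)
        p_burst = min(sc.change_rate / frame_rate, 1.0)
        bursts = rng.random(n) < p_burst  # shared across layers: one scene event
        distances: Dict[str, np.ndarray] = {}
        for name in layer_names:
            ref = threshold_refs[name]
            base_mean = sc.baseline_frac * ref.T_min
            base_sd = sc.noise_floor * ref.T_min
            d = rng.normal(base_mean, base_sd, size=n) if n else np.zeros(0)
            d = np.maximum(d, 0.0)
            d = d + bursts * (sc.burst_gain * ref.T_max)
            distances[name] = d
        out.append(
            DistanceSeries(
                distances=distances,
                frame_rate=frame_rate,
                trial_id=trial.trial_id,
                scene_type=trial.scene_type,
                duration_s=trial.duration_s,
            )
        )
    return out


def _bounce(pos: float, vel: float, lo: float, hi: float) -> tuple[float, float]:
    pos += vel
    if pos < lo:
        pos, vel = 2 * lo - pos, -vel
    elif pos > hi:
        pos, vel = 2 * hi - pos, -vel
    return pos, vel


def generate_synthetic_video(
    design: TrialDesign,
    scenes: Mapping[str, SceneSpec] | None = None,
    frame_size: tuple[int, int] = (120, 160),
    frame_rate: float = 30.0,
    seed: int = 0,
) -> list[FrameSequence]:
    """Pixel-space fixtures: bright squares bouncing over a mid-grey field.

    Object count and speed come from each trial's SceneSpec.  Each returned
    FrameSequence carries an ``object_paths`` attribute of shape
    (n_objects, n_frames, 2) with per-frame (x, y) object centres, which the
    gaze generator's tracking mode follows.
    """
    scenes = dict(scenes) if scenes is not None else DEFAULT_SCENES
    h, w = frame_size
    root = np.random.SeedSequence(seed)
    out: list[FrameSequence] = []
    for trial in design.trials:
        sc = scenes[trial.scene_type]
        rng = np.random.default_rng(root.spawn(1)[0])
        n_frames = max(int(round(trial.duration_s * frame_rate)), 1)
        half = sc.object_size / 2
        xs = rng.uniform(half, w - half, size=sc.n_objects)
        ys = rng.uniform(half, h - half, size=sc.n_objects)
        angles = rng.uniform(0, 2 * np.pi, size=sc.n_objects)
        vxs = sc.object_speed * np.cos(angles)
        vys = sc.object_speed * np.sin(angles)
        shades = rng.integers(160, 256, size=sc.n_objects)
        frames = np.full((n_frames, h, w, 3), 96, dtype=np.uint8)
        paths = np.zeros((sc.n_objects, n_frames, 2))
        for t in range(n_frames):
            for i in range(sc.n_objects):
                if t > 0:
                    xs[i], vxs[i] = _bounce(xs[i], vxs[i], half, w - half)
                    ys[i], vys[i] = _bounce(ys[i], vys[i], half, h - half)
                paths[i, t] = (xs[i], ys[i])
                r0 = int(max(ys[i] - half, 0))
                r1 = int(min(ys[i] + half, h))
                c0 = int(max(xs[i] - half, 0))
                c1 = int(min(xs[i] + half, w))
                frames[t, r0:r1, c0:c1, :] = shades[i]
        seq = FrameSequence(
            frames=frames,
            frame_rate=frame_rate,
            trial_id=trial.trial_id,
            scene_type=trial.scene_type,
        )
        seq.object_paths = paths  # tracking target for synthetic gaze
        out.append(seq)
    return out


def generate_synthetic_gaze(
    frames: FrameSequence,
    mode: str = "centre",
    seed: int = 0,
    step_sd: float = 8.0,
) -> GazeTrace:
    """Plausible per-frame fixations for one trial.

    Modes: ``centre`` fixates the frame centre; ``random_walk`` is a
    Gaussian walk (sd ``step_sd`` px/frame) reflected at the frame edges;
    ``tracking_object`` follows the first generated object's trajectory
    (requires a video from :func:`generate_synthetic_video`).
    """
    h, w = frames.frame_shape
    n = len(frames)
    if mode == "centre":
        x = np.full(n, w / 2)
        y = np.full(n, h / 2)
    elif mode == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, step_sd, size=(n, 2))
        x = np.empty(n)
        y = np.empty(n)
        px, py = w / 2, h / 2
        for t in range(n):
            px = float(np.clip(px + steps[t, 0], 0, w - 1))
            py = float(np.clip(py + steps[t, 1], 0, h - 1))
            x[t], y[t] = px, py
    elif mode == "tracking_object":
        paths = getattr(frames, "object_paths", None)
        if paths is None or not len(paths):
            raise ValueError(
                "tracking_object mode needs a video with object_paths "
                "(see generate_synthetic_video)"
            )
        x = np.clip(paths[0, :, 0], 0, w - 1)
        y = np.clip(paths[0, :, 1], 0, h - 1)
    else:
        raise ValueError(f"unknown gaze mode {mode!r}")
    return GazeTrace(x=x, y=y, trial_id=frames.trial_id)
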