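"""Per-layer activation streams from frame sequences, and their change series.

A feature extractor maps one RGB frame to one activation vector per named
layer.  Any deterministic map satisfies the contract: a pretrained
image-classification backbone (see :mod:`perceptime.backbones`), a seeded
random-projection hierarchy, or the raw pixels themselves.  Downstream, only
the Euclidean distance between successive activation vectors matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "LayerSpec",
    "ActivationStream",
    "DistanceSeries",
    "DEFAULT_LAYERS",
    "FeatureExtractor",
    "PixelIdentityExtractor",
    "RandomProjectionExtractor",
    "extract_activation_stream",
    "compute_layer_distances",
    "pixel_change_series",
    "random_projection_extractor",
    "load_frame_directory",
    "save_activation_stream",
    "load_activation_stream",
]


class ConfigurationError(ValueError):
    """Raised when inputs are inconsistent with the configured pipeline."""


@dataclass(frozen=True)
class LayerSpec:
    """A named read-out layer of the feature hierarchy.

    ``n_neurons`` is the flattened activation length for that layer.  The
    defaults mirror the canonical read-out points of an AlexNet-class
    classifier: conv2, pool5, fc7 and the 1000-way output probabilities.
    """

    name: str
    n_neurons: int

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigurationError(f"layer {self.name!r}: n_neurons must be >= 1")


#: Canonical read-out layers (name, flattened size) of the reference backbone.
DEFAULT_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("conv2", 290_400),
    LayerSpec("pool5", 9_216),
    LayerSpec("fc7", 4_096),
    LayerSpec("output", 1_000),
)


@dataclass
class FrameSequence:
    """An ordered RGB frame stack for one trial.

    frames : (T, H, W, 3) array; frame_rate in Hz; scene_type is a free
    categorical label used only for downstream grouping.
    """

    frames: np.ndarray
    frame_rate: float = 30.0
    trial_id: str = "trial"
    scene_type: str = "unlabelled"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (T, H, W, 3); got {self.frames.shape}"
            )
        if len(self.frames) < 1:
            raise ValueError("FrameSequence requires at least one frame")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.frame_rate


class FeatureExtractor(Protocol):
    """Deterministic map from one frame to one activation vector per layer."""

    extractor_id: str
    layers: Sequence[LayerSpec]

    def __call__(self, frame: np.ndarray) -> Dict[str, np.ndarray]: ...


@dataclass
class ActivationStream:
    """Per-layer activation time series for one trial.

    ``activations`` maps layer name -> (T, n_neurons) float64 array; every
    layer has exactly one vector per frame.
    """

    activations: Dict[str, np.ndarray]
    frame_rate: float = 30.0
    trial_id: str = "trial"
    scene_type: str = "unlabelled"
    extractor_id: str = "unknown"

    def __post_init__(self) -> None:
        lengths = {name: len(a) for name, a in self.activations.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"layers disagree on timestep count: {lengths}")

    @property
    def n_timesteps(self) -> int:
        return len(next(iter(self.activations.values())))

    @property
    def layer_names(self) -> list[str]:
        return list(self.activations)


@dataclass
class DistanceSeries:
    """Per-layer Euclidean distances between successive activations.

    ``distances`` maps layer name -> (T-1,) non-negative float64 array.
    """

    distances: Dict[str, np.ndarray]
    frame_rate: float = 30.0
    trial_id: str = "trial"
    scene_type: str = "unlabelled"
    duration_s: float = float("nan")

    def __post_init__(self) -> None:
        for name, d in self.distances.items():
            d = np.asarray(d, dtype=np.float64)
            if d.ndim != 1:
                raise ValueError(f"layer {name!r}: distance series must be 1-D")
            if len(d) and d.min() < 0:
                raise ValueError(f"layer {name!r}: negative distance")
            self.distances[name] = d
        lengths = {len(d) for d in self.distances.values()}
        if len(lengths) > 1:
            raise ValueError("all layers must have equal series length")

    @property
    def n_steps(self) -> int:
        return len(next(iter(self.distances.values())))

    @property
    def layer_names(self) -> list[str]:
        return list(self.distances)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: columns trial_id, layer, t, distance."""
        rows = [
            pd.DataFrame(
                {
                    "trial_id": self.trial_id,
                    "layer": name,
                    "t": np.arange(len(d)),
                    "distance": d,
                }
            )
            for name, d in self.distances.items()
        ]
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Extractors
# ---------------------------------------------------------------------------


class PixelIdentityExtractor:
    """The trivial extractor: the flattened frame itself, as one layer.

    Flattening is channel-major-last C order (row, column, channel), fixed so
    distances are reproducible across runs.  Running the change pipeline on
    this extractor is exactly the pixel-wise stimulus-difference baseline.
    """

    extractor_id = "pixel_identity"

    def __init__(self, frame_shape: tuple[int, int]):
        h, w = frame_shape
        self.layers = (LayerSpec("pixels", h * w * 3),)
        self._frame_shape = (h, w)

    def __call__(self, frame: np.ndarray) -> Dict[str, np.ndarray]:
        if frame.shape[:2] != self._frame_shape:
            raise ConfigurationError(
                f"frame shape {frame.shape[:2]} != configured {self._frame_shape}"
            )
        return {"pixels": np.asarray(frame, dtype=np.float64).ravel()}


_NONLINEARITIES: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
}


class RandomProjectionExtractor:
    """Seeded hierarchical random-projection feature extractor.

    Each layer applies a fixed Gaussian random matrix (drawn once from the
    seed, then frozen) to the previous layer's output — layer 0 reads the
    flattened frame — followed by a pointwise nonlinearity.  It stands in for
    a trained backbone at desk scale: deterministic, layered, and with higher
    layers responding to transformed lower-layer features.  With
    ``nonlinearity="linear"`` (or "relu", which is positively homogeneous)
    the map is scale-equivariant: scaling the frame scales every layer's
    inter-frame distance by the same factor.
    """

    def __init__(
        self,
        seed: int,
        frame_shape: tuple[int, int],
        layers: Sequence[LayerSpec],
        nonlinearity: str = "relu",
    ):
        if nonlinearity not in _NONLINEARITIES:
            raise ConfigurationError(
                f"unknown nonlinearity {nonlinearity!r}; choose from {sorted(_NONLINEARITIES)}"
            )
        names = [sp.name for sp in layers]
        if len(set(names)) != len(names):
            raise ConfigurationError("layer names must be unique")
        h, w = frame_shape
        self.layers = tuple(layers)
        self.extractor_id = f"random_projection(seed={seed})"
        self.nonlinearity = nonlinearity
        self._phi = _NONLINEARITIES[nonlinearity]
        self._frame_shape = (h, w)
        rng = np.random.default_rng(seed)
        self._weights: list[np.ndarray] = []
        n_in = h * w * 3
        for sp in layers:
            # 1/sqrt(n_in) scaling keeps activation magnitude stable per layer
            self._weights.append(
                rng.standard_normal((sp.n_neurons, n_in)) / np.sqrt(n_in)
            )
            n_in = sp.n_neurons

    def __call__(self, frame: np.ndarray) -> Dict[str, np.ndarray]:
        if frame.shape[:2] != self._frame_shape:
            raise ConfigurationError(
                f"frame shape {frame.shape[:2]} != configured {self._frame_shape}"
            )
        x = np.asarray(frame, dtype=np.float64).ravel()
        out: Dict[str, np.ndarray] = {}
        for sp, w in zip(self.layers, self._weights):
            x = self._phi(w @ x)
            out[sp.name] = x
        return out


def random_projection_extractor(
    seed: int,
    input_dims: tuple[int, int],
    layers: Sequence[LayerSpec],
    nonlinearity: str = "relu",
) -> RandomProjectionExtractor:
    """Functional constructor for :class:`RandomProjectionExtractor`."""
    return RandomProjectionExtractor(seed, input_dims, layers, nonlinearity)


# ---------------------------------------------------------------------------
# Stream extraction and distances
# ---------------------------------------------------------------------------


def extract_activation_stream(
    frames: FrameSequence,
    extractor: FeatureExtractor,
    layers: Sequence[LayerSpec] | None = None,
) -> ActivationStream:
    """Run every frame through ``extractor`` and stack per-layer activations.

    ``layers`` restricts (and validates) the read-out to a subset of the
    extractor's layers; by default all extractor layers are kept.
    """
    available = {sp.name: sp for sp in extractor.layers}
    if layers is None:
        layers = tuple(extractor.layers)
    for sp in layers:
        if sp.name not in available:
            raise ConfigurationError(
                f"extractor provides no layer {sp.name!r} (has {sorted(available)})"
            )
        if available[sp.name].n_neurons != sp.n_neurons:
            raise ConfigurationError(
                f"layer {sp.name!r}: requested {sp.n_neurons} neurons, "
                f"extractor provides {available[sp.name].n_neurons}"
            )
    wanted = [sp.name for sp in layers]
    stacks: Dict[str, list[np.ndarray]] = {name: [] for name in wanted}
    for frame in frames.frames:
        acts = extractor(frame)
        for name in wanted:
            stacks[name].append(np.asarray(acts[name], dtype=np.float64))
    activations = {name: np.stack(vs) for name, vs in stacks.items()}
    return ActivationStream(
        activations=activations,
        frame_rate=frames.frame_rate,
        trial_id=frames.trial_id,
        scene_type=frames.scene_type,
        extractor_id=extractor.extractor_id,
    )


def compute_layer_distances(stream: ActivationStream) -> DistanceSeries:
    """Euclidean (L2) distance between successive activation vectors, per layer.

    Entry ``t`` is ``||a[t+1] - a[t]||_2``; each layer's series has length
    ``n_timesteps - 1``.  Computed in double precision.  A single-timestep
    stream yields empty series with a warning rather than an error.
    """
    if stream.n_timesteps < 2:
        warnings.warn(
            f"trial {stream.trial_id!r}: fewer than 2 timesteps; "
            "returning empty distance series",
            stacklevel=2,
        )
        distances = {name: np.zeros(0) for name in stream.layer_names}
    else:
        distances = {
            name: np.linalg.norm(np.diff(a.astype(np.float64), axis=0), axis=1)
            for name, a in stream.activations.items()
        }
    return DistanceSeries(
        distances=distances,
        frame_rate=stream.frame_rate,
        trial_id=stream.trial_id,
        scene_type=stream.scene_type,
    )


def pixel_change_series(frames: FrameSequence) -> DistanceSeries:
    """Pixel-wise stimulus-difference baseline: L2 distance between flattened
    successive frames, as a single-"layer" series named ``pixels``.

    Identical to routing ``frames`` through :class:`PixelIdentityExtractor`
    and :func:`compute_layer_distances`, so it drops into change detection in
    place of a network-derived stream.
    """
    if len(frames) < 2:
        raise ValueError("pixel_change_series requires at least 2 frames")
    flat = frames.frames.reshape(len(frames), -1).astype(np.float64)
    d = np.linalg.norm(np.diff(flat, axis=0), axis=1)
    return DistanceSeries(
        distances={"pixels": d},
        frame_rate=frames.frame_rate,
        trial_id=frames.trial_id,
        scene_type=frames.scene_type,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def load_frame_directory(
    path,
    frame_rate: float = 30.0,
    trial_id: str | None = None,
    scene_type: str = "unlabelled",
) -> FrameSequence:
    """Load a directory of numbered PNG/JPEG frames as a FrameSequence."""
    from pathlib import Path

    import imageio.v3 as iio

    p = Path(path)
    files = sorted(
        f for f in p.iterdir() if f.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not files:
        raise FileNotFoundError(f"no PNG/JPEG frames in {p}")
    frames = np.stack([iio.imread(f)[..., :3] for f in files])
    return FrameSequence(
        frames=frames,
        frame_rate=frame_rate,
        trial_id=trial_id or p.name,
        scene_type=scene_type,
    )


def save_activation_stream(stream: ActivationStream, path) -> None:
    """Persist an ActivationStream to an HDF5 file keyed by layer name."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["frame_rate"] = stream.frame_rate
        f.attrs["trial_id"] = stream.trial_id
        f.attrs["scene_type"] = stream.scene_type
        f.attrs["extractor_id"] = stream.extractor_id
        for name, a in stream.activations.items():
            f.create_dataset(name, data=a)


def load_activation_stream(path) -> ActivationStream:
    import h5py

    with h5py.File(path, "r") as f:
        activations = {name: np.asarray(f[name]) for name in f.keys()}
        return ActivationStream(
            activations=activations,
            frame_rate=float(f.attrs["frame_rate"]),
            trial_id=str(f.attrs["trial_id"]),
            scene_type=str(f.attrs["scene_type"]),
            extractor_id=str(f.attrs["extractor_id"]),
        )
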