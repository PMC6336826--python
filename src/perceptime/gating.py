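"""Input gating: centre crop, gaze-contingent crop, shuffled-gaze control.

Three input regimes restrict what the feature hierarchy sees.  The
full-frame regime keeps a fixed centre patch of the video.  The gaze regime
keeps a smaller patch centred on the viewer's fixation at each frame — a
crude spotlight model of visual-spatial attention.  The shuffled-gaze
control applies the gaze trace recorded on one trial to a different trial's
video, dissociating patch movement from patch content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .features import FrameSequence

__all__ = [
    "GazeTrace",
    "CropSpec",
    "centre_crop",
    "gaze_contingent_crop",
    "shuffle_gaze_assignment",
    "read_gaze_csv",
    "write_gaze_csv",
]

#: Source video patch kept in the full-frame regime (pixels).
FULL_FRAME_PATCH = (720, 720)
#: Patch centred on fixation in the gaze regime (pixels).
GAZE_PATCH = (400, 400)


@dataclass
class GazeTrace:
    """Per-frame fixation coordinates in source-frame pixel space.

    ``x`` / ``y`` are float arrays aligned 1:1 with the frames of the paired
    trial; ``valid`` marks usable samples (tracker loss etc. is invalid).
    """

    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray | None = None
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.valid is None:
            self.valid = np.ones(len(self.x), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("x, y and valid must have equal length")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if bad.any():
            raise ValueError(f"trial {self.trial_id!r}: non-finite valid gaze sample")

    def __len__(self) -> int:
        return len(self.x)

    def filled(self) -> "GazeTrace":
        """Forward-fill invalid samples with the most recent valid one;
        leading invalids take the first valid sample."""
        if self.valid.all():
            return self
        if not self.valid.any():
            raise ValueError(f"trial {self.trial_id!r}: gaze trace entirely invalid")
        idx = np.where(self.valid, np.arange(len(self)), -1)
        idx = np.maximum.accumulate(idx)
        first_valid = int(np.argmax(self.valid))
        idx[idx < 0] = first_valid
        return GazeTrace(
            x=self.x[idx], y=self.y[idx],
            valid=np.ones(len(self), dtype=bool),
            trial_id=self.trial_id,
        )

    def aligned_to(self, n_frames: int) -> "GazeTrace":
        """Match the trace length to ``n_frames``: truncate if longer, hold
        the final sample if shorter (used for shuffled donor traces)."""
        t = self.filled()
        if len(t) == n_frames:
            return t
        if len(t) > n_frames:
            return GazeTrace(t.x[:n_frames], t.y[:n_frames], trial_id=t.trial_id)
        pad = n_frames - len(t)
        return GazeTrace(
            np.concatenate([t.x, np.full(pad, t.x[-1])]),
            np.concatenate([t.y, np.full(pad, t.y[-1])]),
            trial_id=t.trial_id,
        )


@dataclass(frozen=True)
class CropSpec:
    """Which patch of the source frame feeds the model.

    ``full_frame_centre`` keeps a fixed centred patch (default 720x720, 56%
    of a 1280x720 source); ``gaze_patch`` keeps a per-frame window centred
    on fixation (default 400x400, ~17% of the source).
    """

    mode: str = "full_frame_centre"
    patch_width: int = FULL_FRAME_PATCH[1]
    patch_height: int = FULL_FRAME_PATCH[0]

    def __post_init__(self) -> None:
        if self.mode not in ("full_frame_centre", "gaze_patch"):
            raise ValueError(f"unknown crop mode {self.mode!r}")
        if self.patch_width < 1 or self.patch_height < 1:
            raise ValueError("patch dimensions must be positive")

    @staticmethod
    def gaze_default() -> "CropSpec":
        return CropSpec("gaze_patch", GAZE_PATCH[1], GAZE_PATCH[0])

    def pixel_fraction(self, frame_height: int, frame_width: int) -> float:
        """Fraction of source pixels the patch retains."""
        return (self.patch_width * self.patch_height) / (frame_height * frame_width)


def _check_patch_fits(spec: CropSpec, h: int, w: int) -> None:
    if spec.patch_height > h or spec.patch_width > w:
        raise ValueError(
            f"patch {spec.patch_height}x{spec.patch_width} exceeds frame {h}x{w}"
        )


def centre_crop(frames: FrameSequence, spec: CropSpec | None = None) -> FrameSequence:
    """Crop every frame to the centred patch (full-frame regime).

    Offsets are floor((source - patch)/2) on each axis, so the patch sits at
    the exact centre (biased one pixel up/left for odd differences).
    """
    if spec is None:
        spec = CropSpec()
    if spec.mode != "full_frame_centre":
        raise ValueError("centre_crop requires mode='full_frame_centre'")
    h, w = frames.frame_shape
    _check_patch_fits(spec, h, w)
    top = (h - spec.patch_height) // 2
    left = (w - spec.patch_width) // 2
    cropped = frames.frames[
        :, top : top + spec.patch_height, left : left + spec.patch_width, :
    ]
    return FrameSequence(
        frames=cropped,
        frame_rate=frames.frame_rate,
        trial_id=frames.trial_id,
        scene_type=frames.scene_type,
    )


def gaze_contingent_crop(
    frames: FrameSequence, gaze: GazeTrace, spec: CropSpec | None = None
) -> FrameSequence:
    """Crop each frame to a patch centred on that frame's fixation.

    The window is clamped to lie fully inside the frame (no padding), so the
    output has constant dimensions and no artificial high-contrast borders.
    Invalid gaze samples are forward-filled before cropping.
    """
    if spec is None:
        spec = CropSpec.gaze_default()
    if spec.mode != "gaze_patch":
        raise ValueError("gaze_contingent_crop requires mode='gaze_patch'")
    h, w = frames.frame_shape
    _check_patch_fits(spec, h, w)
    gz = gaze.aligned_to(len(frames))
    # window top-left per frame: centre on gaze, clamp inside frame
    left = np.clip(
        np.round(gz.x - spec.patch_width / 2).astype(int), 0, w - spec.patch_width
    )
    top = np.clip(
        np.round(gz.y - spec.patch_height / 2).astype(int), 0, h - spec.patch_height
    )
    out = np.empty(
        (len(frames), spec.patch_height, spec.patch_width, frames.frames.shape[-1]),
        dtype=frames.frames.dtype,
    )
    for i, (t, l) in enumerate(zip(top, left)):
        out[i] = frames.frames[i, t : t + spec.patch_height, l : l + spec.patch_width]
    return FrameSequence(
        frames=out,
        frame_rate=frames.frame_rate,
        trial_id=frames.trial_id,
        scene_type=frames.scene_type,
    )


def shuffle_gaze_assignment(
    trials: Sequence[str], seed: int
) -> Dict[str, str]:
    """Seeded derangement mapping each trial to a donor trial's gaze.

    Uses Sattolo's algorithm (a uniform random cyclic permutation), so every
    trial receives gaze recorded on a *different* trial; deterministic given
    the seed.  For two trials the only derangement is the swap.
    """
    trials = list(trials)
    if len(set(trials)) != len(trials):
        raise ValueError("trial ids must be unique")
    if len(trials) < 2:
        raise ValueError("shuffled-gaze control needs at least 2 trials")
    rng = np.random.default_rng(seed)
    perm = np.arange(len(trials))
    for i in range(len(trials) - 1, 0, -1):
        j = int(rng.integers(0, i))  # j < i: guarantees a single cycle
        perm[i], perm[j] = perm[j], perm[i]
    return {trials[i]: trials[perm[i]] for i in range(len(trials))}


def read_gaze_csv(path) -> Dict[str, GazeTrace]:
    """Read gaze traces from CSV (trial_id, frame_index, x_px, y_px, valid)."""
    df = pd.read_csv(path)
    out: Dict[str, GazeTrace] = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        g = g.sort_values("frame_index")
        out[str(trial_id)] = GazeTrace(
            x=g["x_px"].to_numpy(),
            y=g["y_px"].to_numpy(),
            valid=g["valid"].to_numpy().astype(bool) if "valid" in g else None,
            trial_id=str(trial_id),
        )
    return out


def write_gaze_csv(traces: Dict[str, GazeTrace] | Sequence[GazeTrace], path) -> None:
    if isinstance(traces, dict):
        traces = list(traces.values())
    rows = [
        pd.DataFrame(
            {
                "trial_id": t.trial_id,
                "frame_index": np.arange(len(t)),
                "x_px": t.x,
                "y_px": t.y,
                "valid": t.valid.astype(int),
            }
        )
        for t in traces
    ]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
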