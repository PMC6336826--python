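"""Input gating: centre crop, gaze-contingent patch, shuffled gaze.

Builds a small synthetic video of moving squares, then compares what the
model 'sees' under the three input regimes.  The gaze patch follows a
generated object, so it captures the moving content even when the object
leaves the frame centre; the shuffled control applies one trial's gaze to
a different trial's video.
"""

import numpy as np

from perceptime import (
    CropSpec,
    centre_crop,
    gaze_contingent_crop,
    generate_synthetic_gaze,
    generate_synthetic_video,
    generate_trial_list,
    pixel_change_series,
    shuffle_gaze_assignment,
)

design = generate_trial_list(durations=[2.0, 3.0], repetitions=2, seed=5)
videos = generate_synthetic_video(design, frame_size=(120, 160), seed=5)

# the reference geometry: a 720x720 centre patch keeps 56% of a 1280x720
# frame; the 400x400 gaze patch about 17%
centre_spec = CropSpec("full_frame_centre", 720, 720)
gaze_spec = CropSpec("gaze_patch", 400, 400)
print(f"centre patch retains {100 * centre_spec.pixel_fraction(720, 1280):.2f}% of pixels")
print(f"gaze patch covers   {100 * gaze_spec.pixel_fraction(720, 1280):.2f}% of the frame")
print()

small_centre = CropSpec("full_frame_centre", 90, 90)
small_gaze = CropSpec("gaze_patch", 50, 50)
for video in videos[:2]:
    gaze = generate_synthetic_gaze(video, mode="tracking_object")
    full = centre_crop(video, small_centre)
    patch = gaze_contingent_crop(video, gaze, small_gaze)
    c_full = pixel_change_series(full).distances["pixels"].mean()
    c_gaze = pixel_change_series(patch).distances["pixels"].mean()
    print(
        f"trial {video.trial_id:<12} mean pixel change  centre: {c_full:8.1f}   "
        f"gaze patch: {c_gaze:8.1f}"
    )

mapping = shuffle_gaze_assignment([v.trial_id for v in videos], seed=5)
print()
print("shuffled-gaze control (every trial receives another trial's gaze):")
for k, v in mapping.items():
    print(f"  {k} <- gaze of {v}")
assert all(k != v for k, v in mapping.items())
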