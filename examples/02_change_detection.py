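"""Salient-change detection and accumulation on one synthetic trial.

Generates an 8-second activation-change stream for each scene archetype and
runs the threshold mechanism over it.  The per-layer counts are the model's
abstract units of subjective time: busier scenes accumulate more of them,
which is what later makes their durations feel longer.
"""

from perceptime import (
    DEFAULT_SCENES,
    DEFAULT_THRESHOLDS,
    generate_synthetic_stream,
    generate_trial_list,
    run_accumulators,
)

for scene in DEFAULT_SCENES:
    design = generate_trial_list(
        durations=[8.0], repetitions=1, seed=0, scene_types=(scene,)
    )
    streams = generate_synthetic_stream(design, seed=0)
    accs = run_accumulators(streams, DEFAULT_THRESHOLDS, seed=0)
    a = accs[0]
    print(f"{scene:<16} 8-s trial  counts per layer: {a.counts}")

print()
print("Cumulative count curve (conv2, city trial): subjective time in units")
design = generate_trial_list(durations=[8.0], repetitions=1, seed=0, scene_types=("city",))
streams = generate_synthetic_stream(design, seed=0)
accs = run_accumulators(streams, DEFAULT_THRESHOLDS, seed=0)
curve = accs[0].event_train.cumulative("conv2")
for t in range(0, len(curve), 60):  # every 2 s at 30 Hz
    print(f"  t = {t / 30.0:4.1f} s   accumulated changes = {curve[t]}")
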