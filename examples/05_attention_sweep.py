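"""Attention modulation: scaling the thresholds shifts every estimate.

The attention factor C multiplies each layer's threshold ceiling and floor.
High C (high thresholds) means less attention to perceptual change: fewer
salient events register and durations feel shorter.  The count-to-seconds
calibration is learned once under normal attention (C = 1) and held fixed,
so the sweep shows what varying attention does to a calibrated observer.
"""

from perceptime import RunConfig, attention_sweep

config = RunConfig(seed=1, log_level="WARNING")
sweep = attention_sweep(config, [0.5, 1.0, 2.0])

print("mean estimate by duration under each attention level C:")
table = sweep["mean_estimate_by_duration"]
print(table.round(2).to_string())
print()
for C in sweep["C_values"]:
    print(
        f"C = {C:<4g} mean estimate {sweep['mean_estimate'][C]:6.3f} s, "
        f"duration slope {sweep['loglog_slope'][C]:+.4f}"
    )
print()
print(
    "Lower C (more attention) lengthens estimates, higher C shortens them,\n"
    "while every level keeps a positive slope: attention biases the clock\n"
    "without destroying duration discrimination."
)
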