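"""The decaying stochastic threshold, layer by layer.

Each layer's threshold starts at its ceiling T_max and decays towards a
floor just below T_min along a noisy exponential; whenever the inter-frame
activation distance exceeds it, a salient change is registered and the
threshold resets.  This script prints the noiseless single-step decrements,
the closed-form floor per layer, and how long the decay takes to cross a
given distance level.
"""

import numpy as np

from perceptime import DEFAULT_THRESHOLDS, noiseless_threshold_floor, threshold_step
from perceptime.thresholds import ThresholdState

print("layer    T_max    T_min    first-step decrement    floor (closed form)")
for name, p in DEFAULT_THRESHOLDS.items():
    one = threshold_step(ThresholdState(p.T_max, 0), p, noiseless=True)
    print(
        f"{name:<8} {p.T_max:<8g} {p.T_min:<8g} {p.T_max - one.T_current:<23.4f} "
        f"{noiseless_threshold_floor(p):.4f}"
    )

# time-to-cross: steps for the noiseless conv2 threshold to fall below a level
p = DEFAULT_THRESHOLDS["conv2"]
for level in (300, 200, 150, 100):
    state, steps = ThresholdState(p.T_max, 0), 0
    while state.T_current >= level and steps < 10_000:
        state = threshold_step(state, p, noiseless=True)
        steps += 1
    print(f"conv2 threshold falls below {level:>3} after {steps} noiseless steps")

# one stochastic trace: the same decay corrupted by N(0, (T_max-T_min)/alpha)
rng = np.random.default_rng(0)
state = ThresholdState(p.T_max, 0)
trace = [state.T_current]
for _ in range(300):
    state = threshold_step(state, p, rng=rng)
    trace.append(state.T_current)
print(
    f"stochastic trace (seed 0): min {min(trace):.1f}, max {max(trace):.1f} "
    f"over 300 steps — noise lets the threshold wander around the decay"
)
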