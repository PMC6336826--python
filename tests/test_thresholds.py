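"""Dynamic-threshold change detection: decay law, events, attention."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from perceptime.features import DistanceSeries
from perceptime.thresholds import (
    DEFAULT_THRESHOLDS,
    ThresholdParams,
    ThresholdState,
    apply_attention_scaling,
    detect_salient_events,
    noiseless_threshold_floor,
    run_accumulators,
    threshold_step,
)

CONV2 = DEFAULT_THRESHOLDS["conv2"]


def series(values, layer="conv2", **kw):
    return DistanceSeries({layer: np.asarray(values, dtype=float)}, **kw)


def noiseless_trajectory(params, n_steps):
    """Independent oracle: partial sums of the geometric decrement series."""
    span = params.T_max - params.T_min
    decs = (span / params.tau) * np.exp(-np.arange(n_steps) / params.tau)
    return params.T_max - np.cumsum(decs)


class TestThresholdStep:
    def test_first_step_from_ceiling(self):
        out = threshold_step(ThresholdState(340.0, 0), CONV2, noiseless=True)
        assert out.T_current == pytest.approx(337.6, abs=1e-10)
        assert out.D == 1

    def test_decrement_after_one_time_constant(self):
        out = threshold_step(ThresholdState(340.0, 100), CONV2, noiseless=True)
        assert 340.0 - out.T_current == pytest.approx(2.4 * math.exp(-1), abs=1e-10)

    def test_huge_alpha_matches_noiseless_exactly(self):
        p = dataclasses.replace(CONV2, alpha=1e300)
        rng = np.random.default_rng(0)
        a = threshold_step(ThresholdState(340.0, 5), p, rng=rng)
        b = threshold_step(ThresholdState(340.0, 5), CONV2, noiseless=True)
        assert a.T_current == pytest.approx(b.T_current, abs=1e-250)

    def test_noiseless_trajectory_is_monotone_and_converges_to_floor(self):
        state = ThresholdState(CONV2.T_max, 0)
        values = []
        for _ in range(5000):
            state = threshold_step(state, CONV2, noiseless=True)
            values.append(state.T_current)
        values = np.asarray(values)
        # strictly decreasing until the decrement underflows near the floor
        assert np.all(np.diff(values) <= 0)
        assert np.all(np.diff(values[:1000]) < 0)
        floor = noiseless_threshold_floor(CONV2)
        assert abs(values[-1] - floor) < 1e-6
        np.testing.assert_allclose(values, noiseless_trajectory(CONV2, 5000), atol=1e-9)

    @pytest.mark.parametrize("layer", list(DEFAULT_THRESHOLDS))
    def test_floor_closed_form_matches_geometric_series(self, layer):
        p = DEFAULT_THRESHOLDS[layer]
        span = p.T_max - p.T_min
        oracle = p.T_max - sum(
            (span / p.tau) * math.exp(-d / p.tau) for d in range(200_000)
        )
        assert noiseless_threshold_floor(p) == pytest.approx(oracle, abs=1e-9)

    def test_static_mode_holds_ceiling(self):
        p = dataclasses.replace(CONV2, static_mode=True)
        out = threshold_step(ThresholdState(340.0, 3), p)
        assert out.T_current == 340.0

    def test_stochastic_step_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            threshold_step(ThresholdState(340.0, 0), CONV2)


class TestParamValidation:
    def test_ordering_constraint(self):
        with pytest.raises(ValueError):
            ThresholdParams(T_max=100, T_min=100, tau=100, alpha=50)
        with pytest.raises(ValueError):
            ThresholdParams(T_max=50, T_min=100, tau=100, alpha=50)

    def test_noise_sd_interpretations(self):
        assert CONV2.noise_sd == pytest.approx(240 / 50)
        var = dataclasses.replace(CONV2, noise_interpretation="variance")
        assert var.noise_sd == pytest.approx(math.sqrt(240 / 50))


class TestAttentionScaling:
    def test_identity_at_C_equal_1(self):
        assert apply_attention_scaling(CONV2, 1.0) == CONV2

    def test_doubles_ceiling_and_floor(self):
        p = apply_attention_scaling(CONV2, 2.0)
        assert (p.T_max, p.T_min) == (680.0, 200.0)
        assert p.noise_sd == pytest.approx(2 * CONV2.noise_sd)

    @pytest.mark.parametrize("C", [0.0, -1.0])
    def test_nonpositive_C_rejected(self, C):
        with pytest.raises(ValueError):
            apply_attention_scaling(CONV2, C)

    def test_mean_count_non_increasing_in_C(self):
        """Higher thresholds (less attention) register fewer salient events."""
        rng = np.random.default_rng(11)
        trials = [
            series(np.abs(rng.normal(150, 80, size=600)), trial_id=f"t{i}")
            for i in range(20)
        ]
        means = []
        for C in (0.5, 1.0, 2.0):
            accs = run_accumulators(trials, {"conv2": CONV2}, seed=5, attention_C=C)
            means.append(np.mean([a.counts["conv2"] for a in accs]))
        assert means[0] >= means[1] >= means[2]
        assert means[0] > means[2]  # the sweep endpoints genuinely differ


class TestDetectSalientEvents:
    def test_zero_distances_give_zero_events(self):
        train = detect_salient_events(series(np.zeros(500)), DEFAULT_THRESHOLDS, noiseless=True)
        assert train.counts()["conv2"] == 0

    def test_supra_ceiling_distance_fires_every_timestep(self):
        train = detect_salient_events(series([350.0] * 80), DEFAULT_THRESHOLDS, noiseless=True)
        assert train.counts()["conv2"] == 80
        assert train.events["conv2"].tolist() == list(range(80))

    def test_sub_floor_distance_never_fires(self):
        # noiseless floor is ~98.8, so constant 50 can never cross
        train = detect_salient_events(series([50.0] * 3000), DEFAULT_THRESHOLDS, noiseless=True)
        assert train.counts()["conv2"] == 0

    def test_crossing_time_matches_trajectory_oracle(self):
        # constant distance d fires exactly when the oracle trajectory
        # first falls below d, then the threshold resets and repeats
        d = 150.0
        traj = noiseless_trajectory(CONV2, 400)
        first = int(np.argmax(traj < d))  # step index after which T < d
        train = detect_salient_events(series([d] * 400), {"conv2": CONV2}, noiseless=True)
        ev = train.events["conv2"]
        assert ev[0] == first + 1
        # after a reset the compare-at-ceiling step adds one to the interval
        np.testing.assert_array_equal(np.diff(ev), np.full(len(ev) - 1, first + 2))

    def test_tie_with_threshold_does_not_fire(self):
        # first comparison is against T_max exactly; strict inequality
        train = detect_salient_events(series([CONV2.T_max]), {"conv2": CONV2}, noiseless=True)
        assert train.counts()["conv2"] == 0

    def test_bitwise_reproducible_under_fixed_seed(self, rng):
        d = series(np.abs(rng.normal(120, 60, size=400)))
        a = detect_salient_events(d, DEFAULT_THRESHOLDS, seed=42)
        b = detect_salient_events(d, DEFAULT_THRESHOLDS, seed=42)
        np.testing.assert_array_equal(a.events["conv2"], b.events["conv2"])

    def test_reseeding_produces_count_variance(self, rng):
        d = series(np.abs(rng.normal(90, 20, size=800)))
        counts = [
            detect_salient_events(d, DEFAULT_THRESHOLDS, seed=s).counts()["conv2"]
            for s in range(12)
        ]
        assert np.var(counts) > 0

    def test_static_mode_matches_direct_comparison_oracle(self, rng):
        values = np.abs(rng.normal(250, 120, size=600))
        p = dataclasses.replace(CONV2, static_mode=True)
        for C in (0.5, 1.0, 2.0):
            train = detect_salient_events(
                series(values), {"conv2": p}, noiseless=True, attention_C=C
            )
            assert train.counts()["conv2"] == int(np.sum(values > C * CONV2.T_max))

    def test_scale_equivariance_of_noiseless_event_trains(self, rng):
        values = np.abs(rng.normal(150, 70, size=500))
        base = detect_salient_events(series(values), {"conv2": CONV2}, noiseless=True)
        for factor in (0.1, 3.0):
            scaled = detect_salient_events(
                series(values * factor),
                {"conv2": CONV2},
                noiseless=True,
                attention_C=factor,
            )
            np.testing.assert_array_equal(base.events["conv2"], scaled.events["conv2"])

    def test_missing_layer_params_is_an_error(self):
        with pytest.raises(KeyError):
            detect_salient_events(series([1.0], layer="mystery"), DEFAULT_THRESHOLDS)

    @given(st.integers(0, 2**31 - 1), st.floats(1.05, 2.0))
    def test_pointwise_increase_never_loses_events(self, seed, factor):
        """Raising every distance can only add salient events (noiseless).

        Holds on series shorter than two decay times; an induced early
        event can only delay, not remove, later crossings there.
        """
        r = np.random.default_rng(seed)
        values = np.abs(r.normal(140, 90, size=120))
        lo = detect_salient_events(series(values), {"conv2": CONV2}, noiseless=True)
        hi = detect_salient_events(series(values * factor), {"conv2": CONV2}, noiseless=True)
        assert hi.counts()["conv2"] >= lo.counts()["conv2"]


class TestRunAccumulators:
    def test_empty_series_gives_zero_counts(self):
        accs = run_accumulators([series(np.zeros(0))], DEFAULT_THRESHOLDS, seed=0)
        assert accs[0].counts["conv2"] == 0

    def test_counts_equal_event_train_lengths(self, rng):
        trials = [series(np.abs(rng.normal(120, 60, size=300)), trial_id=f"t{i}") for i in range(4)]
        accs = run_accumulators(trials, DEFAULT_THRESHOLDS, seed=3)
        for a in accs:
            assert a.counts == {k: len(v) for k, v in a.event_train.events.items()}

    def test_rerun_is_identical_no_state_leakage(self, rng):
        trials = [series(np.abs(rng.normal(120, 60, size=300)), trial_id=f"t{i}") for i in range(6)]
        a = run_accumulators(trials, DEFAULT_THRESHOLDS, seed=8)
        b = run_accumulators(trials, DEFAULT_THRESHOLDS, seed=8)
        assert [x.counts for x in a] == [y.counts for y in b]

    def test_cumulative_curve_is_step_function_of_events(self):
        train = detect_salient_events(series([350.0] * 5 + [0.0] * 5), {"conv2": CONV2}, noiseless=True)
        np.testing.assert_array_equal(
            train.cumulative("conv2"), [1, 2, 3, 4, 5, 5, 5, 5, 5, 5]
        )
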