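"""Forward-model pieces: learning rule, distances, similarity, mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genmix.designs import build_exp2_design, exp2_stimuli, realize_schedule
from genmix.model import (
    LAMBDA_BOUNDARY,
    NONLEARNER,
    OVERGENERALIZER,
    PERCEPTUAL,
    PHYSICAL,
    ParticipantParams,
    PerceptStream,
    forward_trajectory,
    generalized_strength,
    lambda_boundary,
    loglik,
    perceptual_distance,
    physical_distance,
    rw_update,
    sigmoid_map,
    similarity,
)


class TestRescorlaWagner:
    @pytest.mark.parametrize(
        "v, alpha, r, k, m, expected",
        [
            (0.0, 0.5, 1, 1, PHYSICAL, 0.5),
            (0.6, 0.2, 0, 1, PHYSICAL, 0.48),
            (0.9, 0.7, 1, 0, PHYSICAL, 0.9),
            (0.4, 0.9, 1, 1, NONLEARNER, 0.0),
            (0.0, 0.3, -1, 1, PHYSICAL, -0.3),
        ],
    )
    def test_single_step(self, v, alpha, r, k, m, expected):
        assert rw_update(v, alpha, r, k, m) == pytest.approx(expected)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            rw_update(0.0, 1.5, 1, 1, PHYSICAL)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.integers(1, 50))
    def test_closed_form_under_constant_reinforcement(self, alpha, j):
        """With v0 = 0 and r = k = 1 on every trial, v_j = 1 - (1-alpha)^j."""
        v = 0.0
        for _ in range(j):
            v = rw_update(v, alpha, 1, 1, PHYSICAL)
        assert v == pytest.approx(1.0 - (1.0 - alpha) ** j, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.sampled_from([-1, 0, 1]),
        st.sampled_from([0, 1]),
    )
    def test_update_bounded_by_endpoints(self, v, alpha, r, k):
        out = rw_update(v, alpha, r, k, PHYSICAL)
        assert min(v, r) - 1e-12 <= out <= max(v, r) + 1e-12


class TestDistances:
    def test_physical_examples(self):
        assert physical_distance(96.544, 96.544) == 0.0
        assert physical_distance(96.544, 73.672) == pytest.approx(22.872)
        assert round(physical_distance(50.80, 119.416), 2) == 68.62

    def test_physical_symmetry(self):
        assert physical_distance(3.0, 7.5) == physical_distance(7.5, 3.0)

    def test_perceptual_running_mean(self):
        stream = PerceptStream(
            [100.0, 98.0, 90.0], ["CSplus", "CSplus", "TS"]
        )
        assert perceptual_distance(stream, 2) == pytest.approx(9.0)

    def test_perceptual_zero_at_mean(self):
        stream = PerceptStream([100.0, 98.0, 99.0], ["CSplus", "CSplus", "TS"])
        assert perceptual_distance(stream, 2) == pytest.approx(0.0)

    def test_cs_trial_includes_current_percept(self):
        # mean(100, 104) = 102, so the distance on the second CS trial is 2
        stream = PerceptStream([100.0, 104.0], ["CSplus", "CSplus"])
        assert perceptual_distance(stream, 1) == pytest.approx(2.0)

    def test_undefined_before_first_cs_percept(self):
        stream = PerceptStream([90.0, 100.0], ["TS", "CSplus"])
        with pytest.raises(ValueError):
            perceptual_distance(stream, 0)

    def test_missing_percepts_carry_mean_forward(self):
        stream = PerceptStream(
            [100.0, np.nan, 90.0], ["CSplus", "CSplus", "TS"]
        )
        assert stream.cum_mean("plus")[1] == pytest.approx(100.0)
        assert perceptual_distance(stream, 2) == pytest.approx(10.0)


class TestSimilarity:
    def test_zero_distance(self):
        assert similarity(0.3, 0.0, PHYSICAL, v=0.5) == pytest.approx(1.0)

    def test_boundary_similarity_at_max_distance(self):
        assert similarity(LAMBDA_BOUNDARY, 68.62, OVERGENERALIZER, v=0.5) == (
            pytest.approx(0.70, abs=0.005)
        )

    def test_exponential_decay_value(self):
        assert similarity(0.1, 10.0, PERCEPTUAL, v=1.0) == pytest.approx(
            math.exp(-1.0)
        )

    def test_nonlearner_and_unlearned_similarity_is_one(self):
        assert similarity(0.5, 30.0, NONLEARNER, v=0.9) == 1.0
        assert similarity(0.5, 30.0, PHYSICAL, v=0.0) == 1.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            similarity(0.1, -1.0, PHYSICAL)


class TestStrengthAndMapping:
    def test_generalized_strength(self):
        assert generalized_strength(1.0, 1.0, paradigm="simple") == 1.0
        assert generalized_strength(
            0.8, 0.5, -0.6, 0.25, "differential"
        ) == pytest.approx(0.25)
        assert generalized_strength(0.0, 0.9, 0.0, 0.9, "differential") == 0.0

    def test_differential_requires_inhibitory_terms(self):
        with pytest.raises(ValueError):
            generalized_strength(0.5, 0.5, paradigm="differential")

    def test_sigmoid_examples(self):
        assert sigmoid_map(0.0, 0.0, 1.0) == pytest.approx(5.5)
        assert sigmoid_map(1.0, -2.0, 10.0) == pytest.approx(
            1.0 + 9.0 / (1.0 + math.exp(-8.0))
        )
        assert sigmoid_map(1e9, 0.0, 1.0) == pytest.approx(10.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(-1.0, 1.0),
        st.floats(-10.0, 10.0),
        st.floats(0.01, 50.0),
    )
    def test_sigmoid_bounded_and_monotone(self, g, w0, w1):
        t = sigmoid_map(g, w0, w1)
        assert 1.0 <= t <= 10.0
        assert sigmoid_map(g + 0.1, w0, w1) >= t


class TestLogLik:
    def test_mode_value(self):
        assert loglik(2.0, 2.0, 1.0) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_one_sd_away(self):
        assert loglik(3.0, 2.0, 1.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi) - 0.5
        )

    def test_additivity_over_trials(self):
        y = np.array([2.0, 5.0, 7.5])
        theta = np.array([2.5, 5.0, 6.0])
        total = loglik(y, theta, 0.8).sum()
        seq = sum(loglik(yi, ti, 0.8) for yi, ti in zip(y, theta))
        assert total == pytest.approx(seq)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            loglik(1.0, 1.0, 0.0)


class TestLambdaBoundary:
    def test_printed_boundary(self):
        assert lambda_boundary(68.62, 0.7) == pytest.approx(0.0052, abs=5e-5)
        assert round(lambda_boundary(68.62, 0.7), 4) == 0.0052
        assert LAMBDA_BOUNDARY == 0.0052

    def test_degenerate_and_inverse_cases(self):
        assert lambda_boundary(50.0, 1.0) == 0.0
        assert lambda_boundary(10.0, math.exp(-1.0)) == pytest.approx(0.1)

    def test_invalid_retain(self):
        with pytest.raises(ValueError):
            lambda_boundary(10.0, 0.0)


def _hand_unrolled_theta(us, ks, alpha, lam, w0, w1, d):
    """Spreadsheet-style oracle for a simple-paradigm series: updating only
    on CS trials (k = 1), response computed before the trial outcome."""
    v, thetas = 0.0, []
    for r, k, dist in zip(us, ks, d):
        s = math.exp(-lam * dist)
        g = v * s
        thetas.append(1.0 + 9.0 / (1.0 + math.exp(-(w0 + w1 * g))))
        if k:
            v = v + alpha * (r - v)
    return thetas


class TestForwardTrajectory:
    def _schedule(self, seed=2):
        return realize_schedule(build_exp2_design(), exp2_stimuli(), seed)

    def test_matches_hand_unrolled_oracle(self):
        """A 5-trial CS+ series equals explicit trial-by-trial arithmetic."""
        import pandas as pd

        from genmix.designs import TrialSchedule, build_exp1_design, exp1_stimuli

        frame = pd.DataFrame(
            {
                "trial": [1, 2, 3, 4, 5],
                "phase": ["acquisition"] * 3 + ["generalization"] * 2,
                "block": [0, 0, 0, 1, 1],
                "role": ["CSplus"] * 3 + ["TS", "CSplus"],
                "stimulus": ["S7"] * 3 + ["S4", "S7"],
                "size_mm": [96.544] * 3 + [73.672, 96.544],
                "us": [1, 1, 0, 0, 1],
                "k": [1, 1, 1, 0, 1],
            }
        )
        sched = TrialSchedule(frame=frame, design=build_exp1_design(),
                              stimuli=exp1_stimuli())
        params = ParticipantParams(m=PHYSICAL, alpha=0.5, lam=0.05, w0=-2.0, w1=10.0)
        traj = forward_trajectory(sched, None, params, "simple")
        expected = _hand_unrolled_theta(
            [1, 1, 0, 0, 1], [1, 1, 1, 0, 1], 0.5, 0.05, -2.0, 10.0,
            [0.0, 0.0, 0.0, 22.872, 0.0],
        )
        np.testing.assert_allclose(traj.theta, expected, atol=1e-12)
        np.testing.assert_allclose(traj.v_plus, [0.0, 0.5, 0.75, 0.375, 0.375])

    def test_nonlearner_theta_constant(self):
        sched = self._schedule()
        params = ParticipantParams(m=NONLEARNER, alpha=0.0, lam=0.0, w0=1.2, w1=3.0)
        traj = forward_trajectory(sched, None, params, "differential")
        assert np.allclose(traj.theta, sigmoid_map(0.0, 1.2, 3.0))

    def test_full_update_reaches_asymptote_immediately(self):
        sched = self._schedule()
        params = ParticipantParams(m=PHYSICAL, alpha=1.0, lam=0.05, w0=-2.0, w1=10.0)
        traj = forward_trajectory(sched, None, params, "differential")
        f = sched.frame
        first_us = np.flatnonzero((f["role"] == "CSplus") & (f["us"] == 1))[0]
        assert traj.v_plus[first_us + 1 :].max() == 1.0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        st.floats(0.0, 1.0),
        st.floats(0.006, 0.5),
        st.floats(-5.0, 5.0),
        st.floats(0.1, 30.0),
        st.integers(0, 10_000),
    )
    def test_boundedness_on_random_parameters(self, alpha, lam, w0, w1, seed):
        """v+ in [0,1], v- in [-1,0], s in (0,1], theta in (1,10)."""
        sched = realize_schedule(build_exp2_design(), exp2_stimuli(), seed)
        params = ParticipantParams(m=PHYSICAL, alpha=alpha, lam=lam, w0=w0, w1=w1)
        traj = forward_trajectory(sched, None, params, "differential")
        assert np.all((traj.v_plus >= 0) & (traj.v_plus <= 1))
        assert np.all((traj.v_minus >= -1) & (traj.v_minus <= 0))
        assert np.all((traj.s_plus > 0) & (traj.s_plus <= 1))
        assert np.all((traj.theta > 1.0) & (traj.theta < 10.0))

    def test_theta_nonincreasing_in_physical_distance(self):
        """For a Physical Generalizer the mean TS response falls with
        distance from the CS+ once inhibitory influence is excluded."""
        from genmix.designs import build_exp1_design, exp1_stimuli

        sched = realize_schedule(build_exp1_design(), exp1_stimuli(), 4)
        params = ParticipantParams(m=PHYSICAL, alpha=0.9, lam=0.08, w0=-2.0, w1=10.0)
        traj = forward_trajectory(sched, None, params, "simple")
        f = sched.frame
        gen = (f["phase"] == "generalization") & (f["role"] == "TS")
        d = traj.d_plus[gen.to_numpy()]
        t = traj.theta[gen.to_numpy()]
        means = {}
        for di, ti in zip(np.round(d, 6), t):
            means.setdefault(di, []).append(ti)
        dist_sorted = sorted(means)
        curve = [np.mean(means[k]) for k in dist_sorted]
        assert all(a >= b - 1e-9 for a, b in zip(curve, curve[1:]))
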