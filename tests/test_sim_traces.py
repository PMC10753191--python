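import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musclephys import (CohortSpec, ECDProtocolParams, TetanusParams,
                        TwitchParams, ValidationError, decrement_curve,
                        simulate_cohort, simulate_ecd_protocol,
                        simulate_tetanus, simulate_twitch)


class TestDecrementCurve:
    def test_starts_at_one_and_decays_to_r_inf(self):
        a = decrement_curve(30, r_inf=0.24, kappa=5.0)
        assert a[0] == pytest.approx(1.0)
        assert np.all(np.diff(a) < 0)
        assert a[-1] > 0.24
        # closed form at k = 30
        assert a[-1] == pytest.approx(0.24 + 0.76 * np.exp(-29 / 5))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.5, 30.0))
    def test_monotone_and_bounded(self, r_inf, kappa):
        a = decrement_curve(30, r_inf, kappa)
        assert np.all(a <= 1.0 + 1e-12) and np.all(a >= r_inf - 1e-12)
        assert np.all(np.diff(a) <= 1e-12)


class TestTwitch:
    def test_noise_free_peak_equals_amplitude(self, clean_twitch):
        assert clean_twitch.torque_Nm.max() == pytest.approx(2.0, abs=1e-12)
        t_peak = clean_twitch.time_s[np.argmax(clean_twitch.torque_Nm)]
        assert t_peak == pytest.approx(0.05 + 5.0 * 0.012, abs=1e-3)

    def test_baseline_before_stim(self, clean_twitch):
        pre = clean_twitch.torque_Nm[clean_twitch.time_s < 0.05]
        assert np.all(pre == 0.0)

    def test_seed_determinism(self):
        a = simulate_twitch(TwitchParams(noise_sd_Nm=0.01, seed=3))
        b = simulate_twitch(TwitchParams(noise_sd_Nm=0.01, seed=3))
        c = simulate_twitch(TwitchParams(noise_sd_Nm=0.01, seed=4))
        np.testing.assert_array_equal(a.torque_Nm, b.torque_Nm)
        assert not np.array_equal(a.torque_Nm, c.torque_Nm)

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            TwitchParams(amplitude_Nm=-1.0)
        with pytest.raises(ValidationError):
            TwitchParams(tau_rise_s=0.0)
        with pytest.raises(ValidationError):
            TwitchParams(slow_fraction=1.5)


class TestTetanus:
    def test_end_stim_value_closed_form(self, clean_tetanus):
        # plateau * (1 - exp(-stim_duration / tau_rise)), default 8 * (1 - e^-20)
        want = 8.0 * (1.0 - np.exp(-1.0 / 0.05))
        assert clean_tetanus.extra["true_end_stim_Nm"] == pytest.approx(want)
        at_end = np.interp(clean_tetanus.stim_end_s, clean_tetanus.time_s,
                           clean_tetanus.torque_Nm)
        assert at_end == pytest.approx(want, abs=1e-9)

    def test_drift_raises_end_value_linearly(self):
        tr = simulate_tetanus(TetanusParams(drift_Nm_per_s=0.5))
        base = simulate_tetanus(TetanusParams())
        d = np.interp(tr.stim_end_s, tr.time_s, tr.torque_Nm) - \
            np.interp(base.stim_end_s, base.time_s, base.torque_Nm)
        assert d == pytest.approx(0.5 * 1.0, abs=1e-9)

    def test_relaxation_decays(self, clean_tetanus):
        after = clean_tetanus.torque_Nm[clean_tetanus.time_s > clean_tetanus.stim_end_s]
        assert np.all(np.diff(after) <= 1e-12)


class TestECDProtocol:
    def test_thirty_contractions_with_layout(self, ecd_protocol):
        traces, scales = ecd_protocol
        assert len(traces) == 30 and len(scales) == 30
        starts = np.array([tr.extra["protocol_start_s"] for tr in traces])
        gaps = np.diff(starts) - traces[0].duration_s
        # 4 s within a set of ten, 240 s between sets
        expected = [240.0 if (k % 10 == 0) else 4.0 for k in range(1, 30)]
        np.testing.assert_allclose(gaps, expected, atol=1e-9)

    def test_plateau_scaling_matches_truth(self, ecd_protocol):
        traces, scales = ecd_protocol
        for tr, a in zip(traces, scales):
            sel = (tr.time_s >= 0.54) & (tr.time_s < 0.55)  # just before rotation
            assert tr.torque_Nm[sel].mean() == pytest.approx(
                8.0 * a * (1 - np.exp(-0.49 / 0.05)), rel=1e-3)

    def test_transient_confined_to_rotation_window(self, ecd_protocol):
        traces, _ = ecd_protocol
        tr = traces[0]
        rot = tr.extra["rotation_onset_s"]
        inside = (tr.time_s > rot) & (tr.time_s < rot + 0.2)
        before = (tr.time_s >= rot - 0.05) & (tr.time_s <= rot)
        assert tr.torque_Nm[inside].max() > 1.4 * tr.torque_Nm[before].max()

    def test_rotation_must_end_within_stimulation(self):
        with pytest.raises(ValidationError, match="rotation"):
            ECDProtocolParams(tetanus=TetanusParams(stim_duration_s=0.6),
                              rotation_delay_s=0.5, rotation_duration_s=0.2)


class TestCohort:
    def test_truth_within_bounds_and_deterministic(self):
        spec = CohortSpec(n_subjects=20, seed=9)
        _, truth = simulate_cohort(spec)
        assert len(truth) == 20
        assert truth["true_decrement_pct"].between(0, 100).all()
        _, truth2 = simulate_cohort(spec)
        np.testing.assert_array_equal(truth["true_decrement_pct"],
                                      truth2["true_decrement_pct"])

    def test_moment_matching_removes_truncation_bias(self):
        # at 17 +/- 11 truncation to [0, 100] biases the naive mean upward;
        # the solved location restores the target truncated mean exactly
        from scipy import stats

        from musclephys.sim_traces import _truncnorm_loc
        loc = _truncnorm_loc(17.0, 11.0)
        a, b = (0 - loc) / 11.0, (100 - loc) / 11.0
        assert stats.truncnorm.mean(a, b, loc=loc, scale=11.0) == pytest.approx(
            17.0, abs=1e-6)
        naive = stats.truncnorm.mean(-17 / 11, 83 / 11, loc=17, scale=11)
        assert naive > 17.5  # the bias being removed

    def test_zero_sd_gives_constant_decrement(self):
        spec = CohortSpec(decrement_mean_pct=40.0, decrement_sd_pct=0.0,
                          n_subjects=3, noise_sd_Nm=0.0, seed=1)
        _, truth = simulate_cohort(spec)
        assert (truth["true_decrement_pct"] == 40.0).all()
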