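import numpy as np
import pytest

from musclephys import (TetanusParams, TwitchParams, ValidationError,
                        analyze_trace, baseline_correct, contraction_features,
                        qc_trace, relaxation_features, simulate_tetanus,
                        simulate_twitch, twitch_tetanus_ratio)


def _corrected(trace):
    return baseline_correct(trace)


class TestBaseline:
    def test_offset_removed(self):
        tr = simulate_twitch(TwitchParams(baseline_Nm=0.7))
        out = baseline_correct(tr)
        assert out.extra["baseline_Nm"] == pytest.approx(0.7, abs=1e-9)
        assert out.torque_Nm[0] == pytest.approx(0.0, abs=1e-9)

    def test_window_must_fit(self, clean_twitch):
        with pytest.raises(ValidationError, match="window"):
            baseline_correct(clean_twitch, window_s=0.2)


class TestContraction:
    def test_twitch_peak_and_deciles(self, clean_twitch):
        res = contraction_features(_corrected(clean_twitch))
        assert res.peak_torque_Nm == pytest.approx(2.0, abs=1e-9)
        # time to 100% = peak time relative to onset = rise_span * tau_rise
        assert res.contraction_times_s[1.0] == pytest.approx(0.06, abs=1e-3)
        times = [res.contraction_times_s[f] for f in sorted(res.contraction_times_s)]
        assert np.all(np.diff(times) > 0)  # decile monotonicity

    def test_twitch_t50_closed_form(self, clean_twitch):
        # solve (1 - e^(-x/tau)) / (1 - e^(-5)) = 0.5
        res = contraction_features(_corrected(clean_twitch))
        want = -0.012 * np.log(1.0 - 0.5 * (1.0 - np.exp(-5.0)))
        assert res.contraction_times_s[0.5] == pytest.approx(want, abs=1e-3)

    def test_tetanus_reference_is_end_stim(self, clean_tetanus):
        res = contraction_features(_corrected(clean_tetanus))
        assert res.reference_torque_Nm == pytest.approx(
            8.0 * (1 - np.exp(-20.0)), abs=1e-6)
        assert 0.95 in res.contraction_times_s and 1.0 not in res.contraction_times_s
        # t95: plateau(1 - e^(-t/0.05)) = 0.95 * end value -> ~ -0.05 ln(0.05)
        assert res.contraction_times_s[0.95] == pytest.approx(
            -0.05 * np.log(1 - 0.95 * (1 - np.exp(-20.0))), abs=1e-3)

    def test_forces_normalised_by_lever_and_weight(self, clean_tetanus):
        res = contraction_features(_corrected(clean_tetanus))
        assert res.absolute_force_N == pytest.approx(res.reference_torque_Nm / 0.11)
        assert res.relative_force_N_per_kg == pytest.approx(
            res.absolute_force_N / 12.0)


class TestRelaxation:
    def test_twitch_relax95_closed_form(self, clean_twitch):
        res = relaxation_features(_corrected(clean_twitch))
        # biexp 0.9 e^(-t/0.05) + 0.1 e^(-t/0.8) = 0.05 -> solve numerically
        from scipy.optimize import brentq
        want = brentq(lambda x: 0.9 * np.exp(-x / 0.05)
                      + 0.1 * np.exp(-x / 0.8) - 0.05, 1e-6, 5.0)
        assert res.relaxation_times_s[0.95] == pytest.approx(want, abs=1e-3)

    def test_unreached_fraction_is_nan_and_flagged(self):
        tr = simulate_twitch(TwitchParams(slow_fraction=0.5, tau_slow_relax_s=10.0,
                                          post_window_s=0.3))
        res = relaxation_features(_corrected(tr))
        assert 0.95 in res.relaxation_unreached
        assert np.isnan(res.relaxation_times_s[0.95])
        assert res.qc_status == "pass"  # flagged, not rejected

    def test_relaxation_monotone(self, clean_tetanus):
        res = relaxation_features(_corrected(clean_tetanus))
        reached = [v for f, v in sorted(res.relaxation_times_s.items())
                   if np.isfinite(v)]
        assert np.all(np.diff(reached) > 0)


class TestQC:
    def test_clean_noisy_traces_pass(self, noisy_twitch, noisy_tetanus, config):
        for tr in (noisy_twitch, noisy_tetanus):
            status, reasons = qc_trace(_corrected(tr), config)
            assert status == "pass", reasons

    def test_low_snr_rejected(self, config):
        tr = simulate_twitch(TwitchParams(amplitude_Nm=0.04, noise_sd_Nm=0.05, seed=1))
        status, reasons = qc_trace(_corrected(tr), config)
        assert status == "reject" and "low_snr" in reasons

    def test_negative_deflection_rejected(self, clean_twitch, config):
        y = clean_twitch.torque_Nm.copy()
        y[200:260] -= 1.0  # antagonist co-stimulation artefact
        tr = clean_twitch.copy_with(torque_Nm=y)
        status, reasons = qc_trace(tr, config)
        assert status == "reject" and "negative_deflection" in reasons

    def test_multi_peaked_twitch_rejected(self, clean_twitch, config):
        y = clean_twitch.torque_Nm.copy()
        for start in (300, 450, 600):  # three prominent extra bumps
            y[start:start + 40] += 1.5
        tr = clean_twitch.copy_with(torque_Nm=y)
        status, reasons = qc_trace(tr, config)
        assert status == "reject" and "multi_peaked" in reasons

    def test_plateau_collapse_rejected(self, clean_tetanus, config):
        y = clean_tetanus.torque_Nm.copy()
        during = (clean_tetanus.time_s > 0.5) & (clean_tetanus.time_s < 0.7)
        y[during] *= 0.3  # electrode slips mid-stimulation
        tr = clean_tetanus.copy_with(torque_Nm=y)
        status, reasons = qc_trace(tr, config)
        assert status == "reject" and "plateau_collapse" in reasons


class TestAnalyzeAndRatio:
    def test_analyze_trace_end_to_end(self, noisy_tetanus, config):
        res = analyze_trace(noisy_tetanus, config)
        assert res.qc_status == "pass"
        assert res.reference_torque_Nm == pytest.approx(8.0, abs=0.1)

    def test_twitch_tetanus_ratio(self, clean_twitch, clean_tetanus, config):
        tw = analyze_trace(clean_twitch, config)
        te = analyze_trace(clean_tetanus, config)
        assert twitch_tetanus_ratio(tw, te) == pytest.approx(
            2.0 / (8.0 * (1 - np.exp(-20.0))), abs=1e-6)

    def test_ratio_requires_passing_traces(self, clean_twitch, clean_tetanus, config):
        tw = analyze_trace(clean_twitch, config)
        te = analyze_trace(clean_tetanus, config)
        tw.qc_status = "reject"
        with pytest.raises(ValidationError, match="QC"):
            twitch_tetanus_ratio(tw, te)
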