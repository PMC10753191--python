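import numpy as np
import pytest

from musclephys import (ECDProtocolParams, RegressionResult, TetanusParams,
                        ValidationError, decrement_curve, ecd_series,
                        linear_fit, plateau_torque, protocol_qc,
                        simulate_ecd_protocol)


class TestPlateauTorque:
    def test_noise_free_read_matches_model(self, ecd_protocol):
        traces, scales = ecd_protocol
        for tr, a in zip(traces[:5], scales[:5]):
            want = 8.0 * a * (1 - np.exp(-(0.55 - 0.06) / 0.05))  # ~settled
            got = plateau_torque(tr)
            assert got == pytest.approx(8.0 * a, rel=2e-4) or \
                got == pytest.approx(want, rel=1e-3)

    def test_window_zero_degenerates_to_single_sample(self, ecd_protocol):
        tr = ecd_protocol[0][0]
        single = plateau_torque(tr, window_s=0.0)
        assert single == pytest.approx(plateau_torque(tr), rel=1e-3)

    def test_window_before_stim_onset_rejected(self, ecd_protocol):
        tr = ecd_protocol[0][0]
        with pytest.raises(ValidationError, match="before stimulus"):
            plateau_torque(tr, window_s=0.8)


class TestProtocolQC:
    def test_clean_protocol_accepted(self, noisy_ecd_protocol, config):
        traces, _ = noisy_ecd_protocol
        accepted, reasons, ok = protocol_qc(traces, config)
        assert ok and all(accepted) and not reasons

    def test_flat_contraction_rejected(self, noisy_ecd_protocol, config):
        traces, _ = noisy_ecd_protocol
        dead = traces[4].copy_with(
            torque_Nm=np.random.default_rng(0).normal(0, 0.02, traces[4].time_s.size))
        traces = traces[:4] + [dead] + traces[5:]
        accepted, reasons, ok = protocol_qc(traces, config)
        assert not accepted[4] and ok  # one bad of 30 still leaves the protocol ok
        assert 5 in reasons

    def test_protocol_fails_below_min_fraction(self, noisy_ecd_protocol, config):
        traces, _ = noisy_ecd_protocol
        rng = np.random.default_rng(0)
        bad = [tr.copy_with(torque_Nm=rng.normal(0, 0.02, tr.time_s.size))
               for tr in traces[:8]]
        accepted, _, ok = protocol_qc(bad + traces[8:], config)
        assert sum(accepted) == 22 and not ok  # 22/30 < 0.8


class TestECDSeries:
    def test_zero_noise_decrement_closed_form(self, ecd_protocol, config):
        traces, _ = ecd_protocol
        res = ecd_series(traces, config)
        a = decrement_curve(30, 0.8, 5.0)
        want = 100.0 * (1.0 - a[-1] / a[0])
        assert res.n_detected == 30
        assert res.final_decrement_pct == pytest.approx(want, abs=0.05)
        assert res.normalised_series_pct[0] == pytest.approx(100.0, abs=0.05)

    def test_series_normalised_to_max(self, noisy_ecd_protocol, config):
        res = ecd_series(noisy_ecd_protocol[0], config)
        assert np.nanmax(res.normalised_series_pct) == pytest.approx(100.0)
        assert res.max_abs_force_N == pytest.approx(res.max_torque_Nm / 0.11)

    def test_rejected_contraction_leaves_nan_gap(self, noisy_ecd_protocol, config):
        traces, _ = noisy_ecd_protocol
        rng = np.random.default_rng(3)
        traces = list(traces)
        traces[9] = traces[9].copy_with(
            torque_Nm=rng.normal(0, 0.02, traces[9].time_s.size))
        res = ecd_series(traces, config)
        assert np.isnan(res.plateau_torques_Nm[9])
        assert res.n_detected == 29
        assert not res.final_position_flagged

    def test_missing_final_position_flagged(self, noisy_ecd_protocol, config):
        traces, _ = noisy_ecd_protocol
        res = ecd_series(list(traces[:-1]), config)
        assert res.final_position == 29
        # n_positions pins the protocol length even if the last trace is absent
        res30 = ecd_series(list(traces[:-1]), config, n_positions=30)
        assert res30.final_position_flagged and res30.final_position == 29

    def test_empty_input_rejected(self, config):
        with pytest.raises(ValidationError, match="no traces"):
            ecd_series([], config)

    def test_eccentric_spike_does_not_set_max(self, ecd_protocol, config):
        # the transient peaks at ~1.6x plateau; T_max must come from plateaus
        res = ecd_series(ecd_protocol[0], config)
        assert res.max_torque_Nm < 8.2


class TestLinearFit:
    def test_hand_computed_example(self):
        # x=(1,2,3), y=(1,2,4): slope 1.5, intercept -2/3, R^2 = 27/28
        res = linear_fit([1, 2, 3], [1, 2, 4])
        assert isinstance(res, RegressionResult)
        assert res.slope == pytest.approx(1.5)
        assert res.intercept == pytest.approx(-2.0 / 3.0)
        assert res.r_squared == pytest.approx(27.0 / 28.0)

    def test_perfect_fit(self):
        res = linear_fit([0, 1, 2, 3], [5, 7, 9, 11])
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 2.0 * x + rng.normal(size=40)
        from scipy import stats
        ref = stats.linregress(x, y)
        res = linear_fit(x, y)
        assert res.slope == pytest.approx(ref.slope)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            linear_fit([1, 1, 1], [1, 2, 3])
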