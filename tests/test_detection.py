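"""Event conditions, floating thresholds, FSM sequencing, full pipeline."""

import numpy as np
import pytest

from gaitfes.detection import (
    DetectorConfig,
    DetectorState,
    adapt_factor,
    detect_heel_off,
    detect_initial_contact,
    detect_toe_off,
    jerk_series,
    process_stream,
    step_fsm,
    update_floating_threshold,
)
from gaitfes.imu_io import GRAVITY, EventKind, ImuStream
from gaitfes.simulator import GaitSimConfig, simulate_gait


def _stream_with_az(az, fs=500.0):
    n = len(az)
    acc = np.zeros((n, 3))
    acc[:, 2] = az
    return ImuStream(t=np.arange(n) / fs, acc=acc, gyr=np.zeros((n, 3)), fs=fs)


class TestJerkSeries:
    def test_constant_acceleration_zero_jerk(self):
        jerk = jerk_series(_stream_with_az(np.full(100, GRAVITY)))
        np.testing.assert_allclose(jerk, 0.0)

    def test_step_yields_delta_times_fs(self):
        az = np.full(100, GRAVITY)
        az[50:] += 2.0
        jerk = jerk_series(_stream_with_az(az))
        assert jerk[50] == pytest.approx(1000.0)
        assert np.count_nonzero(jerk) == 1

    def test_simulator_pulse_peak_matches_analytic(self, clean_sim):
        stream, truth = clean_sim
        jerk = jerk_series(stream)
        t_ic = truth.times(EventKind.IC)[3]
        window = (stream.t >= t_ic) & (stream.t <= t_ic + 0.04)
        # configured peak jerk of the heel-strike pulse is 3000 m/s^3
        assert np.abs(jerk[window]).max() == pytest.approx(3000.0, rel=0.05)

    def test_smoothing_reduces_peak(self, clean_sim):
        stream, _ = clean_sim
        raw = np.abs(jerk_series(stream)).max()
        smooth = np.abs(jerk_series(stream, smooth_width=5)).max()
        assert smooth < raw


class TestFloatingThreshold:
    def test_alpha_zero_freezes_band(self):
        cfg = DetectorConfig(float_alpha=0.0)
        assert update_floating_threshold((500.0, 6000.0), 1000.0, cfg) == (500.0, 6000.0)

    def test_alpha_one_full_replacement(self):
        cfg = DetectorConfig(float_alpha=1.0, float_gamma_lo=0.5, float_gamma_hi=1.5)
        assert update_floating_threshold((500.0, 6000.0), 1000.0, cfg) == (500.0, 1500.0)

    def test_geometric_convergence_to_fixed_point(self):
        # closed-form recurrence: err_k = err_0 * (1 - alpha)^k toward gamma*peak
        cfg = DetectorConfig(float_alpha=0.3)
        band = (500.0, 6000.0)
        peak = 1000.0
        target_hi = cfg.float_gamma_hi * peak
        err0 = abs(band[1] - target_hi)
        for k in range(1, 21):
            band = update_floating_threshold(band, peak, cfg)
            expected = err0 * (1 - cfg.float_alpha) ** k
            assert abs(band[1] - target_hi) == pytest.approx(expected, rel=1e-9)
        assert band[0] == pytest.approx(cfg.float_gamma_lo * peak, rel=1e-3)

    def test_inverted_band_rejected(self):
        cfg = DetectorConfig(float_alpha=1.0, float_gamma_lo=0.5, float_gamma_hi=1.5)
        with pytest.raises(ValueError):
            update_floating_threshold((500.0, 6000.0), -1.0, cfg)


class TestAdaptation:
    def test_identity_at_reference(self):
        cfg = DetectorConfig(omega_ref=300.0)
        assert adapt_factor(300.0, cfg) == pytest.approx(1.0)

    def test_double_peak_doubles_factor(self):
        cfg = DetectorConfig(omega_ref=300.0, adapt_min=0.5, adapt_max=2.0)
        f = adapt_factor(600.0, cfg)
        assert f == pytest.approx(2.0)
        # thresholds scale by f, temporal gates by 1/f
        assert cfg.omega_threshold_high * f == pytest.approx(200.0)
        assert cfg.min_swing_time / f == pytest.approx(0.125)

    def test_clamped_at_extremes(self):
        cfg = DetectorConfig(omega_ref=300.0, adapt_min=0.5, adapt_max=2.0)
        assert adapt_factor(3000.0, cfg) == 2.0
        assert adapt_factor(1.0, cfg) == 0.5

    def test_faster_never_lengthens_swing_gate(self):
        cfg = DetectorConfig()
        gates = [cfg.min_swing_time / adapt_factor(w, cfg)
                 for w in np.linspace(50, 3000, 40)]
        assert all(b <= a + 1e-12 for a, b in zip(gates, gates[1:]))


class TestFsm:
    def test_out_of_sequence_discarded(self):
        state, accepted = step_fsm("AwaitFC", EventKind.HO)
        assert not accepted and state == "AwaitFC"

    def test_accepted_transition(self):
        state, accepted = step_fsm("AwaitIC", EventKind.IC)
        assert accepted and state == "AwaitFC"

    def test_full_cycle_order(self):
        state = "AwaitIC"
        for kind in (EventKind.IC, EventKind.FC, EventKind.HO, EventKind.TO):
            state, accepted = step_fsm(state, kind)
            assert accepted
        assert state == "AwaitIC"

    def test_accepted_stream_is_regular(self, clean_detection):
        result, _ = clean_detection
        kinds = "".join(e.kind.value[0] for e in result.events)  # I, F, H, T
        # the accepted sequence must be (IC FC HO TO)* with a possibly open tail
        full = "IFHT"
        assert all(kinds[i:i + 4] == full[: len(kinds[i:i + 4])]
                   for i in range(0, len(kinds), 4))


class TestConditionScanners:
    def _ic_inputs(self, spike_at=100, n=200, amp=1000.0, fs=500.0):
        jerk = np.zeros(n)
        jerk[spike_at] = amp
        return jerk, np.zeros(n), np.arange(n) / fs

    def test_ic_fires_on_in_band_spike(self):
        cfg = DetectorConfig()
        jerk, gy, t = self._ic_inputs(spike_at=150)  # 0.3 s > min swing gate
        state = DetectorState(band=(500.0, 6000.0), last_to_time=0.0)
        assert detect_initial_contact(jerk, gy, t, state, cfg) == 150

    def test_ic_blocked_before_min_swing(self):
        cfg = DetectorConfig(min_swing_time=0.25)
        jerk, gy, t = self._ic_inputs(spike_at=100)  # 0.2 s after the TO
        state = DetectorState(band=(500.0, 6000.0), last_to_time=0.0)
        assert detect_initial_contact(jerk, gy, t, state, cfg) is None

    def test_ic_out_of_band_spike_ignored(self):
        cfg = DetectorConfig()
        jerk, gy, t = self._ic_inputs(amp=10000.0)  # above jerk_max
        state = DetectorState(band=(500.0, 6000.0), last_to_time=0.0)
        assert detect_initial_contact(jerk, gy, t, state, cfg) is None

    def test_lyra_band_discards_rotating_spike(self):
        cfg = DetectorConfig.for_profile("lyra")
        jerk, gy, t = self._ic_inputs(amp=1000.0)
        gy = np.full_like(gy, 200.0)  # foot still rotating
        state = DetectorState(band=(200.0, 3000.0), last_to_time=0.0)
        assert detect_initial_contact(jerk, gy, t, state, cfg) is None
        gy[:] = 0.0
        assert detect_initial_contact(jerk, gy, t, state, cfg) == 100

    def test_heel_off_quiet_foot_no_event(self):
        cfg = DetectorConfig()
        n = 200
        acc = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        state = DetectorState(fsm="AwaitHO", ic_time=0.0)
        assert detect_heel_off(acc, np.zeros(n), np.arange(n) / 500, state, cfg) is None

    def test_heel_off_fires_at_omega_crossing(self):
        cfg = DetectorConfig(omega_heeloff_thresh_y=30.0)
        n = 300
        t = np.arange(n) / 500.0
        gy = np.linspace(0.0, 60.0, n)  # ramp crosses 30 at midpoint
        acc = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        state = DetectorState(fsm="AwaitHO", ic_time=0.0)
        idx = detect_heel_off(acc, gy, t, state, cfg)
        expected = np.argmax(np.abs(gy) > 30.0)
        assert idx == expected

    def test_heel_off_vetoed_by_loud_acceleration(self):
        cfg = DetectorConfig(a_heeloff_thresh_x=2.0)
        n = 300
        t = np.arange(n) / 500.0
        gy = np.linspace(0.0, 60.0, n)
        acc = np.tile([3.0, 0.0, GRAVITY], (n, 1))  # |a_x| above threshold
        state = DetectorState(fsm="AwaitHO", ic_time=0.0)
        assert detect_heel_off(acc, gy, t, state, cfg) is None

    def _triangle(self, peak, n_up=100, n_down=100):
        return np.concatenate([np.linspace(0.0, peak, n_up),
                               np.linspace(peak, 0.0, n_down)])

    def test_toe_off_fires_at_low_crossing(self):
        cfg = DetectorConfig(omega_threshold_high=100.0, omega_threshold_low=50.0, k_to=10)
        gy = self._triangle(300.0)
        t = np.arange(len(gy)) / 500.0
        state = DetectorState(fsm="AwaitTO")
        idx = detect_toe_off(gy, t, state, cfg)
        # first strictly-below-50 sample on the falling edge
        falling = np.arange(100, 200)
        expected = falling[np.argmax(gy[falling] < 50.0)]
        assert idx == expected
        assert state.omega_max_last_to == pytest.approx(300.0)

    def test_toe_off_requires_high_threshold(self):
        cfg = DetectorConfig()
        gy = self._triangle(80.0)  # never exceeds 100
        state = DetectorState(fsm="AwaitTO")
        assert detect_toe_off(gy, np.arange(len(gy)) / 500.0, state, cfg) is None

    def test_toe_off_plateau_resets_decrease_run(self):
        cfg = DetectorConfig(k_to=10)
        up = np.linspace(0.0, 300.0, 50)
        # 5 decreasing samples, then a plateau, then a clean decrease
        blip = np.concatenate([np.linspace(300.0, 290.0, 5), np.full(8, 290.0)])
        down = np.linspace(290.0, 0.0, 100)
        gy = np.concatenate([up, blip, down])
        t = np.arange(len(gy)) / 500.0
        state = DetectorState(fsm="AwaitTO")
        idx = detect_toe_off(gy, t, state, cfg)
        # must fire during the final clean decrease, after the plateau
        assert idx is not None and idx >= 50 + len(blip)
        assert gy[idx] < cfg.omega_threshold_low

    def test_scanners_require_matching_state(self):
        cfg = DetectorConfig()
        state = DetectorState(fsm="AwaitTO")
        assert detect_initial_contact([1000.0], [0.0], [0.0], state, cfg) is None
        assert detect_heel_off(np.zeros((1, 3)), [0.0], [0.0],
                               DetectorState(fsm="AwaitIC"), cfg) is None


class TestProcessStream:
    def test_clean_run_detects_every_cycle(self, clean_detection, clean_sim):
        result, truth = clean_detection
        assert len(result.valid_cycles) == 10
        det_ics = sorted(c.events[0].t for c in result.valid_cycles)
        np.testing.assert_allclose(det_ics, truth.times(EventKind.IC), atol=0.020)

    def test_cycle_event_order(self, clean_detection):
        result, _ = clean_detection
        for cycle in result.valid_cycles:
            kinds = [e.kind for e in cycle.events]
            assert kinds == [EventKind.IC, EventKind.FC, EventKind.HO,
                             EventKind.TO, EventKind.IC]
            times = [e.t for e in cycle.events]
            assert times == sorted(times) and len(set(times)) == 5

    def test_pure_rest_stream_yields_nothing(self):
        cfg = GaitSimConfig(n_cycles=0, rest_lead=4.0, noise_sd_acc=0.0,
                            noise_sd_gyr=0.0, seed=3)
        stream, _ = simulate_gait(cfg)
        result = process_stream(stream, DetectorConfig())
        assert result.events == [] and result.cycles == []

    def test_dropout_invalidates_spanning_cycle_only(self):
        cfg = GaitSimConfig(n_cycles=10, cycle_duration=1.2, noise_sd_acc=0.0,
                            noise_sd_gyr=0.0, seed=5, dropout=(6.0, 5.0))
        stream, _ = simulate_gait(cfg)
        result = process_stream(stream, DetectorConfig())
        invalid = [c for c in result.cycles if not c.valid]
        assert len(invalid) >= 1
        assert all(c.start <= 6.0 <= c.end or c.start <= 11.0 <= c.end
                   for c in invalid)
        # cycles after the gap recover
        assert any(c.valid and c.start > 11.0 for c in result.cycles)

    def test_noisy_run_still_complete(self, noisy_sim):
        stream, truth = noisy_sim
        result = process_stream(stream, DetectorConfig())
        assert len(result.valid_cycles) == 10

    def test_debug_log_records_fsm(self, clean_sim):
        stream, _ = clean_sim
        result = process_stream(stream.segment(0, 2000), DetectorConfig(), debug=True)
        assert result.log and {"index", "t", "fsm", "band_lo"} <= set(result.log[0])


class TestConfig:
    def test_profile_presets(self):
        lyra = DetectorConfig.for_profile("lyra")
        loko = DetectorConfig.for_profile("lokomat")
        assert lyra.ic_band_enabled and not loko.ic_band_enabled
        assert lyra.jerk_max < loko.jerk_max

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(jerk_min=1000.0, jerk_max=500.0)
        with pytest.raises(ValueError):
            DetectorConfig(omega_threshold_high=40.0, omega_threshold_low=50.0)

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig.for_profile("exo9000")
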