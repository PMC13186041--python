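"""Single-spore integration, event detection and outcome classification tests."""

import numpy as np
import pytest

from sporegerm import (
    PulseProtocol,
    classify_outcome,
    detect_threshold_crossing,
    integrate_spore,
    release_interval,
)

from .oracles import first_crossing, rk4_integrate


@pytest.fixture(scope="module")
def rk4_1500(fig3):
    return rk4_integrate(1500.0, fig3.params, fig3.protocol, dt=0.001)


class TestIntegrateSpore:
    def test_no_germination_below_950(self, fig3):
        traj = integrate_spore(900.0, fig3.params, fig3.protocol)
        assert traj.t_open is None
        assert traj.Co.max() < fig3.params.germination_threshold

    def test_first_pulse_germination_at_1500(self, fig3):
        traj = integrate_spore(1500.0, fig3.params, fig3.protocol)
        assert traj.t_open is not None and traj.t_open < 30.0

    def test_zero_stimulus_stays_dormant(self, fig3):
        proto = PulseProtocol(pulses=(), horizon=60.0)
        traj = integrate_spore(1800.0, fig3.params, proto)
        assert traj.t_open is None
        assert np.all(traj.Co == 0.0)
        assert np.all(traj.Ra == 0.0)

    def test_negative_ri0_rejected(self, fig3):
        with pytest.raises(ValueError):
            integrate_spore(-1.0, fig3.params, fig3.protocol)

    @pytest.mark.parametrize("ri0", [800.0, 1200.0, 1500.0])
    def test_conservation_along_trajectory(self, fig3, ri0):
        traj = integrate_spore(ri0, fig3.params, fig3.protocol)
        rec_err, chan_err = traj.conservation_error()
        assert rec_err <= 1e-6 * ri0
        assert chan_err <= 1e-6 * fig3.params.c_total


class TestOracleAgreement:
    def test_t_open_matches_rk4(self, fig3, rk4_1500):
        ts, ys = rk4_1500
        t_oracle = first_crossing(ts, ys[:, 4], 50.0)
        traj = integrate_spore(1500.0, fig3.params, fig3.protocol)
        assert traj.t_open == pytest.approx(t_oracle, abs=0.05)

    def test_supnorm_against_rk4_nongerminating(self, fig3):
        ts, ys = rk4_integrate(800.0, fig3.params, fig3.protocol, dt=0.001)
        traj = integrate_spore(800.0, fig3.params, fig3.protocol, grid_dt=0.05)
        idx = np.searchsorted(ts, traj.times - 5e-4)
        assert np.abs(ts[idx] - traj.times).max() < 1e-9
        assert np.abs(ys[idx] - traj.states).max() <= 0.1

    def test_supnorm_against_rk4_germinating(self, fig3, rk4_1500):
        # The autocatalytic ramp moves ~2e4 molecules/min, so sup-norm
        # agreement demands micro-minute phase agreement; tight adaptive
        # tolerances are needed to beat the oracle's own phase error.
        ts, ys = rk4_1500
        traj = integrate_spore(
            1500.0, fig3.params, fig3.protocol, grid_dt=0.05, rtol=1e-10, atol=1e-12
        )
        idx = np.searchsorted(ts, traj.times - 5e-4)
        assert np.abs(ts[idx] - traj.times).max() < 1e-9
        assert np.abs(ys[idx] - traj.states).max() <= 0.1

    def test_release_interval_matches_rk4(self, fig3, rk4_1500):
        ts, ys = rk4_1500
        t50 = first_crossing(ts, ys[:, 4], 50.0)
        t95 = first_crossing(ts, ys[:, 4], 0.95 * fig3.params.c_total)
        traj = integrate_spore(1500.0, fig3.params, fig3.protocol)
        assert release_interval(traj) == pytest.approx(t95 - t50, abs=0.1)


class TestDetectThresholdCrossing:
    def test_flat_trajectory_has_no_crossing(self):
        assert detect_threshold_crossing(np.arange(10.0), np.zeros(10), 50.0) is None

    def test_crossing_exactly_on_grid_point(self):
        times = np.array([0.0, 1.0, 2.0, 3.0])
        co = np.array([0.0, 25.0, 50.0, 75.0])
        assert detect_threshold_crossing(times, co, 50.0) == 2.0

    def test_linear_interpolation_between_grid_points(self):
        times = np.array([0.0, 1.0])
        co = np.array([0.0, 100.0])
        assert detect_threshold_crossing(times, co, 50.0) == pytest.approx(0.5)

    def test_grid_detection_agrees_with_event_location(self, fig3):
        # a dense grid is required: the ramp is convex at the crossing, so
        # linear interpolation needs ~0.01-min spacing for 0.01-min accuracy
        traj = integrate_spore(1500.0, fig3.params, fig3.protocol, grid_dt=0.01)
        t_grid = detect_threshold_crossing(traj.times, traj.Co, 50.0)
        assert t_grid == pytest.approx(traj.t_open, abs=0.01)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_threshold_crossing(np.arange(3.0), np.ones(3), 0.0)


class TestClassifyOutcome:
    def test_absent_crossing_is_no_germination(self, fig1):
        out = classify_outcome(None, fig1.protocol)
        assert out.outcome == "no_germination"
        assert out.t_open is None and out.t_lag is None

    def test_crossing_before_second_pulse_is_first_pulse(self, fig1):
        out = classify_outcome(12.0, fig1.protocol)
        assert out.outcome == "first_pulse"
        assert out.t_lag == pytest.approx(12.0 - 5.0)

    def test_crossing_after_second_pulse_start_is_second_pulse(self, fig1):
        out = classify_outcome(40.0, fig1.protocol)
        assert out.outcome == "second_pulse"
        assert out.t_lag == pytest.approx(40.0 - 35.0)

    def test_single_pulse_protocol_only_first_class(self):
        proto = PulseProtocol(pulses=((0.0, 5.0, 3.5),), horizon=60.0)
        assert classify_outcome(20.0, proto).outcome == "first_pulse"

    def test_empty_protocol_rejected(self):
        proto = PulseProtocol(pulses=(), horizon=60.0)
        with pytest.raises(ValueError):
            classify_outcome(10.0, proto)


class TestReleaseInterval:
    def test_absent_for_non_germinating_spore(self, fig3):
        traj = integrate_spore(800.0, fig3.params, fig3.protocol)
        assert release_interval(traj) is None

    def test_release_interval_roughly_constant_across_spores(self, fig3):
        vals = [
            release_interval(integrate_spore(ri, fig3.params, fig3.protocol))
            for ri in (1500.0, 1700.0)
        ]
        assert all(v is not None for v in vals)
        assert abs(vals[0] - vals[1]) / vals[0] <= 0.2


@pytest.fixture(scope="module")
def alt_params(fig1):
    return fig1.params.with_overrides(k_minus1=225e-3, k2=45e-7)


class TestMemoryWithoutReceptorPersistence:
    """Memory can live in the channel subsystem alone: with faster GR
    deactivation (k_minus1 = 225e-3) and stronger channel activation
    (k2 = 45e-7), the active-GR pool collapses to baseline between pulses
    yet mid-range spores still germinate only on the second pulse."""

    def test_ra_returns_to_baseline_before_second_pulse(self, alt_params, fig1):
        traj = integrate_spore(1150.0, alt_params, fig1.protocol)
        pre_second = traj.times < 30.0
        ra_peak = traj.Ra[traj.times <= 5.0].max()
        ra_before_second = traj.Ra[pre_second][-1]
        assert ra_before_second < 0.01 * ra_peak

    def test_memory_band_persists(self, alt_params, fig1):
        traj = integrate_spore(1150.0, alt_params, fig1.protocol)
        out = classify_outcome(traj.t_open, fig1.protocol)
        assert out.outcome == "second_pulse"
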