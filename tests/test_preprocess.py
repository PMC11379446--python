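"""Filtering, bad-channel screening, segmentation and endurance time."""

import numpy as np
import pytest

from emgspace import (
    EMGRecording,
    GridLayout,
    TorqueTrace,
    detect_bad_channels,
    endurance_time,
    filter_emg,
    filter_torque,
    segment_contraction,
    simulate_torque,
    torque_segment_stats,
)
from emgspace.core_types import AnalysisRegion
from emgspace.preprocess import FilterSpec, SegmentationError
from emgspace.simulate import SimulationConfig

FS = 2048.0


def _rec(signals, layout=None):
    layout = layout or GridLayout(n_rows=2, n_cols=2, missing=frozenset())
    return EMGRecording(signals=signals, fs=FS, layout=layout)


def _tone(freq, n=int(8 * FS), amp=1.0):
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def _interior_rms(x):
    n = x.size
    return np.sqrt(np.mean(x[n // 4: -n // 4] ** 2))


class TestFilterEMG:
    def test_dc_rejected(self):
        rec = _rec(np.full((4, int(4 * FS)), 3.0))
        out = filter_emg(rec)
        assert _interior_rms(out.signals[0]) < 1e-6

    def test_notch_kills_power_line(self):
        rec = _rec(np.tile(_tone(50.0), (4, 1)))
        out = filter_emg(rec)
        assert _interior_rms(out.signals[0]) < 0.05 * _interior_rms(rec.signals[0])

    def test_passband_tone_preserved(self):
        rec = _rec(np.tile(_tone(100.0), (4, 1)))
        out = filter_emg(rec)
        ratio = _interior_rms(out.signals[0]) / _interior_rms(rec.signals[0])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_band_above_nyquist_rejected(self):
        rec = _rec(np.zeros((4, 1024)))
        rec.fs = 800.0
        with pytest.raises(ValueError):
            filter_emg(rec)

    def test_no_phase_shift_in_passband(self):
        # forward-backward filtering must leave a passband tone exactly in
        # phase with the input (no group delay to skew centroid timing)
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 100.0 * t)
        out = filter_emg(_rec(np.tile(x, (4, 1)))).signals[0]
        n = t.size
        sl = slice(n // 4, -n // 4)
        inphase = 2 * np.mean(out[sl] * np.sin(2 * np.pi * 100.0 * t[sl]))
        quad = 2 * np.mean(out[sl] * np.cos(2 * np.pi * 100.0 * t[sl]))
        phase = np.arctan2(quad, inphase)
        assert abs(phase) < 1e-3

    def test_time_reversal_symmetry_away_from_edges(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, int(4 * FS)))
        fwd = filter_emg(_rec(np.tile(x, (4, 1)))).signals[0]
        rev = filter_emg(_rec(np.tile(x[:, ::-1], (4, 1)))).signals[0][::-1]
        n = fwd.size
        sl = slice(n // 8, -n // 8)
        # residual differences come from edge transients of the long
        # notch impulse response; interior agreement is what matters
        resid = np.sqrt(np.mean((fwd[sl] - rev[sl]) ** 2))
        assert resid < 0.01 * np.sqrt(np.mean(fwd[sl] ** 2))


class TestFilterTorque:
    def _tq(self, x):
        return TorqueTrace(torque=x, fs=FS, mvt=100.0)

    def test_unity_dc_gain(self):
        out = filter_torque(self._tq(np.full(int(4 * FS), 42.0)))
        assert np.allclose(out.torque, 42.0, atol=1e-6)

    def test_slow_oscillation_preserved(self):
        out = filter_torque(self._tq(_tone(1.0)))
        assert _interior_rms(out.torque) == pytest.approx(_interior_rms(_tone(1.0)),
                                                          rel=0.02)

    def test_fast_oscillation_strongly_attenuated(self):
        out = filter_torque(self._tq(_tone(40.0)))
        atten_db = 20 * np.log10(_interior_rms(_tone(40.0)) / _interior_rms(out.torque))
        assert atten_db >= 30.0


class TestDetectBadChannels:
    def _layout(self):
        return GridLayout(n_rows=3, n_cols=3, missing=frozenset())

    def test_noise_floor_channel_flagged_by_snr(self):
        rng = np.random.default_rng(1)
        n = int(8 * FS)
        sig = np.zeros((9, n))
        sig[:, n // 2:] = rng.standard_normal((9, n // 2))  # active half
        sig += 0.01 * rng.standard_normal((9, n))           # floor everywhere
        sig[4, n // 2:] = 0.01 * rng.standard_normal(n // 2)  # dead electrode
        rec = EMGRecording(signals=sig, fs=FS, layout=self._layout())
        bad = detect_bad_channels(rec, snr_floor_db=6.0,
                                  hold_window=(4.0, 8.0), reference_window=(0.0, 4.0))
        assert bad == {(1, 1)}

    def test_identical_channels_all_kept(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(4 * FS))
        rec = EMGRecording(signals=np.tile(x, (9, 1)), fs=FS, layout=self._layout())
        assert detect_bad_channels(rec) == set()

    def test_saturated_channel_flagged_by_fallback_rule(self):
        rng = np.random.default_rng(3)
        sig = rng.standard_normal((9, int(4 * FS)))
        sig[2] *= 10.0
        rec = EMGRecording(signals=sig, fs=FS, layout=self._layout())
        assert detect_bad_channels(rec) == {(0, 2)}

    def test_sidecar_declared_bad_always_included(self):
        rng = np.random.default_rng(4)
        layout = GridLayout(n_rows=3, n_cols=3, missing=frozenset(),
                            bad=frozenset({(2, 2)}))
        rec = EMGRecording(signals=rng.standard_normal((9, 4096)), fs=FS,
                           layout=layout, channel_map=[(r, c) for r in range(3)
                                                       for c in range(3)])
        assert (2, 2) in detect_bad_channels(rec)


def _sim_torque(**overrides):
    layout = GridLayout(n_rows=4, n_cols=4, missing=frozenset())
    defaults = dict(layout=layout, fs=1024.0, duration_s=100.0,
                    failure_time_s=92.0, rest_s=0.0, torque_ramp_s=2.0,
                    torque_noise_cov0=0.0, torque_noise_cov_slope=0.0, seed=0,
                    center_path=((0.0, 12.0, 12.0), (100.0, 12.0, 12.0)))
    defaults.update(overrides)
    return simulate_torque(SimulationConfig(**defaults))


class TestSegmentContraction:
    def test_region_from_simulated_profile(self):
        # ramp ends at 2 s (0.5 MVT crossed at 5/3 s), failure at 92 s:
        # quasi-zero windows are marks +- 2 s, so region ~ [3.67, 90.0]
        tq = filter_torque(_sim_torque())
        region = segment_contraction(tq)
        assert region.start_s == pytest.approx(5.0 / 3.0 + 2.0, abs=0.05)
        assert region.end_s == pytest.approx(90.0, abs=0.05)
        t1, t2, t3 = region.segments
        assert t1.start_s == pytest.approx(region.start_s)
        assert t3.end_s == pytest.approx(region.end_s)
        mid = (region.start_s + region.end_s) / 2
        assert (t2.start_s + t2.end_s) / 2 == pytest.approx(mid)
        for w in region.quasi_zero:
            assert w[1] - w[0] == pytest.approx(4.0)

    def test_short_region_overlaps_with_warning(self):
        tq = filter_torque(_sim_torque(duration_s=40.0, failure_time_s=30.0))
        with pytest.warns(UserWarning, match="overlap"):
            region = segment_contraction(tq)
        assert region.duration_s < 30.0
        assert all(s.duration_s == pytest.approx(10.0) for s in region.segments)

    def test_flat_zero_torque_is_an_error(self):
        tq = TorqueTrace(torque=np.zeros(4096), fs=1024.0, mvt=100.0)
        with pytest.raises(SegmentationError, match="no contraction"):
            segment_contraction(tq)

    def test_manual_marks_take_precedence(self):
        tq = filter_torque(_sim_torque())
        region = segment_contraction(tq, marks=(2.0, 92.0))
        assert region.start_s == pytest.approx(4.0)
        assert region.end_s == pytest.approx(90.0)


class TestEnduranceTime:
    def test_constructed_failure_recovered(self):
        tq = filter_torque(_sim_torque(rest_s=2.0, duration_s=100.0,
                                       failure_time_s=92.0))
        res = endurance_time(tq)
        assert not res.censored
        # hold starts at rest + ramp = 4 s; failure at 92 s
        assert res.endurance_s == pytest.approx(88.0, abs=0.1)

    def test_brief_dip_ignored(self):
        fs = 1024.0
        t = np.arange(int(30 * fs)) / fs
        torque = np.full(t.size, 60.0)
        torque[(t >= 10) & (t < 11)] = 40.0  # 1-s dip below 50 % MVT
        res = endurance_time(TorqueTrace(torque, fs=fs, mvt=100.0))
        assert res.censored
        assert res.endurance_s == pytest.approx(30.0, abs=0.01)

    def test_never_drops_is_censored(self):
        tq = TorqueTrace(np.full(4096, 60.0), fs=1024.0, mvt=100.0)
        res = endurance_time(tq)
        assert res.censored


class TestTorqueSegmentStats:
    def _region(self):
        return AnalysisRegion.from_bounds(0.0, 30.0, 10.0)

    def test_constant_hold(self):
        tq = TorqueTrace(np.full(int(30 * 100), 60.0), fs=100.0, mvt=100.0)
        stats = torque_segment_stats(tq, self._region())
        for mean, cov in stats.values():
            assert mean == pytest.approx(0.6)
            assert cov == pytest.approx(0.0, abs=1e-12)

    def test_two_level_hand_computation(self):
        # alternating 0.5 / 0.7 MVT: mean 0.6, population std 0.1, CoV 1/6
        x = np.tile([50.0, 70.0], int(30 * 50))
        tq = TorqueTrace(x, fs=100.0, mvt=100.0)
        stats = torque_segment_stats(tq, self._region())
        mean, cov = stats["T2"]
        assert mean == pytest.approx(0.6)
        assert cov == pytest.approx(0.1 / 0.6, rel=1e-9)

    def test_zero_torque_cov_undefined(self):
        tq = TorqueTrace(np.zeros(3000), fs=100.0, mvt=100.0)
        stats = torque_segment_stats(tq, self._region())
        assert np.isnan(stats["T1"][1])
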