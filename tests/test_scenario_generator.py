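"""Synthetic room field, walking trajectories, gap filling, stimuli, neural."""

import numpy as np
import pytest

from opmloop.scenario_generator import (DriftSpec, EvokedTemplate,
                                        RoomFieldSpec, Trajectory,
                                        default_room_field, default_waypoints,
                                        fill_gaps, make_field,
                                        make_helmet_array, make_neural,
                                        make_stimuli, make_walk,
                                        spatial_pattern)


# ----------------------------------------------------------------- field
class TestMakeField:
    def test_gradient_worked_example(self):
        """20 nT/m gradient: points 0.15 m apart differ by 3 nT."""
        spec = RoomFieldSpec(homogeneous_offset=np.zeros(3),
                             gradient=np.diag([20e-9, -10e-9, -10e-9]))
        fn = make_field(spec)
        p1 = np.array([[0.0, 0, 0]])
        p2 = np.array([[0.15, 0, 0]])
        diff = fn(p2, 0.0) - fn(p1, 0.0)
        assert np.linalg.norm(diff) == pytest.approx(3e-9)

    def test_zero_spec_zero_field(self):
        fn = make_field(RoomFieldSpec(homogeneous_offset=np.zeros(3),
                                      gradient=np.zeros((3, 3))))
        assert np.all(fn(np.random.randn(5, 3), np.arange(5.0)) == 0)

    def test_drift_is_homogeneous(self):
        spec = RoomFieldSpec(homogeneous_offset=np.zeros(3),
                             gradient=np.zeros((3, 3)),
                             drift=DriftSpec(seed=1, duration=10.0))
        fn = make_field(spec)
        t = np.full(4, 3.7)
        pos = np.random.default_rng(0).uniform(-1, 1, (4, 3))
        B = fn(pos, t)
        assert np.ptp(B, axis=0).max() < 1e-18

    def test_drift_deterministic_and_band_limited(self):
        spec = DriftSpec(sd=150e-12, cutoff_hz=0.2, duration=120.0, seed=3)
        d1, d2 = spec.realise(), spec.realise()
        t = np.linspace(0, 100, 10000)
        np.testing.assert_array_equal(d1(t), d2(t))
        x = d1(t)[:, 0]
        # most variance below 0.5 Hz
        from scipy import signal
        f, p = signal.welch(x, fs=100.0, nperseg=4096)
        low = p[f <= 0.5].sum()
        assert low / p.sum() > 0.95

    def test_default_room_magnitudes(self):
        """<2 nT within 0.5 m of centre, ~3.5 nT at the front."""
        fn = make_field(default_room_field())
        rng = np.random.default_rng(0)
        near = rng.uniform(-0.5, 0.5, (200, 3))
        near = near[np.linalg.norm(near, axis=1) < 0.5]
        B = fn(near, np.zeros(near.shape[0]))
        assert np.linalg.norm(B, axis=1).max() < 2e-9
        front = fn(np.array([[0.0, 2.0, 0.0]]), 0.0)
        assert 2.5e-9 < np.linalg.norm(front) < 4.5e-9


# ------------------------------------------------------------ trajectory
class TestMakeWalk:
    def test_zero_speed_stationary(self):
        traj = make_walk(5.0, speed=0.0)
        assert np.ptp(traj.positions, axis=0).max() == 0.0

    def test_lap_closure_within_1cm(self):
        speed = 0.5
        traj = make_walk(60.0, speed=speed, seed=0)
        wp = default_waypoints()
        closed = np.vstack([wp, wp[:1]])
        lap = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        lap_t = lap / speed
        n_laps = int(traj.times[-1] / lap_t)
        start = traj.positions[0]
        for k in range(1, n_laps + 1):
            i = int(round(k * lap_t * 120))
            assert np.linalg.norm(traj.positions[i] - start) < 0.01

    def test_default_pattern_mostly_outside_half_metre(self):
        traj = make_walk(120.0, seed=1)
        r = np.linalg.norm(traj.positions[:, :2], axis=1)
        assert (r > 0.5).mean() > 0.40

    def test_sampled_at_120hz_unit_quaternions(self):
        traj = make_walk(10.0, seed=2)
        assert traj.sample_rate == pytest.approx(120.0)
        np.testing.assert_allclose(
            np.linalg.norm(traj.quaternions, axis=1), 1.0, atol=1e-9)

    def test_waypoints_outside_room_rejected(self):
        with pytest.raises(ValueError, match="room"):
            make_walk(10.0, waypoints=np.array([[0, 0], [2.0, 3.0]]))

    def test_edge_dropouts_only_near_edges(self):
        traj = make_walk(120.0, seed=3, dropout="edges")
        assert not traj.tracked.all()
        r = np.linalg.norm(traj.positions[~traj.tracked, :2], axis=1)
        assert r.min() > 1.2


# -------------------------------------------------- gap filling (pchip)
def _pchip_edge(h0, h1, s0, s1):
    d = ((2 * h0 + h1) * s0 - h0 * s1) / (h0 + h1)
    if np.sign(d) != np.sign(s0):
        return 0.0
    if np.sign(s0) != np.sign(s1) and abs(d) > 3 * abs(s0):
        return 3 * s0
    return d


def reference_pchip(x, y, xq):
    """Independent shape-preserving piecewise-cubic (Fritsch-Carlson)."""
    h = np.diff(x)
    s = np.diff(y) / h
    n = x.size
    d = np.zeros(n)
    for k in range(1, n - 1):
        if s[k - 1] * s[k] <= 0:
            d[k] = 0.0
        else:
            w1 = 2 * h[k] + h[k - 1]
            w2 = h[k] + 2 * h[k - 1]
            d[k] = (w1 + w2) / (w1 / s[k - 1] + w2 / s[k])
    d[0] = _pchip_edge(h[0], h[1], s[0], s[1])
    d[-1] = _pchip_edge(h[-1], h[-2], s[-1], s[-2])
    out = np.empty_like(np.asarray(xq, dtype=float))
    for i, xi in enumerate(np.atleast_1d(xq)):
        k = min(np.searchsorted(x, xi, side="right") - 1, n - 2)
        t = (xi - x[k]) / h[k]
        h00 = 2 * t ** 3 - 3 * t ** 2 + 1
        h10 = t ** 3 - 2 * t ** 2 + t
        h01 = -2 * t ** 3 + 3 * t ** 2
        h11 = t ** 3 - t ** 2
        out[i] = (h00 * y[k] + h10 * h[k] * d[k]
                  + h01 * y[k + 1] + h11 * h[k] * d[k + 1])
    return out


def _traj_from_positions(times, pos, tracked):
    n = times.size
    quat = np.tile([1.0, 0, 0, 0], (n, 1))
    return Trajectory(times, pos, quat, tracked)


class TestFillGaps:
    def test_no_gaps_identity(self):
        traj = make_walk(5.0, seed=0)
        out = fill_gaps(traj)
        np.testing.assert_array_equal(out.positions, traj.positions)
        assert not out.interpolated.any()

    def test_short_gap_linear_exact_on_linear_motion(self):
        t = np.arange(0, 2, 1 / 120)
        pos = np.outer(t, [0.3, 0.1, 0.0])
        tracked = np.ones(t.size, dtype=bool)
        tracked[100:110] = False                 # 10/120 s < 0.2 s
        traj = _traj_from_positions(t, pos.copy(), tracked)
        out = fill_gaps(traj)
        np.testing.assert_allclose(out.positions[100:110], pos[100:110],
                                   atol=1e-12)
        assert out.interpolated[100:110].all()
        assert (out.gap_length_s[100:110] < 0.2).all()

    def test_long_gap_matches_reference_pchip(self):
        rate = 120.0
        t = np.arange(0, 5, 1 / rate)
        x = 0.1 * t ** 3 - 0.2 * t               # monotone-ish cubic path
        pos = np.column_stack([x, np.zeros_like(t), np.zeros_like(t)])
        tracked = np.ones(t.size, dtype=bool)
        gap = slice(240, 240 + 120)              # 1 s gap
        tracked[gap] = False
        traj = _traj_from_positions(t, pos.copy(), tracked)
        out = fill_gaps(traj)
        ref = reference_pchip(t[tracked], x[tracked], t[gap])
        np.testing.assert_allclose(out.positions[gap, 0], ref, atol=1e-9)
        # shape preservation: no overshoot beyond the bracketing samples
        lo = min(x[gap.start - 1], x[gap.stop])
        hi = max(x[gap.start - 1], x[gap.stop])
        assert out.positions[gap, 0].min() >= lo - 1e-12
        assert out.positions[gap, 0].max() <= hi + 1e-12
        assert (out.gap_length_s[gap] >= 0.2).all()

    def test_boundary_gap_left_unfilled(self):
        t = np.arange(0, 1, 1 / 120)
        pos = np.zeros((t.size, 3))
        tracked = np.ones(t.size, dtype=bool)
        tracked[:5] = False
        traj = _traj_from_positions(t, pos, tracked)
        with pytest.warns(UserWarning, match="boundary"):
            out = fill_gaps(traj)
        assert not out.tracked[:5].any()

    def test_filled_quaternions_unit_norm(self):
        t = np.arange(0, 2, 1 / 120)
        n = t.size
        yaw = np.linspace(0, np.pi / 2, n)
        quat = np.column_stack([np.cos(yaw / 2), np.zeros(n), np.zeros(n),
                                np.sin(yaw / 2)])
        tracked = np.ones(n, dtype=bool)
        tracked[60:100] = False
        traj = Trajectory(t, np.zeros((n, 3)), quat, tracked)
        out = fill_gaps(traj)
        np.testing.assert_allclose(
            np.linalg.norm(out.quaternions[60:100], axis=1), 1.0, atol=1e-12)


# --------------------------------------------------------------- stimuli
class TestMakeStimuli:
    def test_mean_tone_count_near_570(self):
        counts = [make_stimuli(80, seed=s).n_tones for s in range(50)]
        assert abs(np.mean(counts) - 570) / 570 < 0.10

    def test_deviants_change_frequency(self):
        s = make_stimuli(80, seed=1)
        dev = np.flatnonzero(s.is_deviant)[1:]   # skip the first tone
        assert np.all(s.tone_freq[dev] != s.tone_freq[dev - 1])

    def test_isi_exactly_half_second(self):
        s = make_stimuli(40, seed=2)
        np.testing.assert_array_equal(np.diff(s.onsets), 0.5)

    def test_frequencies_from_allowed_set(self):
        s = make_stimuli(40, seed=3)
        assert set(np.unique(s.tone_freq)) <= {500.0, 550, 600, 650, 700,
                                               750, 800}

    def test_tsv_roundtrip(self, tmp_path):
        s = make_stimuli(10, seed=4)
        s.to_tsv(tmp_path / "stim.tsv")
        from opmloop.scenario_generator import StimulusSchedule
        back = StimulusSchedule.from_tsv(tmp_path / "stim.tsv")
        np.testing.assert_array_equal(back.onsets, s.onsets)
        np.testing.assert_array_equal(back.is_deviant, s.is_deviant)


# ---------------------------------------------------------------- neural
class TestMakeNeural:
    def test_empty_schedule_zero(self):
        from opmloop.scenario_generator import StimulusSchedule
        arr = make_helmet_array(5)
        empty = StimulusSchedule(np.array([]), np.array([]), np.array([], bool))
        out = make_neural(empty, arr, sample_rate=500.0, duration=1.0)
        assert np.all(out == 0)

    def test_single_tone_scaled_template(self):
        arr = make_helmet_array(5)
        from opmloop.scenario_generator import StimulusSchedule
        sched = StimulusSchedule(np.array([0.5]), np.array([600.0]),
                                 np.array([True]))
        tpl = EvokedTemplate()
        out = make_neural(sched, arr, template=tpl, sample_rate=1000.0,
                          duration=1.5)
        w = spatial_pattern(arr, tpl) * tpl.amplitude
        t = np.arange(1500) / 1000.0
        best = np.argmax(np.abs(w))
        peak_idx = np.argmax(np.abs(out[best]))
        assert abs(t[peak_idx] - 0.6) < 0.005    # onset + 100 ms latency
        assert np.abs(out[best]).max() == pytest.approx(abs(w[best]))

    def test_bilateral_signed_pattern(self):
        arr = make_helmet_array(17)
        w = spatial_pattern(arr)
        assert (w > 0).any() and (w < 0).any()
        assert np.abs(w).max() == pytest.approx(1.0)

    def test_trial_average_recovers_template(self):
        """Averaging 1000 noisy trials recovers the waveform to within
        2 noise-sd / sqrt(1000) at the best channel."""
        arr = make_helmet_array(4)
        fs = 500.0
        onsets = 0.2 + 0.5 * np.arange(1000)
        from opmloop.scenario_generator import StimulusSchedule
        sched = StimulusSchedule(onsets, np.full(1000, 600.0),
                                 np.ones(1000, bool))
        tpl = EvokedTemplate()
        clean = make_neural(sched, arr, template=tpl, sample_rate=fs)
        rng = np.random.default_rng(5)
        noise_sd = 200e-15
        noisy = clean + rng.normal(0, noise_sd, clean.shape)
        w = spatial_pattern(arr, tpl) * tpl.amplitude
        best = int(np.argmax(np.abs(w)))
        nt = int(0.3 * fs)
        trials = np.stack([noisy[best, int(o * fs):int(o * fs) + nt]
                           for o in onsets])
        avg = trials.mean(axis=0)
        t = np.arange(nt) / fs
        expected = w[best] * tpl.waveform(t)
        rms_err = np.sqrt(np.mean((avg - expected) ** 2))
        assert rms_err < 2 * noise_sd / np.sqrt(1000)


class TestHelmetArray:
    def test_dual_axis_counts(self):
        arr = make_helmet_array(17)
        assert arr.n_channels == 34
        assert arr.axes.count("Y") == 17 and arr.axes.count("Z") == 17

    def test_feedback_subset(self):
        arr = make_helmet_array(21, feedback=11)
        assert arr.feedback.sum() == 22

    def test_orthogonal_axes_per_sensor(self):
        arr = make_helmet_array(10)
        for j in range(10):
            y = arr.orientations[2 * j]
            z = arr.orientations[2 * j + 1]
            assert abs(np.dot(y, z)) < 1e-9
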