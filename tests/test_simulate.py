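"""Simulator: respiration signal, movement injection, session assembly."""

import numpy as np
import pytest
from pydantic import ValidationError

from cathstab import (
    MovementEvent,
    RespirationConfig,
    SessionConfig,
    Waveform,
    inject_movement,
    make_respiration_signal,
    simulate_session,
)
from cathstab.simulate import movement_profile
from cathstab.trajectory import Trajectory

RNG = np.random.default_rng(0)


class TestRespirationSignal:
    def test_jitter_free_cycle_grid(self):
        """10 bpm without jitter gives exactly 6.0 s cycles over 60 s."""
        cfg = RespirationConfig(rate_bpm=10, period_jitter_frac=0.0, phase0=0.0)
        sig = make_respiration_signal(cfg, 60.0, 60.0)
        assert np.allclose(sig.cycle_lengths, 6.0)
        assert np.allclose(sig.ee_times, np.arange(11) * 6.0)

    def test_zero_amplitude_is_flat(self):
        cfg = RespirationConfig(amplitude_mm=(0, 0, 0), phase0=0.0)
        sig = make_respiration_signal(cfg, 30.0, 60.0)
        assert np.all(sig.disp == 0.0)

    def test_jittered_mean_cycle_length(self):
        """12 bpm with 5% jitter: mean cycle length within 2% of 5.0 s."""
        cfg = RespirationConfig(rate_bpm=12, period_jitter_frac=0.05, phase0=0.0)
        sig = make_respiration_signal(cfg, 120.0, 60.0,
                                      rng=np.random.default_rng(11))
        assert abs(sig.cycle_lengths.mean() - 5.0) < 0.02 * 5.0

    def test_cycle_count_invariant(self):
        """Jitter-free end-expiration count over T is floor(T*rate/60) +/- 1."""
        for rate, T in [(10, 60), (12, 45), (8, 100)]:
            cfg = RespirationConfig(rate_bpm=rate, period_jitter_frac=0.0,
                                    phase0=0.3)
            sig = make_respiration_signal(cfg, float(T), 60.0)
            assert abs(sig.ee_times.size - int(T * rate / 60)) <= 1

    def test_sinusoid_waveform_peaks_at_end_expiration(self):
        cfg = RespirationConfig(rate_bpm=10, waveform=Waveform.SINUSOID,
                                period_jitter_frac=0.0, phase0=0.0,
                                amplitude_mm=(0, 0, 8))
        sig = make_respiration_signal(cfg, 12.0, 60.0)
        assert sig.disp[0, 2] == pytest.approx(4.0)      # half peak-to-peak
        assert sig.disp[:, 2].min() == pytest.approx(-4.0, abs=1e-3)

    def test_invalid_inputs(self):
        cfg = RespirationConfig()
        with pytest.raises(ValueError):
            make_respiration_signal(cfg, -1.0, 60.0)
        with pytest.raises(ValueError):
            make_respiration_signal(cfg, 10.0, 0.0)
        with pytest.raises(ValidationError):
            RespirationConfig(rate_bpm=0)
        with pytest.raises(ValidationError):
            RespirationConfig(period_jitter_frac=0.6)
        with pytest.raises(ValidationError):
            RespirationConfig(amplitude_mm=(-1, 0, 0))


class TestMovementInjection:
    def _flat_traj(self, duration=20.0, fs=60.0):
        n = int(duration * fs) + 1
        t = np.arange(n) / fs
        return Trajectory(t, np.zeros((n, 3)), np.zeros(n, bool))

    def test_zero_displacement_is_identity(self):
        traj = self._flat_traj()
        ev = MovementEvent(t_start=5, duration=3, displacement_mm=(0, 0, 0))
        out = inject_movement(traj, ev)
        assert np.array_equal(out.pos, traj.pos)

    def test_sustained_displacement_persists(self):
        traj = self._flat_traj()
        ev = MovementEvent(t_start=5, duration=3, displacement_mm=(5, 0, 0),
                           return_to_origin=False)
        out = inject_movement(traj, ev)
        assert out.pos[-1, 0] == pytest.approx(5.0)
        assert np.all(out.pos[traj.t < 5.0] == 0.0)

    def test_returning_event_leaves_outside_untouched(self):
        traj = self._flat_traj()
        ev = MovementEvent(t_start=5, duration=3, displacement_mm=(4, -2, 1),
                           return_to_origin=True)
        out = inject_movement(traj, ev)
        outside = (traj.t < 5.0) | (traj.t >= 8.0 + 1e-9)
        assert np.array_equal(out.pos[outside], traj.pos[outside])
        inside = (traj.t > 5.5) & (traj.t < 7.5)
        assert np.all(np.linalg.norm(out.pos[inside], axis=1) > 1.0)

    def test_opposite_events_cancel(self):
        traj = self._flat_traj()
        e1 = MovementEvent(t_start=4, duration=2, displacement_mm=(5, 0, 0),
                           return_to_origin=False)
        e2 = MovementEvent(t_start=10, duration=2, displacement_mm=(-5, 0, 0),
                           return_to_origin=False)
        out = inject_movement(inject_movement(traj, e1), e2)
        assert np.linalg.norm(out.pos[-1]) < 1e-9

    def test_profile_is_smooth_and_bounded(self):
        t = np.arange(0, 20, 1 / 60)
        ev = MovementEvent(t_start=5, duration=3, displacement_mm=(1, 0, 0))
        f = movement_profile(t, ev)
        assert f.min() >= 0.0 and f.max() <= 1.0
        assert np.abs(np.diff(f)).max() < 0.15     # no sample-to-sample jumps

    def test_event_outside_span_raises(self):
        traj = self._flat_traj(duration=10.0)
        with pytest.raises(ValueError):
            inject_movement(traj, MovementEvent(t_start=9, duration=3,
                                                displacement_mm=(1, 0, 0)))


class TestSimulateSession:
    def test_degenerate_session_is_constant(self):
        cfg = SessionConfig(
            jitter_sd_mm=0.0,
            respiration=RespirationConfig(amplitude_mm=(0, 0, 0)),
            baseline_mm=(1.0, -2.0, 3.0),
        )
        s = simulate_session(cfg)
        assert np.allclose(s.trajectory.pos, [1.0, -2.0, 3.0])

    def test_seed_determinism(self):
        cfg = SessionConfig(seed=42)
        a = simulate_session(cfg).trajectory
        b = simulate_session(cfg).trajectory
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.t, b.t)

    def test_truth_channels_reconstruct_trajectory(self):
        """pos - resp_truth equals the zero-amplitude session exactly."""
        cfg = SessionConfig(seed=9)
        full = simulate_session(cfg)
        quiet = simulate_session(cfg.model_copy(update={
            "respiration": cfg.respiration.model_copy(
                update={"amplitude_mm": (0.0, 0.0, 0.0)})
        }))
        assert np.allclose(full.trajectory.pos - full.trajectory.resp_truth,
                           quiet.trajectory.pos, atol=1e-12)

    def test_returning_movement_matches_reference_outside_window(self):
        mv = MovementEvent(t_start=16, duration=3, displacement_mm=(6, 0, 0))
        cfg = SessionConfig(rf_duration_s=10, seed=2, movements=[mv])
        ref = simulate_session(cfg.model_copy(update={"movements": []}))
        out = simulate_session(cfg)
        t = out.trajectory.t
        outside = (t < 16.0) | (t >= 19.0 + 1e-9)
        assert np.array_equal(out.trajectory.pos[outside],
                              ref.trajectory.pos[outside])

    def test_timeline_flags(self):
        cfg = SessionConfig(training_s=6, pre_ablation_s=2, rf_duration_s=4)
        s = simulate_session(cfg)
        t, rf = s.trajectory.t, s.trajectory.rf_on
        assert not rf[t < 8.0].any()
        assert rf[(t >= 8.0) & (t < 12.0)].all()
        assert not rf[t >= 12.0].any()

    def test_overlapping_movements_rejected(self):
        e1 = MovementEvent(t_start=5, duration=3, displacement_mm=(1, 0, 0))
        e2 = MovementEvent(t_start=7, duration=3, displacement_mm=(1, 0, 0))
        with pytest.raises(ValidationError):
            SessionConfig(movements=[e1, e2])

    def test_uniform_sampling(self):
        s = simulate_session(SessionConfig(sample_rate_hz=100.0))
        assert np.ptp(np.diff(s.trajectory.t)) < 1e-9
        assert s.trajectory.sample_rate_hz == pytest.approx(100.0)


class TestTrajectoryCsv:
    def test_round_trip_at_declared_precision(self, tmp_path):
        s = simulate_session(SessionConfig(seed=3, rf_duration_s=3))
        path = tmp_path / "traj.csv"
        s.trajectory.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.pos, s.trajectory.pos, atol=1e-4)
        assert np.allclose(back.t, s.trajectory.t, atol=1e-4)
        assert np.array_equal(back.rf_on, s.trajectory.rf_on)
        assert np.allclose(back.resp_truth, s.trajectory.resp_truth, atol=1e-4)

    def test_missing_columns_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t_s,x_mm\n0,1\n")
        with pytest.raises(ValueError, match="y_mm"):
            Trajectory.from_csv(p)
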