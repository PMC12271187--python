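"""Synthetic catheter-trajectory and ablation-session simulator.

Generates seeded trajectories with known ground truth: respiration-driven tip
motion at physiologic rates, stationary contact with localisation jitter,
sustained displacement events, and brief move-and-return excursions.  Every
downstream stage (respiration estimation, both stability algorithms, metrics)
is testable against the truth channels this module attaches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._filters import moving_average
from .config import (
    MOVEMENT_RAMP_S,
    PLATEAU_FRACTION,
    MovementEvent,
    RespirationConfig,
    SessionConfig,
    Waveform,
)
from .trajectory import Trajectory


@dataclass
class RespirationSignal:
    """Ground-truth respiration displacement with per-sample phase.

    Phase is the cycle fraction in [0, 1); phase 0 sits at the centre of the
    end-expiration dwell, so ground-truth end-expiration instants are the
    cycle boundaries.
    """

    t: np.ndarray
    disp: np.ndarray          # (n, 3) mm
    phase: np.ndarray         # (n,) in [0, 1)
    ee_times: np.ndarray      # ground-truth end-expiration instants (s)
    cycle_lengths: np.ndarray


def waveform_value(phase: np.ndarray, waveform: Waveform) -> np.ndarray:
    """Normalised waveform in [-1, 1]; +1 is the end-expiration extremum."""
    phase = np.asarray(phase, dtype=float)
    if waveform is Waveform.SINUSOID:
        return np.cos(2.0 * np.pi * phase)
    half = PLATEAU_FRACTION / 2.0
    w = np.ones_like(phase)
    mid = (phase >= half) & (phase < 1.0 - half)
    w[mid] = np.cos(2.0 * np.pi * (phase[mid] - half) / (1.0 - PLATEAU_FRACTION))
    return w


def _cycle_grid(
    cfg: RespirationConfig, duration: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cycle boundary times covering [0, duration], plus the starting phase."""
    period = cfg.period_s
    phase0 = rng.uniform(0.0, 1.0) if cfg.phase0 is None else float(cfg.phase0)

    def draw() -> float:
        if cfg.period_jitter_frac == 0:
            return period
        f = 1.0 + cfg.period_jitter_frac * rng.standard_normal()
        return period * min(max(f, 0.5), 1.5)

    bounds = [-phase0 * draw()]         # start of the cycle containing t=0
    while bounds[-1] < duration:
        bounds.append(bounds[-1] + draw())
    bounds = np.array(bounds)
    return bounds, np.diff(bounds), phase0


def make_respiration_signal(
    cfg: RespirationConfig,
    duration: float,
    sample_rate: float,
    rng: Optional[np.random.Generator] = None,
) -> RespirationSignal:
    """Respiration displacement time series with ground-truth phase.

    Raises ``ValueError`` for non-positive duration or sample rate.  With
    ``period_jitter_frac`` > 0 cycle lengths vary cycle-to-cycle (Gaussian,
    clipped at +/-50% of the nominal period), drawn from ``rng``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(0)

    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    bounds, lengths, _ = _cycle_grid(cfg, duration, rng)

    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, lengths.size - 1)
    phase = (t - bounds[idx]) / lengths[idx]
    phase = np.mod(phase, 1.0)

    w = waveform_value(phase, cfg.waveform)
    amp = 0.5 * np.asarray(cfg.amplitude_mm, dtype=float)
    disp = w[:, None] * amp[None, :]

    ee = bounds[(bounds >= 0.0) & (bounds <= t[-1])]
    return RespirationSignal(t=t, disp=disp, phase=phase, ee_times=ee,
                             cycle_lengths=lengths)


def movement_profile(t: np.ndarray, ev: MovementEvent) -> np.ndarray:
    """Scalar activation in [0, 1]: half-cosine ramps, plateau in between.

    The whole excursion lives inside ``[t_start, t_start + duration]``: the
    rise ramp starts at ``t_start`` and, for returning events, the fall ramp
    completes at ``t_start + duration``.
    """
    ramp = min(MOVEMENT_RAMP_S, ev.duration / (2.0 if ev.return_to_origin else 1.0))
    f = np.zeros_like(t)
    rise = (t >= ev.t_start) & (t < ev.t_start + ramp)
    f[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - ev.t_start) / ramp))
    end = ev.t_start + ev.duration
    if ev.return_to_origin:
        fall_start = end - ramp
        f[(t >= ev.t_start + ramp) & (t < fall_start)] = 1.0
        fall = (t >= fall_start) & (t < end)
        f[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - fall_start) / ramp))
    else:
        f[t >= ev.t_start + ramp] = 1.0
    return f


def inject_movement(traj: Trajectory, ev: MovementEvent) -> Trajectory:
    """Add a ramped displacement event to a trajectory (new object)."""
    if ev.t_start < traj.t[0] or ev.t_start + ev.duration > traj.t[-1]:
        raise ValueError("movement event window lies outside the trajectory span")
    f = movement_profile(traj.t, ev)
    pos = traj.pos + f[:, None] * np.asarray(ev.displacement_mm, dtype=float)
    return Trajectory(traj.t, pos, traj.rf_on, traj.phase_truth, traj.resp_truth)


@dataclass
class AblationSession:
    """A simulated (or loaded) RF application ready for analysis."""

    config: SessionConfig
    trajectory: Trajectory
    t_rf_start: float
    t_rf_end: float
    ee_times_truth: Optional[np.ndarray] = None

    @property
    def rf_duration_s(self) -> float:
        return self.t_rf_end - self.t_rf_start


def simulate_session(cfg: SessionConfig) -> AblationSession:
    """Simulate one ablation application.

    The trajectory is baseline + respiration + movement events + white-noise
    jitter.  Respiration and jitter use independent child streams of the
    session seed, so the same seed with zero respiration amplitude reproduces
    the identical jitter — the truth channels reconstruct the trajectory
    exactly.  Deterministic for a fixed config.
    """
    resp_rng, jitter_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    )
    duration = cfg.total_duration_s
    fs = cfg.sample_rate_hz
    sig = make_respiration_signal(cfg.respiration, duration, fs, resp_rng)
    n = sig.t.size

    pos = np.asarray(cfg.baseline_mm, dtype=float)[None, :] + sig.disp
    if cfg.jitter_sd_mm > 0:
        # localisation jitter: white noise smoothed over 0.1 s, emulating the
        # low-pass filtering of mapping-system location streams
        noise = jitter_rng.normal(0.0, cfg.jitter_sd_mm, size=(n, 3))
        w = max(int(round(0.1 * fs)), 1)
        pos = pos + moving_average(noise, w + (w % 2 == 0))
    rf_on = (sig.t >= cfg.t_rf_start) & (sig.t < cfg.t_rf_end)

    traj = Trajectory(sig.t, pos, rf_on, phase_truth=sig.phase, resp_truth=sig.disp)
    for ev in cfg.movements:
        traj = inject_movement(traj, ev)

    return AblationSession(
        config=cfg,
        trajectory=traj,
        t_rf_start=cfg.t_rf_start,
        t_rf_end=cfg.t_rf_end,
        ee_times_truth=sig.ee_times,
    )
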