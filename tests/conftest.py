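import numpy as np
import pytest

from cathstab import (
    AblationSession,
    RespirationConfig,
    SessionConfig,
    analyze_session,
    simulate_session,
)
from cathstab.respiration import RespirationEstimate
from cathstab.trajectory import Trajectory


def stationary_config(rate_bpm: float = 10.0, rf_duration_s: float = 10.0,
                      seed: int = 1, **kw) -> SessionConfig:
    """A stationary-contact session: respiration + jitter, no movements."""
    resp = kw.pop("respiration", RespirationConfig(rate_bpm=rate_bpm))
    return SessionConfig(rf_duration_s=rf_duration_s, seed=seed,
                         respiration=resp, **kw)


def synthetic_session(pos: np.ndarray, t_rf_start: float, t_rf_end: float,
                      fs: float = 60.0) -> tuple[AblationSession, RespirationEstimate]:
    """Wrap a hand-built position array as a session with a pass-through
    (no-respiration) estimate, for direct algorithm-level tests."""
    n = pos.shape[0]
    t = np.arange(n) / fs
    rf = (t >= t_rf_start) & (t < t_rf_end)
    traj = Trajectory(t, pos, rf)
    cfg = SessionConfig(
        training_s=max(t_rf_start - 2.0, 0.0),
        pre_ablation_s=min(2.0, t_rf_start),
        rf_duration_s=t_rf_end - t_rf_start,
        jitter_sd_mm=0.0,
        respiration=RespirationConfig(amplitude_mm=(0.0, 0.0, 0.0)),
    )
    est = RespirationEstimate(
        resp_mm=np.zeros_like(pos),
        compensated_mm=pos.copy(),
        period_s=None,
        valid=np.ones(n, dtype=bool),
    )
    return AblationSession(cfg, traj, t_rf_start, t_rf_end), est


@pytest.fixture
def stable_session():
    return simulate_session(stationary_config(seed=1))


@pytest.fixture
def stable_analysis(stable_session):
    return analyze_session(stable_session)
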