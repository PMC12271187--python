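"""The legacy end-expiration Gated stability algorithm.

The gated detector examines the catheter position only at end-expiration
instants: a tag appears once ``min_ee_events`` consecutive end-expiration
positions (counted from RF onset) agree to within ``d_max_mm``.  Motion
between those instants is invisible to it by contract — the documented blind
spot — and because consecutive events are one respiratory cycle apart, the
earliest possible tag arrives a full cycle after the first post-onset event.
For an onset phase uniform over the cycle the mean latency is therefore
1.5 x period: 9 s at 10 breaths/min.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import GatedParams
from .respiration import RespirationEstimate
from .simulate import AblationSession
from .tags import TagEvent
from .trajectory import Trajectory

#: algorithm label used in tag tables
ALGORITHM = "gated"


def ee_spread_mm(positions: np.ndarray) -> float:
    """Spread of consecutive end-expiration positions.

    For two events this is their Euclidean distance; for longer windows it is
    the standard deviation of the consecutive-pair distances (the windowed
    generalisation of the two-point reading).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("spread needs at least two end-expiration positions")
    d = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    if d.size == 1:
        return float(d[0])
    return float(np.std(d))


def first_tag_time(
    ee_times: np.ndarray,
    ee_positions: np.ndarray,
    t_start: float,
    t_end: float,
    params: Optional[GatedParams] = None,
) -> Optional[tuple[float, np.ndarray]]:
    """First gated tag from an end-expiration event stream.

    Only events with ``t_start <= t < t_end`` participate (an event exactly at
    RF onset counts).  Returns ``(tag_time, window_positions)`` for the first
    window of ``min_ee_events`` consecutive events whose spread is within
    ``d_max_mm``, or ``None`` — the session ended before enough events, or the
    end-expiration positions never settled.
    """
    params = params or GatedParams()
    ee_times = np.asarray(ee_times, dtype=float)
    ee_positions = np.asarray(ee_positions, dtype=float)
    m = (ee_times >= t_start) & (ee_times < t_end)
    times, pos = ee_times[m], ee_positions[m]
    k = params.min_ee_events
    for i in range(k - 1, times.size):
        window = pos[i - k + 1 : i + 1]
        if ee_spread_mm(window) <= params.d_max_mm:
            return float(times[i]), window
    return None


def positions_at(traj: Trajectory, times: np.ndarray) -> np.ndarray:
    """Raw positions sampled at the nearest trajectory sample to each time."""
    idx = np.clip(np.searchsorted(traj.t, times), 0, len(traj) - 1)
    left = np.clip(idx - 1, 0, len(traj) - 1)
    use_left = np.abs(traj.t[left] - times) < np.abs(traj.t[idx] - times)
    idx = np.where(use_left, left, idx)
    return traj.pos[idx]


def gated_verdicts(
    traj: Trajectory,
    ee_times: np.ndarray,
    t_rf_start: float,
    t_rf_end: float,
    params: Optional[GatedParams] = None,
) -> list[TagEvent]:
    """Tag events produced by the gated algorithm (at most one per session)."""
    params = params or GatedParams()
    ee_times = np.asarray(ee_times, dtype=float)
    if ee_times.size == 0:
        return []
    hit = first_tag_time(
        ee_times, positions_at(traj, ee_times), t_rf_start, t_rf_end, params
    )
    if hit is None:
        return []
    t_tag, window = hit
    center = window.mean(axis=0)
    first_event = float(ee_times[(ee_times >= t_rf_start) & (ee_times <= t_tag)][0])
    return [
        TagEvent(
            site_id=0,
            position_mm=tuple(float(c) for c in center),
            t_tag_s=t_tag,
            t_start_s=first_event,
            t_end_s=t_tag,
            algorithm=ALGORITHM,
            time_to_tag_s=t_tag - t_rf_start,
            first_site=True,
        )
    ]


def gated_time_to_tag(
    session: AblationSession,
    est: RespirationEstimate,
    params: Optional[GatedParams] = None,
) -> Optional[float]:
    """Seconds from RF onset to the first gated tag, or ``None`` if no tag."""
    tags = gated_verdicts(
        session.trajectory, est.ee_times_s, session.t_rf_start,
        session.t_rf_end, params,
    )
    return tags[0].time_to_tag_s if tags else None


def monte_carlo_time_to_tag(
    n_draws: int,
    period_s: float,
    rng: np.random.Generator,
    params: Optional[GatedParams] = None,
    jitter_sd_mm: float = 0.0,
    rf_duration_s: Optional[float] = None,
) -> np.ndarray:
    """Gated tag latency for a stationary catheter, onset phase uniform.

    Each draw builds the end-expiration event grid of one session — onset at
    t=0 with respiratory phase uniform over the cycle, events every
    ``period_s`` thereafter, positions stationary up to optional localisation
    jitter — and runs the gated detector on it.  Returns the per-draw
    time-to-tag (NaN where no tag appeared before ``rf_duration_s``).
    """
    params = params or GatedParams()
    if rf_duration_s is None:
        rf_duration_s = (params.min_ee_events + 1.5) * period_s
    out = np.full(n_draws, np.nan)
    k_max = int(np.ceil(rf_duration_s / period_s)) + 1
    for i in range(n_draws):
        phase = rng.uniform(0.0, 1.0)
        first = (1.0 - phase) % 1.0 * period_s
        times = first + period_s * np.arange(k_max)
        pos = np.zeros((k_max, 3))
        if jitter_sd_mm > 0:
            pos = pos + rng.normal(0.0, jitter_sd_mm, size=pos.shape)
        hit = first_tag_time(times, pos, 0.0, rf_duration_s, params)
        if hit is not None:
            out[i] = hit[0]
    return out
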