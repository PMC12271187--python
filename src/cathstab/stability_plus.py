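"""The Stability+ algorithm: continuous respiration-compensated stability.

A sample is stable iff the compensated tip position lies strictly within
``d_max_mm`` of the centre of mass of the current site AND its smoothed speed
is strictly below ``v_max_cm_s``.  The site centre accumulates only stable
samples, so an excursion cannot drag the centre with it: an unstable run ends
either when the tip returns within ``d_max_mm`` of the unchanged centre, or
when it outlives ``latency_grace_s``.

Brief excursions (at most ``latency_grace_s``) that end back within
``return_radius_mm`` of the pre-excursion centre are forgiven — thermal
latency means tissue temperature keeps rising for about 3 s after RF stops,
so such movements do not compromise the lesion.  An excursion that outlives
the grace period breaks the site; classification restarts there with a fresh
centre, so a catheter that settles at a new position opens a new site.

A tag is displayed once ``min_dwell_s`` of continuous (forgiveness-filtered)
stability accrues, with the dwell clock never starting before RF onset; for a
catheter stable from the beginning of the ablation the tag appears exactly
``min_dwell_s`` (2 s) after RF-on, independent of respiratory rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import StabilityPlusParams
from .respiration import RespirationEstimate, moving_average
from .simulate import AblationSession
from .tags import TagEvent

ALGORITHM = "splus"

_EPS = 1e-9


def instantaneous_velocity(
    pos: np.ndarray, sample_rate_hz: float, window_s: float = 0.2
) -> np.ndarray:
    """Per-sample speed (cm/s) of a position stream.

    Centred finite differences (one-sided at the endpoints), then a moving
    average over ``window_s``.  Positions are in mm; output is cm/s.
    """
    pos = np.asarray(pos, dtype=float)
    if pos.shape[0] < 3:
        raise ValueError("velocity needs at least 3 samples")
    vel = np.gradient(pos, axis=0) * sample_rate_hz      # mm/s
    window = max(int(round(window_s * sample_rate_hz)), 1)
    window += window % 2 == 0
    vel = moving_average(vel, window)                    # vector smoothing
    return np.linalg.norm(vel, axis=1) / 10.0            # mm/s -> cm/s


def running_center_of_mass(
    pos: np.ndarray,
    breaks: Sequence[int] = (),
    stable_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Running centre of mass of the current site.

    The mean restarts at each index in ``breaks`` (a site break), so a later
    site's centre is independent of earlier clusters.  With ``stable_mask``
    only samples flagged stable contribute (the centre freezes during an
    excursion); samples before the first stable one take the first position
    of their site.
    """
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    out = np.empty_like(pos)
    starts = [0] + sorted(int(b) for b in breaks if 0 < b < n) + [n]
    for a, b in zip(starts[:-1], starts[1:]):
        if a >= b:
            continue
        seg = pos[a:b]
        if stable_mask is None:
            c = np.cumsum(seg, axis=0)
            out[a:b] = c / np.arange(1, b - a + 1)[:, None]
        else:
            w = stable_mask[a:b].astype(float)
            c = np.cumsum(seg * w[:, None], axis=0)
            cnt = np.cumsum(w)
            out[a:b] = np.where(
                cnt[:, None] > 0, c / np.maximum(cnt, 1.0)[:, None], seg[0]
            )
    return out


@dataclass
class _EngineState:
    raw: np.ndarray                        # verdicts before forgiveness
    stable: np.ndarray                     # after the thermal-latency filter
    break_runs: list[tuple[int, int]]      # unforgiven excursions [a, b)
    forgiven_runs: list[tuple[int, int]]


def _stability_engine(
    comp: np.ndarray, speed: np.ndarray, t: np.ndarray, params: StabilityPlusParams
) -> _EngineState:
    """Causal sample-by-sample classification with site management."""
    n = comp.shape[0]
    raw = np.zeros(n, dtype=bool)
    stable = np.zeros(n, dtype=bool)
    break_runs: list[tuple[int, int]] = []
    forgiven: list[tuple[int, int]] = []
    c_sum = np.zeros(3)
    c_n = 0
    run_start: Optional[int] = None

    def reset_site() -> None:
        nonlocal c_sum, c_n, run_start
        c_sum = np.zeros(3)
        c_n = 0
        run_start = None

    for i in range(n):
        center = c_sum / c_n if c_n else comp[i]
        d = float(np.linalg.norm(comp[i] - center))
        ok = d < params.d_max_mm and speed[i] < params.v_max_cm_s
        if not ok and run_start is not None and (
            t[i] - t[run_start] > params.latency_grace_s + _EPS
        ):
            # excursion outlived the grace period: break the site here and
            # re-classify this sample against a fresh centre
            break_runs.append((run_start, i))
            reset_site()
            center = comp[i]
            d = 0.0
            ok = speed[i] < params.v_max_cm_s
        if ok:
            if run_start is not None:
                # excursion ended by returning within d_max of the centre
                within_grace = t[i] - t[run_start] <= params.latency_grace_s + _EPS
                returned = d <= params.return_radius_mm + _EPS
                if within_grace and returned:
                    stable[run_start:i] = True
                    forgiven.append((run_start, i))
                else:
                    break_runs.append((run_start, i))
                    c_sum = np.zeros(3)
                    c_n = 0
                run_start = None
            raw[i] = True
            stable[i] = True
            c_sum += comp[i]
            c_n += 1
        elif run_start is None:
            run_start = i
    if run_start is not None:
        break_runs.append((run_start, n))
    return _EngineState(raw, stable, break_runs, forgiven)


def classify_stability(
    compensated: np.ndarray,
    speed_cm_s: np.ndarray,
    t: np.ndarray,
    params: Optional[StabilityPlusParams] = None,
) -> np.ndarray:
    """Raw per-sample stable flags (before thermal-latency forgiveness).

    Stable iff distance to the site centre of mass < ``d_max_mm`` AND speed <
    ``v_max_cm_s`` — strict inequalities at both thresholds.  Site breaks
    (excursions outliving the grace period) reset the centre, so samples
    after a sustained displacement are judged against the new site.
    """
    params = params or StabilityPlusParams()
    comp = np.asarray(compensated, dtype=float)
    return _stability_engine(comp, np.asarray(speed_cm_s), np.asarray(t), params).raw


def apply_thermal_latency(
    raw_flags: np.ndarray,
    compensated: np.ndarray,
    t: np.ndarray,
    params: Optional[StabilityPlusParams] = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Forgive brief move-and-return excursions in a flag stream.

    A maximal unstable run of duration <= ``latency_grace_s`` whose final
    position lies within ``return_radius_mm`` of the pre-excursion site
    centre (the mean of the stable samples before it) is reclassified stable.
    Longer or non-returning runs stay unstable and end the site.  Returns the
    filtered flags and the unforgiven runs as ``[start, stop)`` pairs.  The
    operation is idempotent.
    """
    params = params or StabilityPlusParams()
    comp = np.asarray(compensated, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.asarray(raw_flags, dtype=bool).copy()
    n = out.size
    d = np.diff((~out).astype(np.int8), prepend=0, append=0)
    site_start = 0
    break_runs: list[tuple[int, int]] = []
    for a, b in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        duration = t[min(b, n - 1)] - t[a]
        pre = out[site_start:a]
        pre_center = (
            comp[site_start:a][pre].mean(axis=0) if pre.any() else comp[a]
        )
        final = comp[b] if b < n else comp[-1]
        returned = float(np.linalg.norm(final - pre_center)) <= (
            params.return_radius_mm + _EPS
        )
        if duration <= params.latency_grace_s + _EPS and returned:
            out[a:b] = True
        else:
            break_runs.append((int(a), int(b)))
            site_start = b
    return out, break_runs


@dataclass
class StabilityPlusResult:
    """Per-session output of the Stability+ pipeline."""

    tags: list[TagEvent]
    pre_ablation_stable: bool
    stable: np.ndarray                      # filtered per-sample flags
    stable_raw: np.ndarray                  # before the latency filter
    break_runs: list[tuple[int, int]]       # unforgiven unstable runs
    unstable_during_rf: bool
    speed_cm_s: np.ndarray
    compensated: np.ndarray                 # positions the verdicts used

    @property
    def time_to_tag_s(self) -> Optional[float]:
        return self.tags[0].time_to_tag_s if self.tags else None


def splus_tags(
    session: AblationSession,
    est: RespirationEstimate,
    params: Optional[StabilityPlusParams] = None,
) -> StabilityPlusResult:
    """Run Stability+ on a session: tags, halo flags, pre-ablation indication.

    During the respiration estimator's warm-up (``est.valid`` False) the raw
    positions stand in for the compensated ones — automatic training needs no
    operator step, but verdicts in that window see uncompensated motion.
    """
    params = params or StabilityPlusParams()
    traj = session.trajectory
    if not traj.rf_on.any():
        raise ValueError("session has no RF-on samples")
    n = len(traj)
    comp = np.where(est.valid[:, None], est.compensated_mm, traj.pos)

    # classify per channel segment: automatic training completes at the
    # warm-up boundary and classification restarts there with a fresh site,
    # so the raw-to-compensated channel switch never fakes an excursion
    first_valid = int(np.argmax(est.valid)) if est.valid.any() else n
    bounds = [0, n] if first_valid in (0, n) else [0, first_valid, n]
    raw = np.zeros(n, dtype=bool)
    flags = np.zeros(n, dtype=bool)
    speed = np.zeros(n)
    break_runs: list[tuple[int, int]] = []
    sites: list[tuple[int, int]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 3:
            continue
        seg_speed = instantaneous_velocity(
            comp[a:b], traj.sample_rate_hz, params.velocity_window_s
        )
        state = _stability_engine(comp[a:b], seg_speed, traj.t[a:b], params)
        speed[a:b] = seg_speed
        raw[a:b] = state.raw
        flags[a:b] = state.stable
        break_runs += [(x + a, y + a) for x, y in state.break_runs]
        sites += [(x + a, y + a) for x, y in _site_segments(b - a, state.break_runs)]

    t = traj.t
    t_rf_start, t_rf_end = session.t_rf_start, session.t_rf_end

    tags: list[TagEvent] = []
    for site_id, (s0, s1) in enumerate(sites):
        # halo: the excursion that ended this site happened during RF
        halo = any(
            t[a] < t_rf_end and t[min(b, n) - 1] >= t_rf_start
            for a, b in break_runs
            if a == s1
        )
        # the dwell clock runs on raw stability: a forgiven excursion keeps
        # the site (and session) stable but still postpones the tag display
        tag = _first_tag_in_site(t, raw[s0:s1], s0, t_rf_start, t_rf_end, params)
        if tag is None:
            continue
        t_tag, run_a, run_b = tag
        center = comp[run_a:run_b][raw[run_a:run_b]].mean(axis=0)
        tags.append(
            TagEvent(
                site_id=site_id,
                position_mm=tuple(float(c) for c in center),
                t_tag_s=float(t_tag),
                t_start_s=float(max(t[run_a], t_rf_start)),
                t_end_s=float(t[run_b - 1]),
                algorithm=ALGORITHM,
                time_to_tag_s=float(t_tag - t_rf_start),
                halo=halo,
            )
        )
    if tags:
        tags[0].first_site = True

    # pre-ablation indication demands raw stability: thermal latency is an
    # RF-heating argument and forgives nothing before energy delivery
    pre_mask = (t >= t_rf_start - params.pre_ablation_window_s) & (t < t_rf_start)
    pre_ablation_stable = bool(pre_mask.any() and raw[pre_mask].all())
    unstable_during_rf = bool((~flags[traj.rf_on]).any())

    return StabilityPlusResult(
        tags=tags,
        pre_ablation_stable=pre_ablation_stable,
        stable=flags,
        stable_raw=raw,
        break_runs=break_runs,
        unstable_during_rf=unstable_during_rf,
        speed_cm_s=speed,
        compensated=comp,
    )


def _site_segments(n: int, break_runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sites as [start, stop) index pairs between unforgiven runs."""
    sites = []
    start = 0
    for a, b in break_runs:
        if a > start:
            sites.append((start, a))
        start = b
    if start < n:
        sites.append((start, n))
    return sites


def _first_tag_in_site(
    t: np.ndarray,
    site_flags: np.ndarray,
    offset: int,
    t_rf_start: float,
    t_rf_end: float,
    params: StabilityPlusParams,
) -> Optional[tuple[float, int, int]]:
    """First sample in the site at which ``min_dwell_s`` of stability accrued.

    The dwell clock starts at the later of the stable run's start and RF
    onset; the tag must display no later than RF end.  Returns (tag time,
    run start, run stop) in absolute sample indices, or None.
    """
    d = np.diff(site_flags.astype(np.int8), prepend=0, append=0)
    for a, b in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        a_abs, b_abs = a + offset, b + offset
        clock0 = max(float(t[a_abs]), t_rf_start)
        idx = np.searchsorted(t[a_abs:b_abs], clock0 + params.min_dwell_s - _EPS)
        if idx >= b_abs - a_abs:
            continue
        t_tag = float(t[a_abs + idx])
        if t_tag <= t_rf_end + _EPS:
            return t_tag, a_abs, b_abs
    return None
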