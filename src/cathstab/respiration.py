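"""Respiratory motion estimation from catheter-tip trajectories.

Estimation runs in two stages.  First, a centred moving average of window
length one respiratory period splits the position stream into a slow trend
and an oscillatory residual; the dominant period and the end-expiration
events are found on that residual.  Second (``analyze_respiration``), the
respiration displacement proper is a phase-locked cycle template — the
synchronous average of the oscillatory component over the training window —
evaluated at the continuously tracked phase, so that aperiodic catheter
movements are not absorbed into the respiration channel.  Either way the
decomposition is additive by construction: ``resp + compensated == raw``
holds exactly for every sample.

End-expiration events are the centres of the long-dwell extremum of the
respiration component projected onto the principal respiratory axis — the
reference instants the legacy gated algorithm compares, and the natural
definition when the expiratory plateau dominates the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._filters import moving_average
from .trajectory import Trajectory

#: physiologic band searched for a respiratory period (s) — 5 to 30 breaths/min
PERIOD_BAND_S = (2.0, 12.0)

#: minimum normalised autocorrelation at the candidate period; below this the
#: motion is treated as non-periodic (no-respiration flag)
MIN_AUTOCORR = 0.2

#: minimum RMS excursion (mm) along the principal axis to call it respiration
MIN_RMS_MM = 0.1


@dataclass
class RespirationEstimate:
    """Per-sample decomposition of tip motion into respiration + compensated.

    ``valid`` is False until one full respiratory cycle has been observed
    (the automatic-training warm-up); consumers must honour it — the gated
    algorithm cannot use events before it, Stability+ falls back to raw
    positions.  ``period_s`` is ``None`` when no respiratory periodicity was
    found, in which case ``resp_mm`` is zero and ``compensated_mm`` is the raw
    stream.
    """

    resp_mm: np.ndarray            # (n, 3)
    compensated_mm: np.ndarray     # (n, 3)
    period_s: Optional[float]
    valid: np.ndarray              # (n,) bool
    ee_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    phase: Optional[np.ndarray] = None     # tracked cycle fraction in [0, 1)

    @property
    def has_respiration(self) -> bool:
        return self.period_s is not None

    @property
    def is_valid(self) -> bool:
        return bool(self.valid.any())


def principal_axis(x: np.ndarray) -> np.ndarray:
    """Unit direction of maximum variance of a demeaned (n, 3) point cloud."""
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return vt[0]


def estimate_period(traj: Trajectory) -> Optional[float]:
    """Dominant respiratory period of tip motion, or ``None`` if none found.

    Projects the demeaned positions onto their principal axis and searches the
    autocorrelation for a peak in the physiologic band; the peak lag is
    refined by parabolic interpolation.  Requires a span of at least two
    nominal cycles to resolve a period.
    """
    s = (traj.pos - traj.pos.mean(axis=0)) @ principal_axis(traj.pos)
    if float(np.sqrt(np.mean(s**2))) < MIN_RMS_MM:
        return None
    s = s - np.polyval(np.polyfit(traj.t, s, 1), traj.t)   # remove drift
    dt = traj.dt
    n = s.size
    ac = np.correlate(s, s, mode="full")[n - 1:]
    ac = ac / np.arange(n, 0, -1)          # unbiased: mean product per lag
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    lo = max(int(round(PERIOD_BAND_S[0] / dt)), 2)
    hi = min(int(round(PERIOD_BAND_S[1] / dt)), n - 2)
    if hi <= lo:
        return None
    band = ac[lo : hi + 1]
    best = float(band.max())
    if best < MIN_AUTOCORR:
        return None
    # earliest strong peak: the fundamental, not a multiple of it
    peaks = [
        k for k in range(lo + 1, hi)
        if ac[k] >= ac[k - 1] and ac[k] >= ac[k + 1] and ac[k] >= 0.85 * best
    ]
    k0 = peaks[0] if peaks else lo + int(np.argmax(band))

    def refine(k: int) -> float:
        y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        return k + float(np.clip(shift, -0.5, 0.5))

    rough = refine(k0) * dt
    cyc = _median_cycle_from_crossings(s, traj.t)
    if cyc is not None and abs(cyc - rough) < 0.25 * rough:
        return cyc
    return float(rough)


def _median_cycle_from_crossings(s: np.ndarray, t: np.ndarray) -> Optional[float]:
    """Median spacing of hysteresis upward zero crossings.

    Short-window autocorrelation carries an O(period/span) lag bias; cycle
    lengths measured between successive upward crossings do not.  Hysteresis
    at half the RMS keeps noise from double-counting crossings; the median
    rejects cycles corrupted by movement transients.
    """
    h = 0.5 * float(np.sqrt(np.mean(s**2)))
    label = np.where(s > h, 1, np.where(s < -h, -1, 0))
    nz = np.flatnonzero(label)
    if nz.size < 2:
        return None
    lab = label[nz]
    ups = nz[1:][(lab[1:] == 1) & (lab[:-1] == -1)]
    if ups.size < 2:
        return None
    return float(np.median(np.diff(t[ups])))


def decompose(traj: Trajectory, period_s: Optional[float]) -> RespirationEstimate:
    """Split raw positions into respiration + compensated components.

    ``compensated = moving_average(raw)`` over one period, ``resp = raw −
    compensated``; the reconstruction is exact.  With ``period_s=None``
    (no-respiration flag) resp is zero and compensated equals raw.  A
    trajectory shorter than one period yields ``valid`` all-False and
    compensated defaulting to raw.
    """
    n = len(traj)
    if period_s is None:
        return RespirationEstimate(
            resp_mm=np.zeros((n, 3)),
            compensated_mm=traj.pos.copy(),
            period_s=None,
            valid=np.ones(n, dtype=bool),
        )
    window = int(round(period_s * traj.sample_rate_hz))
    window += window % 2 == 0  # odd length keeps the filter zero-lag
    if n < window:
        return RespirationEstimate(
            resp_mm=np.zeros((n, 3)),
            compensated_mm=traj.pos.copy(),
            period_s=float(period_s),
            valid=np.zeros(n, dtype=bool),
        )
    comp = moving_average(traj.pos, window)
    valid = np.arange(n) >= window  # first full cycle = warm-up
    return RespirationEstimate(
        resp_mm=traj.pos - comp,
        compensated_mm=comp,
        period_s=float(period_s),
        valid=valid,
    )


def _run_bounds(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds of True runs."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _grid_consistent(events: list[float], period: float) -> list[float]:
    """Largest subset of events lying on a common one-per-cycle grid.

    Movement artefacts can fake or displace a plateau; genuine end-expiration
    events recur near multiples of the period, so keep the largest
    grid-consistent subset (tolerance 0.2 cycle, absorbing physiologic
    cycle-length jitter).
    """
    def offgrid(x: float) -> float:
        return abs((x + period / 2.0) % period - period / 2.0)

    best: list[float] = []
    for ref in events:
        members = [e for e in events if offgrid(e - ref) <= 0.2 * period]
        if len(members) > len(best):
            best = members
    return best


def detect_end_expiration(
    est: RespirationEstimate,
    t: np.ndarray,
    training_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """End-expiration instants: centres of the long-dwell extremum per cycle.

    The respiration component is projected on its principal respiratory axis
    with the sign chosen so the extremum where the signal dwells longest (the
    expiratory plateau) is positive; events are the centres of the
    above-threshold runs, one per cycle.  Axis, sign and threshold are
    derived from the quiescent training samples (``training_mask``, default
    the post-warm-up samples) so that deliberate catheter movements elsewhere
    cannot corrupt them.  Returns an empty array when the estimate is invalid
    or carries the no-respiration flag.  Event times are stored on
    ``est.ee_times_s`` as well as returned.
    """
    est.ee_times_s = np.empty(0)
    if not est.has_respiration or not est.is_valid:
        return est.ee_times_s
    resp = est.resp_mm
    tt = np.asarray(t)
    train = est.valid if training_mask is None else (training_mask & est.valid)
    if not train.any():
        train = est.valid
    if resp.shape[0] < 3 or np.count_nonzero(train) < 3:
        return est.ee_times_s

    s = resp @ principal_axis(resp[train])
    st = s[train]
    # robust extrema of the quiescent signal
    smin, smax = (float(q) for q in np.quantile(st, [0.005, 0.995]))
    rng = smax - smin
    if rng <= 0:
        return est.ee_times_s
    # long-dwell extremum: more samples near the end-expiration plateau
    near_hi = np.count_nonzero(st > smax - 0.15 * rng)
    near_lo = np.count_nonzero(st < smin + 0.15 * rng)
    if near_lo > near_hi:
        s = -s
        smin, smax = -smax, -smin
    thr = smax - 0.15 * rng

    runs = _run_bounds(s >= thr)
    if not runs:
        return est.ee_times_s
    # merge fragments split by noise; plateaus of successive cycles stay
    # separated by well over a quarter period even for a 40% expiratory dwell
    merge_gap = 0.25 * est.period_s
    merged: list[tuple[int, int]] = [runs[0]]
    for a, b in runs[1:]:
        if tt[a] - tt[merged[-1][1] - 1] < merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    # a run clipped by the data boundary has a biased centre — drop it
    merged = [(a, b) for a, b in merged if a > 0 and b < s.size]
    events = [0.5 * (tt[a] + tt[b - 1]) for a, b in merged]
    events = _grid_consistent(events, est.period_s)
    # enforce one event per cycle, keeping the earlier on a near-tie
    min_spacing = 0.5 * est.period_s
    kept: list[float] = []
    for e in events:
        if not kept or e - kept[-1] >= min_spacing:
            kept.append(e)
    est.ee_times_s = np.asarray(kept)
    return est.ee_times_s


def phase_from_events(
    t: np.ndarray, ee_times: np.ndarray, period_s: float
) -> np.ndarray:
    """Continuous respiratory phase tracked from end-expiration events.

    Phase is 0 at each event and advances linearly to 1 at the next; outside
    the detected events it is extrapolated at the nominal period.  Returns
    the cycle fraction in [0, 1) per sample.
    """
    t = np.asarray(t, dtype=float)
    ee = np.asarray(ee_times, dtype=float)
    if ee.size == 0:
        raise ValueError("phase tracking needs at least one end-expiration event")
    if ee.size == 1:
        cycles = (t - ee[0]) / period_s
    else:
        cycles = np.interp(t, ee, np.arange(ee.size, dtype=float))
        left = t < ee[0]
        right = t > ee[-1]
        cycles[left] = (t[left] - ee[0]) / period_s
        cycles[right] = (ee.size - 1) + (t[right] - ee[-1]) / period_s
    return np.mod(cycles, 1.0)


def cycle_template(
    osc: np.ndarray, phase: np.ndarray, mask: np.ndarray, n_bins: int = 24
) -> np.ndarray:
    """Synchronous-average respiration waveform: per-phase-bin mean vectors.

    ``osc`` is the oscillatory component of the position stream, ``phase`` the
    tracked cycle fraction, ``mask`` the (training) samples to average over.
    Empty bins are filled by circular linear interpolation.  Returns an
    (n_bins, 3) array of displacement means.
    """
    bins = np.clip((np.asarray(phase) * n_bins).astype(int), 0, n_bins - 1)
    tmpl = np.zeros((n_bins, 3))
    counts = np.zeros(n_bins)
    np.add.at(tmpl, bins[mask], osc[mask])
    np.add.at(counts, bins[mask], 1.0)
    filled = counts > 0
    if not filled.any():
        raise ValueError("no training samples to build a respiration template")
    if not filled.all():
        centers = (np.arange(n_bins) + 0.5) / n_bins
        for ax in range(3):
            tmpl[~filled, ax] = np.interp(
                centers[~filled], centers[filled],
                tmpl[filled, ax] / counts[filled], period=1.0,
            )
    tmpl[filled] /= counts[filled, None]
    return tmpl


def evaluate_template(tmpl: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Template displacement at each phase, circularly interpolated."""
    n_bins = tmpl.shape[0]
    centers = (np.arange(n_bins) + 0.5) / n_bins
    out = np.empty((np.asarray(phase).size, 3))
    for ax in range(3):
        out[:, ax] = np.interp(phase, centers, tmpl[:, ax], period=1.0)
    return out


def analyze_respiration(
    traj: Trajectory, training_end_s: Optional[float] = None
) -> RespirationEstimate:
    """Full respiration pipeline: period, end-expiration events, compensation.

    Period estimation and the moving-average split are restricted to / anchored
    on the initial quiescent window when ``training_end_s`` is given, keeping
    deliberate catheter movements during RF from corrupting them.  The final
    respiration estimate is a phase-locked cycle template (synchronous average
    of the oscillatory component over the training window) evaluated at the
    phase tracked from the detected end-expiration events: periodic motion is
    removed continuously while aperiodic movements pass to the compensated
    channel unsmoothed.  Reconstruction stays exact: resp + compensated ==
    raw per sample.
    """
    sub = traj
    if training_end_s is not None:
        sub = traj.slice_time(traj.t[0], training_end_s)
        if len(sub) < 16:
            sub = traj
    period = estimate_period(sub)
    base = decompose(traj, period)
    train = base.valid.copy()
    if training_end_s is not None and np.count_nonzero(
        train & (traj.t < training_end_s)
    ) * traj.dt >= (base.period_s or np.inf):
        train &= traj.t < training_end_s
    detect_end_expiration(base, traj.t, training_mask=train)
    if base.period_s is None or base.ee_times_s.size < 2:
        return base

    phase = phase_from_events(traj.t, base.ee_times_s, base.period_s)
    try:
        tmpl = cycle_template(base.resp_mm, phase, train)
    except ValueError:
        return base
    resp = evaluate_template(tmpl, phase)
    est = RespirationEstimate(
        resp_mm=resp,
        compensated_mm=traj.pos - resp,
        period_s=base.period_s,
        valid=base.valid,
        ee_times_s=base.ee_times_s,
        phase=phase,
    )
    return est
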