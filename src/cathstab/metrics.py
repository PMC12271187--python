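"""Session- and study-level metrics.

Covers the ablation-index surrogate and its time-to-target, gated-vs-Stability+
time-to-tag statistics, the overshoot fraction (sessions whose AI target is
reached before the gated tag would even display), and the study summary of
counts and percentages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import AiSurrogateParams, Mode
from .simulate import AblationSession


# ---------------------------------------------------------------- AI surrogate

def ai_value(
    t_rf_s: float | np.ndarray,
    force_g: float,
    power_w: float,
    params: Optional[AiSurrogateParams] = None,
) -> float | np.ndarray:
    """Surrogate ablation index after ``t_rf_s`` seconds of RF at F, P."""
    p = params or AiSurrogateParams()
    base = force_g**p.alpha * power_w**p.beta * np.asarray(t_rf_s, dtype=float)
    return p.k * base**p.gamma


def time_to_target(
    target: float,
    force_g: float,
    power_w: float,
    params: Optional[AiSurrogateParams] = None,
) -> float:
    """RF-on seconds needed to reach an AI target (closed-form inverse)."""
    p = params or AiSurrogateParams()
    return (target / p.k) ** (1.0 / p.gamma) / (force_g**p.alpha * power_w**p.beta)


def ai_accrual(
    session: AblationSession,
    params: Optional[AiSurrogateParams] = None,
    force_g: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """AI(t) over the session grid; AI accrues only while RF is on."""
    traj = session.trajectory
    if not traj.rf_on.any():
        raise ValueError("session has no RF-on samples")
    f = session.config.contact_force_g if force_g is None else force_g
    t_rf = np.cumsum(traj.rf_on) * traj.dt
    ai = ai_value(t_rf, f, float(session.config.power_w), params)
    return traj.t, np.asarray(ai)


def session_time_to_target(
    session: AblationSession,
    target: Optional[float] = None,
    params: Optional[AiSurrogateParams] = None,
) -> Optional[float]:
    """Seconds of RF needed for the session's AI target; None if unreachable."""
    tgt = session.config.ai_target if target is None else target
    need = time_to_target(
        tgt, session.config.contact_force_g, float(session.config.power_w), params
    )
    return need if need <= session.rf_duration_s + 1e-9 else None


# ------------------------------------------------------------------- overshoot

def overshoot_fraction(
    times_to_target: Sequence[float], reference_s: float, inclusive: bool = True
) -> float:
    """Fraction of sessions reaching the AI target within the reference time.

    These are the sessions that would already have delivered the target lesion
    before a tag with latency ``reference_s`` (the gated mean) displays — i.e.
    the operator would overshoot.  ``inclusive`` counts times equal to the
    reference ("within"); set False for a strict comparison.
    """
    times = np.asarray(list(times_to_target), dtype=float)
    if times.size == 0:
        raise ValueError("overshoot_fraction needs a nonempty list")
    hit = times <= reference_s if inclusive else times < reference_s
    return float(np.count_nonzero(hit)) / times.size


# ------------------------------------------------------------ time-to-tag stats

@dataclass
class TimeToTagStats:
    mean_s: float
    sd_s: float          # NaN when only one tagged session
    n_tagged: int
    n_no_tag: int


def time_to_tag_stats(times: Iterable[Optional[float]]) -> TimeToTagStats:
    """Mean/SD of time-to-tag over tagged sessions; no-tag counted separately.

    ``None`` entries are sessions that never produced a tag; they are never
    imputed into the mean.  Raises if no session tagged at all.
    """
    vals = [v for v in times if v is not None and not (isinstance(v, float) and math.isnan(v))]
    n_no = sum(1 for v in times if v is None or (isinstance(v, float) and math.isnan(v)))
    if not vals:
        raise ValueError("no tagged sessions")
    arr = np.asarray(vals, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return TimeToTagStats(float(arr.mean()), sd, arr.size, n_no)


# ---------------------------------------------------------------- study summary

def percentage(count: int, denominator: int, decimals: int = 0) -> float:
    """Percentage at the requested printed precision (int when decimals=0)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = round(100.0 * count / denominator, decimals)
    return int(pct) if decimals == 0 else pct


@dataclass
class ApplicationRecord:
    """One RF application's analysed outcome, the unit of the study summary."""

    mode: Mode
    unstable: bool
    pre_ablation_stable: bool
    ttt_splus_s: Optional[float] = None
    ttt_gated_s: Optional[float] = None
    time_to_ai_target_s: Optional[float] = None


@dataclass
class StudySummary:
    """Counts and percentages over a cohort of applications.

    Application shares are printed to one decimal, stability shares to the
    integer, matching the mixed precision of clinical summaries.
    """

    n_applications: int
    n_qmode: int
    n_qmode_plus: int
    pct_qmode: float
    pct_qmode_plus: float
    unstable_qmode: int
    unstable_qmode_plus: int
    pct_unstable_qmode: float
    pct_unstable_qmode_plus: float
    pre_ablation_stable: int
    pct_pre_ablation_stable: float
    pre_ablation_stable_qmode: int
    pct_pre_ablation_stable_qmode: float
    pre_ablation_stable_qmode_plus: int
    pct_pre_ablation_stable_qmode_plus: float
    mean_ttt_splus_s: Optional[float] = None
    sd_ttt_splus_s: Optional[float] = None
    mean_ttt_gated_s: Optional[float] = None
    sd_ttt_gated_s: Optional[float] = None
    n_no_tag_gated: int = 0
    overshoot_fraction: Optional[float] = None

    def to_json(self, **kwargs) -> str:
        def clean(v):
            return None if isinstance(v, float) and math.isnan(v) else v
        return json.dumps({k: clean(v) for k, v in asdict(self).items()},
                          indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [
            f"applications            {self.n_applications}",
            f"  QMODE                 {self.n_qmode} ({self.pct_qmode}%)",
            f"  QMODE+                {self.n_qmode_plus} ({self.pct_qmode_plus}%)",
            f"unstable QMODE          {self.unstable_qmode} ({self.pct_unstable_qmode}%)",
            f"unstable QMODE+         {self.unstable_qmode_plus} ({self.pct_unstable_qmode_plus}%)",
            f"pre-ablation stable     {self.pre_ablation_stable} ({self.pct_pre_ablation_stable}%)",
            f"  QMODE                 {self.pre_ablation_stable_qmode} ({self.pct_pre_ablation_stable_qmode}%)",
            f"  QMODE+                {self.pre_ablation_stable_qmode_plus} ({self.pct_pre_ablation_stable_qmode_plus}%)",
        ]
        if self.mean_ttt_splus_s is not None:
            lines.append(f"time-to-tag Stability+  {self.mean_ttt_splus_s:.1f} +/- "
                         f"{(self.sd_ttt_splus_s or float('nan')):.1f} s")
        if self.mean_ttt_gated_s is not None:
            lines.append(f"time-to-tag Gated       {self.mean_ttt_gated_s:.1f} +/- "
                         f"{(self.sd_ttt_gated_s or float('nan')):.1f} s "
                         f"(no tag: {self.n_no_tag_gated})")
        if self.overshoot_fraction is not None:
            lines.append(f"overshoot fraction      {100 * self.overshoot_fraction:.0f}%")
        return "\n".join(lines)


def summary_from_counts(
    n_qmode: int,
    n_qmode_plus: int,
    unstable_qmode: int,
    unstable_qmode_plus: int,
    pre_stable_qmode: int,
    pre_stable_qmode_plus: int,
) -> StudySummary:
    """Study summary straight from counts (worked-example arithmetic)."""
    n = n_qmode + n_qmode_plus
    pre = pre_stable_qmode + pre_stable_qmode_plus
    return StudySummary(
        n_applications=n,
        n_qmode=n_qmode,
        n_qmode_plus=n_qmode_plus,
        pct_qmode=percentage(n_qmode, n, 1),
        pct_qmode_plus=percentage(n_qmode_plus, n, 1),
        unstable_qmode=unstable_qmode,
        unstable_qmode_plus=unstable_qmode_plus,
        pct_unstable_qmode=percentage(unstable_qmode, n_qmode, 1),
        pct_unstable_qmode_plus=percentage(unstable_qmode_plus, n_qmode_plus, 1),
        pre_ablation_stable=pre,
        pct_pre_ablation_stable=percentage(pre, n, 0),
        pre_ablation_stable_qmode=pre_stable_qmode,
        pct_pre_ablation_stable_qmode=percentage(pre_stable_qmode, n_qmode, 0),
        pre_ablation_stable_qmode_plus=pre_stable_qmode_plus,
        pct_pre_ablation_stable_qmode_plus=percentage(pre_stable_qmode_plus, n_qmode_plus, 0),
    )


def summarize_study(
    records: Sequence[ApplicationRecord],
    overshoot_reference_s: Optional[float] = None,
    overshoot_inclusive: bool = True,
) -> StudySummary:
    """Aggregate per-application records into the study summary.

    The overshoot fraction is computed over QMODE applications with a finite
    AI-target time, against ``overshoot_reference_s`` (defaulting to the
    gated mean time-to-tag of the cohort).
    """
    if not records:
        raise ValueError("summarize_study needs at least one application")
    q = [r for r in records if r.mode is Mode.QMODE]
    qp = [r for r in records if r.mode is Mode.QMODE_PLUS]
    summary = summary_from_counts(
        n_qmode=len(q),
        n_qmode_plus=len(qp),
        unstable_qmode=sum(r.unstable for r in q),
        unstable_qmode_plus=sum(r.unstable for r in qp),
        pre_stable_qmode=sum(r.pre_ablation_stable for r in q),
        pre_stable_qmode_plus=sum(r.pre_ablation_stable for r in qp),
    )

    splus = [r.ttt_splus_s for r in records]
    if any(v is not None for v in splus):
        st = time_to_tag_stats(splus)
        summary.mean_ttt_splus_s, summary.sd_ttt_splus_s = st.mean_s, st.sd_s
    gated = [r.ttt_gated_s for r in records]
    if any(v is not None for v in gated):
        st = time_to_tag_stats(gated)
        summary.mean_ttt_gated_s, summary.sd_ttt_gated_s = st.mean_s, st.sd_s
        summary.n_no_tag_gated = st.n_no_tag
    else:
        summary.n_no_tag_gated = sum(1 for v in gated if v is None)

    ai_times = [r.time_to_ai_target_s for r in q if r.time_to_ai_target_s is not None]
    ref = overshoot_reference_s
    if ref is None:
        ref = summary.mean_ttt_gated_s
    if ai_times and ref is not None:
        summary.overshoot_fraction = overshoot_fraction(
            ai_times, ref, overshoot_inclusive
        )
    return summary
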