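"""End-to-end analysis: respiration -> algorithms -> per-application record.

Also hosts the Monte-Carlo cohort runner used by the ``study`` command: it
draws per-application respiratory rate, contact force, wall target and
occasional instability events, simulates each application, runs both
algorithms and aggregates the study summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import Field

from .config import (
    AiSurrogateParams,
    GatedParams,
    Mode,
    MovementEvent,
    RespirationConfig,
    SessionConfig,
    StabilityPlusParams,
    StrictModel,
)
from .gated import gated_time_to_tag, gated_verdicts
from .metrics import (
    ApplicationRecord,
    StudySummary,
    session_time_to_target,
    summarize_study,
    time_to_target,
)
from .respiration import RespirationEstimate, analyze_respiration
from .simulate import AblationSession, simulate_session
from .stability_plus import StabilityPlusResult, splus_tags
from .tags import TagEvent


@dataclass
class SessionAnalysis:
    session: AblationSession
    respiration: RespirationEstimate
    gated_tags: list[TagEvent]
    splus: Optional[StabilityPlusResult]
    record: ApplicationRecord

    @property
    def all_tags(self) -> list[TagEvent]:
        return self.gated_tags + (self.splus.tags if self.splus else [])


def analyze_session(
    session: AblationSession,
    algorithms: tuple[str, ...] = ("gated", "splus"),
    gated_params: Optional[GatedParams] = None,
    splus_params: Optional[StabilityPlusParams] = None,
    ai_params: Optional[AiSurrogateParams] = None,
) -> SessionAnalysis:
    """Run the respiration estimator and the requested algorithms."""
    est = analyze_respiration(session.trajectory, training_end_s=session.t_rf_start)
    gated_out: list[TagEvent] = []
    splus_out: Optional[StabilityPlusResult] = None
    if "gated" in algorithms:
        gated_out = gated_verdicts(
            session.trajectory, est.ee_times_s, session.t_rf_start,
            session.t_rf_end, gated_params,
        )
    if "splus" in algorithms:
        splus_out = splus_tags(session, est, splus_params)
    record = ApplicationRecord(
        mode=session.config.mode,
        unstable=splus_out.unstable_during_rf if splus_out else False,
        pre_ablation_stable=splus_out.pre_ablation_stable if splus_out else False,
        ttt_splus_s=splus_out.time_to_tag_s if splus_out else None,
        ttt_gated_s=gated_out[0].time_to_tag_s if gated_out else None,
        time_to_ai_target_s=session_time_to_target(session, 350.0, ai_params),
    )
    return SessionAnalysis(session, est, gated_out, splus_out, record)


class CohortConfig(StrictModel):
    """A simulated study cohort: how many applications per mode and the
    per-application parameter distributions.

    Each application draws its respiratory rate uniformly from
    ``rate_bpm_range`` (the clinical ventilation setting), its contact force
    from ``force_g_range`` (driving the AI accrual speed), a posterior or
    anterior wall target, and — with probability ``p_unstable`` — one
    sustained displacement event during RF.
    """

    n_qmode: int = Field(default=40, ge=0)
    n_qmode_plus: int = Field(default=8, ge=0)
    seed: int = 0
    rate_bpm_range: tuple[float, float] = (10.0, 12.0)
    force_g_range: tuple[float, float] = (6.0, 25.0)
    p_posterior: float = Field(default=0.5, ge=0, le=1)
    p_unstable: float = Field(default=0.08, ge=0, le=1)
    unstable_displacement_mm: float = Field(default=6.0, gt=0)
    jitter_sd_mm: float = Field(default=0.15, ge=0)
    sample_rate_hz: float = Field(default=60.0, gt=0)
    gated: GatedParams = Field(default_factory=GatedParams)
    splus: StabilityPlusParams = Field(default_factory=StabilityPlusParams)
    ai: AiSurrogateParams = Field(default_factory=AiSurrogateParams)


def _draw_session(
    cohort: CohortConfig, mode: Mode, rng: np.random.Generator, seed: int
) -> SessionConfig:
    rate = rng.uniform(*cohort.rate_bpm_range)
    force = rng.uniform(*cohort.force_g_range)
    posterior = rng.uniform() < cohort.p_posterior
    ai_target = 350.0 if posterior else 500.0
    if mode is Mode.QMODE_PLUS:
        rf = float(rng.uniform(3.0, 4.0))
    else:
        # AI-guided: RF runs until the (surrogate) target is reached
        rf = time_to_target(ai_target, force, 50.0, cohort.ai)
    movements: list[MovementEvent] = []
    cfg = SessionConfig(
        mode=mode,
        ai_target=ai_target,
        rf_duration_s=rf,
        sample_rate_hz=cohort.sample_rate_hz,
        respiration=RespirationConfig(rate_bpm=rate, phase0=None),
        jitter_sd_mm=cohort.jitter_sd_mm,
        contact_force_g=force,
        seed=seed,
    )
    if rng.uniform() < cohort.p_unstable:
        # a sustained drag away from the site, some time into RF
        t0 = cfg.t_rf_start + rng.uniform(0.2, max(0.3, 0.5 * rf))
        d = cohort.unstable_displacement_mm
        u = rng.normal(size=3)
        u = u / np.linalg.norm(u) * d
        movements.append(
            MovementEvent(
                t_start=float(t0),
                duration=float(max(cfg.total_duration_s - t0 - 0.3, 0.5)),
                displacement_mm=tuple(u),
                return_to_origin=False,
            )
        )
        cfg = cfg.model_copy(update={"movements": movements})
    return cfg


def run_study(cohort: CohortConfig) -> tuple[StudySummary, list[SessionAnalysis]]:
    """Simulate and analyse a full cohort, returning summary and per-session
    analyses."""
    n_total = cohort.n_qmode + cohort.n_qmode_plus
    if n_total == 0:
        raise ValueError("cohort has no applications")
    rng = np.random.default_rng(cohort.seed)
    analyses: list[SessionAnalysis] = []
    modes = [Mode.QMODE] * cohort.n_qmode + [Mode.QMODE_PLUS] * cohort.n_qmode_plus
    for i, mode in enumerate(modes):
        seed = int(rng.integers(0, 2**31 - 1))
        cfg = _draw_session(cohort, mode, rng, seed)
        session = simulate_session(cfg)
        analyses.append(
            analyze_session(
                session,
                gated_params=cohort.gated,
                splus_params=cohort.splus,
                ai_params=cohort.ai,
            )
        )
    summary = summarize_study([a.record for a in analyses])
    return summary, analyses
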