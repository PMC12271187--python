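"""Configuration models for simulation, algorithms, and study runs.

All models are strict pydantic models: unknown keys are rejected, so a saved
configuration re-validates byte-for-byte and silent typos cannot change a run.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

Vec3 = tuple[float, float, float]

#: rise/fall time of injected movement events (s); half-cosine ramps avoid
#: unphysical velocity steps at event boundaries
MOVEMENT_RAMP_S = 0.2

#: fraction of each respiratory cycle spent on the end-expiration plateau of
#: the asymmetric waveform (expiratory dwell dominates clinically)
PLATEAU_FRACTION = 0.4


class Waveform(str, enum.Enum):
    SINUSOID = "sinusoid"
    ASYMMETRIC_PLATEAU = "asymmetric_plateau"


class Mode(str, enum.Enum):
    """RF power modes: 50 W ablation-index guided vs 90 W for 3-4 s (vHPSD)."""

    QMODE = "QMODE"
    QMODE_PLUS = "QMODE_PLUS"


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class RespirationConfig(StrictModel):
    """Respiration-driven catheter-tip motion.

    ``amplitude_mm`` is the peak-to-peak excursion per axis; the principal
    respiratory axis is whichever component is largest.  ``phase0`` is the
    respiratory phase at t=0 (cycle fraction in [0, 1), 0 = end-expiration
    plateau centre); ``None`` draws it uniformly, which is how a cohort with
    ablation onset uniform over the respiratory cycle is produced.
    """

    rate_bpm: float = Field(default=10.0, gt=0)
    amplitude_mm: Vec3 = (2.0, 3.0, 6.0)
    waveform: Waveform = Waveform.ASYMMETRIC_PLATEAU
    period_jitter_frac: float = Field(default=0.02, ge=0, lt=0.5)
    phase0: Optional[float] = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "RespirationConfig":
        if any(a < 0 for a in self.amplitude_mm):
            raise ValueError("amplitude components must be >= 0")
        if self.phase0 is not None and self.phase0 >= 1.0:
            raise ValueError("phase0 must lie in [0, 1)")
        return self

    @property
    def period_s(self) -> float:
        return 60.0 / self.rate_bpm


class MovementEvent(StrictModel):
    """A sustained or transient catheter displacement.

    With ``return_to_origin`` the tip ramps back to its pre-event position
    right after ``duration`` (the brief move-and-return excursion that thermal
    latency forgives); otherwise the displacement persists to the end of the
    trajectory.
    """

    t_start: float = Field(ge=0)
    duration: float = Field(gt=0)
    displacement_mm: Vec3
    return_to_origin: bool = True

    @property
    def footprint_end(self) -> float:
        """Last instant at which the event can still move the catheter."""
        return self.t_start + self.duration


class SessionConfig(StrictModel):
    """One ablation application: timeline, power mode, and motion model.

    The timeline is ``[0, training_s)`` mapping/training, then ``pre_ablation_s``
    of irrigation, then ``rf_duration_s`` of RF-on, then ``post_rf_s`` of
    trailing samples.  ``training_s`` defaults to two nominal respiratory
    cycles so the respiration estimator always has a full training window.
    """

    mode: Mode = Mode.QMODE
    power_w: Optional[float] = Field(default=None, gt=0)
    ai_target: float = Field(default=350.0, gt=0)
    rf_duration_s: Optional[float] = Field(default=None, gt=0)
    pre_ablation_s: float = Field(default=2.0, ge=0)
    post_rf_s: float = Field(default=0.5, ge=0)
    training_s: Optional[float] = Field(default=None, ge=0)
    sample_rate_hz: float = Field(default=60.0, gt=0)
    respiration: RespirationConfig = Field(default_factory=RespirationConfig)
    movements: list[MovementEvent] = Field(default_factory=list)
    jitter_sd_mm: float = Field(default=0.15, ge=0)
    baseline_mm: Vec3 = (0.0, 0.0, 0.0)
    contact_force_g: float = Field(default=10.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _fill_and_check(self) -> "SessionConfig":
        if self.power_w is None:
            object.__setattr__(
                self, "power_w", 90.0 if self.mode is Mode.QMODE_PLUS else 50.0
            )
        if self.rf_duration_s is None:
            object.__setattr__(
                self, "rf_duration_s", 3.5 if self.mode is Mode.QMODE_PLUS else 20.0
            )
        if self.training_s is None:
            object.__setattr__(self, "training_s", 2.0 * self.respiration.period_s)
        evs = sorted(self.movements, key=lambda e: e.t_start)
        for a, b in zip(evs, evs[1:]):
            if a.footprint_end > b.t_start:
                raise ValueError(
                    f"overlapping movement events at t={a.t_start:g} and t={b.t_start:g}"
                )
        return self

    @property
    def t_rf_start(self) -> float:
        return float(self.training_s) + self.pre_ablation_s

    @property
    def t_rf_end(self) -> float:
        return self.t_rf_start + float(self.rf_duration_s)

    @property
    def total_duration_s(self) -> float:
        return self.t_rf_end + self.post_rf_s


class GatedParams(StrictModel):
    """Legacy end-expiration gated stability detector.

    A tag requires ``min_ee_events`` consecutive end-expiration positions whose
    spread (distance for two events, SD of consecutive-pair distances beyond
    that) stays within ``d_max_mm``.  Motion between end-expiration instants is
    ignored by construction.
    """

    d_max_mm: float = Field(default=3.0, gt=0)
    min_ee_events: int = Field(default=2, ge=2)


class StabilityPlusParams(StrictModel):
    """Respiration-compensated continuous stability detector.

    A sample is stable iff the compensated tip lies within ``d_max_mm`` of the
    running centre of mass of its site AND moves slower than ``v_max_cm_s``
    (strict inequalities).  Unstable excursions shorter than
    ``latency_grace_s`` that return within ``return_radius_mm`` of the
    pre-excursion centre are forgiven (thermal latency: tissue keeps heating
    ~3 s after RF stops).  A tag is displayed after ``min_dwell_s`` of
    continuous stability.
    """

    v_max_cm_s: float = Field(default=2.5, gt=0)
    d_max_mm: float = Field(default=3.0, gt=0)
    latency_grace_s: float = Field(default=3.0, gt=0)
    return_radius_mm: Optional[float] = Field(default=None, gt=0)
    min_dwell_s: float = Field(default=2.0, gt=0)
    velocity_window_s: float = Field(default=0.2, gt=0)
    pre_ablation_window_s: float = Field(default=2.0, gt=0)

    @model_validator(mode="after")
    def _fill(self) -> "StabilityPlusParams":
        if self.return_radius_mm is None:
            object.__setattr__(self, "return_radius_mm", self.d_max_mm)
        return self


class AiSurrogateParams(StrictModel):
    """Configurable surrogate for the proprietary ablation index.

    AI(t) = k * (F^alpha * P^beta * t_rf)^gamma with F in grams, P in watts and
    t_rf the accumulated RF-on time in seconds.  The default constants are
    calibrated so that at 50 W / 10 g the 350 target is reached at 8 s and the
    500 target at 20 s, which concentrates simulated QMODE target times below
    the 9 s gated tag latency.
    """

    alpha: float = Field(default=0.68, gt=0)
    beta: float = Field(default=1.63, gt=0)
    gamma: float = Field(default=math.log(500.0 / 350.0) / math.log(20.0 / 8.0), gt=0)
    k: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _fill(self) -> "AiSurrogateParams":
        if self.k is None:
            object.__setattr__(self, "k", self._calibrate_k())
        return self

    def _calibrate_k(
        self, force_g: float = 10.0, power_w: float = 50.0,
        t_cal_s: float = 8.0, target: float = 350.0,
    ) -> float:
        base = force_g**self.alpha * power_w**self.beta * t_cal_s
        return target / base**self.gamma
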