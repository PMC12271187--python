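"""Trajectory container and CSV round-tripping.

A trajectory is a uniformly sampled stream of 3-D catheter-tip positions with
an RF-on flag per sample, optionally carrying simulator ground truth
(respiratory phase and respiration displacement) so downstream estimators can
be validated sample-by-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

_BASE_COLUMNS = ["t_s", "x_mm", "y_mm", "z_mm", "rf_on"]
_TRUTH_COLUMNS = ["phase_truth", "resp_x", "resp_y", "resp_z"]

#: decimal places used when writing CSV; round-trip is lossless at this grid
CSV_DECIMALS = 4


@dataclass
class Trajectory:
    t: np.ndarray                       # s, strictly increasing, uniform step
    pos: np.ndarray                     # (n, 3) mm
    rf_on: np.ndarray                   # (n,) bool
    phase_truth: Optional[np.ndarray] = None   # cycle fraction in [0, 1)
    resp_truth: Optional[np.ndarray] = None    # (n, 3) mm

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.rf_on = np.asarray(self.rf_on, dtype=bool)
        n = self.t.size
        if self.pos.shape != (n, 3) or self.rf_on.shape != (n,):
            raise ValueError("t, pos and rf_on must have matching lengths")
        if n >= 2:
            steps = np.diff(self.t)
            if steps.min() <= 0 or np.ptp(steps) > 1e-9:
                raise ValueError("timestamps must be strictly increasing and uniform")
        if not np.isfinite(self.pos).all():
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.dt

    def slice_time(self, t0: float, t1: float) -> "Trajectory":
        """Samples with t in the half-open window [t0, t1)."""
        m = (self.t >= t0) & (self.t < t1)
        return Trajectory(
            self.t[m], self.pos[m], self.rf_on[m],
            None if self.phase_truth is None else self.phase_truth[m],
            None if self.resp_truth is None else self.resp_truth[m],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t_s": self.t,
            "x_mm": self.pos[:, 0],
            "y_mm": self.pos[:, 1],
            "z_mm": self.pos[:, 2],
            "rf_on": self.rf_on.astype(int),
        }
        if self.phase_truth is not None:
            data["phase_truth"] = self.phase_truth
        if self.resp_truth is not None:
            data["resp_x"] = self.resp_truth[:, 0]
            data["resp_y"] = self.resp_truth[:, 1]
            data["resp_z"] = self.resp_truth[:, 2]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=f"%.{CSV_DECIMALS}f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        missing = [c for c in _BASE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table is missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("trajectory table is empty")
        phase = df["phase_truth"].to_numpy(float) if "phase_truth" in df.columns else None
        resp = None
        if {"resp_x", "resp_y", "resp_z"} <= set(df.columns):
            resp = df[["resp_x", "resp_y", "resp_z"]].to_numpy(float)
        t = df["t_s"].to_numpy(float)
        if t.size >= 2:
            # timestamps written at finite precision: snap back onto the
            # uniform grid when they are within rounding of one
            steps = np.diff(t)
            dt = float(t[-1] - t[0]) / (t.size - 1)
            if dt > 0 and np.abs(steps - dt).max() <= 1e-3 * max(dt, 1.0):
                t = t[0] + dt * np.arange(t.size)
        return cls(
            t=t,
            pos=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            rf_on=df["rf_on"].to_numpy().astype(bool),
            phase_truth=phase,
            resp_truth=resp,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"empty trajectory CSV: {path}") from exc
        return cls.from_frame(df)
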