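"""Ablation-site tag events and their tabular form.

Both algorithms emit the same tag-table schema; the ``algorithm`` column
distinguishes them.  Visual semantics (white first-site tag, instability
halo ring) are represented as boolean fields only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

TAG_COLUMNS = [
    "site_id", "t_tag_s", "x_mm", "y_mm", "z_mm", "stable", "algorithm",
    "t_start_s", "t_end_s", "first_site", "halo", "time_to_tag_s",
]


@dataclass
class TagEvent:
    """One ablation site: where it was tagged, when, and with what verdict."""

    site_id: int
    position_mm: tuple[float, float, float]
    t_tag_s: float
    t_start_s: float
    t_end_s: float
    algorithm: str
    time_to_tag_s: float
    first_site: bool = False
    halo: bool = False
    stable: bool = True


def tags_to_frame(tags: Iterable[TagEvent]) -> pd.DataFrame:
    rows = [
        {
            "site_id": tg.site_id,
            "t_tag_s": tg.t_tag_s,
            "x_mm": tg.position_mm[0],
            "y_mm": tg.position_mm[1],
            "z_mm": tg.position_mm[2],
            "stable": int(tg.stable),
            "algorithm": tg.algorithm,
            "t_start_s": tg.t_start_s,
            "t_end_s": tg.t_end_s,
            "first_site": int(tg.first_site),
            "halo": int(tg.halo),
            "time_to_tag_s": tg.time_to_tag_s,
        }
        for tg in tags
    ]
    return pd.DataFrame(rows, columns=TAG_COLUMNS)


def tags_to_csv(tags: Iterable[TagEvent], path: str | Path) -> None:
    tags_to_frame(tags).to_csv(path, index=False, float_format="%.4f")


def tags_from_csv(path: str | Path) -> list[TagEvent]:
    df = pd.read_csv(path)
    missing = [c for c in TAG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tag table is missing columns: {missing}")
    return [
        TagEvent(
            site_id=int(r.site_id),
            position_mm=(float(r.x_mm), float(r.y_mm), float(r.z_mm)),
            t_tag_s=float(r.t_tag_s),
            t_start_s=float(r.t_start_s),
            t_end_s=float(r.t_end_s),
            algorithm=str(r.algorithm),
            time_to_tag_s=float(r.time_to_tag_s),
            first_site=bool(r.first_site),
            halo=bool(r.halo),
            stable=bool(r.stable),
        )
        for r in df.itertuples()
    ]
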