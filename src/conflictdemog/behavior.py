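"""Behavioural rate indices from scan-sampling counts.

Scan sampling records all occurrences of courtship, female rejection and
male-male aggression across repeated sweeps of each vial; totals are turned
into hourly rates over the full observation window: courtship intensity as
courting events per female per hour, rejection and aggression as events per
hour.  Rejections per courtship conditions on courtship having occurred and
is undefined (absent) in vials with zero courtship.  Aggression is only
meaningful with more than one male, so it is absent under monogamy.  Total
matings are carried along as a count but never modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .records import ScanDataset, ScanRecord

__all__ = ["BehaviorIndices", "indices", "indices_table", "cell_summary"]


@dataclass(frozen=True)
class BehaviorIndices:
    vial_id: str
    temperature: float
    mating_system: str
    courtship_per_female_hour: float
    rejections_per_hour: float
    aggressions_per_hour: Optional[float]  # absent with a single male
    rejections_per_courtship: Optional[float]  # absent when courtship count is 0
    matings_total: int


def indices(scan: ScanRecord) -> BehaviorIndices:
    """Hourly rate indices for one vial."""
    hours = scan.observation_hours
    courtship = scan.counts.get("courtship", 0)
    rejection = scan.counts.get("rejection", 0)
    aggression = scan.counts.get("aggression", 0)
    return BehaviorIndices(
        vial_id=scan.vial_id,
        temperature=scan.temperature,
        mating_system=scan.mating_system,
        courtship_per_female_hour=courtship / (scan.n_females * hours),
        rejections_per_hour=rejection / hours,
        aggressions_per_hour=(aggression / hours) if scan.n_males > 1 else None,
        rejections_per_courtship=(rejection / courtship) if courtship > 0 else None,
        matings_total=scan.counts.get("mating", 0),
    )


_INDEX_COLS = [
    "courtship_per_female_hour",
    "rejections_per_hour",
    "aggressions_per_hour",
    "rejections_per_courtship",
]


def indices_table(scans: ScanDataset) -> pd.DataFrame:
    """One row of rate indices per vial."""
    rows = []
    for v in scans.vials:
        ix = indices(v)
        rows.append(
            {
                "vial_id": ix.vial_id,
                "temperature": ix.temperature,
                "mating_system": ix.mating_system,
                "courtship_per_female_hour": ix.courtship_per_female_hour,
                "rejections_per_hour": ix.rejections_per_hour,
                "aggressions_per_hour": np.nan if ix.aggressions_per_hour is None else ix.aggressions_per_hour,
                "rejections_per_courtship": np.nan
                if ix.rejections_per_courtship is None
                else ix.rejections_per_courtship,
                "matings_total": ix.matings_total,
            }
        )
    return pd.DataFrame(rows, columns=["vial_id", "temperature", "mating_system", *_INDEX_COLS, "matings_total"])


def cell_summary(scans: ScanDataset) -> pd.DataFrame:
    """Per (temperature, mating_system) mean +/- SEM of each index.

    The SEM is absent (NaN) for single-vial cells; absent per-vial values
    (aggression under monogamy, per-courtship with zero courtship) are
    dropped before averaging.
    """
    df = indices_table(scans)
    rows = []
    for (T, system), cell in df.groupby(["temperature", "mating_system"], sort=True):
        row: dict[str, object] = {"temperature": T, "mating_system": system, "n_vials": len(cell)}
        for col in _INDEX_COLS:
            vals = cell[col].dropna().astype(float)
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_sem"] = (
                float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
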