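"""Per-female fitness components and the relative-harm statistic H.

Overall lifetime reproductive success (LRS) is partitioned into early
reproductive rate (offspring in the first two weeks), reproductive aging
(offspring in weeks 3-4 minus weeks 1-2; negative values indicate
senescence) and actuarial aging (lifespan).  Relative harm is

    H = (W_mono - W_poly) / W_mono

where W is mean female fitness (LRS) in each mating-system arm: the
proportional decrease in female fitness attributable to elevated male
competition.  Uncertainty on H comes from a percentile bootstrap resampling
females within each arm.

Censored females (lost before death) are excluded from component summaries
and from H — the final analysed n counts only females followed to death —
but they remain in the records for life-table construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import CohortDataset, FemaleRecord, ObservationCalendar

__all__ = [
    "FitnessComponents",
    "HarmEstimate",
    "UndefinedStatisticError",
    "components",
    "components_table",
    "harm_index",
    "harm_by_temperature",
    "harm_ratio",
    "group_summary",
    "lifespan_decrease",
]

EARLY_LATE_BOUNDARY = 14.0  # day separating weeks 1-2 from weeks 3-4
LATE_WINDOW_END = 28.0


class UndefinedStatisticError(ZeroDivisionError):
    """A ratio statistic's denominator is zero (or a group is empty)."""


@dataclass(frozen=True)
class FitnessComponents:
    """One female's fitness partition; all fields absent when censored."""

    female_id: str
    lrs: Optional[int]
    early: Optional[int]
    late: Optional[int]
    repro_aging_score: Optional[int]  # late - early; negative = senescence
    lifespan: Optional[int]  # days; death_day


@dataclass(frozen=True)
class HarmEstimate:
    """Relative harm H at one temperature with bootstrap uncertainty."""

    temperature: float
    W_mono: float
    W_poly: float
    H: float
    ci_low: float
    ci_high: float
    n_mono: int
    n_poly: int
    n_boot: int
    seed: Optional[int]


def _interval_side(start: float, end: float) -> Optional[str]:
    """Attribute an interval to 'early'/'late' by its midpoint (unbiased for
    grids that straddle a week boundary by at most a couple of days)."""
    mid = (start + end) / 2.0
    if mid < EARLY_LATE_BOUNDARY:
        return "early"
    if mid < LATE_WINDOW_END:
        return "late"
    return None


def components(record: FemaleRecord, calendar: ObservationCalendar) -> FitnessComponents:
    """Compute the fitness partition for one female.

    Censored females return a shell with every component absent; they carry
    no complete lifetime observation.
    """
    if record.censored:
        return FitnessComponents(record.female_id, None, None, None, None, None)
    early = late = 0
    for count, start, end in zip(
        record.offspring_counts, calendar.interval_starts, calendar.interval_ends
    ):
        side = _interval_side(start, end)
        if side == "early":
            early += count
        elif side == "late":
            late += count
    lrs = int(sum(record.offspring_counts))
    return FitnessComponents(
        female_id=record.female_id,
        lrs=lrs,
        early=int(early),
        late=int(late),
        repro_aging_score=int(late - early),
        lifespan=record.death_day,
    )


def components_table(cohort: CohortDataset, drop_censored: bool = True) -> pd.DataFrame:
    """Long table of fitness components with treatment labels attached."""
    rows = []
    for r in cohort.records:
        if drop_censored and r.censored:
            continue
        c = components(r, cohort.calendar)
        rows.append(
            {
                "female_id": c.female_id,
                "temperature": r.temperature,
                "mating_system": r.mating_system,
                "lrs": c.lrs,
                "early": c.early,
                "late": c.late,
                "repro_aging": c.repro_aging_score,
                "lifespan": c.lifespan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "female_id",
            "temperature",
            "mating_system",
            "lrs",
            "early",
            "late",
            "repro_aging",
            "lifespan",
        ],
    )


def harm_index(
    mono: Sequence[FitnessComponents],
    poly: Sequence[FitnessComponents],
    n_boot: int = 2000,
    seed: Optional[int] = None,
    temperature: float = float("nan"),
) -> HarmEstimate:
    """Relative harm H = (W_mono - W_poly)/W_mono with a percentile bootstrap CI.

    Females are resampled with replacement within each arm (stratified), so
    the CI reflects sampling of females, not of offspring.
    """
    w_mono = np.array([c.lrs for c in mono if c.lrs is not None], dtype=float)
    w_poly = np.array([c.lrs for c in poly if c.lrs is not None], dtype=float)
    if w_mono.size == 0 or w_poly.size == 0:
        raise UndefinedStatisticError("both mating-system groups must be non-empty")
    W_mono = float(w_mono.mean())
    W_poly = float(w_poly.mean())
    if W_mono == 0:
        raise UndefinedStatisticError("H undefined: monogamy mean fitness is zero")
    H = (W_mono - W_poly) / W_mono

    rng = np.random.default_rng(seed)
    idx_m = rng.integers(0, w_mono.size, size=(n_boot, w_mono.size))
    idx_p = rng.integers(0, w_poly.size, size=(n_boot, w_poly.size))
    bm = w_mono[idx_m].mean(axis=1)
    bp = w_poly[idx_p].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hb = (bm - bp) / bm
    hb = hb[np.isfinite(hb)]
    lo, hi = (np.percentile(hb, [2.5, 97.5]) if hb.size else (np.nan, np.nan))
    return HarmEstimate(
        temperature=temperature,
        W_mono=W_mono,
        W_poly=W_poly,
        H=float(H),
        ci_low=float(lo),
        ci_high=float(hi),
        n_mono=int(w_mono.size),
        n_poly=int(w_poly.size),
        n_boot=int(n_boot),
        seed=seed,
    )


def harm_by_temperature(
    cohort: CohortDataset, n_boot: int = 2000, seed: Optional[int] = None
) -> list[HarmEstimate]:
    """One :class:`HarmEstimate` per temperature, with per-cell derived seeds."""
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    children = ss.spawn(len(cohort.temperatures))
    out = []
    for T, child in zip(cohort.temperatures, children):
        mono = [
            components(r, cohort.calendar)
            for r in cohort.records
            if r.temperature == T and r.mating_system == "monogamy" and not r.censored
        ]
        poly = [
            components(r, cohort.calendar)
            for r in cohort.records
            if r.temperature == T and r.mating_system == "polyandry" and not r.censored
        ]
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(harm_index(mono, poly, n_boot=n_boot, seed=sub_seed, temperature=T))
    return out


def harm_ratio(h_a: HarmEstimate, h_b: HarmEstimate) -> float:
    """Quotient of two harm estimates, on unrounded H values."""
    if h_b.H == 0:
        raise UndefinedStatisticError("harm ratio undefined: denominator H is zero")
    return h_a.H / h_b.H


def group_summary(cohort: CohortDataset) -> pd.DataFrame:
    """Per-cell mean +/- SEM of each fitness component over uncensored females."""
    df = components_table(cohort, drop_censored=True)
    rows = []
    temps = cohort.temperatures
    for T in temps:
        for system in ("monogamy", "polyandry"):
            cell = df[(df.temperature == T) & (df.mating_system == system)]
            row: dict[str, object] = {"temperature": T, "mating_system": system, "n": len(cell)}
            for comp in ("lrs", "early", "late", "repro_aging", "lifespan"):
                vals = cell[comp].dropna().astype(float)
                if len(vals) == 0:
                    row[f"{comp}_mean"] = np.nan
                    row[f"{comp}_sem"] = np.nan
                else:
                    row[f"{comp}_mean"] = float(vals.mean())
                    row[f"{comp}_sem"] = (
                        float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def lifespan_decrease(cohort: CohortDataset) -> pd.DataFrame:
    """Percent decrease in mean lifespan under polyandry, per temperature."""
    df = components_table(cohort, drop_censored=True)
    rows = []
    for T in cohort.temperatures:
        mono = df[(df.temperature == T) & (df.mating_system == "monogamy")]["lifespan"].dropna()
        poly = df[(df.temperature == T) & (df.mating_system == "polyandry")]["lifespan"].dropna()
        if len(mono) == 0 or float(mono.mean()) == 0:
            raise UndefinedStatisticError(f"no uncensored monogamy lifespans at {T} degC")
        dec = 100.0 * (mono.mean() - poly.mean()) / mono.mean()
        rows.append(
            {
                "temperature": T,
                "mean_lifespan_mono": float(mono.mean()),
                "mean_lifespan_poly": float(poly.mean()),
                "decrease_pct": float(dec),
            }
        )
    return pd.DataFrame(rows)
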