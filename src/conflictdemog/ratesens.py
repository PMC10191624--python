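"""Rate-sensitive fitness: discounted reproduction under background growth.

When a population grows or declines at intrinsic rate r, offspring produced
at age x contribute to fitness with weight exp(-r*x): early reproduction is
favoured in growing populations (r > 0), late reproduction gains weight in
declining ones (r < 0).  Two indices are computed on a grid of r values:

* individual fitness  omega_ind(r) = sum_j exp(-r*x_j) * c_j  over a
  female's collection intervals with counts c_j at midpoint ages x_j;
* population fitness  omega_pop(r) = sum_j exp(-r*x_j) * l_j * m_j  from a
  cohort life table with product-limit survivorship l and per-capita
  fecundity m.

The relative cost of polyandry is C_r = omega_pop(poly)/omega_pop(mono);
population costs are reported as 1 - C_r.  At r = 0, omega_ind is exactly
LRS, omega_pop is exactly mean LRS (absent censoring), and 1 - C_r equals
relative harm H.

r is interpreted per day on the interval-midpoint age axis; a different
time unit can be absorbed via ``time_scale`` (ages are multiplied by it
before discounting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitness import UndefinedStatisticError
from .records import CohortDataset, FemaleRecord, ObservationCalendar

__all__ = [
    "LifeTable",
    "RateSensitiveResult",
    "DEFAULT_R_GRID",
    "omega_individual",
    "omega_individual_table",
    "build_life_table",
    "omega_population",
    "relative_cost",
    "rate_sensitive_table",
]

DEFAULT_R_GRID: tuple[float, ...] = (-0.1, -0.05, 0.0, 0.05, 0.1)


@dataclass(frozen=True)
class LifeTable:
    """Cohort life table on the calendar's interval grid.

    ``x`` are interval midpoints (days); ``l`` is the product-limit
    probability of still being at risk at the interval's *start* (so that,
    absent censoring, ``l * n`` is exactly the number of females alive and
    ``sum(l*m)`` is exactly mean LRS); ``m`` is total offspring in the
    interval divided by the number at risk; ``n_risk`` the at-risk count.
    """

    x: tuple[float, ...]
    l: tuple[float, ...]
    m: tuple[float, ...]
    n_risk: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.l) == len(self.m) == len(self.n_risk) == n):
            raise ValueError("life-table columns must have equal length")
        if any(b > a + 1e-12 for a, b in zip(self.l, self.l[1:])):
            raise ValueError("survivorship must be non-increasing")
        if self.l and self.l[0] > 1 + 1e-12:
            raise ValueError("survivorship exceeds 1")
        if any(v < 0 for v in self.m):
            raise ValueError("fecundity must be non-negative")


def omega_individual(
    record: FemaleRecord,
    calendar: ObservationCalendar,
    r: float,
    time_scale: float = 1.0,
) -> float:
    """Discounted lifetime reproduction of one (uncensored) female."""
    if record.censored:
        raise UndefinedStatisticError(
            f"omega_ind undefined for censored female {record.female_id}"
        )
    mids = np.asarray(calendar.midpoints[: len(record.offspring_counts)]) * time_scale
    counts = np.asarray(record.offspring_counts, dtype=float)
    return float(np.sum(np.exp(-r * mids) * counts))


def omega_individual_table(
    cohort: CohortDataset, r_grid: Sequence[float] = DEFAULT_R_GRID, time_scale: float = 1.0
) -> pd.DataFrame:
    """Long table (female_id, temperature, mating_system, r, omega_ind)."""
    rows = []
    for rec in cohort.records:
        if rec.censored:
            continue
        for r in r_grid:
            rows.append(
                {
                    "female_id": rec.female_id,
                    "temperature": rec.temperature,
                    "mating_system": rec.mating_system,
                    "r": float(r),
                    "omega_ind": omega_individual(rec, cohort.calendar, r, time_scale),
                }
            )
    return pd.DataFrame(rows, columns=["female_id", "temperature", "mating_system", "r", "omega_ind"])


def _product_limit(durations: np.ndarray, died: np.ndarray):
    """Kaplan-Meier survivorship S(t) = P(T > t) at daily resolution.

    At a death day t the risk set is everyone with duration >= t (censoring
    tied with a death is treated as occurring after it, the standard
    convention).  Returns (death_days, S_after_each_death_day).
    """
    death_days = np.unique(durations[died])
    s = 1.0
    out = []
    for t in death_days:
        n_risk = int(np.sum(durations >= t))
        d = int(np.sum(durations[died] == t))
        s *= 1.0 - d / n_risk
        out.append(s)
    return death_days, np.asarray(out)


def build_life_table(group: Sequence[FemaleRecord], calendar: ObservationCalendar) -> LifeTable:
    """Product-limit life table for one treatment group.

    Survivorship ``l`` at each interval is the daily-resolution
    Kaplan-Meier estimate of P(still at risk) evaluated at the interval's
    start day (censored females leave the risk set at their censor day);
    absent censoring this is exactly the fraction of females entering the
    interval alive.  Fecundity ``m`` is the interval's total offspring among
    at-risk females divided by the at-risk count, so that at r = 0 and with
    no censoring ``sum(l*m)`` telescopes to the group's mean LRS exactly.
    """
    if not group:
        raise ValueError("cannot build a life table from an empty group")
    durations = np.array(
        [
            rec.end_of_observation
            if rec.end_of_observation is not None
            else calendar.reproductive_window_end + 10**6
            for rec in group
        ],
        dtype=float,
    )
    died = np.array([not rec.censored for rec in group])
    death_days, surv = _product_limit(durations, died)

    def km_at(t: float) -> float:
        # S(t): product over death days <= t
        k = int(np.searchsorted(death_days, t, side="right"))
        return float(surv[k - 1]) if k > 0 else 1.0

    xs, ls, ms, ns = [], [], [], []
    for j, (s, e) in enumerate(zip(calendar.interval_starts, calendar.interval_ends)):
        at_risk = [rec for rec, d in zip(group, durations) if d > s]
        n_risk = len(at_risk)
        total = sum(
            rec.offspring_counts[j] for rec in at_risk if j < len(rec.offspring_counts)
        )
        xs.append((s + e) / 2.0)
        ls.append(km_at(s))
        ms.append(total / n_risk if n_risk > 0 else 0.0)
        ns.append(n_risk)
    return LifeTable(tuple(xs), tuple(ls), tuple(ms), tuple(ns))


def omega_population(table: LifeTable, r: float, time_scale: float = 1.0) -> float:
    """Survivorship-weighted discounted fecundity of a cohort."""
    x = np.asarray(table.x) * time_scale
    return float(np.sum(np.exp(-r * x) * np.asarray(table.l) * np.asarray(table.m)))


@dataclass(frozen=True)
class RateSensitiveResult:
    """C_r and population cost across the r grid for one temperature."""

    temperature: float
    r_grid: tuple[float, ...]
    omega_pop_mono: tuple[float, ...]
    omega_pop_poly: tuple[float, ...]
    c_r: tuple[float, ...]
    pop_cost: tuple[float, ...]  # 1 - C_r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature": self.temperature,
                "r": self.r_grid,
                "omega_pop_mono": self.omega_pop_mono,
                "omega_pop_poly": self.omega_pop_poly,
                "c_r": self.c_r,
                "pop_cost": self.pop_cost,
            }
        )


def relative_cost(
    mono_table: LifeTable,
    poly_table: LifeTable,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
    temperature: float = float("nan"),
    time_scale: float = 1.0,
) -> RateSensitiveResult:
    """C_r(r) = omega_pop(poly)/omega_pop(mono) and pop_cost = 1 - C_r."""
    op_m, op_p, cr, cost = [], [], [], []
    for r in r_grid:
        wm = omega_population(mono_table, r, time_scale)
        wp = omega_population(poly_table, r, time_scale)
        if wm == 0:
            raise UndefinedStatisticError(f"omega_pop(monogamy) is zero at r={r}")
        op_m.append(wm)
        op_p.append(wp)
        cr.append(wp / wm)
        cost.append(1.0 - wp / wm)
    return RateSensitiveResult(
        temperature=temperature,
        r_grid=tuple(float(r) for r in r_grid),
        omega_pop_mono=tuple(op_m),
        omega_pop_poly=tuple(op_p),
        c_r=tuple(cr),
        pop_cost=tuple(cost),
    )


def rate_sensitive_table(
    cohort: CohortDataset, r_grid: Sequence[float] = DEFAULT_R_GRID, time_scale: float = 1.0
) -> pd.DataFrame:
    """Long per-temperature table of omega_pop, C_r and population cost."""
    frames = []
    for T in cohort.temperatures:
        mono = [r for r in cohort.records if r.temperature == T and r.mating_system == "monogamy"]
        poly = [r for r in cohort.records if r.temperature == T and r.mating_system == "polyandry"]
        res = relative_cost(
            build_life_table(mono, cohort.calendar),
            build_life_table(poly, cohort.calendar),
            r_grid,
            temperature=T,
            time_scale=time_scale,
        )
        frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)
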