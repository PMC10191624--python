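"""Data model and delimited-text I/O for longitudinal female records and scan observations.

The experimental unit is a single female followed from the first day of
cohabitation (day 0): offspring are collected per vial-flip interval during a
fixed reproductive window, after which survival alone is followed until death
or right-censoring (females lost during handling).  Scan observations are
per-vial all-occurrence behaviour counts over a stated observation window.

Day coordinates are integer offsets from experiment start.  Intervals are
half-open ``[start, end)``; an offspring count belongs to the vial the female
occupied when the eggs were laid.  A missing count for an interval in which a
female was alive and under observation is a validation error, not a zero:
zero and unobserved are distinct.
"""

from __future__ import annotations

import dataclasses
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

MATING_SYSTEMS = ("monogamy", "polyandry")

__all__ = [
    "MATING_SYSTEMS",
    "ObservationCalendar",
    "FemaleRecord",
    "CohortDataset",
    "ScanRecord",
    "ScanDataset",
    "Violation",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "read_scans",
    "write_scans",
]


class SchemaError(ValueError):
    """A required column is missing or malformed in an input file."""


class CohortValidationError(ValueError):
    """A record violates the cohort data model; the message names the female."""


@dataclass(frozen=True)
class ObservationCalendar:
    """Ordered, non-overlapping half-open collection intervals in days.

    Parameters
    ----------
    interval_starts, interval_ends
        Day offsets from experiment start; ``interval_starts[0]`` must be 0
        and consecutive intervals must tile without gaps or overlaps.
    reproductive_window_end
        Last day (exclusive) of offspring collection; intervals must not
        extend past it.  Survival follow-up continues beyond this day but is
        carried on the records, not the calendar.
    """

    interval_starts: tuple[int, ...]
    interval_ends: tuple[int, ...]
    reproductive_window_end: int = 42

    def __post_init__(self) -> None:
        starts, ends = self.interval_starts, self.interval_ends
        if len(starts) != len(ends) or not starts:
            raise ValueError("calendar needs equal, non-empty start/end lists")
        if starts[0] != 0:
            raise ValueError("first interval must start at day 0")
        for s, e in zip(starts, ends):
            if e <= s:
                raise ValueError(f"empty or inverted interval [{s}, {e})")
        for e, s_next in zip(ends, starts[1:]):
            if s_next < e:
                raise ValueError("intervals overlap")
        if ends[-1] > self.reproductive_window_end:
            raise ValueError("intervals extend past the reproductive window")

    @classmethod
    def twice_weekly(cls, window_end: int = 42) -> "ObservationCalendar":
        """The standard alternating 3/4-day vial-flip grid, e.g. [0,3), [3,7), ..."""
        starts, ends = [], []
        t, step = 0, 3
        while t < window_end:
            starts.append(t)
            ends.append(min(t + step, window_end))
            t += step
            step = 7 - step  # alternate 3 and 4
        return cls(tuple(starts), tuple(ends), window_end)

    @property
    def n_intervals(self) -> int:
        return len(self.interval_starts)

    @property
    def midpoints(self) -> tuple[float, ...]:
        return tuple(
            (s + e) / 2.0 for s, e in zip(self.interval_starts, self.interval_ends)
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(
            f"d{s}_{e}" for s, e in zip(self.interval_starts, self.interval_ends)
        )


@dataclass(frozen=True)
class FemaleRecord:
    """One female's treatment labels, interval offspring schedule and fate.

    ``offspring_counts`` has one entry per calendar interval the female
    entered alive (interval start strictly before her death/censor day);
    later intervals carry no entry.  ``death_day`` and ``censor_day`` are
    mutually exclusive.
    """

    female_id: str
    temperature: float
    mating_system: str
    offspring_counts: tuple[int, ...]
    death_day: Optional[int] = None
    censored: bool = False
    censor_day: Optional[int] = None

    @property
    def end_of_observation(self) -> Optional[int]:
        """Day the female left the experiment (death or censoring)."""
        return self.censor_day if self.censored else self.death_day

    def n_observed_intervals(self, calendar: ObservationCalendar) -> int:
        """Number of calendar intervals the female entered under observation."""
        end = self.end_of_observation
        if end is None:
            return calendar.n_intervals
        return sum(1 for s in calendar.interval_starts if s < end)

    @property
    def lrs(self) -> int:
        return int(sum(self.offspring_counts))


@dataclass
class CohortDataset:
    """A collection of :class:`FemaleRecord` sharing one observation calendar."""

    calendar: ObservationCalendar
    records: list[FemaleRecord]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, temperature=None, mating_system=None) -> "CohortDataset":
        recs = [
            r
            for r in self.records
            if (temperature is None or r.temperature == temperature)
            and (mating_system is None or r.mating_system == mating_system)
        ]
        return CohortDataset(self.calendar, recs, dict(self.provenance))

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted({r.temperature for r in self.records}))

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row-per-female table matching the on-disk layout."""
        cal = self.calendar
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "female_id": r.female_id,
                "temperature": r.temperature,
                "mating_system": r.mating_system,
                "death_day": r.death_day,
                "censored": int(r.censored),
                "censor_day": r.censor_day,
            }
            for j, lab in enumerate(cal.labels):
                row[lab] = r.offspring_counts[j] if j < len(r.offspring_counts) else None
            rows.append(row)
        cols = [
            "female_id",
            "temperature",
            "mating_system",
            "death_day",
            "censored",
            "censor_day",
            *cal.labels,
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class ScanRecord:
    """All-occurrence behaviour counts for one vial over an observation window."""

    vial_id: str
    temperature: float
    mating_system: str
    n_females: int
    n_males: int
    observation_hours: float
    n_scans: int
    counts: Mapping[str, int]  # behaviour -> count

    def __post_init__(self) -> None:
        if self.observation_hours <= 0:
            raise ValueError(f"vial {self.vial_id}: observation_hours must be > 0")
        if self.n_scans <= 0:
            raise ValueError(f"vial {self.vial_id}: n_scans must be > 0")
        if self.n_females < 1 or self.n_males < 1:
            raise ValueError(f"vial {self.vial_id}: need at least one fly of each sex")
        if self.counts.get("aggression", 0) > 0 and self.n_males == 1:
            raise CohortValidationError(
                f"vial {self.vial_id}: aggression recorded with a single male"
            )
        for k, v in self.counts.items():
            if v < 0:
                raise ValueError(f"vial {self.vial_id}: negative {k} count")


@dataclass
class ScanDataset:
    """Per-vial scan-sampling counts across treatment cells."""

    vials: list[ScanRecord]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.vials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.vials:
            rows.append(
                {
                    "vial_id": v.vial_id,
                    "temperature": v.temperature,
                    "mating_system": v.mating_system,
                    "n_females": v.n_females,
                    "n_males": v.n_males,
                    "observation_hours": v.observation_hours,
                    "n_scans": v.n_scans,
                    "courtship": v.counts.get("courtship", 0),
                    "rejection": v.counts.get("rejection", 0),
                    "aggression": v.counts.get("aggression", 0),
                    "mating": v.counts.get("mating", 0),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    female_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.female_id}: {self.message}"


def validate_cohort(dataset: CohortDataset) -> list[Violation]:
    """Check every record against the data model; violations are data, not exceptions."""
    out: list[Violation] = []
    cal = dataset.calendar
    seen: set[str] = set()
    for r in dataset.records:
        if r.female_id in seen:
            out.append(Violation(r.female_id, "duplicate female_id"))
        seen.add(r.female_id)
        if r.mating_system not in MATING_SYSTEMS:
            out.append(Violation(r.female_id, f"unknown mating_system {r.mating_system!r}"))
        if r.censored:
            if r.censor_day is None:
                out.append(Violation(r.female_id, "censored without censor_day"))
            if r.death_day is not None:
                out.append(Violation(r.female_id, "both death_day and censor_day present"))
        else:
            if r.censor_day is not None:
                out.append(Violation(r.female_id, "censor_day present but censored flag unset"))
        end = r.end_of_observation
        if end is not None and end <= cal.interval_starts[0]:
            out.append(Violation(r.female_id, f"death/censor day {end} precedes first interval"))
        for c in r.offspring_counts:
            if c < 0 or int(c) != c:
                out.append(Violation(r.female_id, f"offspring count {c!r} is not a non-negative integer"))
                break
        expected = r.n_observed_intervals(cal)
        if len(r.offspring_counts) > expected:
            out.append(
                Violation(r.female_id, "offspring counts present for intervals after death/censor")
            )
        elif len(r.offspring_counts) < expected:
            out.append(
                Violation(
                    r.female_id,
                    f"missing counts for {expected - len(r.offspring_counts)} observed interval(s)",
                )
            )
    return out


# ---------------------------------------------------------------------------
# cohort file I/O

_FIXED_COLUMNS = ["female_id", "temperature", "mating_system", "death_day", "censored", "censor_day"]
_COUNT_RE = re.compile(r"^d(\d+)_(\d+)$")


def _sniff_sep(path: Path) -> str:
    head = Path(path).open().readline()
    return "\t" if ("\t" in head and "," not in head) else ","


def read_cohort(
    path,
    schema: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> CohortDataset:
    """Load a cohort table (one row per female) into a validated :class:`CohortDataset`.

    Parameters
    ----------
    path
        Delimited text file; comma default, tab accepted.
    schema
        Optional map from the canonical column names
        (``female_id, temperature, mating_system, death_day, censored,
        censor_day``) to the names used in the file.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"female_id": str})
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    for col in _FIXED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    count_cols: list[tuple[int, int, str]] = []
    for col in df.columns:
        m = _COUNT_RE.match(str(col))
        if m:
            count_cols.append((int(m.group(1)), int(m.group(2)), col))
    count_cols.sort()
    if not count_cols:
        raise SchemaError("no interval count columns (d<start>_<end>) found")
    starts = tuple(s for s, _, _ in count_cols)
    ends = tuple(e for _, e, _ in count_cols)
    calendar = ObservationCalendar(starts, ends, reproductive_window_end=ends[-1])

    records: list[FemaleRecord] = []
    for idx, row in df.iterrows():
        fid = str(row["female_id"])
        censored = bool(int(row["censored"])) if pd.notna(row["censored"]) else False
        death_day = None if pd.isna(row["death_day"]) else int(row["death_day"])
        censor_day = None if pd.isna(row["censor_day"]) else int(row["censor_day"])
        counts: list[int] = []
        for _, _, col in count_cols:
            v = row[col]
            if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                continue
            fv = float(v)
            if fv < 0 or fv != int(fv):
                raise CohortValidationError(
                    f"row {idx} (female {fid}): invalid offspring count {v!r} in {col}"
                )
            counts.append(int(fv))
        records.append(
            FemaleRecord(
                female_id=fid,
                temperature=float(row["temperature"]),
                mating_system=str(row["mating_system"]),
                offspring_counts=tuple(counts),
                death_day=death_day,
                censored=censored,
                censor_day=censor_day,
            )
        )
    dataset = CohortDataset(calendar, records, provenance={"source": str(path)})
    problems = validate_cohort(dataset)
    if problems:
        raise CohortValidationError("; ".join(str(p) for p in problems[:10]))
    return dataset


def write_cohort(dataset: CohortDataset, path, sep: str = ",") -> Path:
    """Write a cohort as delimited text re-readable by :func:`read_cohort`."""
    path = Path(path)
    df = dataset.to_frame()
    df.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# scan file I/O

_SCAN_COLUMNS = [
    "vial_id",
    "temperature",
    "mating_system",
    "n_females",
    "n_males",
    "observation_hours",
    "n_scans",
    "courtship",
    "rejection",
    "aggression",
    "mating",
]


def read_scans(path, sep: Optional[str] = None) -> ScanDataset:
    """Load a per-vial scan-count table."""
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"vial_id": str})
    for col in _SCAN_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    vials = [
        ScanRecord(
            vial_id=str(row.vial_id),
            temperature=float(row.temperature),
            mating_system=str(row.mating_system),
            n_females=int(row.n_females),
            n_males=int(row.n_males),
            observation_hours=float(row.observation_hours),
            n_scans=int(row.n_scans),
            counts={
                "courtship": int(row.courtship),
                "rejection": int(row.rejection),
                "aggression": int(row.aggression),
                "mating": int(row.mating),
            },
        )
        for row in df.itertuples()
    ]
    return ScanDataset(vials, provenance={"source": str(path)})


def write_scans(dataset: ScanDataset, path, sep: str = ",") -> Path:
    path = Path(path)
    dataset.to_frame().to_csv(path, sep=sep, index=False)
    return path
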