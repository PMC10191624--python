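import numpy as np
import pytest

from conflictdemog import (
    CohortDataset,
    FemaleRecord,
    ObservationCalendar,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def weekly_calendar() -> ObservationCalendar:
    """Four exact weeks: [0,7), [7,14), [14,21), [21,28)."""
    return ObservationCalendar((0, 7, 14, 21), (7, 14, 21, 28), reproductive_window_end=28)


@pytest.fixture(scope="session")
def flip_calendar() -> ObservationCalendar:
    """The default twice-weekly 3/4-day grid over 42 days."""
    return ObservationCalendar.twice_weekly()


def make_record(
    counts,
    calendar,
    female_id="f1",
    temperature=24.0,
    mating_system="monogamy",
    death_day=None,
    censored=False,
    censor_day=None,
):
    if death_day is None and not censored:
        death_day = calendar.reproductive_window_end + 30
    return FemaleRecord(
        female_id=female_id,
        temperature=temperature,
        mating_system=mating_system,
        offspring_counts=tuple(counts),
        death_day=death_day,
        censored=censored,
        censor_day=censor_day,
    )


@pytest.fixture(scope="session")
def small_cohort(weekly_calendar) -> CohortDataset:
    """Hand-built two-cell cohort: 3 monogamy + 3 polyandry females at 24 degC."""
    recs = [
        make_record((10, 12, 8, 6), weekly_calendar, "m1", mating_system="monogamy", death_day=40),
        make_record((8, 10, 6, 4), weekly_calendar, "m2", mating_system="monogamy", death_day=35),
        make_record((12, 14, 10, 8), weekly_calendar, "m3", mating_system="monogamy", death_day=45),
        make_record((6, 8, 4, 2), weekly_calendar, "p1", mating_system="polyandry", death_day=30),
        make_record((4, 6, 2, 0), weekly_calendar, "p2", mating_system="polyandry", death_day=28),
        make_record((8, 8, 6, 4), weekly_calendar, "p3", mating_system="polyandry", death_day=33),
    ]
    return CohortDataset(weekly_calendar, recs)


@pytest.fixture(scope="session")
def simulated_cohort() -> CohortDataset:
    """A moderate no-harm simulated cohort shared across tests."""
    cfg = SimConfig(n_per_cell=40, seed=11, censor_prob=0.05)
    return simulate_cohort(cfg)
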