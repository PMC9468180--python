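import numpy as np
import pytest

from agestage import (
    Cohort,
    DailyObservation,
    IndividualRecord,
    ScenarioConfig,
    default_scenarios,
    generate_cohort,
)


def make_individual(ident, stages, eggs=None, prey=None, death_stage=None):
    """Build a record from a per-day stage list plus a terminal death day."""
    eggs = eggs or [0] * len(stages)
    prey = prey or [0] * len(stages)
    days = [
        DailyObservation(age=x, stage=s, alive=True, eggs_laid=e, prey_consumed=p)
        for x, (s, e, p) in enumerate(zip(stages, eggs, prey))
    ]
    days.append(
        DailyObservation(age=len(stages), stage=death_stage or stages[-1], alive=False)
    )
    return IndividualRecord(individual_id=ident, days=days)


@pytest.fixture
def toy_cohort():
    """Three hand-built individuals: a female, a preadult death, a male."""
    a = make_individual(
        "A",
        ["egg", "egg", "L1", "L2", "L3", "L4", "pupa", "female", "female", "female"],
        eggs=[0, 0, 0, 0, 0, 0, 0, 0, 10, 4],
        prey=[0, 0, 3, 5, 8, 20, 0, 30, 30, 28],
    )
    b = make_individual("B", ["egg", "egg", "L1"], prey=[0, 0, 2])
    c = make_individual(
        "C",
        ["egg", "egg", "L1", "L1", "L2", "L3", "L4", "pupa", "male", "male"],
        prey=[0, 0, 2, 3, 6, 9, 18, 0, 25, 24],
    )
    cohort = Cohort(label="toy", individuals=[a, b, c])
    cohort.validate()
    return cohort


def deterministic_config(**overrides):
    """All survivals 1, zero spread: every individual identical through preadult."""
    base = dict(
        label="det",
        n_01=6,
        duration_mean={"egg": 2, "L1": 3, "L2": 2, "L3": 2, "L4": 3, "pupa": 4},
        duration_sd={s: 0.0 for s in ("egg", "L1", "L2", "L3", "L4", "pupa")},
        survival={s: 1.0 for s in ("egg", "L1", "L2", "L3", "L4", "pupa")},
        sex_ratio_female=1.0,
        fecundity_total_mean=100.0,
        oviposition_days_mean=5.0,
        apop_mean=2.0,
        adult_longevity_mean={"female": 10.0, "male": 8.0},
        adult_longevity_sd={"female": 0.0, "male": 0.0},
        predation_daily_mean={"L1": 2.0, "L2": 4.0, "L3": 8.0, "L4": 16.0,
                              "female": 20.0, "male": 15.0},
        rng_seed=7,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture
def det_config():
    return deterministic_config()


@pytest.fixture(scope="session")
def cohort_25():
    """One seeded 50-individual synthetic cohort (25C scenario)."""
    cohort = generate_cohort(default_scenarios()[2], seed=2025)
    cohort.validate()
    return cohort


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()
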