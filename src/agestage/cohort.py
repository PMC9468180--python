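"""Daily individual life-history records for an age-stage, two-sex cohort study.

A cohort is a set of individuals followed daily from oviposition (age 0) to
death.  Each individual-day carries the developmental stage, an alive flag,
the number of eggs laid (females only) and the number of prey consumed.
These records are the raw material of the age-stage, two-sex life table: the
grid ``n_xj`` (number of individuals alive in stage ``j`` at age ``x``) is a
pure aggregation of them.

Census convention: an individual observed alive at the start of day ``x``
contributes to ``n_xj``; the death day itself is the first day *not* counted.
A day on which a moult is observed belongs to the new stage, so stage
durations are integral and additive.  Censoring is disallowed: every record
must end with exactly one terminal day flagged dead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StageOrder",
    "DEFAULT_STAGE_ORDER",
    "DailyObservation",
    "IndividualRecord",
    "Cohort",
    "AgeStageCounts",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "agestage_counts",
]

CSV_COLUMNS = ["individual_id", "age", "stage", "alive", "eggs_laid", "prey_consumed"]


class SchemaError(ValueError):
    """The file does not conform to the documented cohort CSV schema."""


class CohortValidationError(ValueError):
    """A record violates a life-history invariant (names individual and age)."""


class StageOrder:
    """Ordered life stages: preadult sequence plus terminal adult alternatives.

    ``female`` and ``male`` are both successors of the last preadult stage
    (pupa) and are absorbing: an adult never changes stage again.  ``beta``
    is the total number of stages.
    """

    def __init__(
        self,
        preadult: tuple[str, ...] = ("egg", "L1", "L2", "L3", "L4", "pupa"),
        adult: tuple[str, ...] = ("female", "male"),
    ):
        self.preadult = tuple(preadult)
        self.adult = tuple(adult)
        self.labels = self.preadult + self.adult
        self.index = {s: i for i, s in enumerate(self.labels)}
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate stage labels")

    @property
    def beta(self) -> int:
        return len(self.labels)

    @property
    def non_predatory(self) -> tuple[str, ...]:
        """Stages that never consume prey (egg and pupa)."""
        return ("egg", "pupa")

    def is_adult(self, stage: str) -> bool:
        return stage in self.adult

    def __repr__(self) -> str:  # pragma: no cover
        return f"StageOrder({'>'.join(self.labels)})"


DEFAULT_STAGE_ORDER = StageOrder()


@dataclass
class DailyObservation:
    """One individual-day: age x, stage j, alive flag, eggs laid, prey eaten."""

    age: int
    stage: str
    alive: bool
    eggs_laid: int = 0
    prey_consumed: int = 0


@dataclass
class IndividualRecord:
    """An individual's full daily life history.

    Days are consecutive ages starting at 0 (the focal egg's oviposition
    day); the stage sequence is monotone through the stage order; the last
    day is the (single) death day.
    """

    individual_id: str
    days: list[DailyObservation] = field(default_factory=list)

    def sorted_days(self) -> list[DailyObservation]:
        return sorted(self.days, key=lambda d: d.age)

    @property
    def lifespan(self) -> int:
        """Number of days observed alive."""
        return sum(1 for d in self.days if d.alive)

    def sex(self, stage_order: StageOrder = DEFAULT_STAGE_ORDER) -> str:
        """female/male if the individual reached adulthood, else undetermined."""
        for d in self.days:
            if d.alive and stage_order.is_adult(d.stage):
                return d.stage
        return "undetermined"

    def validate(self, stage_order: StageOrder = DEFAULT_STAGE_ORDER) -> None:
        ident = self.individual_id
        days = self.sorted_days()
        if not days:
            raise CohortValidationError(f"individual {ident!r}: no observations")
        ages = [d.age for d in days]
        if ages != list(range(len(days))):
            raise CohortValidationError(
                f"individual {ident!r}: ages must be consecutive integers from 0, got {ages}"
            )
        if not days[0].alive:
            raise CohortValidationError(f"individual {ident!r}: dead on day 0")
        if days[0].stage != stage_order.labels[0]:
            raise CohortValidationError(
                f"individual {ident!r}: must begin as {stage_order.labels[0]!r} at age 0"
            )
        if days[-1].alive:
            raise CohortValidationError(
                f"individual {ident!r}: record ends without a death day (censoring is disallowed)"
            )
        for d in days[:-1]:
            if not d.alive:
                raise CohortValidationError(
                    f"individual {ident!r}: dead flag before the terminal day (age {d.age})"
                )
        prev_idx = -1
        prev_stage = None
        for d in days:
            if d.stage not in stage_order.index:
                raise CohortValidationError(
                    f"individual {ident!r}: unknown stage {d.stage!r} at age {d.age}"
                )
            idx = stage_order.index[d.stage]
            if idx < prev_idx:
                raise CohortValidationError(
                    f"individual {ident!r}: stage regression "
                    f"{prev_stage}->{d.stage} at age {d.age}"
                )
            if (
                prev_stage is not None
                and stage_order.is_adult(prev_stage)
                and d.stage != prev_stage
            ):
                raise CohortValidationError(
                    f"individual {ident!r}: adult stage change "
                    f"{prev_stage}->{d.stage} at age {d.age}"
                )
            prev_idx, prev_stage = idx, d.stage
        for d in days:
            if d.eggs_laid < 0 or d.prey_consumed < 0:
                raise CohortValidationError(
                    f"individual {ident!r}: negative count at age {d.age}"
                )
            if int(d.eggs_laid) != d.eggs_laid or int(d.prey_consumed) != d.prey_consumed:
                raise CohortValidationError(
                    f"individual {ident!r}: non-integer count at age {d.age}"
                )
            if not d.alive and (d.eggs_laid or d.prey_consumed):
                raise CohortValidationError(
                    f"individual {ident!r}: eggs/prey recorded on the death day (age {d.age})"
                )
            if d.eggs_laid and d.stage != "female":
                raise CohortValidationError(
                    f"individual {ident!r}: eggs laid in stage {d.stage!r} at age {d.age}"
                )
            if d.prey_consumed and d.stage in stage_order.non_predatory:
                raise CohortValidationError(
                    f"individual {ident!r}: prey consumed in non-predatory stage "
                    f"{d.stage!r} at age {d.age}"
                )
        self.days = days


@dataclass
class Cohort:
    """A set of individual records sharing one scenario label (temperature)."""

    label: str | None
    individuals: list[IndividualRecord] = field(default_factory=list)
    stage_order: StageOrder = field(default_factory=StageOrder)

    @property
    def n_01(self) -> int:
        """Number of individuals at the beginning of the study."""
        return len(self.individuals)

    def validate(self) -> None:
        if self.n_01 < 1:
            raise CohortValidationError("cohort has no individuals")
        seen = set()
        for ind in self.individuals:
            if ind.individual_id in seen:
                raise CohortValidationError(f"duplicate individual id {ind.individual_id!r}")
            seen.add(ind.individual_id)
            ind.validate(self.stage_order)


@dataclass
class AgeStageCounts:
    """Dense ``n_xj`` grid: individuals alive in stage j at age x."""

    counts: np.ndarray  # (n_ages, beta) int
    n_01: int
    stage_order: StageOrder

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.counts.shape[0])


def agestage_counts(cohort: Cohort) -> AgeStageCounts:
    """Aggregate a cohort to the ``n_xj`` age-stage count grid.

    The grid extends to the maximum age at which any individual was alive;
    death days are not counted (census convention).  Invariant to individual
    ordering.
    """
    so = cohort.stage_order
    max_age = 0
    for ind in cohort.individuals:
        max_age = max(max_age, max((d.age for d in ind.days if d.alive), default=0))
    counts = np.zeros((max_age + 1, so.beta), dtype=np.int64)
    for ind in cohort.individuals:
        for d in ind.days:
            if d.alive:
                counts[d.age, so.index[d.stage]] += 1
    return AgeStageCounts(counts=counts, n_01=cohort.n_01, stage_order=so)


# ---------------------------------------------------------------------------
# CSV I/O.  Schema: UTF-8, header row with the canonical columns, one row per
# individual-day; metadata (scenario label, seed, ...) in "# key=value" lines
# before the header.
# ---------------------------------------------------------------------------

def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_cohort(path: str | Path, stage_order: StageOrder | None = None) -> Cohort:
    """Read and validate a cohort CSV (see module docstring for the schema).

    Row order in the file is irrelevant; ages are re-sorted per individual.
    """
    path = Path(path)
    stage_order = stage_order or DEFAULT_STAGE_ORDER
    meta = _read_metadata(path)
    try:
        df = pd.read_csv(path, comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in ("age", "alive", "eggs_laid", "prey_consumed"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col!r} must be integer") from exc
    bad_alive = ~df["alive"].isin([0, 1])
    if bad_alive.any():
        raise SchemaError(f"{path}: column 'alive' must be 0 or 1")
    individuals = []
    for ident, grp in df.groupby("individual_id", sort=True):
        days = [
            DailyObservation(
                age=int(r.age),
                stage=str(r.stage),
                alive=bool(r.alive),
                eggs_laid=int(r.eggs_laid),
                prey_consumed=int(r.prey_consumed),
            )
            for r in grp.itertuples()
        ]
        individuals.append(IndividualRecord(individual_id=str(ident), days=days))
    cohort = Cohort(label=meta.get("label"), individuals=individuals, stage_order=stage_order)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a cohort to CSV in canonical column order, one row per individual-day."""
    cohort.validate()
    path = Path(path)
    meta = {"label": cohort.label if cohort.label is not None else ""}
    if metadata:
        meta.update({str(k): str(v) for k, v in metadata.items()})
    rows = []
    for ind in cohort.individuals:
        for d in ind.sorted_days():
            rows.append(
                (ind.individual_id, d.age, d.stage, int(d.alive), d.eggs_laid, d.prey_consumed)
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    buf = io.StringIO()
    for key, val in meta.items():
        buf.write(f"# {key}={val}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path
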