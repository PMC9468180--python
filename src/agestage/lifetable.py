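"""Age-stage, two-sex life table: survival/fecundity schedules, population
parameters and per-cell life expectancy and reproductive value.

Notation (grids are age x by stage j):

* ``s_xj = n_xj / n_01`` -- probability a newborn is alive in stage j at age x
* ``l_x = sum_j s_xj`` -- age-specific survival
* ``m_x = sum_j s_xj f_xj / sum_j s_xj`` -- age-specific fecundity, with
  ``f_xj`` the mean daily eggs of (x, j) occupants (nonzero only for the
  female stage); both sexes and preadult deaths sit in the denominator
* ``R0 = sum_x l_x m_x`` -- net reproductive rate
* ``r`` -- intrinsic rate of increase, root of the Euler-Lotka equation
  ``sum_x exp(-r(x+1)) l_x m_x = 1`` (age indexed from 0)
* ``lambda = exp(r)``, ``T = ln(R0)/r`` -- finite rate and mean generation time
* ``e_xj`` / ``v_xj`` -- life expectancy and reproductive value per cell

The exponent convention ``exp(-r(x+1))`` is used consistently in the rate
solver and the reproductive-value grid; mixing conventions shifts ``r``
materially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from ._core import CohortArrays, UndefinedRateError, as_arrays
from .cohort import AgeStageCounts, Cohort, StageOrder, read_cohort

__all__ = [
    "AgeStageTable",
    "DemographyResult",
    "LifeTableModel",
    "LifeTableResults",
    "UndefinedRateError",
    "compute_sxj",
    "compute_lx",
    "compute_mx",
    "compute_R0",
    "solve_r",
    "compute_lambda",
    "compute_T",
    "compute_exj",
    "compute_vxj",
    "compute_fxj",
    "reproduction_summaries",
    "stage_summaries",
]


# ---------------------------------------------------------------------------
# Functional operations
# ---------------------------------------------------------------------------

def compute_sxj(counts: AgeStageCounts | np.ndarray, n_01: int | None = None) -> np.ndarray:
    """Age-stage survival grid s_xj = n_xj / n_01."""
    if isinstance(counts, AgeStageCounts):
        n_01 = counts.n_01 if n_01 is None else n_01
        grid = counts.counts
    else:
        grid = np.asarray(counts)
    if not n_01:
        raise ValueError("n_01 must be >= 1")
    return grid / float(n_01)


def compute_lx(s_xj: np.ndarray) -> np.ndarray:
    """Age-specific survival l_x = sum_j s_xj."""
    return np.asarray(s_xj).sum(axis=1)


def compute_mx(s_xj: np.ndarray, f_xj: np.ndarray) -> np.ndarray:
    """Age-specific fecundity; defined as 0 at ages where l_x = 0."""
    s_xj = np.asarray(s_xj, dtype=float)
    num = (s_xj * np.asarray(f_xj, dtype=float)).sum(axis=1)
    den = s_xj.sum(axis=1)
    return _core._safe_div(num, den)


def compute_R0(l_x: np.ndarray, m_x: np.ndarray) -> float:
    """Net reproductive rate R0 = sum_x l_x m_x."""
    return float(np.asarray(l_x) @ np.asarray(m_x))


def solve_r(l_x: np.ndarray, m_x: np.ndarray, tol: float = 1e-12) -> float:
    """Intrinsic rate of increase from the Euler-Lotka equation.

    Raises :class:`UndefinedRateError` when R0 = 0.  Negative rates are
    allowed (R0 in (0, 1) simply gives r < 0).
    """
    return _core.euler_lotka_rate(np.asarray(l_x) * np.asarray(m_x), tol=tol)


def compute_lambda(r: float) -> float:
    """Finite rate of increase lambda = e^r."""
    return math.exp(r)


def compute_T(R0: float, r: float) -> float:
    """Mean generation time T = ln(R0)/r (NaN when r = 0 or R0 <= 0)."""
    if R0 <= 0 or r == 0 or not math.isfinite(r):
        return math.nan
    return math.log(R0) / r


def compute_fxj(cohort: Cohort | CohortArrays) -> np.ndarray:
    """Mean daily eggs per occupant of each (x, j) cell (female column only)."""
    a = as_arrays(cohort)
    d = _core.demography(a, grids=True)
    return d["f_xj"]


def compute_exj(cohort: Cohort | CohortArrays) -> np.ndarray:
    """Age-stage life expectancy grid; NaN for cells never reached."""
    return _core.life_expectancy_grid(as_arrays(cohort))


def compute_vxj(cohort: Cohort | CohortArrays, r: float) -> np.ndarray:
    """Age-stage reproductive value grid; NaN for cells never reached."""
    a = as_arrays(cohort)
    f_xj = compute_fxj(a)
    return _core.reproductive_value_grid(a, r, f_xj)


@dataclass
class ReproductionSummary:
    F: float      # mean lifetime eggs per female
    Od: float     # mean number of laying days per female
    APOP: float   # adult pre-oviposition period (ovipositing females)
    TPOP: float   # total pre-oviposition period (ovipositing females)


def reproduction_summaries(cohort: Cohort | CohortArrays) -> ReproductionSummary:
    d = _core.demography(as_arrays(cohort), grids=False)
    return ReproductionSummary(F=d["F"], Od=d["Od"], APOP=d["APOP"], TPOP=d["TPOP"])


@dataclass
class StageSummary:
    duration_means: dict[str, float]   # days in stage, completers only
    longevity: dict[str, float]        # female/male adult and total longevity
    preadult_survival: float


def stage_summaries(cohort: Cohort | CohortArrays) -> StageSummary:
    d = _core.demography(as_arrays(cohort), grids=False)
    return StageSummary(
        duration_means=d["stage_durations"],
        longevity=d["longevity"],
        preadult_survival=d["preadult_survival"],
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class AgeStageTable:
    """Dense age-stage grids of the fitted life table."""

    stage_order: StageOrder
    s_xj: np.ndarray
    l_x: np.ndarray
    f_xj: np.ndarray
    m_x: np.ndarray
    e_xj: np.ndarray | None = None
    v_xj: np.ndarray | None = None

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.s_xj.shape[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per (age, stage) cell."""
        X, beta = self.s_xj.shape
        rows = {
            "age": np.repeat(np.arange(X), beta),
            "stage": np.tile(np.array(self.stage_order.labels), X),
            "s_xj": self.s_xj.ravel(),
            "f_xj": self.f_xj.ravel(),
        }
        if self.e_xj is not None:
            rows["e_xj"] = self.e_xj.ravel()
        if self.v_xj is not None:
            rows["v_xj"] = self.v_xj.ravel()
        return pd.DataFrame(rows)


@dataclass
class DemographyResult:
    """Scalar population parameters with optional bootstrap SEs."""

    R0: float
    r: float
    lambda_: float
    T: float
    F: float
    Od: float
    APOP: float
    TPOP: float
    preadult_survival: float
    stage_duration_means: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "R0": self.R0,
            "r": self.r,
            "lambda": self.lambda_,
            "T": self.T,
            "F": self.F,
            "Od": self.Od,
            "APOP": self.APOP,
            "TPOP": self.TPOP,
            "preadult_survival": self.preadult_survival,
        }


class LifeTableModel:
    """Age-stage, two-sex life table model for one cohort.

    Parameters
    ----------
    cohort
        A validated :class:`~agestage.cohort.Cohort` (or prebuilt arrays).

    Examples
    --------
    >>> from agestage import default_scenarios, generate_cohort, LifeTableModel
    >>> res = LifeTableModel(generate_cohort(default_scenarios()[0])).fit()
    >>> round(res.lambda_, 4) == round(math.exp(res.r), 4)
    True
    """

    def __init__(self, cohort: Cohort | CohortArrays):
        self.arrays = as_arrays(cohort)
        self.label = cohort.label if isinstance(cohort, Cohort) else None

    @classmethod
    def from_csv(cls, path) -> "LifeTableModel":
        return cls(read_cohort(path))

    def fit(self, tol: float = 1e-12, expectancy: bool = True) -> "LifeTableResults":
        d = _core.demography(self.arrays, tol=tol, grids=True)
        table = AgeStageTable(
            stage_order=self.arrays.stage_order,
            s_xj=d["s_xj"],
            l_x=d["l_x"],
            f_xj=d["f_xj"],
            m_x=d["m_x"],
        )
        if expectancy:
            table.e_xj = _core.life_expectancy_grid(self.arrays)
            if math.isfinite(d["r"]):
                table.v_xj = _core.reproductive_value_grid(self.arrays, d["r"], d["f_xj"])
        params = DemographyResult(
            R0=d["R0"],
            r=d["r"],
            lambda_=d["lambda"],
            T=d["T"],
            F=d["F"],
            Od=d["Od"],
            APOP=d["APOP"],
            TPOP=d["TPOP"],
            preadult_survival=d["preadult_survival"],
            stage_duration_means=d["stage_durations"],
        )
        return LifeTableResults(self, table, params, d)


class LifeTableResults:
    """Fitted life table: grids, population parameters and reporting."""

    def __init__(self, model: LifeTableModel, table: AgeStageTable,
                 params: DemographyResult, _raw: dict):
        self.model = model
        self.table = table
        self.params = params
        self._raw = _raw

    # convenient scalar accessors
    @property
    def R0(self) -> float: return self.params.R0
    @property
    def r(self) -> float: return self.params.r
    @property
    def lambda_(self) -> float: return self.params.lambda_
    @property
    def T(self) -> float: return self.params.T
    @property
    def F(self) -> float: return self.params.F
    @property
    def Od(self) -> float: return self.params.Od
    @property
    def APOP(self) -> float: return self.params.APOP
    @property
    def TPOP(self) -> float: return self.params.TPOP
    @property
    def preadult_survival(self) -> float: return self.params.preadult_survival
    @property
    def lxmx(self) -> np.ndarray: return self._raw["lxmx"]

    def bootstrap(self, B: int = 2000, seed: int | None = None):
        """Bootstrap SEs for the scalar parameters; attaches ``params.se``."""
        from .bootstrap import bootstrap_cohort, bootstrap_se

        dist = bootstrap_cohort(self.model.arrays, B=B, seed=seed)
        self.params.se = {name: bootstrap_se(vals) for name, vals in dist.params.items()}
        return dist

    def summary(self, round_days: int = 2, round_rates: int = 4) -> str:
        """Plain-text parameter table (rates to 4 dp, days/counts to 2 dp)."""
        rows = []
        rates = {"r", "lambda"}
        for name, val in self.params.as_dict().items():
            digits = round_rates if name in rates else round_days
            se = self.params.se.get(name)
            cell = f"{val:.{digits}f}" if math.isfinite(val) else "--"
            if se is not None and math.isfinite(se):
                cell += f" ± {se:.{digits}f}"
            rows.append((name, cell))
        label = self.model.label or "cohort"
        width = max(len(n) for n, _ in rows)
        lines = [f"Age-stage two-sex life table: {label} "
                 f"(n_01 = {self.model.arrays.n})", "-" * 44]
        lines += [f"{n:<{width}}  {c}" for n, c in rows]
        return "\n".join(lines)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(long age-stage table, one-row parameter table)."""
        long = self.table.to_frame()
        params = pd.DataFrame([self.params.as_dict()])
        return long, params

    def plot_survival_fecundity(self, ax=None):
        from .plotting import plot_survival_fecundity

        return plot_survival_fecundity(self, ax=ax)
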