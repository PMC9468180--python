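"""Predation-rate demography of a predator cohort.

Combines the prey-consumption records with the age-stage survival schedule:

* ``c_xj`` -- mean daily prey consumption of (x, j) occupants; the egg and
  pupa stages never feed, which produces the two characteristic gaps in the
  age curves
* ``k_x = sum_j s_xj c_xj / l_x`` -- survivor-averaged daily predation
* ``q_x = l_x k_x`` -- survivorship-weighted daily predation
* ``C0 = sum_x q_x`` -- net predation rate: lifetime prey consumed by an
  average cohort member, preadult deaths included
* ``Qp = C0 / R0`` -- transformation rate: prey needed per offspring
* ``a_xj`` -- stable age-stage distribution, ``a_xj ~ lambda^{-x} s_xj``
* ``psi = sum a_xj c_xj`` and ``omega = lambda * psi`` -- stable and finite
  predation rates of a population at the stable age-stage distribution
* ``D_j`` -- stage daily predation: prey eaten in stage j per individual-day
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from ._core import CohortArrays, as_arrays
from .cohort import Cohort, StageOrder
from .lifetable import LifeTableResults

__all__ = [
    "PredationTable",
    "PredationModel",
    "PredationResults",
    "compute_cxj",
    "compute_kx",
    "compute_qx",
    "compute_C0",
    "compute_Qp",
    "compute_sasd",
    "compute_psi_omega",
    "stage_daily_predation",
]


def compute_cxj(cohort: Cohort | CohortArrays) -> np.ndarray:
    """Mean daily predation of individuals in each (x, j) cell (0 when empty)."""
    d = _core.demography(as_arrays(cohort), grids=True)
    return d["c_xj"]


def compute_kx(s_xj: np.ndarray, c_xj: np.ndarray) -> np.ndarray:
    """Survivor-averaged predation k_x; 0 at ages with no survivors."""
    s_xj = np.asarray(s_xj, dtype=float)
    num = (s_xj * np.asarray(c_xj, dtype=float)).sum(axis=1)
    return _core._safe_div(num, s_xj.sum(axis=1))


def compute_qx(l_x: np.ndarray, k_x: np.ndarray) -> np.ndarray:
    """Survivorship-weighted predation q_x = l_x k_x (= sum_j s_xj c_xj)."""
    return np.asarray(l_x, dtype=float) * np.asarray(k_x, dtype=float)


def compute_C0(q_x: np.ndarray) -> float:
    """Net predation rate C0 = sum_x q_x (lifetime prey per average individual)."""
    return float(np.asarray(q_x).sum())


def compute_Qp(C0: float, R0: float) -> float:
    """Transformation rate Qp = C0 / R0 (prey per offspring produced).

    Defined as 0 for a cohort that never preys; NaN when R0 = 0.
    """
    if R0 > 0:
        return C0 / R0
    return 0.0 if C0 == 0 else math.nan


def compute_sasd(s_xj: np.ndarray, lam: float) -> np.ndarray:
    """Stable age-stage distribution a_xj ~ s_xj * lambda^{-x}, normalized.

    Truncated at the cohort's maximum observed age (s_xj = 0 beyond it).
    """
    if not lam > 0:
        raise ValueError("lambda must be > 0")
    s_xj = np.asarray(s_xj, dtype=float)
    decay = float(lam) ** (-np.arange(s_xj.shape[0], dtype=float))
    a = s_xj * decay[:, None]
    return a / a.sum()


def compute_psi_omega(a_xj: np.ndarray, c_xj: np.ndarray, lam: float) -> tuple[float, float]:
    """Stable predation rate psi = sum a_xj c_xj and finite rate omega = lambda*psi."""
    psi = float((np.asarray(a_xj) * np.asarray(c_xj)).sum())
    return psi, lam * psi


def stage_daily_predation(cohort: Cohort | CohortArrays) -> dict[str, float]:
    """D_j: prey eaten in stage j per individual-day, plus preadult/adult pools."""
    d = _core.demography(as_arrays(cohort), grids=False)
    return d["stage_daily_predation"]


@dataclass
class PredationTable:
    """Grids and scalars of the fitted predation analysis."""

    stage_order: StageOrder
    c_xj: np.ndarray
    k_x: np.ndarray
    q_x: np.ndarray
    a_xj: np.ndarray
    C0: float
    Qp: float
    psi: float
    omega: float
    D_j: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        X, beta = self.c_xj.shape
        return pd.DataFrame(
            {
                "age": np.repeat(np.arange(X), beta),
                "stage": np.tile(np.array(self.stage_order.labels), X),
                "c_xj": self.c_xj.ravel(),
                "a_xj": self.a_xj.ravel(),
            }
        )


class PredationModel:
    """Predation-rate analysis of a predator cohort.

    The stable-distribution statistics (a_xj, psi, omega) require the finite
    rate lambda; pass fitted :class:`LifeTableResults` to reuse them, or the
    model fits its own life table internally.
    """

    def __init__(self, cohort: Cohort | CohortArrays,
                 lifetable: LifeTableResults | None = None):
        self.arrays = as_arrays(cohort)
        self.label = cohort.label if isinstance(cohort, Cohort) else None
        self.lifetable = lifetable

    def fit(self) -> "PredationResults":
        d = _core.demography(self.arrays, grids=True)
        table = PredationTable(
            stage_order=self.arrays.stage_order,
            c_xj=d["c_xj"],
            k_x=d["k_x"],
            q_x=d["q_x"],
            a_xj=d["a_xj"],
            C0=d["C0"],
            Qp=d["Qp"],
            psi=d["psi"],
            omega=d["omega"],
            D_j=d["stage_daily_predation"],
        )
        return PredationResults(self, table, d)


class PredationResults:
    def __init__(self, model: PredationModel, table: PredationTable, _raw: dict):
        self.model = model
        self.table = table
        self._raw = _raw
        self.se: dict[str, float] = {}

    @property
    def C0(self) -> float: return self.table.C0
    @property
    def Qp(self) -> float: return self.table.Qp
    @property
    def psi(self) -> float: return self.table.psi
    @property
    def omega(self) -> float: return self.table.omega
    @property
    def D_j(self) -> dict[str, float]: return self.table.D_j

    def bootstrap(self, B: int = 2000, seed: int | None = None):
        from .bootstrap import bootstrap_cohort, bootstrap_se

        dist = bootstrap_cohort(self.model.arrays, B=B, seed=seed)
        self.se = {name: bootstrap_se(vals) for name, vals in dist.params.items()}
        return dist

    def summary(self) -> str:
        label = self.model.label or "cohort"
        rows = [("C0", self.C0, 2), ("Qp", self.Qp, 4),
                ("psi", self.psi, 4), ("omega", self.omega, 4)]
        lines = [f"Predation rates: {label}", "-" * 36]
        for name, val, dig in rows:
            cell = f"{val:.{dig}f}" if math.isfinite(val) else "--"
            se = self.se.get(name)
            if se is not None and math.isfinite(se):
                cell += f" ± {se:.{dig}f}"
            lines.append(f"{name:<6}{cell}")
        lines.append("stage daily predation D_j:")
        for stage, val in self.D_j.items():
            if math.isfinite(val) and val > 0:
                lines.append(f"  {stage:<10}{val:.2f}")
        return "\n".join(lines)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        long = self.table.to_frame()
        params = {"C0": self.C0, "Qp": self.Qp, "psi": self.psi, "omega": self.omega}
        params.update({f"D_{k}": v for k, v in self.D_j.items()})
        return long, pd.DataFrame([params])
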