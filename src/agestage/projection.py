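"""Deterministic day-by-day population and predation projection.

The cohort's empirical age-stage bookkeeping is turned into a projection
schedule: for every occupied (x, j) cell, the observed frequencies of moving
to each (x+1, y) cell (the remainder dying), the mean daily eggs f_xj and
the mean daily prey consumption c_xj.  Projection then iterates expected
(real-valued) masses:

* survivors/developers move along the observed transition frequencies,
* newborn eggs enter at (age 0, egg) on the next day (post-breeding census),
  N(t+1) new eggs = sum_xj f_xj n_xj(t),
* N(t) = sum_xj n_xj(t) and the predation potential P(t) = sum_xj c_xj
  n_xj(t).

No density dependence or prey depletion is modelled ("growth without
suppression").  Asymptotically the growth factor of N(t) equals the finite
rate lambda of the fitted life table and the composition converges to the
stable age-stage distribution a_xj; confidence bands come from re-projecting
the bootstrap resamples that attain the 2.5th/97.5th percentiles of lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from ._core import CohortArrays, as_arrays
from .cohort import Cohort, StageOrder

__all__ = [
    "ProjectionSchedule",
    "ProjectionResult",
    "build_schedule",
    "initial_vector",
    "project",
    "project_with_bands",
]


@dataclass
class ProjectionSchedule:
    """Daily survival/development frequencies with fecundity and predation."""

    stage_order: StageOrder
    transitions: np.ndarray   # (X-1, beta, beta): P((x,j) -> (x+1,y))
    f_xj: np.ndarray          # (X, beta) daily eggs per individual
    c_xj: np.ndarray          # (X, beta) daily prey per individual
    s_xj: np.ndarray          # (X, beta) cohort schedule (for stable-dist checks)
    first_adult_age: dict[str, int]  # first observed adult age per sex

    @property
    def max_age(self) -> int:
        return self.f_xj.shape[0] - 1


def build_schedule(cohort: Cohort | CohortArrays) -> ProjectionSchedule:
    """Estimate transition frequencies and daily rates from a cohort."""
    a = as_arrays(cohort)
    X, beta = a.X, a.stage_order.beta
    trans = np.zeros((max(X - 1, 0), beta, beta))
    cur = a.stage_idx[:, :-1]
    nxt = a.stage_idx[:, 1:]
    both = (cur >= 0) & (nxt >= 0)
    ages = np.broadcast_to(np.arange(X - 1), cur.shape)
    np.add.at(
        trans,
        (ages[both], cur[both].astype(np.int64), nxt[both].astype(np.int64)),
        1.0,
    )
    occ = np.zeros((max(X - 1, 0), beta))
    alive = cur >= 0
    np.add.at(occ, (ages[alive], cur[alive].astype(np.int64)), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(occ[:, :, None] > 0, trans / occ[:, :, None], 0.0)

    d = _core.demography(a, grids=True)
    first_adult = {}
    for name in a.stage_order.adult:
        j = a.stage_order.index[name]
        ages_j = np.nonzero(d["count_xj"][:, j] > 0)[0]
        first_adult[name] = int(ages_j[0]) if len(ages_j) else -1
    return ProjectionSchedule(
        stage_order=a.stage_order,
        transitions=trans,
        f_xj=d["f_xj"],
        c_xj=d["c_xj"],
        s_xj=d["s_xj"],
        first_adult_age=first_adult,
    )


def initial_vector(
    schedule: ProjectionSchedule,
    pairs: int = 10,
    as_eggs: bool = False,
) -> np.ndarray:
    """Initial age-stage mass for "N pairs" of adults (or 2N newly laid eggs).

    Adults are placed at their sex's first observed adult age; with
    ``as_eggs`` the same head count enters as age-0 eggs instead (the study
    does not define "pairs" in age terms, so both are offered).
    """
    so = schedule.stage_order
    init = np.zeros_like(schedule.f_xj)
    if as_eggs:
        init[0, so.index["egg"]] = 2.0 * pairs
        return init
    for name in so.adult:
        age = schedule.first_adult_age[name]
        if age < 0:
            raise ValueError(f"cohort produced no {name} adults")
        init[age, so.index[name]] = float(pairs)
    return init


@dataclass
class ProjectionResult:
    """Per-day age-stage masses with population and predation totals."""

    stage_order: StageOrder
    n_xj_t: np.ndarray        # (horizon+1, X, beta)
    N_t: np.ndarray           # (horizon+1,)
    P_t: np.ndarray           # (horizon+1,)
    lower: "ProjectionResult | None" = None
    upper: "ProjectionResult | None" = None

    @property
    def horizon(self) -> int:
        return len(self.N_t) - 1

    def stage_totals(self) -> pd.DataFrame:
        """Per-day totals per stage plus N(t) and P(t)."""
        df = pd.DataFrame(
            self.n_xj_t.sum(axis=1), columns=list(self.stage_order.labels)
        )
        df.insert(0, "t", np.arange(self.horizon + 1))
        df["N_t"] = self.N_t
        df["P_t"] = self.P_t
        if self.lower is not None:
            df["N_t_lower"] = self.lower.N_t
            df["P_t_lower"] = self.lower.P_t
        if self.upper is not None:
            df["N_t_upper"] = self.upper.N_t
            df["P_t_upper"] = self.upper.P_t
        return df

    def composition(self, t: int = -1) -> np.ndarray:
        """Age-stage proportions at day t (defaults to the final day)."""
        snap = self.n_xj_t[t]
        return snap / snap.sum()

    def plot(self, ax=None, log10: bool = True):
        from .plotting import plot_projection

        return plot_projection(self, ax=ax, log10=log10)


def project(
    schedule: ProjectionSchedule,
    initial: np.ndarray,
    horizon: int,
) -> ProjectionResult:
    """Project expected masses for ``horizon`` days from an initial vector."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    X = schedule.max_age + 1
    beta = schedule.stage_order.beta
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (X, beta):
        raise ValueError(
            f"initial vector must have shape {(X, beta)} (ages 0..{X - 1}), "
            f"got {initial.shape}"
        )
    egg_j = schedule.stage_order.index["egg"]
    n = initial.copy()
    traj = np.empty((horizon + 1, X, beta))
    traj[0] = n
    for t in range(1, horizon + 1):
        births = float((schedule.f_xj * n).sum())
        nxt = np.zeros_like(n)
        if X > 1:
            nxt[1:] = np.einsum("xjy,xj->xy", schedule.transitions, n[:-1])
        nxt[0, egg_j] += births
        n = nxt
        traj[t] = n
    N_t = traj.sum(axis=(1, 2))
    P_t = (traj * schedule.c_xj[None]).sum(axis=(1, 2))
    return ProjectionResult(
        stage_order=schedule.stage_order, n_xj_t=traj, N_t=N_t, P_t=P_t
    )


def project_with_bands(
    cohort: Cohort | CohortArrays,
    initial: np.ndarray | None = None,
    horizon: int = 90,
    B: int = 2000,
    seed: int | None = None,
    pairs: int = 10,
) -> ProjectionResult:
    """Point projection plus lower/upper bands from the percentile cohorts.

    The bands re-project the bootstrap resamples attaining the 2.5th and
    97.5th percentiles of lambda (B must be >= 40).
    """
    from .bootstrap import percentile_cohorts

    a = as_arrays(cohort)
    pct = percentile_cohorts(a, B=B, seed=seed)
    lo_arrays, hi_arrays = pct.cohorts(a)
    point_sched = build_schedule(a)
    auto_initial = initial is None
    if auto_initial:
        initial = initial_vector(point_sched, pairs=pairs)
    result = project(point_sched, initial, horizon)

    def _band(arrays: CohortArrays) -> ProjectionResult:
        sched = build_schedule(arrays)
        if auto_initial:
            init = initial_vector(sched, pairs=pairs)
        else:
            init = np.zeros_like(sched.f_xj)
            src = min(initial.shape[0], init.shape[0])
            init[:src] = initial[:src]
        return project(sched, init, horizon)

    result.lower = _band(lo_arrays)
    result.upper = _band(hi_arrays)
    return result
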