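"""Dense array representation of a cohort and the weighted demography engine.

Everything downstream of the raw records (life table, predation statistics,
bootstrap resampling) is an average over individuals, so the whole analysis
is expressed as weighted sums over a fixed per-individual array layout.  The
point estimate uses unit weights; a bootstrap replicate uses multinomial
resampling counts.  This keeps a full parameter recomputation cheap enough
for tens of thousands of replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .cohort import Cohort, StageOrder, DEFAULT_STAGE_ORDER

# sex codes in the arrays
SEX_UNDETERMINED, SEX_FEMALE, SEX_MALE = 0, 1, 2


@dataclass
class CohortArrays:
    """Per-individual dense arrays over ages 0..max_age (alive days only)."""

    stage_order: StageOrder
    n: int                      # n_01
    stage_idx: np.ndarray       # (n, X) int8; -1 where not alive
    eggs: np.ndarray            # (n, X) float64
    prey: np.ndarray            # (n, X) float64
    lifespan: np.ndarray        # (n,) int64: number of alive days
    sex: np.ndarray             # (n,) int8
    emergence_age: np.ndarray   # (n,) int64; -1 if never adult
    first_egg_age: np.ndarray   # (n,) int64; -1 if never laid
    # derived, filled in __post_init__
    X: int = field(init=False)
    masks: list[np.ndarray] = field(init=False)         # per stage (n, X) bool
    lifetime_eggs: np.ndarray = field(init=False)       # (n,)
    lifetime_prey: np.ndarray = field(init=False)       # (n,)
    egg_days: np.ndarray = field(init=False)            # (n,) days with eggs>0
    days_in_stage: np.ndarray = field(init=False)       # (n, beta)
    prey_in_stage: np.ndarray = field(init=False)       # (n, beta)
    completed_stage: np.ndarray = field(init=False)     # (n, beta) bool

    def __post_init__(self) -> None:
        self.X = self.stage_idx.shape[1]
        beta = self.stage_order.beta
        self.masks = [self.stage_idx == j for j in range(beta)]
        self.lifetime_eggs = self.eggs.sum(axis=1)
        self.lifetime_prey = self.prey.sum(axis=1)
        self.egg_days = (self.eggs > 0).sum(axis=1)
        self.days_in_stage = np.stack([m.sum(axis=1) for m in self.masks], axis=1)
        self.prey_in_stage = np.stack(
            [(self.prey * m).sum(axis=1) for m in self.masks], axis=1
        )
        # a preadult stage is "completed" when the individual went beyond it;
        # adult stages are terminal, so being an adult completes the stage
        # (every adult is followed to death).
        last_idx = np.array(
            [row[row >= 0].max() if (row >= 0).any() else -1 for row in self.stage_idx],
            dtype=np.int64,
        )
        n_pre = len(self.stage_order.preadult)
        comp = np.zeros((self.n, beta), dtype=bool)
        for j in range(n_pre):
            comp[:, j] = last_idx > j
        for j in range(n_pre, beta):
            comp[:, j] = last_idx == j
        self.completed_stage = comp

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "CohortArrays":
        so = cohort.stage_order
        n = cohort.n_01
        X = int(
            max(
                max((d.age for d in ind.days if d.alive), default=0)
                for ind in cohort.individuals
            )
            + 1
        )
        stage_idx = np.full((n, X), -1, dtype=np.int8)
        eggs = np.zeros((n, X))
        prey = np.zeros((n, X))
        lifespan = np.zeros(n, dtype=np.int64)
        sex = np.zeros(n, dtype=np.int8)
        emergence = np.full(n, -1, dtype=np.int64)
        first_egg = np.full(n, -1, dtype=np.int64)
        for i, ind in enumerate(cohort.individuals):
            for d in ind.sorted_days():
                if not d.alive:
                    continue
                j = so.index[d.stage]
                stage_idx[i, d.age] = j
                eggs[i, d.age] = d.eggs_laid
                prey[i, d.age] = d.prey_consumed
                lifespan[i] += 1
                if so.is_adult(d.stage) and emergence[i] < 0:
                    emergence[i] = d.age
                    sex[i] = SEX_FEMALE if d.stage == "female" else SEX_MALE
                if d.eggs_laid > 0 and first_egg[i] < 0:
                    first_egg[i] = d.age
        return cls(
            stage_order=so,
            n=n,
            stage_idx=stage_idx,
            eggs=eggs,
            prey=prey,
            lifespan=lifespan,
            sex=sex,
            emergence_age=emergence,
            first_egg_age=first_egg,
        )

    def subset(self, idx: np.ndarray) -> "CohortArrays":
        """A resampled cohort built from an index list (bootstrap replicate)."""
        idx = np.asarray(idx, dtype=np.int64)
        return CohortArrays(
            stage_order=self.stage_order,
            n=len(idx),
            stage_idx=self.stage_idx[idx],
            eggs=self.eggs[idx],
            prey=self.prey[idx],
            lifespan=self.lifespan[idx],
            sex=self.sex[idx],
            emergence_age=self.emergence_age[idx],
            first_egg_age=self.first_egg_age[idx],
        )


def as_arrays(cohort: Cohort | CohortArrays) -> CohortArrays:
    if isinstance(cohort, CohortArrays):
        return cohort
    return CohortArrays.from_cohort(cohort)


class UndefinedRateError(ValueError):
    """Euler-Lotka rate is undefined (no reproduction: R0 = 0)."""


def euler_lotka_rate(lxmx: np.ndarray, tol: float = 1e-12) -> float:
    """Solve sum_x exp(-r(x+1)) lx*mx = 1 for r (age indexed from 0).

    The left side is strictly decreasing in r; the root is bracketed in
    [-1, 5] and the bracket is expanded geometrically if needed.  Terms are
    combined on the log scale so that very negative brackets cannot overflow.
    """
    lxmx = np.asarray(lxmx, dtype=float)
    pos = lxmx > 0
    if not pos.any():
        raise UndefinedRateError("R0 = 0: intrinsic rate is undefined")
    logphi = np.log(lxmx[pos])
    ages1 = (np.nonzero(pos)[0] + 1).astype(float)

    def f(r: float) -> float:
        return logsumexp(logphi - r * ages1)  # log of the Euler-Lotka sum

    lo, hi = -1.0, 5.0
    while f(lo) < 0:
        lo *= 2.0
        if lo < -1e6:  # pragma: no cover - pathological schedule
            raise UndefinedRateError("failed to bracket the Euler-Lotka root")
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            raise UndefinedRateError("failed to bracket the Euler-Lotka root")
    r = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    resid = abs(math.expm1(f(r)))
    if resid > tol and resid > 1e-10:  # pragma: no cover - brentq is exact enough
        raise RuntimeError(f"Euler-Lotka residual {resid:g} exceeds tolerance")
    return float(r)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    np.divide(num, den, out=out, where=den > 0)
    return out


def demography(
    arrays: CohortArrays,
    weights: np.ndarray | None = None,
    *,
    tol: float = 1e-12,
    grids: bool = True,
) -> dict:
    """All life-table and predation statistics under individual weights.

    With ``weights=None`` this is the point estimate; with multinomial
    resampling counts it is one bootstrap replicate.  Undefined quantities
    (e.g. r when no eggs were laid) are returned as NaN.  Set ``grids=False``
    to skip assembling the age-stage grids (bootstrap fast path keeps them
    for internal use but callers only need scalars).
    """
    a = arrays
    so = a.stage_order
    w = np.ones(a.n) if weights is None else np.asarray(weights, dtype=float)
    W = w.sum()
    beta = so.beta

    count_xj = np.stack([w @ m for m in a.masks], axis=1)  # (X, beta)
    alive_x = count_xj.sum(axis=1)
    s_xj = count_xj / W
    l_x = alive_x / W

    eggs_x = w @ a.eggs          # total eggs laid at age x (all in female stage)
    prey_x = w @ a.prey
    lxmx = eggs_x / W            # = sum_j s_xj f_xj
    m_x = _safe_div(eggs_x, alive_x)
    R0 = float(lxmx.sum())

    if R0 > 0:
        r = euler_lotka_rate(lxmx, tol=tol)
        lam = math.exp(r)
        T = math.log(R0) / r if r != 0 else math.nan
    else:
        r = lam = T = math.nan

    fem = a.sex == SEX_FEMALE
    w_fem = float(w[fem].sum())
    F = float(w @ a.lifetime_eggs) / w_fem if w_fem > 0 else math.nan
    Od = float(w @ a.egg_days) / w_fem if w_fem > 0 else math.nan
    ovi = a.first_egg_age >= 0
    w_ovi = float(w[ovi].sum())
    if w_ovi > 0:
        apop = float(w[ovi] @ (a.first_egg_age[ovi] - a.emergence_age[ovi])) / w_ovi
        tpop = float(w[ovi] @ a.first_egg_age[ovi]) / w_ovi
    else:
        apop = tpop = math.nan
    adult = a.emergence_age >= 0
    s_a = float(w[adult].sum()) / W

    # stage summaries: duration means over completers; daily predation D_j
    # over all individual-days spent in the stage.
    dur = {}
    for j, name in enumerate(so.labels):
        wc = w * a.completed_stage[:, j]
        tot = wc.sum()
        dur[name] = float(wc @ a.days_in_stage[:, j]) / tot if tot > 0 else math.nan
    stage_days = w @ a.days_in_stage     # (beta,) total individual-days per stage
    stage_prey = w @ a.prey_in_stage
    D = {
        name: (float(stage_prey[j]) / float(stage_days[j]) if stage_days[j] > 0 else math.nan)
        for j, name in enumerate(so.labels)
    }
    larval = [so.index[s] for s in so.preadult]
    adults_j = [so.index[s] for s in so.adult]
    pre_days, pre_prey = stage_days[larval].sum(), stage_prey[larval].sum()
    ad_days, ad_prey = stage_days[adults_j].sum(), stage_prey[adults_j].sum()
    D["preadult"] = float(pre_prey) / float(pre_days) if pre_days > 0 else math.nan
    D["adult"] = float(ad_prey) / float(ad_days) if ad_days > 0 else math.nan

    longevity = {}
    for code, name in ((SEX_FEMALE, "female"), (SEX_MALE, "male")):
        sel = a.sex == code
        ws = float(w[sel].sum())
        j = so.index[name]
        longevity[f"{name}_adult"] = (
            float(w[sel] @ a.days_in_stage[sel, j]) / ws if ws > 0 else math.nan
        )
        longevity[f"{name}_total"] = (
            float(w[sel] @ a.lifespan[sel]) / ws if ws > 0 else math.nan
        )

    # predation statistics
    prey_xj = np.stack([w @ (a.prey * m) for m in a.masks], axis=1)
    c_xj = _safe_div(prey_xj, count_xj)
    k_x = _safe_div(prey_x, alive_x)
    q_x = prey_x / W
    C0 = float(q_x.sum())
    if R0 > 0:
        Qp = C0 / R0
    elif C0 == 0:
        Qp = 0.0
    else:
        Qp = math.nan
    if math.isfinite(lam):
        decay = lam ** (-np.arange(a.X, dtype=float))
        a_xj = s_xj * decay[:, None]
        a_xj /= a_xj.sum()
        psi = float((a_xj * c_xj).sum())
        omega = lam * psi
    else:
        a_xj = np.full_like(s_xj, math.nan)
        psi = omega = math.nan

    out = {
        "R0": R0,
        "r": r,
        "lambda": lam,
        "T": T,
        "F": F,
        "Od": Od,
        "APOP": apop,
        "TPOP": tpop,
        "preadult_survival": s_a,
        "C0": C0,
        "Qp": Qp,
        "psi": psi,
        "omega": omega,
        "n_females": w_fem,
        "stage_durations": dur,
        "stage_daily_predation": D,
        "longevity": longevity,
    }
    if grids:
        f_xj = np.zeros_like(s_xj)
        jf = so.index["female"]
        f_xj[:, jf] = _safe_div(eggs_x, count_xj[:, jf])
        out.update(
            {
                "count_xj": count_xj,
                "s_xj": s_xj,
                "l_x": l_x,
                "f_xj": f_xj,
                "m_x": m_x,
                "lxmx": lxmx,
                "c_xj": c_xj,
                "k_x": k_x,
                "q_x": q_x,
                "a_xj": a_xj,
            }
        )
    return out


def life_expectancy_grid(arrays: CohortArrays) -> np.ndarray:
    """e_xj: expected remaining alive days (current day included) at (x, j).

    Estimated from the sub-cohort of individuals that actually reached age x
    in stage j; cells never reached are NaN.  Because stages are monotone,
    the double sum over the conditional forward schedule telescopes to the
    mean remaining lifespan of that sub-cohort.
    """
    a = arrays
    X, beta = a.X, a.stage_order.beta
    e = np.full((X, beta), np.nan)
    ages = np.arange(X, dtype=float)
    for j in range(beta):
        m = a.masks[j]
        n_xj = m.sum(axis=0).astype(float)
        tot = a.lifespan @ m  # sum of lifespans of occupants, per age
        with np.errstate(invalid="ignore", divide="ignore"):
            col = tot / n_xj - ages
        e[:, j] = np.where(n_xj > 0, col, np.nan)
    return e


def reproductive_value_grid(arrays: CohortArrays, r: float, f_xj: np.ndarray) -> np.ndarray:
    """v_xj: expected contribution of an (x, j) individual to the future
    population, discounted at the intrinsic rate r.

    v_xj = e^{r(x+1)} * sum_{i>=x} e^{-r(i+1)} * E[f at (i, stage_i) | alive
    path through (x, j)], with the conditional forward schedule estimated by
    raw pass-through frequencies of the sub-cohort that reached (x, j) and
    the fecundity grid f_xj taken from the whole cohort.  Cells never reached
    are NaN; v of a newborn equals the finite rate lambda.
    """
    a = arrays
    X, beta = a.X, a.stage_order.beta
    disc = np.exp(-r * (np.arange(X, dtype=float) + 1.0))
    # g[i, x] = f at (x, stage of individual i at x), 0 if dead
    alive = a.stage_idx >= 0
    ages_idx = np.broadcast_to(np.arange(X), (a.n, X))
    g = np.where(
        alive,
        f_xj[ages_idx, np.clip(a.stage_idx, 0, beta - 1).astype(np.int64)],
        0.0,
    )
    G = np.cumsum((g * disc[None, :])[:, ::-1], axis=1)[:, ::-1]  # tail sums
    v = np.full((X, beta), np.nan)
    grow = np.exp(r * (np.arange(X, dtype=float) + 1.0))
    for j in range(beta):
        m = a.masks[j]
        n_xj = m.sum(axis=0).astype(float)
        num = (G * m).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            col = grow * num / n_xj
        v[:, j] = np.where(n_xj > 0, col, np.nan)
    return v
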