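"""Bootstrap inference for life-table and predation parameters.

The resampling unit is the whole individual with its entire daily history,
which preserves within-individual correlation between survival, development,
reproduction and feeding.  Each replicate draws n_01 individuals with
replacement and recomputes every scalar parameter.  Replicates in which no
eggs are laid contribute R0 = 0 but have no defined intrinsic rate; they are
excluded from the r/lambda/T (and Qp/psi/omega) distributions and counted so
users can judge their weight.

Between-scenario comparisons use the confidence-interval-of-difference
construction: B independent replicate pairs, the 2.5th/97.5th percentiles of
the differences, significance at 5% iff zero falls outside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _core
from ._core import CohortArrays, as_arrays, SEX_FEMALE
from .cohort import Cohort

__all__ = [
    "BootstrapDistributions",
    "PairedTestResult",
    "PercentileCohorts",
    "bootstrap_cohort",
    "bootstrap_se",
    "paired_bootstrap_test",
    "percentile_cohorts",
]

SCALAR_PARAMS = (
    "R0", "r", "lambda", "T", "F", "Od", "APOP", "TPOP",
    "preadult_survival", "C0", "Qp", "psi", "omega",
)


@dataclass
class BootstrapDistributions:
    """Replicate estimates per parameter (NaN where a replicate is undefined)."""

    B: int
    seed: int | None
    params: dict[str, np.ndarray]
    n_undefined: int  # replicates with no eggs laid (no defined r/lambda/T)

    def defined(self, name: str) -> np.ndarray:
        vals = self.params[name]
        return vals[np.isfinite(vals)]


def _spawn_seeds(seed: int | None, k: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(k)]


def bootstrap_cohort(
    cohort: Cohort | CohortArrays,
    B: int = 100_000,
    seed: int | None = None,
    include_stage_stats: bool = True,
) -> BootstrapDistributions:
    """Resample the cohort B times and recompute all scalar parameters.

    The printed analyses use B = 100,000; tests and examples run at a few
    thousand, which is plenty for SEs to a couple of significant digits.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    a = as_arrays(cohort)
    rng = np.random.default_rng(seed)
    names = list(SCALAR_PARAMS)
    extra: list[str] = []
    if include_stage_stats:
        extra = [f"dur_{s}" for s in a.stage_order.labels] + [
            f"D_{s}" for s in list(a.stage_order.labels) + ["preadult", "adult"]
        ]
    out = {name: np.full(B, np.nan) for name in names + extra}
    n_undef = 0
    for b in range(B):
        w = np.bincount(rng.integers(0, a.n, a.n), minlength=a.n).astype(float)
        d = _core.demography(a, w, grids=False)
        if d["R0"] == 0:
            n_undef += 1
        for name in names:
            out[name][b] = d[name]
        if include_stage_stats:
            for s, v in d["stage_durations"].items():
                out[f"dur_{s}"][b] = v
            for s, v in d["stage_daily_predation"].items():
                out[f"D_{s}"][b] = v
    return BootstrapDistributions(B=B, seed=seed, params=out, n_undefined=n_undef)


def bootstrap_se(distribution: np.ndarray) -> float:
    """Sample standard deviation of the defined replicate estimates.

    NaN (flagged missing) when fewer than two replicates are defined.
    """
    vals = np.asarray(distribution, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        return math.nan
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# Fast per-individual statistics (linear or ratio forms) used for the paired
# test; everything else goes through the full per-replicate recomputation.
# ---------------------------------------------------------------------------

def _fast_replicates(a: CohortArrays, name: str, idx: np.ndarray) -> np.ndarray | None:
    """Vectorized replicate estimates for statistics that are per-individual
    sums or ratios; ``idx`` is a (B, n) resampling index matrix."""
    n = a.n
    if name == "R0":
        return a.lifetime_eggs[idx].sum(axis=1) / n
    if name == "C0":
        return a.lifetime_prey[idx].sum(axis=1) / n
    if name == "preadult_survival":
        return (a.emergence_age[idx] >= 0).mean(axis=1)
    if name in ("F", "Od"):
        fem = (a.sex[idx] == SEX_FEMALE).sum(axis=1).astype(float)
        num = (a.lifetime_eggs if name == "F" else a.egg_days)[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num / fem
        return np.where(fem > 0, vals, np.nan)
    return None


def _replicate_estimates(
    a: CohortArrays, name: str, B: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.integers(0, a.n, size=(B, a.n))
    fast = _fast_replicates(a, name, idx)
    if fast is not None:
        return fast
    vals = np.full(B, np.nan)
    for b in range(B):
        w = np.bincount(idx[b], minlength=a.n).astype(float)
        d = _core.demography(a, w, grids=False)
        if name.startswith("dur_"):
            vals[b] = d["stage_durations"][name[4:]]
        elif name.startswith("D_"):
            vals[b] = d["stage_daily_predation"][name[2:]]
        else:
            vals[b] = d[name]
    return vals


@dataclass
class PairedTestResult:
    """Percentile-CI comparison of one parameter between two cohorts."""

    parameter: str
    difference: float         # point estimate A - B
    ci_low: float
    ci_high: float
    significant: bool         # zero outside the 95% CI
    inconclusive: bool = False  # >50% of replicate differences undefined
    n_defined: int = 0


def _order_stat_ci(diffs: np.ndarray, probs=(0.025, 0.975)) -> tuple[float, float]:
    """CI from the ceil(p*B)-th order statistics of the defined differences."""
    diffs = np.sort(diffs)
    B = len(diffs)
    lo = diffs[min(B - 1, max(0, math.ceil(probs[0] * B) - 1))]
    hi = diffs[min(B - 1, max(0, math.ceil(probs[1] * B) - 1))]
    return float(lo), float(hi)


def paired_bootstrap_test(
    cohort_a: Cohort | CohortArrays,
    cohort_b: Cohort | CohortArrays,
    parameter: str,
    B: int = 2000,
    seed: int | None = None,
) -> PairedTestResult:
    """Compare one parameter between two cohorts at the 5% level.

    Draws B independent replicate estimates from each cohort (deterministic
    per-cohort streams spawned from ``seed``), forms the B differences, and
    takes the 2.5th/97.5th percentile interval.
    """
    a, b = as_arrays(cohort_a), as_arrays(cohort_b)
    rng_a, rng_b = _spawn_seeds(seed, 2)
    est_a = _replicate_estimates(a, parameter, B, rng_a)
    est_b = _replicate_estimates(b, parameter, B, rng_b)
    diffs = est_a - est_b
    defined = diffs[np.isfinite(diffs)]

    def _point(arr: CohortArrays) -> float:
        d = _core.demography(arr, grids=False)
        if parameter.startswith("dur_"):
            return d["stage_durations"][parameter[4:]]
        if parameter.startswith("D_"):
            return d["stage_daily_predation"][parameter[2:]]
        return d[parameter]

    point = _point(a) - _point(b)
    if len(defined) < B / 2:
        return PairedTestResult(parameter, point, math.nan, math.nan,
                                significant=False, inconclusive=True,
                                n_defined=len(defined))
    lo, hi = _order_stat_ci(defined)
    return PairedTestResult(
        parameter=parameter,
        difference=point,
        ci_low=lo,
        ci_high=hi,
        significant=not (lo <= 0.0 <= hi),
        n_defined=len(defined),
    )


@dataclass
class PercentileCohorts:
    """Bootstrap resamples attaining chosen order statistics of lambda."""

    indices_low: np.ndarray
    indices_high: np.ndarray
    lambda_low: float
    lambda_high: float
    lambda_point: float

    def cohorts(self, arrays: CohortArrays) -> tuple[CohortArrays, CohortArrays]:
        return arrays.subset(self.indices_low), arrays.subset(self.indices_high)


def percentile_cohorts(
    cohort: Cohort | CohortArrays,
    B: int = 2000,
    seed: int | None = None,
    probs: tuple[float, float] = (0.025, 0.975),
) -> PercentileCohorts:
    """The bootstrap resamples whose lambda attains the ceil(p*B)-th order
    statistics -- the cohorts used to project confidence bands.

    Replicates with undefined lambda (no eggs) are excluded before sorting.
    """
    if B < 40:
        raise ValueError("B must be >= 40 to resolve the 2.5th percentile")
    a = as_arrays(cohort)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.n, size=(B, a.n))
    lambdas = np.full(B, np.nan)
    for b in range(B):
        w = np.bincount(idx[b], minlength=a.n).astype(float)
        d = _core.demography(a, w, grids=False)
        lambdas[b] = d["lambda"]
    defined = np.nonzero(np.isfinite(lambdas))[0]
    if len(defined) < 40:
        raise ValueError("fewer than 40 replicates with a defined lambda")
    order = defined[np.argsort(lambdas[defined], kind="stable")]
    nd = len(order)
    i_lo = order[min(nd - 1, max(0, math.ceil(probs[0] * nd) - 1))]
    i_hi = order[min(nd - 1, max(0, math.ceil(probs[1] * nd) - 1))]
    point = _core.demography(a, grids=False)["lambda"]
    return PercentileCohorts(
        indices_low=idx[i_lo],
        indices_high=idx[i_hi],
        lambda_low=float(lambdas[i_lo]),
        lambda_high=float(lambdas[i_hi]),
        lambda_point=float(point),
    )
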