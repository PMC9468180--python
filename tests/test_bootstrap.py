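"""Bootstrap SEs, paired tests and percentile-cohort extraction."""

import math

import numpy as np
import pytest

from agestage import (
    Cohort,
    LifeTableModel,
    bootstrap_cohort,
    bootstrap_se,
    default_scenarios,
    generate_cohort,
    paired_bootstrap_test,
    percentile_cohorts,
)
from agestage._core import as_arrays, demography
from conftest import make_individual


def _clone_cohort(n):
    """n byte-identical individuals: every bootstrap replicate is the same."""
    inds = [
        make_individual(
            str(i),
            ["egg", "L1", "L2", "L3", "L4", "pupa", "female", "female"],
            eggs=[0, 0, 0, 0, 0, 0, 0, 6],
            prey=[0, 1, 2, 3, 4, 0, 5, 5],
        )
        for i in range(n)
    ]
    cohort = Cohort(label="clones", individuals=inds)
    cohort.validate()
    return cohort


class TestBootstrapCohort:
    def test_degenerate_cohort_has_zero_se(self):
        dist = bootstrap_cohort(_clone_cohort(5), B=200, seed=1)
        for name in ("R0", "r", "lambda", "T", "F", "C0", "Qp", "psi", "omega"):
            assert bootstrap_se(dist.params[name]) == pytest.approx(0.0, abs=1e-12)
        assert dist.n_undefined == 0

    def test_same_seed_identical_distributions(self, cohort_25):
        d1 = bootstrap_cohort(cohort_25, B=50, seed=42)
        d2 = bootstrap_cohort(cohort_25, B=50, seed=42)
        for name in d1.params:
            assert np.array_equal(d1.params[name], d2.params[name], equal_nan=True)

    def test_bootstrap_mean_near_point_estimate(self, cohort_25):
        dist = bootstrap_cohort(cohort_25, B=600, seed=3)
        point = demography(as_arrays(cohort_25), grids=False)["R0"]
        vals = dist.defined("R0")
        se = vals.std(ddof=1)
        assert abs(vals.mean() - point) < 3 * se / math.sqrt(len(vals)) + 0.05 * se

    def test_se_R0_close_to_delta_method_binomial_component(self):
        # cohort built so R0 variation is dominated by the female count:
        # every female lays the same total E; R0_hat = E * Nf_hat / n with
        # Nf_hat binomial -> SE(R0) ~ E * sqrt(p(1-p)/n)
        rng = np.random.default_rng(0)
        inds = []
        E = 40
        p = 0.5
        for i in range(200):
            female = rng.random() < p
            stages = ["egg", "L1", "L2", "L3", "L4", "pupa"] + (
                ["female"] * 4 if female else ["male"] * 4
            )
            eggs = [0] * 6 + ([0, E, 0, 0] if female else [0, 0, 0, 0])
            inds.append(make_individual(str(i), stages, eggs=eggs))
        cohort = Cohort(label=None, individuals=inds)
        cohort.validate()
        p_hat = sum(1 for ind in inds if ind.sex() == "female") / 200
        analytic = E * math.sqrt(p_hat * (1 - p_hat) / 200)
        dist = bootstrap_cohort(cohort, B=2000, seed=5, include_stage_stats=False)
        assert bootstrap_se(dist.params["R0"]) == pytest.approx(analytic, rel=0.10)

    def test_zero_female_replicates_counted_and_excluded(self):
        # one ovipositing female among many males: resamples often miss her
        inds = [
            make_individual("F", ["egg", "L1", "L2", "L3", "L4", "pupa", "female"],
                            eggs=[0, 0, 0, 0, 0, 0, 50])
        ] + [
            make_individual(f"M{i}", ["egg", "L1", "L2", "L3", "L4", "pupa", "male"])
            for i in range(9)
        ]
        cohort = Cohort(label=None, individuals=inds)
        cohort.validate()
        dist = bootstrap_cohort(cohort, B=300, seed=6, include_stage_stats=False)
        assert dist.n_undefined > 0
        r_vals = dist.params["r"]
        assert np.isnan(r_vals).sum() == dist.n_undefined
        assert (~np.isnan(dist.params["R0"])).all()  # R0 recorded as 0 instead
        assert (dist.params["R0"][np.isnan(r_vals)] == 0).all()


class TestBootstrapSe:
    def test_constant_and_hand_computed(self):
        assert bootstrap_se(np.full(10, 3.3)) == 0.0
        assert bootstrap_se(np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)

    def test_fewer_than_two_defined_is_nan(self):
        assert math.isnan(bootstrap_se(np.array([np.nan, 2.0])))


class TestPairedTest:
    def test_identical_cohorts_not_significant(self, cohort_25):
        res = paired_bootstrap_test(cohort_25, cohort_25, "F", B=400, seed=1)
        assert not res.significant
        assert res.ci_low <= 0 <= res.ci_high

    def test_antisymmetry(self, cohort_25, scenarios):
        other = generate_cohort(scenarios[3], seed=77)
        ab = paired_bootstrap_test(cohort_25, other, "F", B=800, seed=9)
        ba = paired_bootstrap_test(other, cohort_25, "F", B=800, seed=9)
        assert ab.difference == pytest.approx(-ba.difference)
        assert ab.significant == ba.significant

    def test_separated_fecundity_scenarios_significant(self, scenarios):
        # 15C (F target 550) vs 30C (F target 335), n_01 = 50
        cold = generate_cohort(scenarios[0], seed=21)
        warm = generate_cohort(scenarios[3], seed=22)
        res = paired_bootstrap_test(cold, warm, "F", B=2000, seed=10)
        assert res.significant and res.difference > 0

    def test_full_recompute_parameter(self, cohort_25, scenarios):
        warm = generate_cohort(scenarios[3], seed=23)
        res = paired_bootstrap_test(cohort_25, warm, "r", B=120, seed=11)
        assert res.n_defined == 120
        assert isinstance(res.significant, bool)


class TestPercentileCohorts:
    def test_order_statistic_indices_at_B40(self, cohort_25):
        # ceil(0.025*40) = 1st and ceil(0.975*40) = 39th order statistics
        arrays = as_arrays(cohort_25)
        rng = np.random.default_rng(8)
        idx = rng.integers(0, arrays.n, size=(40, arrays.n))
        lambdas = np.array(
            [
                demography(arrays, np.bincount(row, minlength=arrays.n).astype(float),
                           grids=False)["lambda"]
                for row in idx
            ]
        )
        pct = percentile_cohorts(arrays, B=40, seed=8)
        ranks = np.sort(lambdas)
        assert pct.lambda_low == pytest.approx(ranks[0])
        assert pct.lambda_high == pytest.approx(ranks[38])

    def test_bounds_bracket_point_estimate(self, cohort_25):
        pct = percentile_cohorts(cohort_25, B=300, seed=12)
        assert pct.lambda_low <= pct.lambda_point <= pct.lambda_high

    def test_deterministic_given_seed(self, cohort_25):
        p1 = percentile_cohorts(cohort_25, B=60, seed=13)
        p2 = percentile_cohorts(cohort_25, B=60, seed=13)
        assert np.array_equal(p1.indices_low, p2.indices_low)
        assert np.array_equal(p1.indices_high, p2.indices_high)

    def test_small_B_rejected(self, cohort_25):
        with pytest.raises(ValueError):
            percentile_cohorts(cohort_25, B=20, seed=1)
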