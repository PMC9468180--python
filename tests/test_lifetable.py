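"""Life-table computations: grids, Euler-Lotka solver, expectancy, value."""

import math

import numpy as np
import pytest

from agestage import (
    Cohort,
    LifeTableModel,
    UndefinedRateError,
    agestage_counts,
    compute_exj,
    compute_lambda,
    compute_lx,
    compute_mx,
    compute_R0,
    compute_sxj,
    compute_T,
    compute_vxj,
    generate_cohort,
    reproduction_summaries,
    solve_r,
    stage_summaries,
)
from agestage._core import as_arrays, demography
from conftest import deterministic_config, make_individual


class TestGrids:
    def test_sxj_is_counts_over_n01(self, toy_cohort):
        counts = agestage_counts(toy_cohort)
        s = compute_sxj(counts)
        egg = counts.stage_order.index["egg"]
        assert s[1, egg] == 1.0  # all three alive as eggs at age 1
        assert s.max() <= 1.0 and s.min() >= 0.0
        with pytest.raises(ValueError):
            compute_sxj(counts.counts, 0)

    def test_lx_starts_at_one_and_hits_zero_after_deaths(self, toy_cohort):
        s = compute_sxj(agestage_counts(toy_cohort))
        l_x = compute_lx(s)
        assert l_x[0] == 1.0
        assert (np.diff(l_x) <= 1e-12).all()
        # age 3: individual B (died after its age-2 day) is gone
        assert l_x[3] == pytest.approx(2 / 3)

    def test_mx_hand_computed_two_survivor_case(self):
        # one female laying 10 among two survivors: m_x = (0.5*10)/(0.5+0.5)
        s = np.zeros((1, 8))
        f = np.zeros((1, 8))
        s[0, 6] = s[0, 7] = 0.5
        f[0, 6] = 10.0
        assert compute_mx(s, f)[0] == pytest.approx(5.0)

    def test_mx_zero_when_no_survivors(self):
        s = np.zeros((2, 8))
        f = np.zeros((2, 8))
        s[0, 0] = 1.0
        assert compute_mx(s, f).tolist() == [0.0, 0.0]

    def test_lxmx_conservation(self, cohort_25):
        # sum_x l_x m_x must equal total eggs laid / n_01 (oracle: raw scan)
        total_eggs = sum(
            d.eggs_laid for ind in cohort_25.individuals for d in ind.days
        )
        res = LifeTableModel(cohort_25).fit(expectancy=False)
        assert res.R0 == pytest.approx(total_eggs / cohort_25.n_01, rel=1e-12)


class TestRates:
    def test_r_closed_form_single_age(self):
        # all reproduction R0 = 8 at age x = 3 -> r = ln(8)/4
        l_x = np.array([1.0, 1.0, 1.0, 1.0])
        m_x = np.array([0.0, 0.0, 0.0, 8.0])
        assert solve_r(l_x, m_x) == pytest.approx(math.log(8) / 4, abs=1e-12)

    def test_r_zero_when_R0_is_one(self):
        l_x = np.array([1.0, 0.8, 0.5])
        m_x = np.array([0.0, 0.5 / 0.8, 0.6 / 0.5 * 1.0])
        # l*m = [0, .5, .6] -> rescale to R0=1
        lm = l_x * m_x
        m_x = m_x / lm.sum()
        assert solve_r(l_x, m_x) == pytest.approx(0.0, abs=1e-12)

    def test_r_matches_grid_search_oracle(self):
        # toy schedule: l*m = 2 at age 1, 2 at age 2
        l_x = np.array([1.0, 1.0, 1.0])
        m_x = np.array([0.0, 2.0, 2.0])
        grid = np.arange(0.0, 1.0, 1e-6)
        resid = np.abs(
            np.exp(-grid[:, None] * np.array([2.0, 3.0])) @ np.array([2.0, 2.0]) - 1
        )
        r_brute = grid[resid.argmin()]
        assert solve_r(l_x, m_x) == pytest.approx(r_brute, abs=2e-6)

    def test_negative_r_allowed_and_zero_R0_raises(self):
        l_x = np.array([1.0, 0.5])
        assert solve_r(l_x, np.array([0.0, 0.4])) < 0
        with pytest.raises(UndefinedRateError):
            solve_r(l_x, np.zeros(2))

    def test_lambda_and_T(self):
        assert compute_lambda(0.0) == 1.0
        assert compute_T(math.e, 1.0) == pytest.approx(1.0)
        assert math.isnan(compute_T(5.0, 0.0))


class TestLifeExpectancy:
    def test_deterministic_cohort_decrements_by_one(self, det_config):
        cohort = generate_cohort(deterministic_config(apop_mean=3.0))
        e = compute_exj(cohort)
        total = 2 + 3 + 2 + 2 + 3 + 4 + 10  # preadult + female adult days
        # newborn expectancy equals the fixed lifespan; decreases 1/day
        assert e[0, 0] == pytest.approx(total)
        finite = ~np.isnan(e)
        diag = [e[x][np.nonzero(finite[x])[0][0]] for x in range(total)]
        assert np.allclose(np.diff(diag), -1.0)

    def test_e01_equals_mean_lifespan(self, cohort_25):
        e = compute_exj(cohort_25)
        lifespans = [ind.lifespan for ind in cohort_25.individuals]
        assert e[0, 0] == pytest.approx(np.mean(lifespans), rel=1e-12)

    def test_constant_remaining_life(self):
        # every individual reaching L1 at age 1 lives exactly 5 more days
        inds = [
            make_individual(str(i), ["egg", "L1", "L1", "L1", "L1", "L1"])
            for i in range(4)
        ]
        cohort = Cohort(label=None, individuals=inds)
        cohort.validate()
        e = compute_exj(cohort)
        assert e[1, 1] == pytest.approx(5.0)


class TestReproductiveValue:
    def test_v01_equals_lambda(self, cohort_25):
        res = LifeTableModel(cohort_25).fit()
        assert res.table.v_xj[0, 0] == pytest.approx(res.lambda_, abs=1e-9)

    def test_zero_after_last_reproduction(self, cohort_25):
        res = LifeTableModel(cohort_25).fit()
        v = res.table.v_xj
        last_egg_age = max(
            d.age for ind in cohort_25.individuals for d in ind.days if d.eggs_laid
        )
        tail = v[last_egg_age + 1:]
        assert np.nanmax(tail, initial=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_toy_cohort_matches_spreadsheet_oracle(self, toy_cohort):
        arrays = as_arrays(toy_cohort)
        d = demography(arrays)
        r = d["r"]
        v = compute_vxj(toy_cohort, r)
        so = arrays.stage_order
        # independent cell-by-cell recomputation with explicit loops
        X, beta = arrays.X, so.beta
        for x in range(X):
            for j in range(beta):
                members = [
                    i for i in range(arrays.n) if arrays.stage_idx[i, x] == j
                ]
                if not members:
                    assert math.isnan(v[x, j])
                    continue
                acc = 0.0
                for i in members:
                    for age in range(x, X):
                        y = arrays.stage_idx[i, age]
                        if y >= 0:
                            acc += math.exp(-r * (age + 1)) * d["f_xj"][age, y]
                expected = math.exp(r * (x + 1)) * acc / len(members)
                assert v[x, j] == pytest.approx(expected, rel=1e-10)


class TestSummaries:
    def test_single_female_apop_tpop(self):
        stages = (
            ["egg"] * 3 + ["L1"] * 3 + ["L2"] * 3 + ["L3"] * 3 + ["L4"] * 4
            + ["pupa"] * 4 + ["female"] * 12
        )
        eggs = [0] * len(stages)
        eggs[28] = 5  # emergence at age 20, first egg at age 28
        ind = make_individual("F", stages, eggs=eggs)
        cohort = Cohort(label=None, individuals=[ind])
        cohort.validate()
        rep = reproduction_summaries(cohort)
        assert rep.APOP == 8 and rep.TPOP == 28
        assert rep.F == 5 and rep.Od == 1

    def test_R0_identity_on_cohort(self, cohort_25):
        res = LifeTableModel(cohort_25).fit(expectancy=False)
        n_f = sum(1 for i in cohort_25.individuals if i.sex() == "female")
        assert res.R0 == pytest.approx(res.F * n_f / cohort_25.n_01, rel=1e-12)

    def test_stage_summaries_on_deterministic_cohort(self, det_config):
        cohort = generate_cohort(det_config)
        summary = stage_summaries(cohort)
        assert summary.duration_means == pytest.approx(
            {"egg": 2, "L1": 3, "L2": 2, "L3": 2, "L4": 3, "pupa": 4,
             "female": 10, "male": math.nan},
            nan_ok=True,
        )
        assert summary.preadult_survival == 1.0
        assert summary.longevity["female_total"] == pytest.approx(2 + 3 + 2 + 2 + 3 + 4 + 10)

    def test_durations_agree_with_per_individual_scan(self, cohort_25):
        summary = stage_summaries(cohort_25)
        from collections import defaultdict

        per_stage = defaultdict(list)
        order = cohort_25.stage_order
        for ind in cohort_25.individuals:
            stages = [d.stage for d in ind.days if d.alive]
            seen = {}
            for s in stages:
                seen[s] = seen.get(s, 0) + 1
            last = stages[-1]
            for s, count in seen.items():
                completed = (s != last) or order.is_adult(s)
                if completed:
                    per_stage[s].append(count)
        for stage, values in per_stage.items():
            assert summary.duration_means[stage] == pytest.approx(np.mean(values))


class TestModelInterface:
    def test_summary_text_and_frames(self, cohort_25):
        res = LifeTableModel(cohort_25).fit()
        text = res.summary()
        assert "R0" in text and "lambda" in text
        long_df, par_df = res.to_frames()
        assert {"age", "stage", "s_xj", "e_xj", "v_xj"} <= set(long_df.columns)
        assert par_df.shape[0] == 1

    def test_from_csv(self, cohort_25, tmp_path):
        from agestage import write_cohort

        path = write_cohort(cohort_25, tmp_path / "c.csv")
        res = LifeTableModel.from_csv(path).fit(expectancy=False)
        ref = LifeTableModel(cohort_25).fit(expectancy=False)
        assert res.r == pytest.approx(ref.r, rel=1e-14)
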