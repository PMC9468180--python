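"""Synthetic cohort generator: scenario targets, samplers, reproducibility."""

import math

import numpy as np
import pytest

from agestage import (
    LifeTableModel,
    ScenarioConfig,
    default_scenarios,
    generate_cohort,
    read_config,
    write_config,
)
from agestage.cohort import write_cohort
from agestage.scenarios import (
    PREADULT,
    ScenarioConfigError,
    duration_pmf,
    expected_birth_schedule,
    expected_window_profile,
    sample_fecundity_schedule,
    sample_predation_schedule,
    sample_stage_durations,
)
from conftest import deterministic_config


class TestDefaultScenarios:
    def test_four_scenarios_with_published_targets(self, scenarios):
        by_label = {c.label: c for c in scenarios}
        assert sorted(by_label) == ["15C", "20C", "25C", "30C"]
        assert by_label["15C"].duration_mean["egg"] == 6.02
        assert by_label["15C"].duration_mean["L1"] == 7.08
        assert by_label["15C"].fecundity_total_mean == 550.06
        assert by_label["15C"].predation_daily_mean["L1"] == 8.02
        assert by_label["20C"].predation_daily_mean["L4"] == 140.95
        assert by_label["30C"].predation_daily_mean["L1"] == 22.94
        # preadult survival = product of per-stage survivals
        assert by_label["30C"].preadult_survival == pytest.approx(0.76)
        assert by_label["15C"].preadult_survival == pytest.approx(0.92)
        assert by_label["25C"].preadult_survival == pytest.approx(0.82)
        # observed adult sex counts (18/46, 24/46, 19/41, 20/38)
        assert by_label["15C"].sex_ratio_female == pytest.approx(18 / 46)
        assert by_label["30C"].sex_ratio_female == pytest.approx(20 / 38)

    def test_config_file_round_trip(self, scenarios, tmp_path):
        cfg = scenarios[1]
        path = write_config(cfg, tmp_path / "sc.cfg")
        back = read_config(path)
        assert back == cfg


class TestStageDurations:
    def test_degenerate_sd_zero(self, det_config):
        rng = np.random.default_rng(0)
        for _ in range(5):
            durations = sample_stage_durations(det_config, rng)
            assert durations == {"egg": 2, "L1": 3, "L2": 2, "L3": 2, "L4": 3, "pupa": 4}

    def test_draws_are_positive_integers_with_target_mean(self, scenarios):
        cfg = scenarios[0]
        rng = np.random.default_rng(1)
        draws = np.array(
            [sample_stage_durations(cfg, rng)["pupa"] for _ in range(10_000)]
        )
        assert draws.dtype.kind == "i" and (draws >= 1).all()
        mc_se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - cfg.duration_mean["pupa"]) < 2 * mc_se + 1e-3

    def test_discrete_pmf_mean_is_calibrated(self):
        for mean, sd in [(6.02, 0.78), (2.24, 0.41), (11.8, 1.63), (46.65, 7.29)]:
            values, probs = duration_pmf(mean, sd)
            assert abs(values @ probs - mean) < 1e-6

    def test_mean_below_one_rejected(self, det_config):
        det_config.duration_mean["egg"] = 0.4
        with pytest.raises(ScenarioConfigError):
            sample_stage_durations(det_config, np.random.default_rng(0))


class TestFecunditySchedule:
    def test_apop_draw_beyond_lifespan_gives_all_zero(self, det_config):
        # the pre-oviposition draw is always >= 1 day, so a female living a
        # single adult day dies before ovipositing, whatever the seed
        rng = np.random.default_rng(3)
        scheds = [sample_fecundity_schedule(det_config, 1, rng) for _ in range(50)]
        assert sum(s.sum() for s in scheds) == 0
        # and day 0 of adult life never carries eggs
        for _ in range(200):
            sched = sample_fecundity_schedule(det_config, 30, rng)
            assert sched[0] == 0

    def test_monte_carlo_mean_matches_targets(self, scenarios):
        cfg = scenarios[0]  # 15C: F target 550.06
        rng = np.random.default_rng(4)
        totals, days = [], []
        for _ in range(10_000):
            sched = sample_fecundity_schedule(cfg, 106, rng)
            totals.append(sched.sum())
            days.append((sched > 0).sum())
        totals = np.array(totals)
        mc_se = totals.std(ddof=1) / math.sqrt(len(totals))
        assert abs(totals.mean() - 550.06) < 2 * mc_se + 0.7
        days = np.array(days)
        se_d = days.std(ddof=1) / math.sqrt(len(days))
        assert abs(days.mean() - cfg.oviposition_days_mean) < 3 * se_d + 0.1

    def test_expected_window_profile_sums_to_F(self, scenarios):
        cfg = scenarios[2]
        prof = expected_window_profile(
            60, cfg.oviposition_days_mean, cfg.fecundity_total_mean
        )
        assert prof.sum() == pytest.approx(cfg.fecundity_total_mean, rel=1e-6)


class TestPredationSchedule:
    def test_non_predatory_stages_always_zero(self, scenarios):
        rng = np.random.default_rng(5)
        seq = ["egg"] * 3 + ["L1"] * 2 + ["pupa"] * 4 + ["female"] * 3
        for _ in range(20):
            out = sample_predation_schedule(scenarios[3], seq, rng)
            assert (out[:3] == 0).all() and (out[5:9] == 0).all()
            assert len(out) == len(seq)

    def test_L1_mean_at_30C(self, scenarios):
        cfg = scenarios[3]
        rng = np.random.default_rng(6)
        draws = sample_predation_schedule(cfg, ["L1"] * 50_000, rng)
        assert draws.mean() == pytest.approx(22.94, abs=3 * 22.94**0.5 / 50_000**0.5 + 0.05)


class TestGenerateCohort:
    def test_same_seed_identical(self, scenarios):
        c1 = generate_cohort(scenarios[1], seed=11)
        c2 = generate_cohort(scenarios[1], seed=11)
        assert c1.individuals == c2.individuals

    def test_different_seed_differs(self, scenarios):
        c1 = generate_cohort(scenarios[1], seed=11)
        c2 = generate_cohort(scenarios[1], seed=12)
        assert c1.individuals != c2.individuals

    def test_deterministic_config_identical_preadult(self, det_config):
        cohort = generate_cohort(det_config)
        preadult_len = 2 + 3 + 2 + 2 + 3 + 4
        for ind in cohort.individuals:
            stages = [d.stage for d in ind.days if d.alive][:preadult_len]
            assert stages == (
                ["egg"] * 2 + ["L1"] * 3 + ["L2"] * 2 + ["L3"] * 2
                + ["L4"] * 3 + ["pupa"] * 4
            )

    def test_output_passes_validation(self, cohort_25):
        cohort_25.validate()  # raises on any invariant violation

    def test_round_trip_through_csv(self, cohort_25, tmp_path):
        from agestage import read_cohort

        path = write_cohort(cohort_25, tmp_path / "c.csv")
        assert read_cohort(path).individuals == cohort_25.individuals

    def test_preadult_survival_recovery(self, scenarios):
        cfg = ScenarioConfig(**{**scenarios[2].__dict__, "n_01": 5000})
        cohort = generate_cohort(cfg, seed=99)
        res = LifeTableModel(cohort).fit(expectancy=False)
        assert res.preadult_survival == pytest.approx(0.82, abs=0.02)

    def test_higher_predation_raises_C0(self, det_config):
        from agestage import PredationModel

        low = generate_cohort(det_config)
        boosted = deterministic_config(
            predation_daily_mean={k: 3 * v for k, v in
                                  det_config.predation_daily_mean.items()}
        )
        high = generate_cohort(boosted)
        assert PredationModel(high).fit().C0 > PredationModel(low).fit().C0


class TestExpectedBirthSchedule:
    def test_total_matches_R0_expectation(self, scenarios):
        cfg = scenarios[3]
        phi = expected_birth_schedule(cfg)
        # sum phi = expected eggs per newborn = s_a * q_female * F (up to the
        # small mass of females whose pre-oviposition window outlives them)
        expected = cfg.preadult_survival * cfg.sex_ratio_female * cfg.fecundity_total_mean
        assert phi.sum() == pytest.approx(expected, rel=0.02)
        assert (phi >= 0).all()
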