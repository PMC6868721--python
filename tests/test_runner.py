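"""Scenario orchestration, aggregation and reporting."""

from dataclasses import replace

import numpy as np
import pytest

from hfsim.cohort import CohortSpec
from hfsim.engine import SimToggles
from hfsim.params import ValidationError
from hfsim.runner import (
    ScenarioConfig,
    break_even_year,
    compare_programs,
    iterations_max,
    run_scenario,
    scenario_preset,
    sensitivity_analysis,
)
from hfsim.telemonitoring import TmProgram


def small_config(**kw):
    defaults = dict(
        cohort=CohortSpec(n_patients=400),
        horizon_days=730,
        n_runs=3,
        master_seed=42,
        toggles=SimToggles(True, True, True),
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestIterationsMax:
    @pytest.mark.parametrize(
        "args,expected",
        [((10_000, 1825, 100), 1_825_000_000), ((1, 1, 1), 1), ((3, 7, 2), 42)],
    )
    def test_product(self, args, expected):
        assert iterations_max(*args) == expected

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, -5, 1), (1, 1, 0)])
    def test_non_positive_rejected(self, args):
        with pytest.raises(ValidationError):
            iterations_max(*args)


class TestRunScenario:
    def test_determinism(self):
        cfg = small_config()
        a = run_scenario(cfg)
        b = run_scenario(cfg)
        assert a.summary_mean.equals(b.summary_mean)
        assert np.array_equal(a.occupancy_mean, b.occupancy_mean)

    def test_survival_monotone_and_conserved(self):
        res = run_scenario(small_config())
        surv = res.survival_mean()
        assert (np.diff(surv, axis=0) <= 1e-12).all()
        totals = res.occupancy_mean.sum(axis=1) + res.cum_deaths_mean
        assert np.allclose(totals, res.cohort_size)

    def test_no_mortality_means_full_survival(self):
        res = run_scenario(small_config(toggles=SimToggles(False, True, True)))
        assert np.allclose(res.survival_mean(), 1.0)
        assert res.summary_mean.loc["all", "mortality_pct"] == 0.0

    def test_aggregate_equals_mean_of_ledger_totals(self):
        res = run_scenario(small_config(n_runs=2))
        for run in res.runs:
            per_patient = run.output.total_cost()
            py = run.output.person_days().sum() / 365.0
            assert run.summary.loc["all", "annual_cost_per_patient"] == pytest.approx(
                per_patient.sum() / py
            )
        mean_total = np.mean([r.output.total_cost().sum() for r in res.runs])
        assert res.summary_mean.loc["all", "total_cost"] == pytest.approx(mean_total)

    def test_category_costs_sum_to_total(self):
        res = run_scenario(small_config(tm_program=TmProgram()))
        row = res.summary_mean.loc["all"]
        parts = row["annual_outpatient"] + row["annual_inpatient"] + row["annual_dmp"]
        assert parts == pytest.approx(row["annual_cost_per_patient"])

    def test_point_value_scales_inpatient_costs(self):
        base = run_scenario(small_config(toggles=SimToggles(False, False, False)))
        half = run_scenario(
            small_config(toggles=SimToggles(False, False, False), overrides={"point_value": 0.5})
        )
        assert half.summary_mean.loc["IV", "annual_inpatient"] == pytest.approx(
            0.5 * base.summary_mean.loc["IV", "annual_inpatient"]
        )
        assert half.summary_mean.loc["IV", "annual_outpatient"] == pytest.approx(
            base.summary_mean.loc["IV", "annual_outpatient"]
        )

    def test_presets(self):
        s1 = scenario_preset("scenario1", n_patients=100)
        assert s1.toggles == SimToggles(False, False, False)
        s3 = scenario_preset("scenario3", n_patients=100)
        assert s3.cohort.sex_mix == 1.0 and s3.toggles == SimToggles(True, True, True)
        s4 = scenario_preset("scenario4", n_patients=100)
        assert s4.tm_program is not None
        with pytest.raises(ValidationError):
            scenario_preset("scenario9")


class TestSensitivity:
    def test_reference_is_zero_and_age_increases_mortality(self):
        base = small_config(
            cohort=CohortSpec(n_patients=800),
            horizon_days=1825,
            n_runs=2,
            toggles=SimToggles(True, False, False),
        )
        sens = sensitivity_analysis(base, ages=(70, 90))
        assert np.allclose(sens.mortality_vs_reference.loc["m70"], 0.0)
        assert np.allclose(sens.cost_vs_reference.loc["f70"], 0.0)
        m90 = sens.mortality_vs_reference.loc["m90"]
        assert (m90[["II", "III", "IV"]] > 0).all()
        # the age effect is strongest where admissions are most frequent
        assert m90["IV"] > m90["I"]


class TestComparePrograms:
    def test_break_even_search_on_synthetic_trajectories(self):
        conv = [100, 200, 300, 400]
        assert break_even_year(conv, [150, 210, 290, 380]) == 3
        assert break_even_year(conv, [90, 150, 250, 350]) == 1
        assert break_even_year(conv, [150, 250, 350, 450]) is None

    def test_identity_program_trajectories_match_conventional(self):
        cfg = small_config(n_runs=2)
        ident = TmProgram(
            acquisition_cost=0.0, monthly_fee=0.0,
            admission_rate_factor=1.0, los_mean_factor=1.0, name="ident",
        )
        comp = compare_programs(cfg, [ident])
        assert np.allclose(comp.cumulative["ident"], comp.cumulative["conv"])
        assert comp.break_even_year["ident"] == 1

    def test_program_reduces_long_run_costs(self):
        cfg = small_config(
            cohort=CohortSpec(n_patients=1500),
            horizon_days=1825,
            n_runs=2,
            toggles=SimToggles(False, False, False),
        )
        comp = compare_programs(cfg, [TmProgram(name="TM_1")])
        # acquisition dominates the first year...
        assert comp.first_year_increase_pct["TM_1"] > 0
        # ...but yearly savings eventually outweigh the fees
        incr_conv = np.diff(comp.cumulative["conv"])
        incr_tm = np.diff(comp.cumulative["TM_1"])
        assert incr_tm[-1] < incr_conv[-1]
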