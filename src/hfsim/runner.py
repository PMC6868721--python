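"""Scenario presets, multi-run orchestration, aggregation, sensitivity
analysis and program comparison.

A scenario is a reproducible experiment: a cohort composition, a horizon,
the set of enabled model channels (inpatient mortality, NYHA class changes
in outpatient and inpatient care), an optional telemonitoring overlay, and
registry overrides.  Each scenario is repeated over independently seeded
runs and reported as mean +/- SD (95% CI) across runs, per starting NYHA
class and overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    COST_CATEGORIES,
    DMP_CATEGORIES,
    INPATIENT_CATEGORIES,
    MEDICATION_CATEGORIES,
    OUTPATIENT_CATEGORIES,
    CohortSpec,
    PatientState,
    generate_cohort,
)
from .engine import RunOutput, SimToggles, simulate_run
from .params import NYHA_CLASSES, ParameterRegistry, ValidationError, load_registry
from .telemonitoring import TmProgram

__all__ = [
    "ScenarioConfig",
    "RunResult",
    "ScenarioResult",
    "scenario_preset",
    "run_scenario",
    "iterations_max",
    "sensitivity_analysis",
    "SensitivityResult",
    "compare_programs",
    "ProgramComparison",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class ScenarioConfig:
    """A reproducible experiment description."""

    cohort: CohortSpec
    horizon_days: int = 1825
    n_runs: int = 100
    master_seed: int = 1
    toggles: SimToggles = field(default_factory=SimToggles)
    tm_program: TmProgram | None = None
    overrides: dict = field(default_factory=dict)
    record_history: bool = False
    name: str = "custom"

    def __post_init__(self):
        if self.horizon_days <= 0:
            raise ValidationError("horizon_days must be positive")
        if self.n_runs < 1:
            raise ValidationError("n_runs must be at least 1")


def scenario_preset(
    name: str,
    *,
    n_patients: int = 10_000,
    horizon_days: int = 1825,
    n_runs: int = 100,
    master_seed: int = 1,
    overrides: dict | None = None,
) -> ScenarioConfig:
    """Named scenario presets mirroring the published simulation setups.

    scenario1 - conventional care, mortality and class changes disabled
    scenario2 - conventional care with inpatient mortality, classes fixed
    scenario3 - 70-year-old men, class changes in both care settings plus
                inpatient mortality
    scenario4 - scenario-1 conditions plus the TM_1 telemonitoring overlay
                (compare against conventional care via compare_programs)
    """
    cohort = CohortSpec(n_patients=n_patients, age_model=70.0, sex_mix=0.5)
    common = dict(
        horizon_days=horizon_days,
        n_runs=n_runs,
        master_seed=master_seed,
        overrides=dict(overrides or {}),
        name=name,
    )
    if name == "scenario1":
        return ScenarioConfig(cohort, toggles=SimToggles(False, False, False), **common)
    if name == "scenario2":
        return ScenarioConfig(cohort, toggles=SimToggles(True, False, False), **common)
    if name == "scenario3":
        return ScenarioConfig(
            replace(cohort, sex_mix=1.0), toggles=SimToggles(True, True, True), **common
        )
    if name == "scenario4":
        return ScenarioConfig(
            cohort,
            toggles=SimToggles(False, False, False),
            tm_program=TmProgram(name="TM_1"),
            **common,
        )
    raise ValidationError(f"unknown scenario preset {name!r}")


def iterations_max(n_patients: int, n_days: int, n_runs: int) -> int:
    """Upper bound on per-decision-element iterations of a parameter setting."""
    for v in (n_patients, n_days, n_runs):
        if int(v) != v or v <= 0:
            raise ValidationError("all inputs must be positive integers")
    return int(n_patients) * int(n_days) * int(n_runs)


# --------------------------------------------------------------------------
# Per-run and aggregated results

_CLASS_ROWS = list(NYHA_CLASSES) + ["all"]


@dataclass
class RunResult:
    """One run's raw output plus per-starting-class summary table."""

    output: RunOutput
    summary: pd.DataFrame

    @classmethod
    def from_output(cls, output: RunOutput) -> "RunResult":
        rows = {}
        total = output.total_cost()
        pdays = output.person_days()
        for label in _CLASS_ROWS:
            if label == "all":
                mask = np.ones(output.n_patients, dtype=bool)
            else:
                mask = output.nyha_start == (NYHA_CLASSES.index(label) + 1)
            n = int(mask.sum())
            if n == 0:
                continue
            deaths = int((output.death_day[mask] >= 0).sum())
            py = float(pdays[mask].sum()) / DAYS_PER_YEAR
            row = {
                "n": n,
                "deaths": deaths,
                "mortality_pct": 100.0 * deaths / n,
                "person_years": py,
            }
            cost_sum = float(total[mask].sum())
            row["total_cost"] = cost_sum
            row["annual_cost_per_patient"] = cost_sum / py if py else 0.0
            for group, cats in (
                ("outpatient", OUTPATIENT_CATEGORIES),
                ("inpatient", INPATIENT_CATEGORIES),
                ("medication", MEDICATION_CATEGORIES),
                ("dmp", DMP_CATEGORIES),
            ):
                gsum = float(sum(output.costs[c][mask].sum() for c in cats))
                row[f"annual_{group}"] = gsum / py if py else 0.0
            for c in COST_CATEGORIES:
                row[f"annual_{c}"] = float(output.costs[c][mask].sum()) / py if py else 0.0
            row["inpatient_share_pct"] = (
                100.0 * row["annual_inpatient"] / row["annual_cost_per_patient"]
                if cost_sum
                else 0.0
            )
            row["medication_share_of_outpatient_pct"] = (
                100.0 * row["annual_medication"] / row["annual_outpatient"]
                if row["annual_outpatient"]
                else 0.0
            )
            rows[label] = row
        return cls(output=output, summary=pd.DataFrame(rows).T)

    def survival_by_class(self) -> np.ndarray:
        """Surviving fraction per starting class, shape (horizon + 1, 4)."""
        out = self.output
        h = out.horizon_days
        surv = np.ones((h + 1, 4))
        for ci in range(4):
            mask = out.nyha_start == ci + 1
            n = int(mask.sum())
            if n == 0:
                continue
            dd = out.death_day[mask]
            deaths = np.bincount(dd[dd >= 0] + 1, minlength=h + 1)[: h + 1]
            surv[:, ci] = 1.0 - np.cumsum(deaths) / n
        return surv


@dataclass
class ScenarioResult:
    """All runs of one scenario plus cross-run aggregates."""

    config: ScenarioConfig
    registry: ParameterRegistry
    cohort: list[PatientState]
    runs: list[RunResult]
    summary_mean: pd.DataFrame
    summary_sd: pd.DataFrame
    summary_ci95: pd.DataFrame
    occupancy_mean: np.ndarray
    cum_deaths_mean: np.ndarray
    yearly_cost_mean: np.ndarray

    def survival_mean(self) -> np.ndarray:
        return np.mean([r.survival_by_class() for r in self.runs], axis=0)

    def cumulative_cost_per_patient(self) -> np.ndarray:
        """Mean cumulative total cost per patient at each year boundary."""
        return np.cumsum(self.yearly_cost_mean) / self.cohort_size

    @property
    def cohort_size(self) -> int:
        return len(self.cohort)


def _aggregate(summaries: list[pd.DataFrame]):
    stacked = pd.concat(summaries, keys=range(len(summaries)))
    grouped = stacked.groupby(level=1, sort=False)
    mean = grouped.mean()
    sd = grouped.std(ddof=1) if len(summaries) > 1 else mean * 0.0
    ci = 1.96 * sd / math.sqrt(len(summaries))
    return mean, sd, ci


def run_scenario(config: ScenarioConfig, registry: ParameterRegistry | None = None) -> ScenarioResult:
    """Execute all seeded runs of a scenario and aggregate the outcomes."""
    if registry is None:
        registry = load_registry(config.overrides)
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(config.n_runs + 1)
    cohort = generate_cohort(config.cohort, np.random.default_rng(children[0]))
    runs = []
    for child in children[1:]:
        output = simulate_run(
            cohort,
            registry,
            config.horizon_days,
            np.random.default_rng(child),
            toggles=config.toggles,
            tm_program=config.tm_program,
            record_history=config.record_history,
        )
        runs.append(RunResult.from_output(output))
    mean, sd, ci = _aggregate([r.summary for r in runs])
    return ScenarioResult(
        config=config,
        registry=registry,
        cohort=cohort,
        runs=runs,
        summary_mean=mean,
        summary_sd=sd,
        summary_ci95=ci,
        occupancy_mean=np.mean([r.output.occupancy for r in runs], axis=0),
        cum_deaths_mean=np.mean([r.output.cum_deaths for r in runs], axis=0),
        yearly_cost_mean=np.mean([r.output.yearly_cost for r in runs], axis=0),
    )


# --------------------------------------------------------------------------
# Sensitivity analysis


@dataclass
class SensitivityResult:
    """Relative differences (%) of cost and 5-year mortality by age and sex."""

    cost_vs_reference: pd.DataFrame
    mortality_vs_reference: pd.DataFrame
    male_vs_female_cost: pd.DataFrame
    male_vs_female_mortality: pd.DataFrame
    raw_cost: pd.DataFrame
    raw_mortality: pd.DataFrame


def sensitivity_analysis(
    base: ScenarioConfig,
    *,
    ages: tuple = (50, 60, 70, 80, 90),
    reference_age: int = 70,
    registry: ParameterRegistry | None = None,
) -> SensitivityResult:
    """Influence of age, sex and NYHA class on cost and mortality.

    For each (age, sex) cell a fixed-class cohort (class changes disabled) is
    run twice: with mortality disabled for the cost outcome, and with
    mortality enabled for the 5-year mortality outcome.  Contrasts are
    reported as relative percentage differences of across-run means against
    the same-sex reference age, and male vs female at equal age.
    """
    if registry is None:
        registry = load_registry(base.overrides)
    cost = {}
    mort = {}
    for sex_label, sex_mix in (("m", 1.0), ("f", 0.0)):
        for age in ages:
            cohort = replace(base.cohort, age_model=float(age), sex_mix=sex_mix)
            cfg_cost = replace(
                base, cohort=cohort, toggles=SimToggles(False, False, False), name="sens-cost"
            )
            cfg_mort = replace(
                base, cohort=cohort, toggles=SimToggles(True, False, False), name="sens-mort"
            )
            res_c = run_scenario(cfg_cost, registry)
            res_m = run_scenario(cfg_mort, registry)
            key = f"{sex_label}{age}"
            cost[key] = res_c.summary_mean.loc[list(NYHA_CLASSES), "annual_cost_per_patient"]
            mort[key] = res_m.summary_mean.loc[list(NYHA_CLASSES), "mortality_pct"]
    raw_cost = pd.DataFrame(cost).T
    raw_mort = pd.DataFrame(mort).T

    def vs_reference(raw: pd.DataFrame) -> pd.DataFrame:
        rows = {}
        for key in raw.index:
            ref = raw.loc[f"{key[0]}{reference_age}"]
            rows[key] = 100.0 * (raw.loc[key] - ref) / ref
        return pd.DataFrame(rows).T

    def male_vs_female(raw: pd.DataFrame) -> pd.DataFrame:
        rows = {}
        for age in ages:
            m, f = raw.loc[f"m{age}"], raw.loc[f"f{age}"]
            rows[age] = 100.0 * (m - f) / f
        return pd.DataFrame(rows).T

    return SensitivityResult(
        cost_vs_reference=vs_reference(raw_cost),
        mortality_vs_reference=vs_reference(raw_mort),
        male_vs_female_cost=male_vs_female(raw_cost),
        male_vs_female_mortality=male_vs_female(raw_mort),
        raw_cost=raw_cost,
        raw_mortality=raw_mort,
    )


# --------------------------------------------------------------------------
# Program comparison


def break_even_year(conv_cumulative, program_cumulative) -> int | None:
    """First year (1-based) whose cumulative program cost is at or below
    conventional care; ``None`` if the program never breaks even."""
    conv = np.asarray(conv_cumulative, dtype=float)
    prog = np.asarray(program_cumulative, dtype=float)
    hits = np.flatnonzero(prog <= conv)
    return int(hits[0]) + 1 if hits.size else None


@dataclass
class ProgramComparison:
    """Cumulative cost trajectories of conventional care vs programs."""

    cumulative: pd.DataFrame  # index: year 1..Y; columns: arm names
    break_even_year: dict
    first_year_increase_pct: dict

    def arm(self, name: str) -> pd.Series:
        return self.cumulative[name]


def compare_programs(
    conv: ScenarioConfig,
    programs: list[TmProgram],
    registry: ParameterRegistry | None = None,
) -> ProgramComparison:
    """Run conventional care and each program on identical cohorts and seeds.

    Break-even is the first year whose cumulative per-patient cost under the
    program is at or below conventional care.
    """
    if registry is None:
        registry = load_registry(conv.overrides)
    conv_cfg = replace(conv, tm_program=None)
    results = {"conv": run_scenario(conv_cfg, registry)}
    for prog in programs:
        results[prog.name] = run_scenario(replace(conv, tm_program=prog), registry)

    years = np.arange(1, len(results["conv"].yearly_cost_mean) + 1)
    cumulative = pd.DataFrame(
        {name: res.cumulative_cost_per_patient() for name, res in results.items()},
        index=pd.Index(years, name="year"),
    )
    break_even = {}
    first_year = {}
    for name in results:
        if name == "conv":
            continue
        break_even[name] = break_even_year(cumulative["conv"], cumulative[name])
        first_year[name] = float(
            100.0 * (cumulative[name].iloc[0] - cumulative["conv"].iloc[0]) / cumulative["conv"].iloc[0]
        )
    return ProgramComparison(
        cumulative=cumulative,
        break_even_year=break_even,
        first_year_increase_pct=first_year,
    )
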