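"""Inpatient admission episodes: ICU/IMC branching, ward stay, DRG points,
individual medical procedures, per-admission mortality, discharge class change.

Reimbursement follows the Austrian DRG logic: a case flat rate applies to
stays inside an age-dependent treatment window [min_los, max_los]; each day
beyond the window adds supplementary points, and stays shorter than the
window reimburse a reduced per-day rate.  ICU and IMC days are billed at
fixed per-day point rates on top of the case flat rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PatientState, TreatmentLedger
from .params import (
    NYHA_CLASSES,
    ParameterRegistry,
    ValidationError,
    age_bin_index,
)

__all__ = [
    "AdmissionEpisode",
    "compute_drg_points",
    "run_admission",
    "apply_discharge_class_change",
]


@dataclass
class AdmissionEpisode:
    """One full hospital stay with its billing breakdown (in points)."""

    start_day: int
    icu_days: int
    imc_days: int
    ward_los: int
    imp_performed: bool
    imp_points: float
    drg_points: float
    died: bool
    discharge_nyha: str

    def __post_init__(self):
        if self.icu_days > 0 and self.imc_days > 0:
            raise ValidationError("ICU and IMC are mutually exclusive branches")
        if self.ward_los < 1:
            raise ValidationError("ward_los must be at least 1 day")

    @property
    def total_days(self) -> int:
        return self.icu_days + self.imc_days + self.ward_los

    def total_points(self, registry: ParameterRegistry) -> float:
        return (
            self.drg_points
            + self.imp_points
            + self.icu_days * registry.icu_points_per_day
            + self.imc_days * registry.imc_points_per_day
        )

    def total_cost(self, registry: ParameterRegistry) -> float:
        return self.total_points(registry) * registry.point_value


def compute_drg_points(age, ward_los, registry: ParameterRegistry):
    """DRG points for a ward stay (array-safe in ``age`` and ``ward_los``).

    Age >= 65 uses the (min 4, max 11, 3134 points) rule; younger patients
    the (3, 10, 2688) rule.  Within the window the flat rate applies; above
    it, ``supplement_per_day`` per extra day; below it, a per-day short-stay
    rate replaces the flat rate.
    """
    age = np.asarray(age, dtype=float)
    los = np.asarray(ward_los, dtype=float)
    if (los < 1).any():
        raise ValidationError("ward_los must be at least 1 day")

    older = age >= 65.0
    r_lo, r_hi = registry.drg_rules["le64"], registry.drg_rules["ge65"]
    min_los = np.where(older, r_hi.min_los, r_lo.min_los)
    max_los = np.where(older, r_hi.max_los, r_lo.max_los)
    flat = np.where(older, r_hi.flat_rate, r_lo.flat_rate)
    supp = np.where(older, r_hi.supplement_per_day, r_lo.supplement_per_day)
    short = np.where(older, r_hi.short_stay_rate_per_day, r_lo.short_stay_rate_per_day)

    points = np.where(
        los < min_los,
        short * los,
        np.where(los > max_los, flat + supp * (los - max_los), flat),
    )
    return points if points.ndim else float(points)


def run_admission(
    agent: PatientState,
    ledger: TreatmentLedger,
    registry: ParameterRegistry,
    day: int,
    rng: np.random.Generator,
    *,
    inpatient_mortality: bool = True,
    nyha_change: bool = True,
    los_factor: float = 1.0,
) -> AdmissionEpisode:
    """Execute one admission for a single agent, booking all costs.

    Reference (scalar) implementation of the episode logic: branch into ICU
    or IMC (median stay, no mortality there), then the ward stay with a
    NYHA-specific length of stay, DRG reimbursement, a possible individual
    medical procedure, the combined per-admission mortality draw, and the
    discharge NYHA class change for survivors.
    """
    if not agent.alive:
        raise ValidationError("dead agents cannot be admitted")
    age_at = agent.age + 0.0  # caller advances age; use current
    bin_idx = int(age_bin_index(age_at))
    sx = agent.sex_index

    u = rng.random()
    p_icu = registry.icu_probability.as_array()[sx, bin_idx]
    p_imc = registry.imc_probability.as_array()[sx, bin_idx]
    icu_days = imc_days = 0
    if u < p_icu:
        icu_days = registry.icu_los_days[bin_idx]
    elif u < p_icu + p_imc:
        imc_days = registry.imc_los_days[bin_idx]

    spec = registry.los_specs[agent.nyha].scaled(los_factor)
    ward_los = int(spec.ppf(rng.random()))

    drg = float(compute_drg_points(age_at, ward_los, registry))
    has_imp = rng.random() < registry.imp_probability.as_array()[sx, bin_idx]
    imp_pts = float(registry.imp_points.as_array()[sx, bin_idx]) if has_imp else 0.0
    died = bool(
        inpatient_mortality
        and rng.random() < registry.mortality_per_admission.as_array()[sx, bin_idx]
    )
    u_cc = rng.random()
    discharge = agent.nyha
    if not died and nyha_change:
        discharge = _class_from_row(registry.nyha_inpatient[agent.nyha].cumulative(), u_cc)

    pv = registry.point_value
    ledger.add_cost("admission", drg * pv)
    ledger.counters["visits_inpatient_care"] += 1
    ledger.counters["los"] += ward_los
    ward_entry = day + icu_days + imc_days
    if icu_days:
        ledger.add_cost("intensive_care", icu_days * registry.icu_points_per_day * pv)
        ledger.counters["visits_intensive_care"] += 1
        ledger.counters["los_ic"] += icu_days
        ledger.add_event("IC", day, str(icu_days))
    if imc_days:
        ledger.add_cost("intermediate_care", imc_days * registry.imc_points_per_day * pv)
        ledger.counters["visits_intermediate_care"] += 1
        ledger.counters["los_imc"] += imc_days
        ledger.add_event("IM", day, str(imc_days))
    if has_imp:
        ledger.add_cost("imp", imp_pts * pv)
        ledger.counters["visits_imp"] += 1
    ledger.add_event("AD", ward_entry, f"{ward_los}+IMP" if has_imp else str(ward_los))

    episode = AdmissionEpisode(
        start_day=day,
        icu_days=icu_days,
        imc_days=imc_days,
        ward_los=ward_los,
        imp_performed=has_imp,
        imp_points=imp_pts,
        drg_points=drg,
        died=died,
        discharge_nyha=discharge,
    )
    end_day = day + episode.total_days
    if died:
        agent.alive = False
        ledger.add_event("DE", end_day)
    elif discharge != agent.nyha:
        agent.nyha = discharge
        ledger.add_event("CC", end_day, discharge)
    agent.location = "pool" if agent.alive else "pool"
    return episode


def apply_discharge_class_change(
    agent: PatientState, registry: ParameterRegistry, rng: np.random.Generator
) -> str:
    """Draw the discharge NYHA class from the agent's inpatient matrix row."""
    new = _class_from_row(registry.nyha_inpatient[agent.nyha].cumulative(), rng.random())
    agent.nyha = new
    return new


def _class_from_row(cumulative: np.ndarray, u: float) -> str:
    return NYHA_CLASSES[int(np.searchsorted(cumulative[:3], u, side="right"))]
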