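"""Outpatient care: physician/specialist visits, outpatient-clinic visits
with NYHA class changes, and annual medication costs.

Physician and specialist are one combined state reimbursed at the annual
standard rate divided by the mean visit frequency (EUR 544 / 12 per visit).
Outpatient-clinic visits pay a first-visit fee and a lower follow-up fee and
are the only outpatient events that can change the NYHA class.  Medication
is drawn once per patient-year per ATC group (C03 diuretics, C07 beta
blockers, C09 renin-angiotensin agents) from sex-specific distributions; an
ATCxx residual covers all remaining heart-failure medication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import MEDICATION_CATEGORIES, PatientState, TreatmentLedger
from .params import NYHA_CLASSES, ParameterRegistry, ValidationError

__all__ = [
    "FeeSchedule",
    "handle_physician_visit",
    "handle_specialist_visit",
    "handle_clinic_visit",
    "accrue_medication",
    "annual_medication_draws",
]

ATC_GROUPS = ("C03", "C07", "C09")


@dataclass(frozen=True)
class FeeSchedule:
    """Outpatient reimbursement rates (EUR)."""

    physician_annual_mean: float
    clinic_first: float
    clinic_followup: float

    @property
    def physician_per_visit(self) -> float:
        return self.physician_annual_mean / 12.0

    @classmethod
    def from_registry(cls, registry: ParameterRegistry) -> "FeeSchedule":
        f = registry.fees
        return cls(f["physician_annual"], f["clinic_first"], f["clinic_followup"])


def handle_physician_visit(
    agent: PatientState, ledger: TreatmentLedger, registry: ParameterRegistry, day: int
):
    """Book one physician visit.  Never changes the NYHA class."""
    if not agent.alive:
        raise ValidationError("dead agents do not visit physicians")
    ledger.add_cost("physician", registry.physician_fee_per_visit())
    ledger.counters["visits_physician"] += 1
    ledger.add_event("PH", day)


def handle_specialist_visit(
    agent: PatientState, ledger: TreatmentLedger, registry: ParameterRegistry, day: int
):
    if not agent.alive:
        raise ValidationError("dead agents do not visit specialists")
    ledger.add_cost("specialist", registry.physician_fee_per_visit())
    ledger.counters["visits_specialist"] += 1
    ledger.add_event("SP", day)


def handle_clinic_visit(
    agent: PatientState,
    ledger: TreatmentLedger,
    registry: ParameterRegistry,
    day: int,
    rng: np.random.Generator,
    *,
    allow_class_change: bool = True,
) -> str | None:
    """Book one outpatient-clinic visit; possibly draw a NYHA class change.

    Returns the new class if it changed, else ``None``.
    """
    if not agent.alive:
        raise ValidationError("dead agents do not visit the clinic")
    ledger.add_cost("outpatient_clinic", registry.clinic_fee(agent.clinic_visits_so_far))
    agent.clinic_visits_so_far += 1
    ledger.counters["visits_outpatient_clinic"] += 1
    ledger.add_event("OC", day)
    if not allow_class_change:
        return None
    cum = registry.nyha_outpatient[agent.nyha].cumulative()
    new = NYHA_CLASSES[int(np.searchsorted(cum[:3], rng.random(), side="right"))]
    if new != agent.nyha:
        agent.nyha = new
        ledger.add_event("CC", day, new)
        return new
    return None


def annual_medication_draws(
    sex: str, registry: ParameterRegistry, rng: np.random.Generator
) -> np.ndarray:
    """One draw per ATC group (C03, C07, C09) for one patient-year."""
    return np.array(
        [registry.medication_specs[g][sex].sample(rng) for g in ATC_GROUPS]
    )


def accrue_medication(
    agent: PatientState,
    ledger: TreatmentLedger,
    registry: ParameterRegistry,
    rng: np.random.Generator,
    *,
    day: int = 0,
    fraction_of_year: float = 1.0,
) -> np.ndarray:
    """Draw and book one year of medication, prorated by survival fraction.

    The three group draws are booked to their accumulators; the ATCxx
    residual is ``residual_factor`` times the group sum, covering the share
    of heart-failure medication outside C03/C07/C09.
    """
    if not agent.alive:
        return np.zeros(3)
    draws = annual_medication_draws(agent.sex, registry, rng)
    frac = fraction_of_year
    amounts = np.append(draws * frac, registry.medication_residual_factor * draws.sum() * frac)
    for cat, amt in zip(MEDICATION_CATEGORIES, amounts):
        ledger.add_cost(cat, float(amt))
    ledger.add_event("MD", day, ",".join(f"{a:.17g}" for a in amounts))
    return draws
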