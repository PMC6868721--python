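"""Disease-management / telemonitoring overlay.

A program charges a one-time acquisition cost per enrolled patient plus a
monthly fee while the patient is alive, and in exchange lowers the daily
admission probability and the mean ward length of stay of enrolled patients
by fixed factors.  Enrollment is a predicate on the baseline NYHA class
(e.g. TM_1 enrolls everyone, TM_2 excludes class I).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .cohort import PatientState, TreatmentLedger
from .params import (
    DAYS_PER_YEAR,
    NYHA_CLASSES,
    DistributionSpec,
    ParameterRegistry,
    ValidationError,
    annual_rate_to_daily,
)

__all__ = ["TmProgram", "fee_days", "apply_program", "ProgramView", "accrue_program_fees"]

DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # keeps 12 fees per simulated year exact


@dataclass(frozen=True)
class TmProgram:
    """Telemonitoring program definition."""

    acquisition_cost: float = 1000.0
    monthly_fee: float = 45.0
    admission_rate_factor: float = 0.79
    los_mean_factor: float = 0.65
    enrolled_classes: tuple = NYHA_CLASSES
    name: str = "TM"

    def __post_init__(self):
        if not (0.0 < self.admission_rate_factor <= 1.0 and 0.0 < self.los_mean_factor <= 1.0):
            raise ValidationError("program effect factors must lie in (0, 1]")
        if self.acquisition_cost < 0 or self.monthly_fee < 0:
            raise ValidationError("program fees must be non-negative")
        bad = set(self.enrolled_classes) - set(NYHA_CLASSES)
        if bad:
            raise ValidationError(f"unknown NYHA classes in enrollment: {bad}")

    def enrolls(self, nyha: str) -> bool:
        return nyha in self.enrolled_classes

    @classmethod
    def from_registry(
        cls, registry: ParameterRegistry, *, enrolled_classes=NYHA_CLASSES, name="TM"
    ) -> "TmProgram":
        d = registry.telemonitoring_defaults
        return cls(
            acquisition_cost=d["acquisition_cost"],
            monthly_fee=d["monthly_fee"],
            admission_rate_factor=d["admission_rate_factor"],
            los_mean_factor=d["los_mean_factor"],
            enrolled_classes=tuple(enrolled_classes),
            name=name,
        )


@lru_cache(maxsize=None)
def fee_days(horizon_days: int) -> tuple:
    """Days on which the monthly fee falls due (month = 365/12 days)."""
    days = []
    m = 0
    while True:
        d = int(m * DAYS_PER_MONTH)
        if d >= horizon_days:
            break
        days.append(d)
        m += 1
    return tuple(days)


@dataclass(frozen=True)
class ProgramView:
    """Registry view with the program's effect factors applied (enrolled agents)."""

    registry: ParameterRegistry
    program: TmProgram

    def daily_admission_probability(self, nyha: str) -> float:
        p = annual_rate_to_daily(self.registry.admission_rate_per_year[nyha])
        if self.program.enrolls(nyha):
            p *= self.program.admission_rate_factor
        return p

    def los_spec(self, nyha: str) -> DistributionSpec:
        spec = self.registry.los_specs[nyha]
        return spec.scaled(self.program.los_mean_factor) if self.program.enrolls(nyha) else spec


def apply_program(registry: ParameterRegistry, program: TmProgram) -> ProgramView:
    """Admission-probability / LOS view of the registry under a program."""
    return ProgramView(registry, program)


def accrue_program_fees(
    agent: PatientState,
    ledger: TreatmentLedger,
    day: int,
    program: TmProgram,
    *,
    horizon_days: int | None = None,
):
    """Book program fees due on ``day`` for an enrolled, living agent.

    The acquisition cost is booked once at day 0 (equipment is purchased up
    front regardless of later death); the monthly fee falls due on each
    365/12-day boundary while the agent is alive.
    """
    if not agent.alive or not program.enrolls(agent.nyha):
        return
    if day == 0:
        ledger.add_cost("dmp_acquisition", program.acquisition_cost)
    schedule = fee_days(horizon_days if horizon_days is not None else day + 1)
    if day in schedule:
        ledger.add_cost("dmp_fixed_rate", program.monthly_fee)
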