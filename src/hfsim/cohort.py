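"""Agents, their treatment ledgers, history files, and cohort generation.

Each patient is an agent whose inner state (age, sex, NYHA class) conditions
the daily transition probabilities of the pathway, and whose ledger logs
itemized costs, visit counts, lengths of stay and a tokenized history such
as ``PH5 OC28 IC52 AD54 CC64`` (physician visit day 5, clinic visit day 28,
intensive care from day 52, ward admission day 54, class change day 64).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    NYHA_CLASSES,
    SEX_LABELS,
    DistributionSpec,
    ParameterRegistry,
    ValidationError,
    age_bin_index,
)

__all__ = [
    "COST_CATEGORIES",
    "OUTPATIENT_CATEGORIES",
    "MEDICATION_CATEGORIES",
    "INPATIENT_CATEGORIES",
    "DMP_CATEGORIES",
    "VISIT_COUNTERS",
    "PatientState",
    "TreatmentLedger",
    "HistoryEvent",
    "CohortSpec",
    "generate_cohort",
    "render_history",
    "parse_history",
    "replay_history",
    "ReplayReport",
    "cohort_to_frame",
    "cohort_from_frame",
]

MEDICATION_CATEGORIES = ("atc03", "atc07", "atc09", "atcxx")
OUTPATIENT_CATEGORIES = ("outpatient_clinic", "physician", "specialist") + MEDICATION_CATEGORIES
INPATIENT_CATEGORIES = ("admission", "intensive_care", "intermediate_care", "imp")
DMP_CATEGORIES = ("dmp_acquisition", "dmp_fixed_rate")
COST_CATEGORIES = OUTPATIENT_CATEGORIES + INPATIENT_CATEGORIES + DMP_CATEGORIES

VISIT_COUNTERS = (
    "visits_physician",
    "visits_specialist",
    "visits_outpatient_clinic",
    "visits_inpatient_care",
    "visits_intensive_care",
    "visits_intermediate_care",
    "visits_imp",
)
DAY_COUNTERS = ("los", "los_ic", "los_imc")

# History token codes: PH physician, SP specialist, OC outpatient clinic,
# AD ward admission, IC intensive care, IM intermediate care, CC class
# change, DE death, MD medication settlement (annual amounts, logged so a
# replay can reproduce the ledger without re-drawing).
HISTORY_CODES = ("PH", "SP", "OC", "AD", "IC", "IM", "CC", "DE", "MD")

_TOKEN_RE = re.compile(r"^([A-Z]{2})(\d+)(?::(\S+))?$")


@dataclass
class HistoryEvent:
    code: str
    day: int
    detail: str | None = None

    def token(self) -> str:
        base = f"{self.code}{self.day}"
        return f"{base}:{self.detail}" if self.detail is not None else base


@dataclass
class PatientState:
    """Inner state of one agent; conditions all transition probabilities."""

    id: int
    age: float
    sex: str
    nyha: str
    alive: bool = True
    location: str = "pool"
    tm_enrolled: bool = False
    clinic_visits_so_far: int = 0

    def __post_init__(self):
        if self.age < 0:
            raise ValidationError("age must be non-negative")
        if self.sex not in SEX_LABELS:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.nyha not in NYHA_CLASSES:
            raise ValidationError(f"unknown NYHA class {self.nyha!r}")

    @property
    def sex_index(self) -> int:
        return SEX_LABELS.index(self.sex)

    @property
    def nyha_index(self) -> int:
        """1-based NYHA class index."""
        return NYHA_CLASSES.index(self.nyha) + 1


@dataclass
class TreatmentLedger:
    """Per-agent auxiliary record: euro accumulators, counters, history."""

    costs: dict = field(default_factory=lambda: {c: 0.0 for c in COST_CATEGORIES})
    counters: dict = field(
        default_factory=lambda: {c: 0 for c in VISIT_COUNTERS + DAY_COUNTERS}
    )
    history: list = field(default_factory=list)

    def add_cost(self, category: str, amount: float):
        if amount < 0:
            raise ValidationError("cost amounts must be non-negative")
        self.costs[category] += amount

    def add_event(self, code: str, day: int, detail: str | None = None):
        if self.history and day < self.history[-1].day:
            raise ValidationError("history days must be non-decreasing")
        self.history.append(HistoryEvent(code, day, detail))

    @property
    def total_cost(self) -> float:
        return sum(self.costs.values())

    def outpatient_cost(self) -> float:
        return sum(self.costs[c] for c in OUTPATIENT_CATEGORIES)

    def inpatient_cost(self) -> float:
        return sum(self.costs[c] for c in INPATIENT_CATEGORIES)


# --------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a simulated cohort.

    ``age_model`` is either a fixed age in years or a :class:`DistributionSpec`
    from which baseline ages are drawn.  Class and sex counts are allocated
    deterministically by largest remainder, so e.g. an even four-class mix of
    10,000 patients yields exactly 2,500 per class.
    """

    n_patients: int
    nyha_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    age_model: float | DistributionSpec = 70.0
    sex_mix: float = 0.5  # fraction male

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        mix = np.asarray(self.nyha_mix, dtype=float)
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValidationError("nyha_mix must be non-negative and sum to 1")
        if not 0.0 <= self.sex_mix <= 1.0:
            raise ValidationError("sex_mix must lie in [0, 1]")


def largest_remainder_allocation(n: int, fractions) -> np.ndarray:
    """Integer counts summing to ``n``; ties broken toward lower indices."""
    fractions = np.asarray(fractions, dtype=float)
    ideal = n * fractions
    base = np.floor(ideal).astype(int)
    leftover = int(round(n - base.sum()))
    # stable sort on negative remainders: ties keep original (class) order
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:leftover]] += 1
    return base


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[PatientState]:
    """Generate exactly ``spec.n_patients`` agents matching the composition."""
    class_counts = largest_remainder_allocation(spec.n_patients, spec.nyha_mix)
    agents: list[PatientState] = []
    next_id = 0
    for ci, nyha in enumerate(NYHA_CLASSES):
        n_c = int(class_counts[ci])
        n_male = int(largest_remainder_allocation(n_c, [spec.sex_mix, 1 - spec.sex_mix])[0])
        for j in range(n_c):
            sex = "male" if j < n_male else "female"
            if isinstance(spec.age_model, DistributionSpec):
                age = float(spec.age_model.ppf(rng.random()))
            else:
                age = float(spec.age_model)
            agents.append(PatientState(id=next_id, age=age, sex=sex, nyha=nyha))
            next_id += 1
    return agents


def cohort_to_frame(agents: list[PatientState]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [a.id for a in agents],
            "age": [a.age for a in agents],
            "sex": [a.sex for a in agents],
            "nyha": [a.nyha for a in agents],
        }
    )


def cohort_from_frame(frame: pd.DataFrame) -> list[PatientState]:
    return [
        PatientState(id=int(r.id), age=float(r.age), sex=str(r.sex), nyha=str(r.nyha))
        for r in frame.itertuples()
    ]


# --------------------------------------------------------------------------
# History rendering and replay


def render_history(ledger: TreatmentLedger) -> str:
    """Space-separated ``code day[:detail]`` tokens in chronological order."""
    return " ".join(ev.token() for ev in ledger.history)


def parse_history(text: str) -> list[HistoryEvent]:
    events = []
    last_day = -1
    for tok in text.split():
        m = _TOKEN_RE.match(tok)
        if not m or m.group(1) not in HISTORY_CODES:
            raise ValidationError(f"malformed history token {tok!r}")
        ev = HistoryEvent(m.group(1), int(m.group(2)), m.group(3))
        if ev.day < last_day:
            raise ValidationError(f"history days decrease at token {tok!r}")
        last_day = ev.day
        events.append(ev)
    return events


@dataclass
class ReplayReport:
    """Outcome of recomputing a ledger from its history file."""

    ledger: TreatmentLedger
    mismatches: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def compare(self, expected_costs: dict) -> "ReplayReport":
        for cat, exp in expected_costs.items():
            got = self.ledger.costs.get(cat, 0.0)
            if got != exp:
                self.mismatches[cat] = (got, exp)
        return self


def replay_history(
    text: str,
    registry: ParameterRegistry,
    *,
    baseline: PatientState | None = None,
    horizon_days: int | None = None,
    program=None,
    expected_costs: dict | None = None,
) -> ReplayReport:
    """Recompute cost accumulators from a history file.

    This is the model's own verification procedure: every euro booked during
    a simulation is recomputable from the event log plus the deterministic
    cost inputs recorded with it (lengths of stay, medication settlements).
    ``baseline`` (age/sex at day 0) is required once admission tokens are
    present; ``program`` and ``horizon_days`` are required to reproduce
    disease-management fees.
    """
    events = parse_history(text)
    ledger = TreatmentLedger()
    pv = registry.point_value
    phys_fee = registry.physician_fee_per_visit()
    clinic_visits = 0
    pending_icu = pending_imc = 0
    episode_start: int | None = None
    death_day: int | None = None

    for ev in events:
        if ev.code == "PH":
            ledger.add_cost("physician", phys_fee)
            ledger.counters["visits_physician"] += 1
        elif ev.code == "SP":
            ledger.add_cost("specialist", phys_fee)
            ledger.counters["visits_specialist"] += 1
        elif ev.code == "OC":
            ledger.add_cost("outpatient_clinic", registry.clinic_fee(clinic_visits))
            clinic_visits += 1
            ledger.counters["visits_outpatient_clinic"] += 1
        elif ev.code == "IC":
            pending_icu = int(ev.detail) if ev.detail else 0
            episode_start = ev.day
        elif ev.code == "IM":
            pending_imc = int(ev.detail) if ev.detail else 0
            episode_start = ev.day
        elif ev.code == "AD":
            if baseline is None:
                raise ValidationError("replay of admissions requires the baseline agent state")
            start = episode_start if episode_start is not None else ev.day
            age_at = baseline.age + start / 365.0
            detail = ev.detail or ""
            parts = detail.split("+")
            ward_los = int(parts[0]) if parts[0] else 0
            has_imp = len(parts) > 1 and parts[1] == "IMP"
            from .inpatient import compute_drg_points  # deferred: avoids import cycle

            ledger.add_cost("admission", float(compute_drg_points(age_at, ward_los, registry)) * pv)
            if pending_icu:
                ledger.add_cost("intensive_care", pending_icu * registry.icu_points_per_day * pv)
                ledger.counters["visits_intensive_care"] += 1
                ledger.counters["los_ic"] += pending_icu
            if pending_imc:
                ledger.add_cost("intermediate_care", pending_imc * registry.imc_points_per_day * pv)
                ledger.counters["visits_intermediate_care"] += 1
                ledger.counters["los_imc"] += pending_imc
            if has_imp:
                bin_idx = int(age_bin_index(age_at))
                pts = registry.imp_points.as_array()[baseline.sex_index, bin_idx]
                ledger.add_cost("imp", float(pts) * pv)
                ledger.counters["visits_imp"] += 1
            ledger.counters["visits_inpatient_care"] += 1
            ledger.counters["los"] += ward_los
            pending_icu = pending_imc = 0
            episode_start = None
        elif ev.code == "MD":
            amounts = [float(x) for x in (ev.detail or "").split(",")]
            if len(amounts) != 4:
                raise ValidationError(f"malformed MD detail {ev.detail!r}")
            for cat, amt in zip(MEDICATION_CATEGORIES, amounts):
                ledger.costs[cat] += amt
        elif ev.code == "DE":
            death_day = ev.day
        ledger.history.append(ev)

    if program is not None and baseline is not None and program.enrolls(baseline.nyha):
        if horizon_days is None:
            raise ValidationError("replaying program fees requires horizon_days")
        from .telemonitoring import fee_days  # deferred: avoids import cycle

        ledger.costs["dmp_acquisition"] += program.acquisition_cost
        for f in fee_days(horizon_days):
            if death_day is None or f < death_day:
                ledger.costs["dmp_fixed_rate"] += program.monthly_fee

    report = ReplayReport(ledger)
    if expected_costs is not None:
        report.compare(expected_costs)
    return report
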