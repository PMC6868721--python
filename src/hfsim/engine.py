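"""Daily-step stochastic pathway engine and its deterministic verification
oracle.

Each simulated day, every living agent in the patient pool makes exactly one
categorical draw over {stay, outpatient death, outpatient clinic, hospital
admission, physician, specialist}; the chosen event is dispatched to the
owning care module.  Agents inside a multi-day hospital episode decrement
their remaining stay instead of drawing.  Competing daily risks are resolved
by a single categorical draw (not independent Bernoullis), matching the
one-transition-per-step semantics of the underlying discrete Markov model at
a one-day sampling step.

The engine is vectorized over agents: each decision channel consumes one
fixed-shape uniform array per day, positionally indexed by agent.  This makes
trajectories deterministic given (config, seed), independent of scheduling
order, and leaves non-enrolled agents' trajectories untouched when a
telemonitoring overlay changes only enrolled agents' parameters.

:func:`propagate_expected_occupancy` iterates the deterministic
expected-occupancy recurrence

    P[i, k+1] = P[i, k] + (sum_j P[j, k] p_ji - sum_j P[i, k] p_ij) * dt

used to cross-check Monte-Carlo occupancies on homogeneous kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    COST_CATEGORIES,
    DAY_COUNTERS,
    HistoryEvent,
    PatientState,
    TreatmentLedger,
    VISIT_COUNTERS,
)
from .inpatient import compute_drg_points
from .params import NYHA_CLASSES, ParameterRegistry, ValidationError, age_bin_index
from .telemonitoring import TmProgram, fee_days

__all__ = [
    "SimToggles",
    "TransitionKernel",
    "propagate_expected_occupancy",
    "RunOutput",
    "simulate_run",
    "step_day",
    "Simulation",
]


@dataclass(frozen=True)
class SimToggles:
    """Switchable model channels, mirroring the published scenario setups."""

    inpatient_mortality: bool = True
    nyha_changes_outpatient: bool = True
    nyha_changes_inpatient: bool = True


# --------------------------------------------------------------------------
# Generic kernel + deterministic propagator (verification oracle)


class TransitionKernel:
    """A state-homogeneous daily transition kernel.

    ``matrix[i, j]`` is the probability of moving from state i to state j in
    one day (off-diagonal); the residual mass is the stay-in-state
    probability.  Used both by the deterministic expected-occupancy
    propagator and by a direct Monte-Carlo chain simulation, whose agreement
    is the discrete-event / agent-based consistency check.
    """

    def __init__(self, matrix):
        m = np.array(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("kernel matrix must be square")
        np.fill_diagonal(m, 0.0)
        if (m < 0).any() or (m > 1).any():
            raise ValidationError("transition probabilities must lie in [0, 1]")
        if (m.sum(axis=1) > 1.0 + 1e-12).any():
            raise ValidationError("outgoing probability mass exceeds 1 in some state")
        self.matrix = m
        self.n_states = m.shape[0]

    def stochastic_matrix(self) -> np.ndarray:
        full = self.matrix.copy()
        np.fill_diagonal(full, 1.0 - self.matrix.sum(axis=1))
        return full

    def simulate(self, p0, n_agents: int, n_days: int, rng: np.random.Generator) -> np.ndarray:
        """Monte-Carlo occupancy counts, shape (n_days + 1, n_states)."""
        p0 = np.asarray(p0, dtype=float)
        state = rng.choice(self.n_states, size=n_agents, p=p0)
        cum = np.cumsum(self.stochastic_matrix(), axis=1)
        counts = np.empty((n_days + 1, self.n_states), dtype=np.int64)
        counts[0] = np.bincount(state, minlength=self.n_states)
        for d in range(n_days):
            u = rng.random(n_agents)
            state = (u[:, None] >= cum[state][:, :-1]).sum(axis=1)
            counts[d + 1] = np.bincount(state, minlength=self.n_states)
        return counts


def propagate_expected_occupancy(p0, kernel: TransitionKernel, n_days: int) -> np.ndarray:
    """Deterministic expected state occupancy, shape (n_days + 1, n_states).

    Exact iteration of the balance recurrence; total mass is conserved at
    every step by construction.
    """
    p = np.asarray(p0, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("initial occupancy must sum to 1")
    out = np.empty((n_days + 1, kernel.n_states))
    out[0] = p
    k = kernel.matrix
    outflow = k.sum(axis=1)
    for d in range(n_days):
        p = p + (p @ k - p * outflow)
        out[d + 1] = p
    return out


# --------------------------------------------------------------------------
# Vectorized cohort simulation


@dataclass
class RunOutput:
    """All per-agent and per-day outcomes of one simulation run."""

    horizon_days: int
    age0: np.ndarray
    sex: np.ndarray  # 0 = male, 1 = female
    nyha_start: np.ndarray  # 1..4
    nyha_final: np.ndarray
    enrolled: np.ndarray
    costs: dict  # category -> float array (n,)
    counters: dict  # counter -> int array (n,)
    death_day: np.ndarray  # -1 while alive at horizon
    occupancy: np.ndarray  # (horizon + 1, 4) living agents per current class
    cum_deaths: np.ndarray  # (horizon + 1,)
    yearly_cost: np.ndarray  # total euros booked per simulated year
    histories: list | None = None

    @property
    def n_patients(self) -> int:
        return self.age0.shape[0]

    @property
    def alive(self) -> np.ndarray:
        return self.death_day < 0

    def total_cost(self) -> np.ndarray:
        return sum(self.costs[c] for c in COST_CATEGORIES)

    def person_days(self) -> np.ndarray:
        return np.where(self.death_day < 0, self.horizon_days, self.death_day)

    def to_ledgers(self) -> list[TreatmentLedger]:
        """Materialize per-agent ledgers (requires record_history=True)."""
        if self.histories is None:
            raise ValidationError("run was executed without history recording")
        ledgers = []
        for i in range(self.n_patients):
            led = TreatmentLedger()
            for c in COST_CATEGORIES:
                led.costs[c] = float(self.costs[c][i])
            for c in VISIT_COUNTERS + DAY_COUNTERS:
                led.counters[c] = int(self.counters[c][i])
            led.history = [HistoryEvent(code, day, detail) for day, _, code, detail in sorted(self.histories[i])]
            ledgers.append(led)
        return ledgers


class Simulation:
    """Mutable state of one vectorized run; advanced one day at a time."""

    def __init__(
        self,
        agents: list[PatientState],
        registry: ParameterRegistry,
        horizon_days: int,
        rng: np.random.Generator,
        *,
        toggles: SimToggles = SimToggles(),
        tm_program: TmProgram | None = None,
        record_history: bool = False,
    ):
        if horizon_days <= 0:
            raise ValidationError("horizon_days must be positive")
        self.registry = registry
        self.horizon = int(horizon_days)
        self.rng = rng
        self.toggles = toggles
        self.program = tm_program
        n = len(agents)
        self.n = n

        self.age0 = np.array([a.age for a in agents], dtype=float)
        self.sex = np.array([a.sex_index for a in agents], dtype=np.int8)
        self.nyha = np.array([a.nyha_index for a in agents], dtype=np.int8)
        self.nyha_start = self.nyha.copy()
        self.alive = np.ones(n, dtype=bool)
        self.remaining = np.zeros(n, dtype=np.int32)
        self.pending_death = np.zeros(n, dtype=bool)
        self.pending_class = np.zeros(n, dtype=np.int8)
        self.death_day = np.full(n, -1, dtype=np.int32)

        self.costs = {c: np.zeros(n) for c in COST_CATEGORIES}
        self.counters = {c: np.zeros(n, dtype=np.int64) for c in VISIT_COUNTERS + DAY_COUNTERS}

        if tm_program is not None:
            self.enrolled = np.array(
                [tm_program.enrolls(NYHA_CLASSES[c - 1]) for c in self.nyha], dtype=bool
            )
            self.adm_factor = np.where(self.enrolled, tm_program.admission_rate_factor, 1.0)
            self.los_factor = np.where(self.enrolled, tm_program.los_mean_factor, 1.0)
            self.fee_days = set(fee_days(self.horizon))
        else:
            self.enrolled = np.zeros(n, dtype=bool)
            self.adm_factor = np.ones(n)
            self.los_factor = np.ones(n)
            self.fee_days = set()

        # registry tables as arrays
        reg = registry
        self.p00 = reg.p_outpatient_death
        self.p01 = reg.p_clinic
        self.p03 = reg.p_physician
        self.p04 = reg.p_specialist
        self.p_adm = np.array(
            [0.0] + [reg.daily_admission_probability(c) for c in NYHA_CLASSES]
        )
        self.icu_p = reg.icu_probability.as_array()
        self.imc_p = reg.imc_probability.as_array()
        self.icu_los = np.asarray(reg.icu_los_days, dtype=np.int32)
        self.imc_los = np.asarray(reg.imc_los_days, dtype=np.int32)
        self.imp_p = reg.imp_probability.as_array()
        self.imp_pts = reg.imp_points.as_array()
        self.mort = reg.mortality_per_admission.as_array()
        self.out_cum = np.vstack([reg.nyha_outpatient[c].cumulative() for c in NYHA_CLASSES])
        self.in_cum = np.vstack([reg.nyha_inpatient[c].cumulative() for c in NYHA_CLASSES])
        self.los_specs = [None] + [reg.los_specs[c] for c in NYHA_CLASSES]
        self.med_specs = {
            s: [reg.medication_specs[g][("male", "female")[s]] for g in ("C03", "C07", "C09")]
            for s in (0, 1)
        }
        self.phys_fee = reg.physician_fee_per_visit()
        self.pv = reg.point_value

        # collectors
        self.occ_delta = np.zeros((self.horizon + 1, 4))
        self.occ_delta[0] = np.bincount(self.nyha, minlength=5)[1:5]
        self.deaths_by_day = np.zeros(self.horizon + 1)
        self.n_years = -(-self.horizon // 365)
        self.yearly = np.zeros(self.n_years)
        self.med_draws = np.zeros((n, 3))
        self.seg_start = 0
        self.record_history = record_history
        self.histories = [[] for _ in range(n)] if record_history else None
        self._seq = 0

        if tm_program is not None and self.enrolled.any():
            amt = tm_program.acquisition_cost
            self.costs["dmp_acquisition"][self.enrolled] += amt
            self.yearly[0] += amt * int(self.enrolled.sum())

    # -- helpers ------------------------------------------------------------

    def _log(self, idx, day, code, details=None):
        if not self.record_history:
            return
        for k, i in enumerate(idx):
            det = None if details is None else details[k]
            self.histories[int(i)].append((int(day), self._seq, code, det))
            self._seq += 1

    def _book(self, category, idx, amounts, day):
        self.costs[category][idx] += amounts
        self.yearly[min(day // 365, self.n_years - 1)] += float(np.sum(amounts))

    def _change_class(self, idx, new_class, day):
        changed = new_class != self.nyha[idx]
        sel = idx[changed]
        if sel.size == 0:
            return
        np.add.at(self.occ_delta[day + 1], self.nyha[sel] - 1, -1.0)
        np.add.at(self.occ_delta[day + 1], new_class[changed] - 1, 1.0)
        self.nyha[sel] = new_class[changed]
        self._log(sel, day, "CC", [NYHA_CLASSES[c - 1] for c in new_class[changed]])

    def _kill(self, idx, day):
        if idx.size == 0:
            return
        self.alive[idx] = False
        self.death_day[idx] = day
        self.deaths_by_day[day + 1] += idx.size
        np.add.at(self.occ_delta[day + 1], self.nyha[idx] - 1, -1.0)
        self._log(idx, day, "DE")

    def _draw_new_class(self, cum, current, u):
        rows = cum[current - 1]
        return (1 + (u[:, None] >= rows[:, :3]).sum(axis=1)).astype(np.int8)

    # -- daily step ----------------------------------------------------------

    def step(self, day: int):
        rng = self.rng
        n = self.n
        year = day // 365

        # annual medication draw for living agents
        if day % 365 == 0:
            u_med = rng.random((n, 3))
            draws = np.zeros((n, 3))
            for s in (0, 1):
                mask = self.alive & (self.sex == s)
                if mask.any():
                    for g, spec in enumerate(self.med_specs[s]):
                        draws[mask, g] = spec.ppf(u_med[mask, g])
            self.med_draws = draws
            self.seg_start = day

        # resolve hospital episodes
        in_ep = self.remaining > 0
        if in_ep.any():
            self.remaining[in_ep] -= 1
            done = in_ep & (self.remaining == 0)
            if done.any():
                dies = done & self.pending_death
                self._kill(np.flatnonzero(dies), day)
                disch = np.flatnonzero(done & ~dies & (self.pending_class > 0))
                if disch.size:
                    self._change_class(disch, self.pending_class[disch], day)
                self.pending_death[done] = False
                self.pending_class[done] = 0

        # one decision channel per day per agent: fixed-shape uniforms keep
        # agents positionally aligned across scenario arms
        u_ev = rng.random(n)
        u_branch = rng.random(n)
        u_los = rng.random(n)
        u_imp = rng.random(n)
        u_mort = rng.random(n)
        u_dcc = rng.random(n)
        u_ccc = rng.random(n)

        pool = self.alive & (self.remaining == 0)
        p_hosp = self.p_adm[self.nyha] * self.adm_factor
        t0 = self.p00
        t1 = t0 + self.p01
        t2 = t1 + p_hosp
        t3 = t2 + self.p03
        t4 = t3 + self.p04

        self._kill(np.flatnonzero(pool & (u_ev < t0)), day)

        clinic = np.flatnonzero(pool & (u_ev >= t0) & (u_ev < t1))
        if clinic.size:
            fee = np.where(
                self.counters["visits_outpatient_clinic"][clinic] == 0,
                self.registry.fees["clinic_first"],
                self.registry.fees["clinic_followup"],
            )
            self._book("outpatient_clinic", clinic, fee, day)
            self.counters["visits_outpatient_clinic"][clinic] += 1
            self._log(clinic, day, "OC")
            if self.toggles.nyha_changes_outpatient:
                new = self._draw_new_class(self.out_cum, self.nyha[clinic], u_ccc[clinic])
                self._change_class(clinic, new, day)

        admit = np.flatnonzero(pool & (u_ev >= t1) & (u_ev < t2))
        if admit.size:
            self._admit(admit, day, u_branch, u_los, u_imp, u_mort, u_dcc)

        phys = np.flatnonzero(pool & (u_ev >= t2) & (u_ev < t3))
        if phys.size:
            self._book("physician", phys, np.full(phys.size, self.phys_fee), day)
            self.counters["visits_physician"][phys] += 1
            self._log(phys, day, "PH")

        spec = np.flatnonzero(pool & (u_ev >= t3) & (u_ev < t4))
        if spec.size:
            self._book("specialist", spec, np.full(spec.size, self.phys_fee), day)
            self.counters["visits_specialist"][spec] += 1
            self._log(spec, day, "SP")

        # monthly telemonitoring fee for living enrolled agents
        if day in self.fee_days:
            due = np.flatnonzero(self.enrolled & self.alive)
            if due.size:
                self._book("dmp_fixed_rate", due, np.full(due.size, self.program.monthly_fee), day)

        # settle the medication year at year boundaries and at the horizon
        if (day + 1) % 365 == 0 or day + 1 == self.horizon:
            self._settle_medication(min(self.seg_start + 365, self.horizon), year)

    def _admit(self, idx, day, u_branch, u_los, u_imp, u_mort, u_dcc):
        age = self.age0[idx] + day / 365.0
        bins = age_bin_index(age)
        sx = self.sex[idx]

        ub = u_branch[idx]
        p_icu = self.icu_p[sx, bins]
        p_imc = self.imc_p[sx, bins]
        is_icu = ub < p_icu
        is_imc = ~is_icu & (ub < p_icu + p_imc)
        icu_d = np.where(is_icu, self.icu_los[bins], 0).astype(np.int32)
        imc_d = np.where(is_imc, self.imc_los[bins], 0).astype(np.int32)

        los = np.empty(idx.size)
        cls = self.nyha[idx]
        for c in (1, 2, 3, 4):
            sel = cls == c
            if sel.any():
                spec = self.los_specs[c]
                los[sel] = spec.ppf_unrounded(u_los[idx][sel]) * self.los_factor[idx][sel]
        los = np.maximum(np.rint(los), 1.0).astype(np.int32)

        drg = np.asarray(compute_drg_points(age, los, self.registry), dtype=float)
        has_imp = u_imp[idx] < self.imp_p[sx, bins]
        imp_points = np.where(has_imp, self.imp_pts[sx, bins], 0.0)
        dies = (
            (u_mort[idx] < self.mort[sx, bins])
            if self.toggles.inpatient_mortality
            else np.zeros(idx.size, dtype=bool)
        )

        self.remaining[idx] = icu_d + imc_d + los
        self.pending_death[idx] = dies
        if self.toggles.nyha_changes_inpatient:
            new = self._draw_new_class(self.in_cum, cls, u_dcc[idx])
            self.pending_class[idx] = np.where(dies, 0, new)
        else:
            self.pending_class[idx] = np.where(dies, 0, cls)

        pv = self.pv
        self._book("admission", idx, drg * pv, day)
        self._book("intensive_care", idx, icu_d * (self.registry.icu_points_per_day * pv), day)
        self._book("intermediate_care", idx, imc_d * (self.registry.imc_points_per_day * pv), day)
        self._book("imp", idx, imp_points * pv, day)
        self.counters["visits_inpatient_care"][idx] += 1
        self.counters["visits_intensive_care"][idx] += is_icu
        self.counters["visits_intermediate_care"][idx] += is_imc
        self.counters["visits_imp"][idx] += has_imp
        self.counters["los"][idx] += los
        self.counters["los_ic"][idx] += icu_d
        self.counters["los_imc"][idx] += imc_d

        if self.record_history:
            icu_sel = np.flatnonzero(is_icu)
            self._log(idx[icu_sel], day, "IC", [str(int(d)) for d in icu_d[icu_sel]])
            imc_sel = np.flatnonzero(is_imc)
            self._log(idx[imc_sel], day, "IM", [str(int(d)) for d in imc_d[imc_sel]])
            details = [
                f"{int(l)}+IMP" if imp else str(int(l)) for l, imp in zip(los, has_imp)
            ]
            # the ward token is logged at ward entry (after any ICU/IMC days)
            for k, i in enumerate(idx):
                entry = int(day + icu_d[k] + imc_d[k])
                self.histories[int(i)].append((entry, self._seq, "AD", details[k]))
                self._seq += 1

    def _settle_medication(self, seg_end, year):
        days = np.where(
            self.death_day >= 0,
            np.clip(self.death_day - self.seg_start, 0, None),
            seg_end - self.seg_start,
        )
        frac = days / 365.0
        amounts = self.med_draws * frac[:, None]
        residual = (
            self.registry.medication_residual_factor * self.med_draws.sum(axis=1) * frac
        )
        for g, cat in enumerate(("atc03", "atc07", "atc09")):
            self.costs[cat] += amounts[:, g]
        self.costs["atcxx"] += residual
        self.yearly[min(year, self.n_years - 1)] += float(amounts.sum() + residual.sum())
        if self.record_history:
            total = amounts.sum(axis=1) + residual
            for i in np.flatnonzero(total > 0):
                md_day = int(self.death_day[i]) if self.death_day[i] >= 0 else seg_end - 1
                det = ",".join(
                    f"{a:.17g}" for a in (*amounts[i], residual[i])
                )
                self.histories[i].append((md_day, self._seq, "MD", det))
                self._seq += 1
        self.med_draws = np.zeros((self.n, 3))
        self.seg_start = seg_end

    def finish(self) -> RunOutput:
        occupancy = np.cumsum(self.occ_delta, axis=0)
        cum_deaths = np.cumsum(self.deaths_by_day)
        return RunOutput(
            horizon_days=self.horizon,
            age0=self.age0,
            sex=self.sex,
            nyha_start=self.nyha_start,
            nyha_final=self.nyha.copy(),
            enrolled=self.enrolled,
            costs=self.costs,
            counters=self.counters,
            death_day=self.death_day,
            occupancy=occupancy,
            cum_deaths=cum_deaths,
            yearly_cost=self.yearly,
            histories=self.histories,
        )


def step_day(sim: Simulation, day: int) -> Simulation:
    """Advance a running simulation by one day (thin wrapper over .step)."""
    sim.step(day)
    return sim


def simulate_run(
    agents: list[PatientState],
    registry: ParameterRegistry,
    horizon_days: int,
    rng: np.random.Generator,
    *,
    toggles: SimToggles = SimToggles(),
    tm_program: TmProgram | None = None,
    record_history: bool = False,
) -> RunOutput:
    """Simulate one cohort over ``horizon_days`` days."""
    sim = Simulation(
        agents,
        registry,
        horizon_days,
        rng,
        toggles=toggles,
        tm_program=tm_program,
        record_history=record_history,
    )
    for day in range(sim.horizon):
        sim.step(day)
    return sim.finish()
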