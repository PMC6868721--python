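"""Engine semantics: kernel propagation, determinism, death handling."""

import numpy as np
import pytest

from hfsim.cohort import CohortSpec, generate_cohort
from hfsim.engine import (
    SimToggles,
    TransitionKernel,
    propagate_expected_occupancy,
    simulate_run,
)
from hfsim.params import ValidationError, load_registry

TOGGLES_ON = SimToggles(True, True, True)
TOGGLES_OFF = SimToggles(False, False, False)


class TestPropagator:
    def test_identity_kernel_is_stationary(self):
        k = TransitionKernel(np.zeros((3, 3)))
        p0 = [0.2, 0.5, 0.3]
        occ = propagate_expected_occupancy(p0, k, 10)
        assert np.allclose(occ, np.tile(p0, (11, 1)))

    def test_mass_conserved(self):
        k = TransitionKernel([[0, 0.2, 0.1], [0.05, 0, 0.3], [0.4, 0.1, 0]])
        occ = propagate_expected_occupancy([1.0, 0.0, 0.0], k, 200)
        assert np.allclose(occ.sum(axis=1), 1.0)

    def test_two_state_closed_form(self):
        a, b = 0.37, 0.11
        k = TransitionKernel([[0, a], [b, 0]])
        occ = propagate_expected_occupancy([1.0, 0.0], k, 80)
        stat = b / (a + b)
        expected = stat + (1 - stat) * (1 - a - b) ** np.arange(81)
        assert np.allclose(occ[:, 0], expected)

    def test_unnormalized_start_rejected(self):
        k = TransitionKernel(np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            propagate_expected_occupancy([0.7, 0.7], k, 5)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValidationError):
            TransitionKernel([[0, 0.8, 0.5], [0.1, 0, 0.2], [0, 0.3, 0]])  # row mass > 1
        with pytest.raises(ValidationError):
            TransitionKernel([[0, -0.1], [0.1, 0]])


class TestMonteCarloConsistency:
    def test_occupancy_within_three_se_of_propagator(self):
        """The discrete-event / agent-based cross-check on a homogeneous kernel."""
        k = TransitionKernel([[0, 0.3, 0.05], [0.5, 0, 0.1], [0.02, 0.08, 0]])
        p0 = [1.0, 0.0, 0.0]
        n = 150_000
        counts = k.simulate(p0, n, 25, np.random.default_rng(11))
        expected = propagate_expected_occupancy(p0, k, 25)
        se = np.sqrt(expected * (1 - expected) / n)
        z = np.abs(counts / n - expected) / np.maximum(se, 1e-12)
        assert z.max() < 3.0

    def test_toy_binomial_transition_frequency(self):
        k = TransitionKernel([[0, 0.5], [1.0, 0]])
        counts = k.simulate([1.0, 0.0], 100_000, 1, np.random.default_rng(2))
        freq = counts[1, 1] / 100_000
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 100_000)


class TestEngineContracts:
    def test_identical_seed_identical_output(self, registry):
        cohort = generate_cohort(CohortSpec(n_patients=300), np.random.default_rng(1))
        a = simulate_run(cohort, registry, 400, np.random.default_rng(9), toggles=TOGGLES_ON)
        b = simulate_run(cohort, registry, 400, np.random.default_rng(9), toggles=TOGGLES_ON)
        for c in a.costs:
            assert np.array_equal(a.costs[c], b.costs[c])
        assert np.array_equal(a.death_day, b.death_day)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_absorbing_pool_when_all_rates_zero(self, registry):
        reg = load_registry(
            {
                "daily_rates_per_year.outpatient_clinic": 0,
                "daily_rates_per_year.physician": 0,
                **{f"admission.rate_per_year.{c}": 0 for c in ("I", "II", "III", "IV")},
            }
        )
        cohort = generate_cohort(CohortSpec(n_patients=100), np.random.default_rng(1))
        out = simulate_run(cohort, reg, 365, np.random.default_rng(3), toggles=TOGGLES_ON)
        for counter, arr in out.counters.items():
            assert arr.sum() == 0, counter
        for cat in ("physician", "outpatient_clinic", "admission", "intensive_care", "imp"):
            assert out.costs[cat].sum() == 0.0
        assert (out.death_day == -1).all()
        assert np.array_equal(out.occupancy[0], out.occupancy[-1])

    def test_dead_agents_frozen(self, registry):
        # force immediate outpatient death for everyone
        reg = load_registry(
            {
                "daily_rates_per_year.outpatient_mortality": 365,
                "daily_rates_per_year.outpatient_clinic": 0,
                "daily_rates_per_year.physician": 0,
                **{f"admission.rate_per_year.{c}": 0 for c in ("I", "II", "III", "IV")},
            }
        )
        cohort = generate_cohort(CohortSpec(n_patients=50), np.random.default_rng(1))
        out = simulate_run(cohort, reg, 200, np.random.default_rng(3), toggles=TOGGLES_ON)
        assert (out.death_day == 0).all()
        assert out.total_cost().sum() == 0.0  # nothing accrues after death
        assert out.cum_deaths[-1] == 50
        assert out.occupancy[-1].sum() == 0

    def test_daily_admission_probability_matches_table(self, registry):
        assert registry.daily_admission_probability("III") == pytest.approx(0.7643 / 365.0)

    def test_occupancy_plus_deaths_conserves_cohort(self, registry):
        cohort = generate_cohort(
            CohortSpec(n_patients=500, sex_mix=1.0), np.random.default_rng(4)
        )
        out = simulate_run(cohort, registry, 730, np.random.default_rng(5), toggles=TOGGLES_ON)
        totals = out.occupancy.sum(axis=1) + out.cum_deaths
        assert np.allclose(totals, 500)

    def test_history_sorted_and_parseable(self, registry):
        from hfsim.cohort import parse_history, render_history

        cohort = generate_cohort(CohortSpec(n_patients=40), np.random.default_rng(8))
        out = simulate_run(
            cohort, registry, 900, np.random.default_rng(2),
            toggles=TOGGLES_ON, record_history=True,
        )
        for led in out.to_ledgers():
            events = parse_history(render_history(led))  # validates monotone days
            assert len(events) == len(led.history)
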