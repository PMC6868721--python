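"""Registry loading, overrides, distribution sampling and unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hfsim.params import (
    ConfigurationError,
    DistributionSpec,
    ValidationError,
    age_bin_index,
    annual_rate_to_daily,
    load_registry,
    sample,
)


class TestRegistryCells:
    """The built-in registry must reproduce every printed cell exactly."""

    def test_spot_checks(self, registry):
        assert registry.mortality_per_admission.as_array()[0, 2] == 0.093
        assert registry.mortality_per_admission.as_array()[1, 4] == 0.156
        assert registry.admission_rate_per_year["III"] == 0.7643
        assert registry.admission_rate_per_year["IV"] == 1.6590
        assert registry.icu_probability.as_array()[0, 0] == 0.1610
        assert registry.imc_probability.as_array()[1, 2] == 0.1354
        assert registry.imp_points.as_array()[0, 2] == 205.60
        assert registry.imp_probability.as_array()[0, 2] == 0.5611
        assert registry.icu_points_per_day == 1664.0
        assert registry.imc_points_per_day == 480.0
        assert registry.fees == {
            "physician_annual": 544.0,
            "clinic_first": 209.0,
            "clinic_followup": 134.0,
        }
        assert registry.point_value == 1.0

    def test_drg_rules(self, registry):
        hi = registry.drg_rules["ge65"]
        lo = registry.drg_rules["le64"]
        assert (hi.min_los, hi.max_los, hi.flat_rate) == (4, 11, 3134.0)
        assert (lo.min_los, lo.max_los, lo.flat_rate) == (3, 10, 2688.0)
        # pro-rata default per-day amounts
        assert hi.supplement_per_day == pytest.approx(3134.0 / 11)
        assert lo.short_stay_rate_per_day == pytest.approx(2688.0 / 10)

    def test_transition_rows_renormalized(self, registry):
        for rows in (registry.nyha_outpatient, registry.nyha_inpatient):
            for row in rows.values():
                assert math.isclose(sum(row.probs), 1.0, abs_tol=1e-9)

    def test_los_specs(self, registry):
        assert registry.los_specs["I"].family == "point"
        assert registry.los_specs["I"].param1 == 3.0
        assert registry.los_specs["IV"].mean() == pytest.approx(7.56 * 1.83)

    def test_medication_specs(self, registry):
        c07m = registry.medication_specs["C07"]["male"]
        assert c07m.family == "gamma"
        assert c07m.mean() == pytest.approx(51.30 * 1.33)
        c09f = registry.medication_specs["C09"]["female"]
        assert c09f.family == "weibull"
        assert c09f.param1 == 165.84  # scale-first convention


class TestOverrides:
    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            load_registry({"fees.nonexistent": 1.0})
        with pytest.raises(ConfigurationError):
            load_registry({"totally.made.up": 1.0})

    def test_zero_point_value_rejected(self):
        with pytest.raises(ValidationError):
            load_registry({"point_value": 0})

    def test_override_applied_and_defaults_untouched(self, registry):
        reg = load_registry({"fees.physician_annual": 600, "admission.rate_per_year.III": 0.5})
        assert reg.fees["physician_annual"] == 600.0
        assert reg.admission_rate_per_year["III"] == 0.5
        assert reg.fees["clinic_first"] == registry.fees["clinic_first"]

    def test_list_index_override(self):
        reg = load_registry({"mortality_per_admission.male.2": 0.2})
        assert reg.mortality_per_admission.as_array()[0, 2] == 0.2

    def test_roundtrip_is_lossless(self, registry):
        flat = registry.to_flat_dict()
        again = load_registry(flat)
        assert again.to_flat_dict() == flat

    def test_reversed_weibull_order_knob(self):
        reg = load_registry({"param_order.weibull": "shape_scale"})
        # printed (59.83, 0.78) now reads shape-first: mean becomes absurdly small
        assert reg.medication_specs["C03"]["male"].mean() < 2.0


class TestRateConversion:
    @pytest.mark.parametrize(
        "rate,expected",
        [(12.0, 12.0 / 365.0), (0.0, 0.0), (1.0, 1.0 / 365.0), (400.0, 1.0)],
    )
    def test_values(self, rate, expected):
        assert annual_rate_to_daily(rate) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            annual_rate_to_daily(-1.0)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    def test_is_probability(self, rate):
        assert 0.0 <= annual_rate_to_daily(rate) <= 1.0


class TestDistributionSpec:
    def test_validation(self):
        with pytest.raises(ValidationError):
            DistributionSpec("point", 3.0, 1.0)
        with pytest.raises(ValidationError):
            DistributionSpec("gamma", -1.0, 2.0)
        with pytest.raises(ValidationError):
            DistributionSpec("gamma", 1.0)
        with pytest.raises(ValidationError):
            DistributionSpec("nbinom", 1.0, 2.0)

    def test_point_sampling_is_constant(self, rng):
        spec = DistributionSpec("point", 3.0, rounding="nearest_int_min1")
        assert sample(spec, rng) == 3.0
        assert np.all(spec.ppf(rng.random(10)) == 3.0)

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("gamma", 7.56, 1.83),
            DistributionSpec("gamma", 51.30, 1.33),
            DistributionSpec("weibull", 153.11, 1.12),
            DistributionSpec("weibull", 59.83, 0.78),
            DistributionSpec("lognormal", 2.0, 0.5),
        ],
    )
    def test_monte_carlo_mean_matches_closed_form(self, spec, rng):
        draws = spec.ppf(rng.random(200_000))
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - spec.mean()) < 3.0 * se

    def test_rounding_never_below_one(self, rng):
        spec = DistributionSpec("weibull", 0.3, 0.8, rounding="nearest_int_min1")
        draws = spec.ppf(rng.random(20_000))
        assert draws.min() >= 1.0
        assert np.all(draws == np.rint(draws))

    def test_scaled_preserves_family_and_mean(self):
        spec = DistributionSpec("gamma", 8.84, 1.27)
        scaled = spec.scaled(0.65)
        assert scaled.family == "gamma"
        assert scaled.mean() == pytest.approx(0.65 * spec.mean())
        point = DistributionSpec("point", 3.0).scaled(0.65)
        assert point.param1 == pytest.approx(1.95)


def test_age_bin_edges():
    assert list(age_bin_index(np.array([0, 55, 55.9, 56, 65.5, 66, 75.99, 76, 85.2, 86, 103]))) == [
        0, 0, 0, 1, 1, 2, 2, 3, 3, 4, 4,
    ]
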