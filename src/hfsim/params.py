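"""Parameter registry: every model constant as typed, validated data.

The built-in registry ships as a human-readable YAML file
(``hfsim/data/default_parameters.yaml``).  Users override individual entries
with flat dotted keys (``fees.physician_annual=600``) either programmatically
or through the CLI ``--set`` flag.  List entries are addressed by index
(``mortality_per_admission.male.2``).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml
from scipy import special

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "DistributionSpec",
    "NyhaTransitionRow",
    "DrgRule",
    "AgeSexTable",
    "ParameterRegistry",
    "load_registry",
    "default_parameters",
    "annual_rate_to_daily",
    "sample",
    "age_bin_index",
    "AGE_BIN_LABELS",
    "NYHA_CLASSES",
    "SEX_LABELS",
]


class ConfigurationError(KeyError):
    """Raised for override keys that do not name a registry entry."""


class ValidationError(ValueError):
    """Raised when a parameter value violates a model invariant."""


NYHA_CLASSES = ("I", "II", "III", "IV")
SEX_LABELS = ("male", "female")
AGE_BIN_LABELS = ("0-55", "56-65", "66-75", "76-85", "86+")
# Closed integer age ranges on *current* age: 0-55, 56-65, 66-75, 76-85, 86+.
_AGE_BIN_EDGES = np.array([56.0, 66.0, 76.0, 86.0])

DAYS_PER_YEAR = 365.0


def age_bin_index(age):
    """Index of the age bin containing ``age`` (in years; scalar or array)."""
    return np.digitize(np.floor(age), _AGE_BIN_EDGES)


def annual_rate_to_daily(rate: float) -> float:
    """Convert an events-per-year rate into a per-day Bernoulli probability.

    The model uses a sampling step of one day, so a rate of 12/year becomes
    12/365 per day.  Rates exceeding 365/year are capped at probability 1.
    """
    if rate < 0:
        raise ValidationError(f"rate must be non-negative, got {rate}")
    return min(rate / DAYS_PER_YEAR, 1.0)


@dataclass(frozen=True)
class DistributionSpec:
    """Declarative sampling distribution for LOS and medication costs.

    Canonical parameter convention: ``weibull`` has (param1=scale λ,
    param2=shape k); ``gamma`` has (param1=shape k, param2=scale θ);
    ``lognormal`` has (param1=mu, param2=sigma) of the underlying normal;
    ``point`` is the degenerate single value param1.
    """

    family: str
    param1: float
    param2: float | None = None
    rounding: str = "none"

    def __post_init__(self):
        if self.family not in ("weibull", "gamma", "lognormal", "point"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.rounding not in ("none", "nearest_int_min1"):
            raise ValidationError(f"unknown rounding {self.rounding!r}")
        if self.family == "point":
            if self.param2 is not None:
                raise ValidationError("point specs take exactly one parameter")
            if self.param1 <= 0:
                raise ValidationError("point value must be positive")
        else:
            if self.param2 is None:
                raise ValidationError(f"{self.family} needs two parameters")
            if self.param1 <= 0 or (self.family != "lognormal" and self.param2 <= 0):
                raise ValidationError("distribution parameters must be positive")
            if self.family == "lognormal" and self.param2 <= 0:
                raise ValidationError("lognormal sigma must be positive")

    # -- sampling -----------------------------------------------------------

    def ppf(self, u):
        """Inverse CDF at ``u`` (array-safe), with the rounding policy applied."""
        return self._round(self.ppf_unrounded(u))

    def ppf_unrounded(self, u):
        """Inverse CDF before the rounding policy (used for LOS scaling)."""
        u = np.asarray(u, dtype=float)
        if self.family == "point":
            x = np.full(u.shape, self.param1)
        elif self.family == "weibull":
            scale, shape = self.param1, self.param2
            x = scale * (-np.log1p(-u)) ** (1.0 / shape)
        elif self.family == "gamma":
            shape, scale = self.param1, self.param2
            x = special.gammaincinv(shape, u) * scale
        else:  # lognormal
            mu, sigma = self.param1, self.param2
            x = np.exp(mu + sigma * math.sqrt(2.0) * special.erfinv(2.0 * u - 1.0))
        return x

    def _round(self, x):
        if self.rounding == "nearest_int_min1":
            return np.maximum(np.rint(x), 1.0)
        return x

    def sample(self, rng: np.random.Generator, size=None):
        out = self.ppf(rng.random(size if size is not None else ()))
        return float(out) if size is None else out

    def mean(self) -> float:
        """Closed-form mean of the un-rounded distribution."""
        if self.family == "point":
            return self.param1
        if self.family == "weibull":
            return self.param1 * math.gamma(1.0 + 1.0 / self.param2)
        if self.family == "gamma":
            return self.param1 * self.param2
        return math.exp(self.param1 + 0.5 * self.param2**2)

    def scaled(self, factor: float) -> "DistributionSpec":
        """Spec with the mean multiplied by ``factor`` (scale family preserved)."""
        if factor == 1.0:
            return self
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        if self.family in ("point", "weibull"):
            return replace(self, param1=self.param1 * factor)
        if self.family == "gamma":
            return replace(self, param2=self.param2 * factor)
        return replace(self, param1=self.param1 + math.log(factor))


def sample(spec: DistributionSpec, rng: np.random.Generator, size=None):
    """Draw from ``spec`` using ``rng`` (module-level convenience)."""
    return spec.sample(rng, size=size)


@dataclass(frozen=True)
class NyhaTransitionRow:
    """One row of a NYHA transition matrix, renormalized to sum to 1."""

    from_class: str
    probs: tuple[float, float, float, float]

    def __post_init__(self):
        if self.from_class not in NYHA_CLASSES:
            raise ValidationError(f"unknown NYHA class {self.from_class!r}")
        raw = np.asarray(self.probs, dtype=float)
        if (raw < 0).any() or (raw > 1).any():
            raise ValidationError("transition probabilities must lie in [0, 1]")
        total = raw.sum()
        # printed rows carry rounding error of < 0.1 percentage points
        if abs(total - 1.0) > 1e-3:
            raise ValidationError(
                f"row {self.from_class} sums to {total:.6f}, expected ~1"
            )
        object.__setattr__(self, "probs", tuple(raw / total))

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.probs)


@dataclass(frozen=True)
class DrgRule:
    """Case flat rate with a [min_los, max_los] treatment window.

    Stays inside the window reimburse ``flat_rate`` points; each day beyond
    ``max_los`` adds ``supplement_per_day``; stays below ``min_los`` pay
    ``short_stay_rate_per_day`` per day instead.  The per-day amounts are not
    printed in the source reimbursement catalogue extract used here, so they
    default to the pro-rata policy flat_rate / max_los.
    """

    age_band: str
    min_los: int
    max_los: int
    flat_rate: float
    supplement_per_day: float | None = None
    short_stay_rate_per_day: float | None = None

    def __post_init__(self):
        if self.age_band not in ("le64", "ge65"):
            raise ValidationError(f"unknown age band {self.age_band!r}")
        if not self.min_los < self.max_los:
            raise ValidationError("min_los must be below max_los")
        if self.flat_rate <= 0:
            raise ValidationError("flat_rate must be positive")
        if self.supplement_per_day is None:
            object.__setattr__(self, "supplement_per_day", self.flat_rate / self.max_los)
        if self.short_stay_rate_per_day is None:
            object.__setattr__(
                self, "short_stay_rate_per_day", self.flat_rate / self.max_los
            )
        if self.supplement_per_day < 0 or self.short_stay_rate_per_day < 0:
            raise ValidationError("per-day DRG rates must be non-negative")


@dataclass(frozen=True)
class AgeSexTable:
    """A (5 age bins x 2 sexes) lookup of probabilities, points or days."""

    name: str
    male: tuple[float, ...]
    female: tuple[float, ...]
    is_probability: bool = True

    def __post_init__(self):
        for vals in (self.male, self.female):
            if len(vals) != len(AGE_BIN_LABELS):
                raise ValidationError(f"{self.name}: expected one value per age bin")
            arr = np.asarray(vals, dtype=float)
            if self.is_probability and ((arr < 0).any() or (arr > 1).any()):
                raise ValidationError(f"{self.name}: probabilities must lie in [0, 1]")
            if (arr < 0).any():
                raise ValidationError(f"{self.name}: values must be non-negative")

    def as_array(self) -> np.ndarray:
        """(2, 5) array indexed by [sex (0=male, 1=female), age bin]."""
        return np.asarray([self.male, self.female], dtype=float)

    def lookup(self, age, sex_index):
        return self.as_array()[sex_index, age_bin_index(age)]


# --------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class ParameterRegistry:
    """All model parameters, addressable by (state, age bin, sex, NYHA)."""

    raw: dict = field(repr=False)

    point_value: float = field(init=False)
    # daily transition probabilities out of the pool
    p_outpatient_death: float = field(init=False)
    p_clinic: float = field(init=False)
    p_physician: float = field(init=False)
    p_specialist: float = field(init=False)

    admission_rate_per_year: dict = field(init=False)
    los_specs: dict = field(init=False)
    medication_specs: dict = field(init=False)
    medication_residual_factor: float = field(init=False)

    icu_probability: AgeSexTable = field(init=False)
    imc_probability: AgeSexTable = field(init=False)
    icu_los_days: tuple = field(init=False)
    imc_los_days: tuple = field(init=False)
    icu_points_per_day: float = field(init=False)
    imc_points_per_day: float = field(init=False)
    imp_probability: AgeSexTable = field(init=False)
    imp_points: AgeSexTable = field(init=False)
    mortality_per_admission: AgeSexTable = field(init=False)

    nyha_outpatient: dict = field(init=False)
    nyha_inpatient: dict = field(init=False)
    drg_rules: dict = field(init=False)

    fees: dict = field(init=False)
    telemonitoring_defaults: dict = field(init=False)

    def __post_init__(self):
        raw = self.raw
        set_ = lambda k, v: object.__setattr__(self, k, v)

        pv = float(raw["point_value"])
        if pv <= 0:
            raise ValidationError("point_value must be positive")
        set_("point_value", pv)

        order = raw.get("param_order", {})
        weib_scale_first = order.get("weibull", "scale_shape") == "scale_shape"
        gamma_shape_first = order.get("gamma", "shape_scale") == "shape_scale"

        def make_spec(d: Mapping) -> DistributionSpec:
            fam = d["family"]
            p1, p2 = float(d["param1"]), d.get("param2")
            p2 = None if p2 is None else float(p2)
            if fam == "weibull" and not weib_scale_first:
                p1, p2 = p2, p1
            if fam == "gamma" and not gamma_shape_first:
                p1, p2 = p2, p1
            return DistributionSpec(fam, p1, p2, d.get("rounding", "none"))

        rates = raw["daily_rates_per_year"]
        set_("p_outpatient_death", annual_rate_to_daily(float(rates["outpatient_mortality"])))
        set_("p_clinic", annual_rate_to_daily(float(rates["outpatient_clinic"])))
        set_("p_physician", annual_rate_to_daily(float(rates["physician"])))
        set_("p_specialist", annual_rate_to_daily(float(rates["specialist"])))

        adm = raw["admission"]
        rate = {c: float(adm["rate_per_year"][c]) for c in NYHA_CLASSES}
        if any(v < 0 for v in rate.values()):
            raise ValidationError("admission rates must be non-negative")
        set_("admission_rate_per_year", rate)
        set_("los_specs", {c: make_spec(adm["los"][c]) for c in NYHA_CLASSES})

        med = raw["medication"]
        factor = float(med["residual_factor"])
        if factor < 0:
            raise ValidationError("medication residual factor must be non-negative")
        set_("medication_residual_factor", factor)
        set_(
            "medication_specs",
            {
                grp: {s: make_spec(med["specs"][grp][s]) for s in SEX_LABELS}
                for grp in ("C03", "C07", "C09")
            },
        )

        icu, imc, imp = raw["intensive_care"], raw["intermediate_care"], raw["imp"]
        set_("icu_probability", AgeSexTable("icu_probability", tuple(icu["probability"]["male"]), tuple(icu["probability"]["female"])))
        set_("imc_probability", AgeSexTable("imc_probability", tuple(imc["probability"]["male"]), tuple(imc["probability"]["female"])))
        set_("icu_los_days", tuple(int(d) for d in icu["los_days"]))
        set_("imc_los_days", tuple(int(d) for d in imc["los_days"]))
        set_("icu_points_per_day", float(icu["points_per_day"]))
        set_("imc_points_per_day", float(imc["points_per_day"]))
        set_("imp_probability", AgeSexTable("imp_probability", tuple(imp["probability"]["male"]), tuple(imp["probability"]["female"])))
        set_("imp_points", AgeSexTable("imp_points", tuple(imp["points"]["male"]), tuple(imp["points"]["female"]), is_probability=False))
        m = raw["mortality_per_admission"]
        set_("mortality_per_admission", AgeSexTable("mortality_per_admission", tuple(m["male"]), tuple(m["female"])))

        trans = raw["nyha_transitions"]
        for key, attr in (("outpatient", "nyha_outpatient"), ("inpatient", "nyha_inpatient")):
            rows = {}
            for c in NYHA_CLASSES:
                pcts = trans[key][c]
                rows[c] = NyhaTransitionRow(c, tuple(float(p) / 100.0 for p in pcts))
            set_(attr, rows)

        set_(
            "drg_rules",
            {
                band: DrgRule(
                    band,
                    int(raw["drg"][band]["min_los"]),
                    int(raw["drg"][band]["max_los"]),
                    float(raw["drg"][band]["flat_rate"]),
                    _opt_float(raw["drg"][band].get("supplement_per_day")),
                    _opt_float(raw["drg"][band].get("short_stay_rate_per_day")),
                )
                for band in ("le64", "ge65")
            },
        )

        fees = {k: float(v) for k, v in raw["fees"].items()}
        if any(v <= 0 for v in fees.values()):
            raise ValidationError("fees must be positive")
        set_("fees", fees)
        set_("telemonitoring_defaults", {k: float(v) for k, v in raw["telemonitoring"].items()})

        # kernel feasibility: one categorical draw per day must have mass <= 1
        p_adm_max = max(annual_rate_to_daily(r) for r in rate.values())
        total = (
            self.p_outpatient_death + self.p_clinic + p_adm_max + self.p_physician + self.p_specialist
        )
        if total > 1.0:
            raise ValidationError(f"daily transition mass {total:.4f} exceeds 1")

    # -- convenience accessors ---------------------------------------------

    def daily_admission_probability(self, nyha: str) -> float:
        return annual_rate_to_daily(self.admission_rate_per_year[nyha])

    def physician_fee_per_visit(self) -> float:
        return self.fees["physician_annual"] / 12.0

    def clinic_fee(self, prior_visits: int) -> float:
        return self.fees["clinic_first"] if prior_visits == 0 else self.fees["clinic_followup"]

    def drg_rule_for_age(self, age: float) -> DrgRule:
        return self.drg_rules["ge65"] if age >= 65 else self.drg_rules["le64"]

    def to_flat_dict(self) -> dict:
        """Registry contents as flat dotted-key mapping (override format)."""
        return _flatten(self.raw)

    def with_overrides(self, overrides: Mapping[str, object]) -> "ParameterRegistry":
        return load_registry(overrides, base=self.raw)


def _opt_float(v):
    return None if v is None else float(v)


def _flatten(d, prefix="") -> dict:
    out = {}
    items = d.items() if isinstance(d, dict) else enumerate(d)
    for k, v in items:
        key = f"{prefix}{k}"
        if isinstance(v, (dict, list)):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def default_parameters() -> dict:
    """The built-in parameter file, parsed into a nested dict."""
    text = (
        importlib.resources.files("hfsim.data")
        .joinpath("default_parameters.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def load_registry(
    overrides: Mapping[str, object] | None = None, *, base: dict | None = None
) -> ParameterRegistry:
    """Build a validated registry from the built-in defaults plus overrides.

    ``overrides`` maps flat dotted keys to values; keys must name existing
    entries (``ConfigurationError`` otherwise).  Values may be numbers or
    strings parseable as numbers.
    """
    import copy

    raw = copy.deepcopy(base if base is not None else default_parameters())
    for key, value in (overrides or {}).items():
        _apply_override(raw, key, value)
    return ParameterRegistry(raw)


def _apply_override(raw: dict, key: str, value):
    parts = key.split(".")
    node = raw
    for p in parts[:-1]:
        if isinstance(node, list):
            try:
                node = node[int(p)]
            except (ValueError, IndexError):
                raise ConfigurationError(f"unknown override key {key!r}") from None
        elif isinstance(node, dict) and p in node:
            node = node[p]
        else:
            raise ConfigurationError(f"unknown override key {key!r}")
    leaf = parts[-1]
    if isinstance(node, list):
        try:
            idx = int(leaf)
            node[idx]
        except (ValueError, IndexError):
            raise ConfigurationError(f"unknown override key {key!r}") from None
        node[idx] = _coerce(value, node[idx])
    elif isinstance(node, dict) and leaf in node:
        if isinstance(node[leaf], (dict, list)):
            raise ConfigurationError(f"override key {key!r} is not a leaf entry")
        node[leaf] = _coerce(value, node[leaf])
    else:
        raise ConfigurationError(f"unknown override key {key!r}")


def _coerce(value, previous):
    if isinstance(value, str) and not isinstance(previous, str):
        try:
            return float(value)
        except ValueError:
            return value
    return value
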