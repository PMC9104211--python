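"""Model parameterization for the renal-mass diagnostic cost-effectiveness model.

The model is driven by a single :class:`ParameterSet` holding the pre-test
probability of malignancy, the diagnostic accuracy and tariff of each imaging
strategy (contrast-enhanced ultrasound, CT, MRI), acute treatment expenses,
long-term monthly expenses per health state, health-state utilities, annual
disease transition probabilities and the economic settings (discount rate,
willingness-to-pay).  Every parameter carries a distribution assignment for
probabilistic sensitivity analysis: beta for probabilities and utilities,
gamma for costs, with dispersion expressed as a coefficient of variation.

Monetary values are 2020 US dollars; no inflation or currency adjustment is
applied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import yaml

__all__ = [
    "DiagnosticTestProfile",
    "DistributionSpec",
    "ParameterSet",
    "Violation",
    "default_parameter_set",
    "load_parameter_set",
    "serialize_parameter_set",
    "validate_parameter_set",
    "parameter_warnings",
    "default_psa_distributions",
    "parameter_ids",
    "get_parameter",
    "set_parameter",
    "parameter_kind",
    "TABLE_LABELS",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

#: Months during which the "first year" cost regime of the long-term expense
#: rows applies (the model's 1-year initial treatment period).
FIRST_YEAR_MONTHS = 12


@dataclass(frozen=True)
class DiagnosticTestProfile:
    """One diagnostic strategy: a test with an accuracy profile and a tariff."""

    name: str
    sensitivity: float
    specificity: float
    exam_cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity of {self.name} must be in [0,1], got {self.sensitivity}")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError(f"specificity of {self.name} must be in [0,1], got {self.specificity}")
        if self.exam_cost < 0:
            raise ValueError(f"exam_cost of {self.name} must be >= 0, got {self.exam_cost}")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one parameter for probabilistic SA.

    ``family`` is ``"beta"`` (probabilities, utilities), ``"gamma"`` (costs)
    or ``"fixed"``.  ``mean`` is on the parameter's natural scale and ``cv``
    is the coefficient of variation (SD/mean, dimensionless).  Distribution
    parameters are recovered by method of moments at sampling time.
    """

    family: str
    mean: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "beta" and not (0.0 < self.mean < 1.0):
            raise ValueError(f"beta mean must be in (0,1), got {self.mean}")
        if self.family == "gamma" and self.mean <= 0:
            raise ValueError(f"gamma mean must be > 0, got {self.mean}")
        if self.family != "fixed" and self.cv <= 0:
            raise ValueError(f"cv must be > 0 for family {self.family!r}, got {self.cv}")


@dataclass(frozen=True)
class ParameterSet:
    """Complete snapshot of the model's input values (one model run)."""

    pretest_malignant: float
    start_age_years: int
    wtp: float
    annual_discount: float
    tests: tuple[DiagnosticTestProfile, ...]
    # Acute expenses (one-off, charged at model entry), USD
    cost_biopsy: float
    cost_timely_treatment: float
    cost_delayed_treatment: float
    cost_unnecessary_biopsy: float
    cost_no_action: float
    # Long-term expenses, USD per monthly cycle
    monthly_cost_no_tumor: float
    monthly_cost_localized_y1: float
    monthly_cost_localized_later: float
    monthly_cost_metastatic_y1: float
    monthly_cost_metastatic_later: float
    # Utilities, QALY weight per year
    utility_no_tumor: float
    utility_localized: float
    utility_metastatic: float
    utility_dead: float
    # Transition probabilities (annual unless noted; p_non_r0 and
    # p_successful_recurrence_surgery are per treatment episode)
    p_non_r0: float
    p_local_recurrence: float
    p_metastases_no_tumor: float
    p_metastases_localized: float
    p_successful_recurrence_surgery: float
    excess_death_metastatic: float
    excess_death_localized: float
    # Distribution assignment per parameter id for probabilistic SA
    psa_dist: Mapping[str, DistributionSpec] = field(default_factory=dict)

    def test(self, name: str) -> DiagnosticTestProfile:
        """Return the strategy profile with the given (case-insensitive) name."""
        for t in self.tests:
            if t.name.lower() == name.lower():
                return t
        raise KeyError(f"no diagnostic strategy named {name!r}")

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tests)


def default_parameter_set(with_psa: bool = True) -> ParameterSet:
    """Baseline input values of the renal-mass model (2020 USD).

    Pre-test probability of malignancy 83.1%, cohort age 62, 3% annual
    discount on costs and utilities, willingness-to-pay 100,000 USD/QALY.
    Strategies: CEUS (Se 99.10%, Sp 80.50%, USD 285), CT (75%, 72%, USD 233),
    MRI (90%, 96%, USD 381).
    """
    ps = ParameterSet(
        pretest_malignant=0.831,
        start_age_years=62,
        wtp=100_000.0,
        annual_discount=0.03,
        tests=(
            DiagnosticTestProfile("CEUS", sensitivity=0.991, specificity=0.805, exam_cost=285.0),
            DiagnosticTestProfile("CT", sensitivity=0.75, specificity=0.72, exam_cost=233.0),
            DiagnosticTestProfile("MRI", sensitivity=0.90, specificity=0.96, exam_cost=381.0),
        ),
        cost_biopsy=1375.0,
        cost_timely_treatment=4231.0,
        cost_delayed_treatment=6346.50,
        cost_unnecessary_biopsy=1375.0,
        cost_no_action=0.0,
        monthly_cost_no_tumor=108.50,
        monthly_cost_localized_y1=2148.25,
        monthly_cost_localized_later=212.67,
        monthly_cost_metastatic_y1=2086.42,
        monthly_cost_metastatic_later=810.58,
        utility_no_tumor=1.0,
        utility_localized=0.75,
        utility_metastatic=0.66,
        utility_dead=0.0,
        p_non_r0=0.0573,
        p_local_recurrence=0.1075,
        p_metastases_no_tumor=0.01,
        p_metastases_localized=0.13,
        p_successful_recurrence_surgery=0.412,
        excess_death_metastatic=0.35,
        excess_death_localized=0.035,
    )
    if with_psa:
        ps = replace(ps, psa_dist=default_psa_distributions(ps))
    return ps


# ---------------------------------------------------------------------------
# Parameter registry: flat ids for sweeping (DSA), sampling (PSA) and config.
# ---------------------------------------------------------------------------

_SCALAR_FIELDS: dict[str, tuple[str, str]] = {
    # id -> (kind, Table-1 style label)
    "pretest_malignant": ("probability", "Pre-test probability of malignant lesion"),
    "start_age_years": ("age", "Expected age at diagnostic procedure"),
    "wtp": ("economic", "Assumed WTP"),
    "annual_discount": ("economic", "Discount rate"),
    "cost_biopsy": ("cost", "Biopsy"),
    "cost_timely_treatment": ("cost", "In time surgery + treatment"),
    "cost_delayed_treatment": ("cost", "Delayed surgery + treatment"),
    "cost_unnecessary_biopsy": ("cost", "Unnecessary biopsy"),
    "cost_no_action": ("cost", "No further action"),
    "monthly_cost_no_tumor": ("cost", "Monthly expenses without tumor"),
    "monthly_cost_localized_y1": ("cost", "Monthly expenses with detected tumor (1st year)"),
    "monthly_cost_localized_later": ("cost", "Monthly expenses with detected tumor (after 1st year)"),
    "monthly_cost_metastatic_y1": ("cost", "Monthly expenses with metastatic tumor (1st year)"),
    "monthly_cost_metastatic_later": ("cost", "Monthly expenses with metastatic tumor (after 1st year)"),
    "utility_no_tumor": ("utility", "QoL of patients without tumor"),
    "utility_localized": ("utility", "QoL of patients with detected tumor"),
    "utility_metastatic": ("utility", "QoL of patients with metastatic tumor"),
    "utility_dead": ("utility", "Death"),
    "p_non_r0": ("probability", "Possibility of initial non-R0 resection"),
    "p_local_recurrence": ("probability", "Possibility of local recurrence after resection"),
    "p_metastases_no_tumor": ("probability", "Risk of metastases without present tumor"),
    "p_metastases_localized": ("probability", "Possibility of occurrence of metastases"),
    "p_successful_recurrence_surgery": ("probability", "Possibility of successful surgery of local recurrence"),
    "excess_death_metastatic": ("probability", "Additional risk of death with metastases"),
    "excess_death_localized": ("probability", "Additional risk of death with localized tumor"),
}

_TEST_FIELDS = {"sensitivity": "probability", "specificity": "probability", "exam_cost": "cost"}


def parameter_ids(ps: ParameterSet) -> list[str]:
    """Flat ids of every numeric parameter, including per-strategy fields
    (e.g. ``sensitivity_ceus``)."""
    ids = list(_SCALAR_FIELDS)
    for t in ps.tests:
        for f in _TEST_FIELDS:
            ids.append(f"{f}_{t.name.lower()}")
    return ids


def parameter_kind(param_id: str) -> str:
    """Return the kind of a parameter id: probability, cost, utility, age or economic."""
    if param_id in _SCALAR_FIELDS:
        return _SCALAR_FIELDS[param_id][0]
    for f, kind in _TEST_FIELDS.items():
        if param_id.startswith(f + "_"):
            return kind
    raise KeyError(f"unknown parameter id {param_id!r}")


def _split_test_id(ps: ParameterSet, param_id: str) -> tuple[str, str] | None:
    for f in _TEST_FIELDS:
        if param_id.startswith(f + "_"):
            name = param_id[len(f) + 1 :]
            for t in ps.tests:
                if t.name.lower() == name:
                    return f, t.name
    return None


def get_parameter(ps: ParameterSet, param_id: str) -> float:
    """Look up a parameter value by flat id."""
    if param_id in _SCALAR_FIELDS:
        return getattr(ps, param_id)
    split = _split_test_id(ps, param_id)
    if split is None:
        raise KeyError(f"unknown parameter id {param_id!r}")
    f, name = split
    return getattr(ps.test(name), f)


def set_parameter(ps: ParameterSet, param_id: str, value: float) -> ParameterSet:
    """Return a copy of ``ps`` with one parameter pinned to ``value``."""
    if param_id in _SCALAR_FIELDS:
        if param_id == "start_age_years":
            value = int(value)
        return replace(ps, **{param_id: value})
    split = _split_test_id(ps, param_id)
    if split is None:
        raise KeyError(f"unknown parameter id {param_id!r}")
    f, name = split
    tests = tuple(
        replace(t, **{f: value}) if t.name == name else t for t in ps.tests
    )
    return replace(ps, tests=tests)


#: Table-1 row label for every parameter id (completeness surface).
TABLE_LABELS: dict[str, str] = {pid: label for pid, (_, label) in _SCALAR_FIELDS.items()}
TABLE_LABELS.update(
    {
        "sensitivity_ceus": "Sensitivity of CEUS",
        "specificity_ceus": "Specificity of CEUS",
        "exam_cost_ceus": "CEUS",
        "sensitivity_ct": "Sensitivity of CT",
        "specificity_ct": "Specificity of CT",
        "exam_cost_ct": "CT",
        "sensitivity_mri": "Sensitivity of MRI",
        "specificity_mri": "Specificity of MRI",
        "exam_cost_mri": "MRI",
    }
)


# ---------------------------------------------------------------------------
# PSA distribution defaults
# ---------------------------------------------------------------------------

#: Default coefficient of variation when a parameter's uncertainty is not
#: reported (common convention in health-economic PSA).
DEFAULT_CV = 0.2


def _feasible_beta_cv(mean: float, cv: float) -> float:
    """Cap a beta cv at half the feasible maximum for the given mean.

    A beta variable with mean m has variance < m(1-m), i.e. cv < sqrt((1-m)/m).
    Near-certain probabilities (e.g. a 99.1% sensitivity) cannot carry a 20%
    coefficient of variation; the cap keeps the method-of-moments conversion
    well defined while preserving the default dispersion elsewhere.
    """
    cv_max = ((1.0 - mean) / mean) ** 0.5
    return min(cv, 0.5 * cv_max)


def default_psa_distributions(ps: ParameterSet, cv: float = DEFAULT_CV) -> dict[str, DistributionSpec]:
    """Distribution assignment per parameter: beta for probabilities and
    utilities, gamma for costs, fixed for structural values (age, WTP,
    discount rate) and for degenerate means (0 or 1)."""
    dists: dict[str, DistributionSpec] = {}
    for pid in parameter_ids(ps):
        kind = parameter_kind(pid)
        mean = get_parameter(ps, pid)
        if kind in ("age", "economic"):
            dists[pid] = DistributionSpec("fixed", mean)
        elif kind in ("probability", "utility"):
            if mean <= 0.0 or mean >= 1.0:
                dists[pid] = DistributionSpec("fixed", mean)
            else:
                dists[pid] = DistributionSpec("beta", mean, _feasible_beta_cv(mean, cv))
        elif kind == "cost":
            if mean <= 0.0:
                dists[pid] = DistributionSpec("fixed", mean)
            else:
                dists[pid] = DistributionSpec("gamma", mean, cv)
    return dists


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One invariant violation: the offending field, its value and the rule."""

    field: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r}: {self.rule}"


def validate_parameter_set(ps: ParameterSet) -> list[Violation]:
    """Check every type invariant; violations are returned as data, not raised."""
    out: list[Violation] = []

    def prob(pid: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            out.append(Violation(pid, value, "probability must be in [0, 1]"))

    def money(pid: str, value: float) -> None:
        if value < 0:
            out.append(Violation(pid, value, "cost must be >= 0"))

    prob("pretest_malignant", ps.pretest_malignant)
    if ps.start_age_years < 0:
        out.append(Violation("start_age_years", ps.start_age_years, "age must be >= 0"))
    if ps.wtp < 0:
        out.append(Violation("wtp", ps.wtp, "willingness-to-pay must be >= 0"))
    if ps.annual_discount < 0:
        out.append(Violation("annual_discount", ps.annual_discount, "discount rate must be >= 0"))
    if not ps.tests:
        out.append(Violation("tests", ps.tests, "at least one diagnostic strategy required"))
    names = [t.name.lower() for t in ps.tests]
    if len(set(names)) != len(names):
        out.append(Violation("tests", names, "strategy names must be unique"))
    for t in ps.tests:
        prob(f"sensitivity_{t.name.lower()}", t.sensitivity)
        prob(f"specificity_{t.name.lower()}", t.specificity)
        money(f"exam_cost_{t.name.lower()}", t.exam_cost)
    for pid, (kind, _) in _SCALAR_FIELDS.items():
        if kind == "cost":
            money(pid, getattr(ps, pid))
        elif kind == "probability":
            prob(pid, getattr(ps, pid))
    for pid in ("utility_no_tumor", "utility_localized", "utility_metastatic", "utility_dead"):
        u = getattr(ps, pid)
        if not 0.0 <= u <= 1.0:
            out.append(Violation(pid, u, "utility must be in [0, 1]"))
    if ps.utility_dead != 0.0:
        out.append(Violation("utility_dead", ps.utility_dead, "utility of death must be 0"))
    return out


def parameter_warnings(ps: ParameterSet) -> list[str]:
    """Non-fatal plausibility warnings (never reported by the validator)."""
    warns: list[str] = []
    if ps.utility_metastatic > ps.utility_localized:
        warns.append(
            "utility_metastatic exceeds utility_localized; metastatic disease "
            "is usually valued no better than localized disease"
        )
    if ps.utility_localized > ps.utility_no_tumor:
        warns.append("utility_localized exceeds utility_no_tumor")
    return warns


# ---------------------------------------------------------------------------
# Config document (YAML) load / serialize
# ---------------------------------------------------------------------------

_CONFIG_SCALARS = tuple(_SCALAR_FIELDS)


class ConfigError(ValueError):
    """Raised on a malformed or invalid parameter configuration document."""


def serialize_parameter_set(ps: ParameterSet) -> str:
    """Render a ParameterSet as a YAML document (round-trips through
    :func:`load_parameter_set`)."""
    doc: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    for pid in _CONFIG_SCALARS:
        doc[pid] = getattr(ps, pid)
    doc["tests"] = [
        {"name": t.name, "sensitivity": t.sensitivity, "specificity": t.specificity, "exam_cost": t.exam_cost}
        for t in ps.tests
    ]
    if ps.psa_dist:
        doc["psa"] = {
            pid: {"family": d.family, "mean": d.mean, "cv": d.cv}
            for pid, d in ps.psa_dist.items()
        }
    return yaml.safe_dump(doc, sort_keys=False)


def _require_number(key: str, value: Any) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"key {key!r} must be a number, got {value!r}")
    return float(value)


def load_parameter_set(config_text: str, allow_defaults: bool = False) -> ParameterSet:
    """Parse and validate a YAML parameter document.

    Unknown keys are rejected.  Missing keys are an error unless
    ``allow_defaults`` is set, in which case they fall back to the baseline
    values of :func:`default_parameter_set`.
    """
    try:
        doc = yaml.safe_load(io.StringIO(config_text))
    except yaml.YAMLError as e:
        raise ConfigError(f"not a valid YAML document: {e}") from e
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration must be a mapping of keys to values")

    known = set(_CONFIG_SCALARS) | {"schema_version", "tests", "psa"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")

    base = default_parameter_set()
    kwargs: dict[str, Any] = {}
    for pid in _CONFIG_SCALARS:
        if pid in doc:
            kwargs[pid] = _require_number(pid, doc[pid])
        elif allow_defaults:
            kwargs[pid] = getattr(base, pid)
        else:
            raise ConfigError(f"missing key {pid!r} (pass allow_defaults to use the baseline value)")
    kwargs["start_age_years"] = int(kwargs["start_age_years"])

    if "tests" in doc:
        raw_tests = doc["tests"]
        if not isinstance(raw_tests, list) or not raw_tests:
            raise ConfigError("key 'tests' must be a non-empty list")
        tests = []
        for i, entry in enumerate(raw_tests):
            if not isinstance(entry, Mapping):
                raise ConfigError(f"tests[{i}] must be a mapping")
            extra = set(entry) - {"name", "sensitivity", "specificity", "exam_cost"}
            if extra:
                raise ConfigError(f"tests[{i}] has unknown key(s): {', '.join(sorted(extra))}")
            try:
                name = str(entry["name"])
                tests.append(
                    DiagnosticTestProfile(
                        name,
                        sensitivity=_require_number(f"tests[{i}].sensitivity", entry["sensitivity"]),
                        specificity=_require_number(f"tests[{i}].specificity", entry["specificity"]),
                        exam_cost=_require_number(f"tests[{i}].exam_cost", entry["exam_cost"]),
                    )
                )
            except KeyError as e:
                raise ConfigError(f"tests[{i}] is missing key {e.args[0]!r}") from e
            except ValueError as e:
                raise ConfigError(str(e)) from e
        kwargs["tests"] = tuple(tests)
    elif allow_defaults:
        kwargs["tests"] = base.tests
    else:
        raise ConfigError("missing key 'tests'")

    ps = ParameterSet(**kwargs, psa_dist={})
    if "psa" in doc:
        raw_psa = doc["psa"]
        if not isinstance(raw_psa, Mapping):
            raise ConfigError("key 'psa' must be a mapping of parameter id to distribution")
        valid_ids = set(parameter_ids(ps))
        dists: dict[str, DistributionSpec] = {}
        for pid, d in raw_psa.items():
            if pid not in valid_ids:
                raise ConfigError(f"psa refers to unknown parameter id {pid!r}")
            if not isinstance(d, Mapping):
                raise ConfigError(f"psa[{pid!r}] must be a mapping")
            try:
                dists[pid] = DistributionSpec(
                    family=str(d["family"]),
                    mean=_require_number(f"psa[{pid}].mean", d["mean"]),
                    cv=_require_number(f"psa[{pid}].cv", d.get("cv", 0.0)),
                )
            except KeyError as e:
                raise ConfigError(f"psa[{pid!r}] is missing key {e.args[0]!r}") from e
            except ValueError as e:
                raise ConfigError(f"psa[{pid!r}]: {e}") from e
        ps = replace(ps, psa_dist=dists)
    else:
        ps = replace(ps, psa_dist=default_psa_distributions(ps))

    violations = validate_parameter_set(ps)
    if violations:
        raise ConfigError("; ".join(str(v) for v in violations))
    return ps
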