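"""Parameter configuration: loading, validation, and round-tripping.

A run is described by one human-editable YAML file per price region (Scotland,
China — the China scenario is a pure price swap) plus a shared coefficients
file holding the regression tables: the ASSIGN score coefficients, the
Gompertz transition models, the probit recurrent-event model, and the utility
and cost regressions.  The published regression tables live in supplementary
material of the source model; the bundled coefficients are plausible
placeholders flagged ``provenance: placeholder`` and the loader warns loudly
whenever placeholders are active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .hazards import GompertzModel

__all__ = [
    "UncertainValue",
    "InterventionSpec",
    "RRSet",
    "UtilityModel",
    "CostModel",
    "AssignCoefficients",
    "ParameterSet",
    "ParameterValidationError",
    "MissingTableError",
    "PlaceholderWarning",
    "load_parameters",
    "write_parameters",
    "bundled_config_path",
]

_FAMILIES = ("beta", "gamma", "lognormal", "uniform", "fixed")

DATA_DIR = Path(__file__).parent / "data"


class ParameterValidationError(ValueError):
    """Raised with the full list of failing fields."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("parameter validation failed:\n  - " + "\n  - ".join(self.errors))


class MissingTableError(KeyError):
    """A required coefficient table is absent from the configuration."""


class PlaceholderWarning(UserWarning):
    """Placeholder (non-published) coefficients are in use."""


def bundled_config_path(region: str = "scotland") -> Path:
    """Path of a bundled region configuration (``scotland`` or ``china``)."""
    p = DATA_DIR / f"{region.lower()}.yml"
    if not p.exists():
        raise FileNotFoundError(f"no bundled config for region {region!r}")
    return p


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class UncertainValue:
    """A base-case value with its 95% CI and sampling family."""

    mean: float
    ci_low: float
    ci_high: float
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket mean {self.mean}"
            )

    @property
    def width(self) -> float:
        return self.ci_high - self.ci_low

    @classmethod
    def fixed(cls, value: float) -> "UncertainValue":
        return cls(value, value, value, "fixed")


@dataclass(frozen=True)
class InterventionSpec:
    """One strategy's lipid effects, side effects, and annual costs.

    Percentages are on the 0–100 scale as printed; ``diabetes_ari`` is the
    absolute risk increase of new-onset type 2 diabetes in percentage points
    (negative = protective, as for berberine).
    """

    name: str
    nonhdl_reduction: UncertainValue
    hdl_increase: UncertainValue
    diabetes_ari: UncertainValue
    pill_disutility: UncertainValue
    drug_cost: UncertainValue
    monitoring_cost_first_year: UncertainValue
    monitoring_cost_subsequent: UncertainValue
    risk_assessment_cost: float
    active: bool = True

    def __post_init__(self) -> None:
        errs = []
        if not (0.0 <= self.nonhdl_reduction.mean <= 100.0):
            errs.append(f"{self.name}: non-HDL-c reduction outside [0, 100]")
        for label, uv in (
            ("drug_cost", self.drug_cost),
            ("monitoring_cost_first_year", self.monitoring_cost_first_year),
            ("monitoring_cost_subsequent", self.monitoring_cost_subsequent),
        ):
            if uv.mean < 0 or uv.ci_low < 0:
                errs.append(f"{self.name}: {label} must be >= 0")
        if self.pill_disutility.mean < 0:
            errs.append(f"{self.name}: pill_disutility must be >= 0")
        if self.risk_assessment_cost < 0:
            errs.append(f"{self.name}: risk_assessment_cost must be >= 0")
        if errs:
            raise ParameterValidationError(errs)


@dataclass(frozen=True)
class RRSet:
    """Relative risks per 1.0 mmol/L reduction in non-HDL cholesterol."""

    nonfatal_chd: UncertainValue
    nonfatal_cbvd: UncertainValue
    fatal_cvd: UncertainValue
    any_cvd: UncertainValue

    def __post_init__(self) -> None:
        for name in ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd", "any_cvd"):
            uv: UncertainValue = getattr(self, name)
            if not (0.0 < uv.mean <= 1.0):
                raise ParameterValidationError([f"rr_per_mmol.{name} must be in (0, 1]"])


@dataclass(frozen=True)
class UtilityModel:
    """Baseline utility regression (sex + age) and event decrements."""

    intercept: float
    male: float
    age: float  # per year of age over 40
    age2: float  # per squared year over 40
    event_decrements: tuple[tuple[str, float], ...]  # state name -> utility loss
    recurrent_event_decrement: float

    def baseline(self, is_male, age):
        a = age - 40.0
        return self.intercept + self.male * is_male + self.age * a + self.age2 * a * a

    def decrement(self, state_name: str) -> float:
        return dict(self.event_decrements)[state_name]


@dataclass(frozen=True)
class CostRegression:
    """One annual-cost regression: covariate terms plus a time spline."""

    intercept: float
    coefficients: tuple[tuple[str, float], ...]
    spline_knots: tuple[float, ...]
    spline_coefficients: tuple[float, ...]


@dataclass(frozen=True)
class CostModel:
    """Annual health-state costs plus programme unit costs (GBP)."""

    pre_event: CostRegression
    post_event: tuple[tuple[str, CostRegression], ...]  # per chronic state
    recurrent_event_cost: float
    diabetes_annual: float
    screening: float
    monitoring_first: float
    monitoring_subsequent: float


@dataclass(frozen=True)
class SexCoefficients:
    baseline_survival: float
    lp_mean: float
    coefficients: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class AssignCoefficients:
    female: SexCoefficients
    male: SexCoefficients

    def for_sex(self, sex: str) -> SexCoefficients:
        if sex not in ("female", "male"):
            raise ValueError(f"unknown sex {sex!r}")
        return getattr(self, sex)


@dataclass(frozen=True)
class ParameterSet:
    """Everything a run needs, validated."""

    interventions: tuple[InterventionSpec, ...]
    rr_per_mmol: RRSet
    gompertz_primary: Mapping[str, GompertzModel]
    gompertz_secondary: Mapping[str, GompertzModel]
    probit_secondary: Mapping[str, float]
    utility_model: UtilityModel
    cost_model: CostModel
    assign: AssignCoefficients
    discount_rate: float
    discount_rate_range: tuple[float, float]
    wtp_threshold: float
    risk_threshold: float
    price_region: str
    generator: Mapping[str, Any]
    shared_uncertain: Mapping[str, UncertainValue] = field(default_factory=dict)
    options: Mapping[str, Any] = field(default_factory=dict)
    provenance: str = "placeholder"

    def intervention(self, name: str) -> InterventionSpec:
        for spec in self.interventions:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def with_discount_rate(self, rate: float) -> "ParameterSet":
        return replace(self, discount_rate=rate)


# ---------------------------------------------------------------------------
# loading


_REQUIRED_PRIMARY = ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd", "noncvd_death")
_REQUIRED_SECONDARY = ("post_chd", "post_cbvd")

_TOP_KEYS = {
    "schema", "region", "price_year", "coefficients", "discount_rate",
    "discount_rate_range", "wtp_threshold", "risk_threshold", "options",
    "rr_per_mmol", "shared_costs", "pill_disutility", "interventions",
    "generator",
}
_INTERVENTION_KEYS = {
    "name", "active", "nonhdl_reduction", "hdl_increase", "diabetes_ari",
    "drug_cost", "pill_disutility", "monitoring_cost_first_year",
    "monitoring_cost_subsequent", "risk_assessment_cost",
}


def _uv(node: Any, where: str, errors: list[str], family_default: str = "fixed") -> UncertainValue:
    if isinstance(node, (int, float)):
        return UncertainValue.fixed(float(node))
    if not isinstance(node, Mapping):
        errors.append(f"{where}: expected number or mapping, got {type(node).__name__}")
        return UncertainValue.fixed(0.0)
    unknown = set(node) - {"mean", "ci", "family"}
    if unknown:
        errors.append(f"{where}: unknown keys {sorted(unknown)}")
    try:
        mean = float(node["mean"])
        lo, hi = (float(v) for v in node.get("ci", (mean, mean)))
        fam = str(node.get("family", family_default))
        return UncertainValue(mean, lo, hi, fam)
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"{where}: {exc}")
        return UncertainValue.fixed(0.0)


def _gompertz(node: Mapping[str, Any], where: str) -> GompertzModel:
    if "covariates" not in node:
        raise MissingTableError(f"{where}: missing 'covariates' table")
    cov = dict(node["covariates"])
    return GompertzModel(
        covariate_names=tuple(cov.keys()),
        beta=tuple(float(v) for v in cov.values()),
        gamma=float(node.get("gamma", 0.0)),
    )


def _cost_regression(node: Mapping[str, Any], where: str) -> CostRegression:
    spline = node.get("spline", {})
    return CostRegression(
        intercept=float(node["intercept"]),
        coefficients=tuple(
            (str(k), float(v)) for k, v in node.get("coefficients", {}).items()
        ),
        spline_knots=tuple(float(v) for v in spline.get("knots", (0.0, 10.0, 20.0, 30.0, 60.0))),
        spline_coefficients=tuple(float(v) for v in spline.get("coefficients", ())),
    )


def _load_yaml(path: Path) -> Mapping[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ParameterValidationError([f"{path}: top level must be a mapping"])
    return data


def load_parameters(path) -> ParameterSet:
    """Load and validate a region configuration (YAML).

    Raises :class:`ParameterValidationError` listing *every* failing field,
    or :class:`MissingTableError` when a whole coefficient table is absent.
    """
    path = Path(path)
    cfg = _load_yaml(path)
    errors: list[str] = []

    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys {sorted(unknown)}")

    # ---- coefficients file (inline mapping also accepted, as written by
    # write_parameters)
    coef_node = cfg.get("coefficients")
    if coef_node is None:
        raise MissingTableError("missing 'coefficients' (file path or inline tables)")
    if isinstance(coef_node, str):
        coef_path = (path.parent / coef_node).resolve()
        if not coef_path.exists():
            coef_path = DATA_DIR / coef_node
        coefs = _load_yaml(coef_path)
    else:
        coefs = coef_node

    provenance = str(coefs.get("provenance", "placeholder"))
    if provenance == "placeholder":
        warnings.warn(
            "Placeholder regression coefficients are active (ASSIGN, Gompertz, "
            "probit, utility and cost tables are plausible stand-ins, not the "
            "published estimates). Absolute event counts, QALYs and costs are "
            "illustrative only.",
            PlaceholderWarning,
            stacklevel=2,
        )

    for table in ("assign", "gompertz_primary", "gompertz_secondary",
                  "probit_secondary", "utility", "cost"):
        if table not in coefs:
            raise MissingTableError(f"missing coefficient table {table!r}")

    gp = {}
    for name in _REQUIRED_PRIMARY:
        if name not in coefs["gompertz_primary"]:
            raise MissingTableError(f"missing gompertz_primary transition {name!r}")
        gp[name] = _gompertz(coefs["gompertz_primary"][name], f"gompertz_primary.{name}")
    gs = {}
    for name in _REQUIRED_SECONDARY:
        if name not in coefs["gompertz_secondary"]:
            raise MissingTableError(f"missing gompertz_secondary transition {name!r}")
        gs[name] = _gompertz(coefs["gompertz_secondary"][name], f"gompertz_secondary.{name}")

    probit = {str(k): float(v) for k, v in coefs["probit_secondary"].items()}

    un = coefs["utility"]
    utility = UtilityModel(
        intercept=float(un["intercept"]),
        male=float(un.get("male", 0.0)),
        age=float(un.get("age", 0.0)),
        age2=float(un.get("age2", 0.0)),
        event_decrements=tuple(
            (str(k), float(v)) for k, v in un["event_decrements"].items()
        ),
        recurrent_event_decrement=float(un.get("recurrent_event_decrement", 0.0)),
    )

    shared = cfg.get("shared_costs", {})
    monitoring_first = _uv(shared.get("monitoring_first_year", 0.0),
                           "shared_costs.monitoring_first_year", errors)
    monitoring_sub = _uv(shared.get("monitoring_subsequent", 0.0),
                         "shared_costs.monitoring_subsequent", errors)
    risk_assessment = _uv(shared.get("risk_assessment", 0.0),
                          "shared_costs.risk_assessment", errors)
    diabetes_annual = _uv(shared.get("diabetes_annual", 0.0),
                          "shared_costs.diabetes_annual", errors)

    cn = coefs["cost"]
    cost_model = CostModel(
        pre_event=_cost_regression(cn["pre_event"], "cost.pre_event"),
        post_event=tuple(
            (str(k), _cost_regression(v, f"cost.post_event.{k}"))
            for k, v in cn["post_event"].items()
        ),
        recurrent_event_cost=float(cn.get("recurrent_event_cost", 0.0)),
        diabetes_annual=diabetes_annual.mean,
        screening=risk_assessment.mean,
        monitoring_first=monitoring_first.mean,
        monitoring_subsequent=monitoring_sub.mean,
    )

    an = coefs["assign"]
    sexes = {}
    for sex in ("female", "male"):
        if sex not in an:
            raise MissingTableError(f"missing ASSIGN coefficients for sex {sex!r}")
        node = an[sex]
        sexes[sex] = SexCoefficients(
            baseline_survival=float(node["baseline_survival"]),
            lp_mean=float(node["lp_mean"]),
            coefficients=tuple((str(k), float(v)) for k, v in node["coefficients"].items()),
        )
    assign = AssignCoefficients(**sexes)

    # ---- region-level scalars
    discount_rate = float(cfg.get("discount_rate", 0.035))
    if not (0.0 <= discount_rate <= 0.2):
        errors.append(f"discount_rate {discount_rate} outside [0, 0.2]")
    lo, hi = cfg.get("discount_rate_range", (discount_rate, discount_rate))
    wtp = float(cfg.get("wtp_threshold", 20000.0))
    if wtp <= 0:
        errors.append("wtp_threshold must be positive")
    risk_threshold = float(cfg.get("risk_threshold", 20.0))
    if not (0.0 < risk_threshold < 100.0):
        errors.append(f"risk_threshold {risk_threshold} outside (0, 100)")

    rr_node = cfg.get("rr_per_mmol", {})
    rr_kwargs = {}
    for name in ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd", "any_cvd"):
        if name not in rr_node:
            errors.append(f"rr_per_mmol.{name} missing")
            rr_kwargs[name] = UncertainValue.fixed(1.0)
        else:
            rr_kwargs[name] = _uv(rr_node[name], f"rr_per_mmol.{name}", errors, "beta")

    pill = _uv(cfg.get("pill_disutility", 0.0), "pill_disutility", errors, "beta")

    specs: list[InterventionSpec] = []
    for i, node in enumerate(cfg.get("interventions", [])):
        where = f"interventions[{i}]"
        unknown = set(node) - _INTERVENTION_KEYS
        if unknown:
            errors.append(f"{where}: unknown keys {sorted(unknown)}")
        name = str(node.get("name", f"strategy {i}"))
        active = bool(node.get("active", True))
        zero = UncertainValue.fixed(0.0)
        try:
            spec = InterventionSpec(
                name=name,
                active=active,
                nonhdl_reduction=_uv(node.get("nonhdl_reduction", 0.0), f"{where}.nonhdl_reduction", errors, "beta"),
                hdl_increase=_uv(node.get("hdl_increase", 0.0), f"{where}.hdl_increase", errors, "beta"),
                diabetes_ari=_uv(node.get("diabetes_ari", 0.0), f"{where}.diabetes_ari", errors, "lognormal"),
                pill_disutility=_uv(node["pill_disutility"], f"{where}.pill_disutility", errors, "beta")
                if "pill_disutility" in node else (pill if active else zero),
                drug_cost=_uv(node.get("drug_cost", 0.0), f"{where}.drug_cost", errors, "gamma"),
                monitoring_cost_first_year=_uv(node["monitoring_cost_first_year"], f"{where}.monitoring_cost_first_year", errors, "gamma")
                if "monitoring_cost_first_year" in node else (monitoring_first if active else zero),
                monitoring_cost_subsequent=_uv(node["monitoring_cost_subsequent"], f"{where}.monitoring_cost_subsequent", errors, "gamma")
                if "monitoring_cost_subsequent" in node else (monitoring_sub if active else zero),
                risk_assessment_cost=float(node["risk_assessment_cost"])
                if "risk_assessment_cost" in node else (risk_assessment.mean if active else 0.0),
            )
        except ParameterValidationError as exc:
            errors.extend(exc.errors)
            continue
        specs.append(spec)

    if errors:
        raise ParameterValidationError(errors)

    return ParameterSet(
        interventions=tuple(specs),
        rr_per_mmol=RRSet(**rr_kwargs),
        gompertz_primary=gp,
        gompertz_secondary=gs,
        probit_secondary=probit,
        utility_model=utility,
        cost_model=cost_model,
        assign=assign,
        discount_rate=discount_rate,
        discount_rate_range=(float(lo), float(hi)),
        wtp_threshold=wtp,
        risk_threshold=risk_threshold,
        price_region=str(cfg.get("region", "Scotland")),
        generator=dict(cfg.get("generator", {})),
        shared_uncertain={
            "monitoring_first_year": monitoring_first,
            "monitoring_subsequent": monitoring_sub,
            "risk_assessment": risk_assessment,
            "diabetes_annual": diabetes_annual,
            "pill_disutility": pill,
        },
        options=dict(cfg.get("options", {})),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# writing (round-trip support)


def _uv_node(uv: UncertainValue):
    if uv.family == "fixed" and uv.ci_low == uv.mean == uv.ci_high:
        return float(uv.mean)
    return {"mean": float(uv.mean), "ci": [float(uv.ci_low), float(uv.ci_high)],
            "family": uv.family}


def write_parameters(params: ParameterSet, path) -> None:
    """Serialise a :class:`ParameterSet` to a single self-contained YAML file.

    ``load_parameters(path)`` on the written file reproduces the parameter set
    field-for-field (coefficients are embedded inline).
    """
    def _gomp_node(m: GompertzModel):
        return {"gamma": float(m.gamma),
                "covariates": {k: float(v) for k, v in zip(m.covariate_names, m.beta)}}

    def _cost_node(r: CostRegression):
        return {
            "intercept": float(r.intercept),
            "coefficients": dict(r.coefficients),
            "spline": {"knots": list(r.spline_knots),
                       "coefficients": list(r.spline_coefficients)},
        }

    um = params.utility_model
    cm = params.cost_model
    coefs = {
        "provenance": params.provenance,
        "assign": {
            sex: {
                "baseline_survival": sc.baseline_survival,
                "lp_mean": sc.lp_mean,
                "coefficients": dict(sc.coefficients),
            }
            for sex, sc in (("female", params.assign.female), ("male", params.assign.male))
        },
        "gompertz_primary": {k: _gomp_node(m) for k, m in params.gompertz_primary.items()},
        "gompertz_secondary": {k: _gomp_node(m) for k, m in params.gompertz_secondary.items()},
        "probit_secondary": dict(params.probit_secondary),
        "utility": {
            "intercept": um.intercept, "male": um.male, "age": um.age, "age2": um.age2,
            "event_decrements": dict(um.event_decrements),
            "recurrent_event_decrement": um.recurrent_event_decrement,
        },
        "cost": {
            "pre_event": _cost_node(cm.pre_event),
            "post_event": {k: _cost_node(r) for k, r in cm.post_event},
            "recurrent_event_cost": cm.recurrent_event_cost,
        },
    }
    doc = {
        "schema": "cvdcea-config-v1",
        "region": params.price_region,
        "coefficients": coefs,
        "discount_rate": params.discount_rate,
        "discount_rate_range": list(params.discount_rate_range),
        "wtp_threshold": params.wtp_threshold,
        "risk_threshold": params.risk_threshold,
        "options": dict(params.options),
        "rr_per_mmol": {
            k: _uv_node(getattr(params.rr_per_mmol, k))
            for k in ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd", "any_cvd")
        },
        "shared_costs": {
            k: _uv_node(uv)
            for k, uv in params.shared_uncertain.items()
            if k != "pill_disutility"
        },
        "pill_disutility": _uv_node(
            params.shared_uncertain.get("pill_disutility", UncertainValue.fixed(0.0))
        ),
        "generator": dict(params.generator),
        "interventions": [
            {
                "name": s.name,
                "active": s.active,
                "nonhdl_reduction": _uv_node(s.nonhdl_reduction),
                "hdl_increase": _uv_node(s.hdl_increase),
                "diabetes_ari": _uv_node(s.diabetes_ari),
                "pill_disutility": _uv_node(s.pill_disutility),
                "drug_cost": _uv_node(s.drug_cost),
                "monitoring_cost_first_year": _uv_node(s.monitoring_cost_first_year),
                "monitoring_cost_subsequent": _uv_node(s.monitoring_cost_subsequent),
                "risk_assessment_cost": s.risk_assessment_cost,
            }
            for s in params.interventions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
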