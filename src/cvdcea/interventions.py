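"""Treatment strategies and their translation into hazard modifiers.

Lipid-lowering works through non-HDL cholesterol: a strategy removes a fixed
percentage of each individual's non-HDL-c (= TC - HDL-c), and meta-analytic
relative risks per 1.0 mmol/L reduction map that absolute change onto the
three first-event transitions as ``RR ** delta`` (log-linear dose-response).
Side effects enter as an expected annual diabetes-treatment cost (absolute
risk increase x annual diabetes cost; negative for berberine, which protects)
and a pill-taking disutility.  The HDL-raising effect of treatment shifts the
HDL covariate in the post-treatment hazard linear predictors (toggleable via
the ``apply_hdl_shift`` option).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .params import InterventionSpec, ParameterSet, RRSet

__all__ = [
    "HazardModifiers",
    "delta_nonhdl",
    "rr_for_transition",
    "build_modifiers",
    "build_cohort_modifiers",
    "strategy_catalog",
]


@dataclass
class HazardModifiers:
    """Per-transition hazard multipliers plus treatment extras.

    ``rr_by_transition`` values may be scalars (one profile) or arrays (one
    per cohort row).  The identity modifier has all multipliers 1 and all
    extras 0.
    """

    rr_by_transition: Mapping[str, float | np.ndarray] = field(
        default_factory=lambda: {"nonfatal_chd": 1.0, "nonfatal_cbvd": 1.0, "fatal_cvd": 1.0}
    )
    extra_annual_cost_first_year: float = 0.0
    extra_annual_cost_subsequent: float = 0.0
    extra_annual_disutility: float = 0.0
    diabetes_expected_cost: float = 0.0
    screening_cost: float = 0.0
    hdl_shift: float | np.ndarray = 0.0
    treated: bool = False

    @classmethod
    def identity(cls) -> "HazardModifiers":
        return cls()


def delta_nonhdl(profile, reduction_pct: float):
    """Absolute non-HDL-c reduction, mmol/L: ``(tc - hdl) * pct / 100``."""
    if not (0.0 <= reduction_pct <= 100.0):
        raise ValueError("reduction_pct must be in [0, 100]")
    if hasattr(profile, "as_dict"):
        profile = profile.as_dict()
    tc = np.asarray(profile["tc"], dtype=float)
    hdl = np.asarray(profile["hdl"], dtype=float)
    if np.any(tc <= hdl):
        raise ValueError("profile violates hdl < tc")
    delta = (tc - hdl) * reduction_pct / 100.0
    return float(delta) if delta.ndim == 0 else delta


def rr_for_transition(rr_per_mmol: float, delta):
    """Log-linear scaling: multiplier ``rr_per_mmol ** delta``."""
    if not (0.0 < rr_per_mmol <= 1.0):
        raise ValueError("rr_per_mmol must be in (0, 1]")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta must be >= 0")
    out = np.power(rr_per_mmol, delta)
    return float(out) if out.ndim == 0 else out


def _modifiers(profile_or_table, spec: InterventionSpec, rrset: RRSet,
               diabetes_annual_cost: float, apply_hdl_shift: bool = True) -> HazardModifiers:
    delta = delta_nonhdl(profile_or_table, spec.nonhdl_reduction.mean)
    rr = {
        "nonfatal_chd": rr_for_transition(rrset.nonfatal_chd.mean, delta),
        "nonfatal_cbvd": rr_for_transition(rrset.nonfatal_cbvd.mean, delta),
        "fatal_cvd": rr_for_transition(rrset.fatal_cvd.mean, delta),
    }
    if hasattr(profile_or_table, "as_dict"):
        hdl = float(profile_or_table.as_dict()["hdl"])
    elif hasattr(profile_or_table, "columns"):
        hdl = profile_or_table["hdl"].to_numpy(float)
    else:
        hdl = float(profile_or_table["hdl"])
    hdl_shift = hdl * spec.hdl_increase.mean / 100.0 if apply_hdl_shift else 0.0
    return HazardModifiers(
        rr_by_transition=rr,
        extra_annual_cost_first_year=spec.drug_cost.mean + spec.monitoring_cost_first_year.mean,
        extra_annual_cost_subsequent=spec.drug_cost.mean + spec.monitoring_cost_subsequent.mean,
        extra_annual_disutility=spec.pill_disutility.mean,
        diabetes_expected_cost=spec.diabetes_ari.mean / 100.0 * diabetes_annual_cost,
        screening_cost=spec.risk_assessment_cost,
        hdl_shift=hdl_shift,
        treated=spec.active,
    )


def build_modifiers(profile, spec: InterventionSpec, rrset: RRSet,
                    diabetes_annual_cost: float, apply_hdl_shift: bool = True) -> HazardModifiers:
    """Hazard modifiers for one profile under one strategy.

    A negative diabetes absolute risk increase yields a negative expected
    annual diabetes cost, i.e. a saving.
    """
    return _modifiers(profile, spec, rrset, diabetes_annual_cost, apply_hdl_shift)


def build_cohort_modifiers(table, spec: InterventionSpec, rrset: RRSet,
                           diabetes_annual_cost: float,
                           apply_hdl_shift: bool = True) -> HazardModifiers:
    """Vectorised :func:`build_modifiers` over a cohort table."""
    return _modifiers(table, spec, rrset, diabetes_annual_cost, apply_hdl_shift)


def strategy_catalog(params: ParameterSet) -> list[tuple[str, InterventionSpec]]:
    """The configured strategies in order, name first.

    The bundled configurations carry the five strategies of the analysis: no
    intervention, atorvastatin 20 mg/day, berberine 1000 mg/day, and the two
    fixed-dose statin+berberine combinations, each with its own measured
    non-HDL-c effect (combination effects are trial-measured, not composed
    from the monotherapies).
    """
    return [(spec.name, spec) for spec in params.interventions]
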