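"""ASSIGN 10-year cardiovascular risk score and eligibility thresholds.

ASSIGN is the Scottish risk score: a sex-specific Cox-type model over age,
systolic blood pressure, total and HDL cholesterol, cigarettes per day,
diabetes, family history of premature CVD, and area deprivation (SIMD).  The
10-year risk is the usual proportional-hazards transform

    risk = 100 * (1 - S0 ** exp(LP - LP_mean))

with ``S0`` the sex-specific 10-year baseline survival and ``LP_mean`` the
centering constant.  The published coefficient set is loaded from the shared
coefficients file (the bundled values are calibration placeholders, flagged
as such there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AssignResult", "assign_score", "assign_scores", "eligibility_mask"]


@dataclass(frozen=True)
class AssignResult:
    linear_predictor: float
    risk_10yr: float  # percent, in (0, 100)


def _lp(table: pd.DataFrame, coefficients) -> np.ndarray:
    lp = np.zeros(len(table))
    for name, coef in coefficients:
        if name not in table.columns:
            raise KeyError(f"ASSIGN coefficient {name!r} has no matching covariate")
        lp += coef * table[name].to_numpy(float)
    return lp


def assign_scores(table: pd.DataFrame, assign_coefficients) -> pd.DataFrame:
    """Vectorised scores for a cohort table; returns lp and risk columns."""
    lp = np.empty(len(table))
    risk = np.empty(len(table))
    sexes = table["sex"].to_numpy()
    for sex in ("female", "male"):
        m = sexes == sex
        if not m.any():
            continue
        sc = assign_coefficients.for_sex(sex)
        lps = _lp(table.loc[m], sc.coefficients)
        lp[m] = lps
        risk[m] = 100.0 * (1.0 - sc.baseline_survival ** np.exp(lps - sc.lp_mean))
    return pd.DataFrame({"linear_predictor": lp, "risk_10yr": risk}, index=table.index)


def assign_score(profile, assign_coefficients) -> AssignResult:
    """10-year CVD risk (percent) for one risk profile."""
    if hasattr(profile, "as_dict"):
        profile = profile.as_dict()
    row = pd.DataFrame([dict(profile)])
    out = assign_scores(row, assign_coefficients)
    return AssignResult(
        linear_predictor=float(out["linear_predictor"].iloc[0]),
        risk_10yr=float(out["risk_10yr"].iloc[0]),
    )


def eligibility_mask(cohort, threshold: float, assign_coefficients) -> pd.Series:
    """True where 10-year risk >= ``threshold`` percent (inclusive)."""
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must be in (0, 100)")
    table = cohort.table if hasattr(cohort, "table") else cohort
    scores = assign_scores(table, assign_coefficients)
    return pd.Series(scores["risk_10yr"] >= threshold, index=table.index, name="eligible")
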