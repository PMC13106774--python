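"""Synthetic risk-profile cohorts with the structure of the eligible Scottish
population.

The generator emulates the marginal structure reported for the
intervention-eligible survey population: 55.6% women; women with lower mean
systolic blood pressure, higher mean total cholesterol, and higher mean HDL
cholesterol than men.  Continuous covariates are truncated normals per sex,
cigarettes per day a zero-inflated count, and area deprivation (SIMD score)
uniform over a configured range.  An optional Gaussian copula correlates age,
SBP and TC; the default is independence.  Statin users and people with prior
CVD are assumed already excluded — every generated row is a member of the
assessed, intervention-eligible pool.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RiskProfile",
    "Cohort",
    "DEFAULT_GENERATOR_CONFIG",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "CohortFormatError",
]

COLUMNS = (
    "id", "age", "sex", "sbp", "tc", "hdl", "cigs_per_day",
    "diabetes", "family_history_cvd", "simd",
)

#: default distribution spec for the eligible pool.  Table-level summary
#: statistics of the survey population live in supplementary material not
#: reproduced here; these are plausible values for a risk-assessed Scottish
#: population aged 40+, honouring the reported qualitative sex contrasts.
DEFAULT_GENERATOR_CONFIG: dict[str, Any] = {
    "female_fraction": 0.556,
    "female": {
        "age": {"mean": 62.0, "sd": 11.0, "min": 40.0, "max": 99.0},
        "sbp": {"mean": 136.0, "sd": 18.0, "min": 70.0, "max": 250.0},
        "tc": {"mean": 6.10, "sd": 1.05, "min": 2.5, "max": 12.0},
        "hdl": {"mean": 1.55, "sd": 0.38, "min": 0.5, "max": 3.5},
        "smoker_fraction": 0.24,
        "cigs_mean": 14.0,
        "diabetes_prevalence": 0.07,
        "family_history_prevalence": 0.32,
    },
    "male": {
        "age": {"mean": 61.0, "sd": 11.0, "min": 40.0, "max": 99.0},
        "sbp": {"mean": 141.0, "sd": 17.0, "min": 70.0, "max": 250.0},
        "tc": {"mean": 5.75, "sd": 1.00, "min": 2.5, "max": 12.0},
        "hdl": {"mean": 1.30, "sd": 0.33, "min": 0.5, "max": 3.5},
        "smoker_fraction": 0.27,
        "cigs_mean": 16.0,
        "diabetes_prevalence": 0.10,
        "family_history_prevalence": 0.28,
    },
    "simd": {"min": 0.5, "max": 85.0},
    # optional Gaussian-copula correlation among (age, sbp, tc); identity by
    # default because the source reports only marginal summaries
    "correlation": {"age_sbp": 0.0, "age_tc": 0.0, "sbp_tc": 0.0},
}


class CohortFormatError(ValueError):
    """A cohort CSV violates the documented schema."""


@dataclass(frozen=True)
class RiskProfile:
    """One individual's ASSIGN covariates."""

    age: float
    sex: str
    sbp: float
    tc: float
    hdl: float
    cigs_per_day: float
    diabetes: int
    family_history_cvd: int
    simd: float

    def __post_init__(self) -> None:
        errs = []
        if self.age < 40:
            errs.append("age must be >= 40")
        if self.sex not in ("female", "male"):
            errs.append(f"sex must be female/male, got {self.sex!r}")
        if not (0 < self.hdl < self.tc):
            errs.append("need 0 < hdl < tc")
        if not (70 <= self.sbp <= 250):
            errs.append("sbp outside [70, 250]")
        if self.cigs_per_day < 0:
            errs.append("cigs_per_day must be >= 0")
        if errs:
            raise ValueError("; ".join(errs))

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class Cohort:
    """A table of risk profiles with stable unique ids."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise CohortFormatError(f"missing columns: {missing}")
        if self.table["id"].duplicated().any():
            raise CohortFormatError("duplicate ids")
        if self.table[list(COLUMNS)].isna().any().any():
            raise CohortFormatError("missing values present")

    def __len__(self) -> int:
        return len(self.table)

    def profile(self, i: int) -> RiskProfile:
        row = self.table.iloc[i]
        return RiskProfile(
            age=float(row["age"]), sex=str(row["sex"]), sbp=float(row["sbp"]),
            tc=float(row["tc"]), hdl=float(row["hdl"]),
            cigs_per_day=float(row["cigs_per_day"]), diabetes=int(row["diabetes"]),
            family_history_cvd=int(row["family_history_cvd"]), simd=float(row["simd"]),
        )


def _merge_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    merged: dict[str, Any] = {}
    for key, val in DEFAULT_GENERATOR_CONFIG.items():
        if isinstance(val, dict):
            merged[key] = {**val, **(config or {}).get(key, {})}
            for k2, v2 in val.items():
                if isinstance(v2, dict):
                    merged[key][k2] = {**v2, **((config or {}).get(key, {}).get(k2, {}) or {})}
        else:
            merged[key] = (config or {}).get(key, val)
    return merged


def _trunc_ppf(u: np.ndarray, mean, sd, lo, hi) -> np.ndarray:
    a = (np.asarray(lo) - mean) / sd
    b = (np.asarray(hi) - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_cohort(
    n: int,
    generator_config: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> Cohort:
    """Draw ``n`` synthetic risk profiles; bit-identical for a given seed.

    The sampling is inverse-CDF throughout so a Gaussian copula (if a
    non-zero correlation is configured) and the independent default share one
    code path.  Total cholesterol is truncated below at just above each
    individual's HDL so ``hdl < tc`` holds row-wise by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = _merge_config(generator_config)
    for sex in ("female", "male"):
        sc = cfg[sex]
        if sc["hdl"]["mean"] >= sc["tc"]["mean"]:
            raise ValueError(f"{sex}: configured mean HDL >= mean TC")

    rng = np.random.default_rng(seed)
    female = rng.random(n) < cfg["female_fraction"]
    sex = np.where(female, "female", "male")

    corr = cfg["correlation"]
    R = np.array([
        [1.0, corr["age_sbp"], corr["age_tc"]],
        [corr["age_sbp"], 1.0, corr["sbp_tc"]],
        [corr["age_tc"], corr["sbp_tc"], 1.0],
    ])
    z = rng.multivariate_normal(np.zeros(3), R, size=n, method="cholesky")
    u_age, u_sbp, u_tc = (stats.norm.cdf(z[:, j]) for j in range(3))
    u_hdl = rng.random(n)

    age = np.empty(n)
    sbp = np.empty(n)
    tc = np.empty(n)
    hdl = np.empty(n)
    cigs = np.zeros(n)
    diabetes = np.zeros(n, dtype=int)
    fh = np.zeros(n, dtype=int)

    u_smoker = rng.random(n)
    pois = rng.poisson  # consumed per-sex below, order fixed by mask evaluation
    u_diab = rng.random(n)
    u_fh = rng.random(n)

    for s in ("female", "male"):
        m = sex == s
        sc = cfg[s]
        age[m] = _trunc_ppf(u_age[m], **{k: sc["age"][j] for k, j in
                                         (("mean", "mean"), ("sd", "sd"), ("lo", "min"), ("hi", "max"))})
        sbp[m] = _trunc_ppf(u_sbp[m], sc["sbp"]["mean"], sc["sbp"]["sd"],
                            sc["sbp"]["min"], sc["sbp"]["max"])
        hdl[m] = _trunc_ppf(u_hdl[m], sc["hdl"]["mean"], sc["hdl"]["sd"],
                            sc["hdl"]["min"], sc["hdl"]["max"])
        # truncate TC below at hdl + 0.1 so hdl < tc always
        lo = np.maximum(sc["tc"]["min"], hdl[m] + 0.1)
        tc[m] = _trunc_ppf(u_tc[m], sc["tc"]["mean"], sc["tc"]["sd"], lo, sc["tc"]["max"])
        smoker = u_smoker[m] < sc["smoker_fraction"]
        counts = pois(sc["cigs_mean"], size=int(m.sum()))
        cigs[m] = np.where(smoker, np.maximum(counts, 1), 0)
        diabetes[m] = (u_diab[m] < sc["diabetes_prevalence"]).astype(int)
        fh[m] = (u_fh[m] < sc["family_history_prevalence"]).astype(int)

    simd = rng.uniform(cfg["simd"]["min"], cfg["simd"]["max"], size=n)

    table = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": np.round(age, 1),
        "sex": sex,
        "sbp": np.round(sbp, 1),
        "tc": np.round(tc, 2),
        "hdl": np.round(hdl, 2),
        "cigs_per_day": cigs,
        "diabetes": diabetes,
        "family_history_cvd": fh,
        "simd": np.round(simd, 2),
    })
    return Cohort(table)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.table.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV, rejecting incomplete rows with their row numbers.

    Mirrors the complete-case rule of the source survey extraction: any row
    with a missing covariate is an error, reported by index.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"{path}: empty file") from exc
    missing_cols = [c for c in COLUMNS if c not in table.columns]
    if missing_cols:
        raise CohortFormatError(f"{path}: missing column(s) {missing_cols}")
    bad = table[list(COLUMNS)].isna().any(axis=1)
    if bad.any():
        rows = [int(i) for i in table.index[bad]]
        raise CohortFormatError(
            f"{path}: rows with missing covariates (complete-case rule): {rows}"
        )
    return Cohort(table)
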