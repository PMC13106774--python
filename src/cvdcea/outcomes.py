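"""Discounted lifetime QALYs, life-years, and costs from a Markov trace.

Utilities come from a linear regression (sex and age baseline, event-specific
decrements for the chronic states, an extra decrement per expected recurrent
event); annual costs from pre-event and post-event cost regressions with
natural-spline time trends.  Life-years are reported undiscounted; QALYs and
costs are discounted at the configured annual rate.  Events are assigned at
cycle end, so accrual in a cycle uses start-of-cycle occupancy and there is no
half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazards import CohortTrace, HealthState, PRIMARY_CAUSES
from .params import CostModel, CostRegression, UtilityModel
from .splines import spline_curve

__all__ = [
    "LifetimeOutcome",
    "discount_factor",
    "annual_utility",
    "accumulate",
    "accumulate_cohort",
]

_POST_STATES = {"post_chd": HealthState.POST_CHD, "post_cbvd": HealthState.POST_CBVD}


@dataclass(frozen=True)
class LifetimeOutcome:
    """Per-individual expected lifetime totals."""

    life_years: float
    qalys: float
    cost: float
    first_events_by_type: dict[str, float]

    @property
    def cvd_events(self) -> float:
        return sum(v for k, v in self.first_events_by_type.items() if k != "noncvd_death")


def discount_factor(year_index: int, rate: float) -> float:
    """``1 / (1 + rate) ** year_index``; year 0 is undiscounted."""
    if year_index < 0:
        raise ValueError("year_index must be >= 0")
    if rate <= -1.0:
        raise ValueError("rate must exceed -1")
    return 1.0 / (1.0 + rate) ** year_index


def annual_utility(state: HealthState, profile, utility_model: UtilityModel,
                   cycle: int, extra_disutility: float = 0.0) -> float:
    """Utility accrued in one cycle for one state, clipped to [0, 1]."""
    if state not in (HealthState.CVD_FREE, HealthState.POST_CHD, HealthState.POST_CBVD):
        return 0.0
    if hasattr(profile, "as_dict"):
        profile = profile.as_dict()
    base = utility_model.baseline(
        1.0 if profile["sex"] == "male" else 0.0, float(profile["age"]) + cycle
    )
    if state is HealthState.POST_CHD:
        base -= utility_model.decrement("post_chd")
    elif state is HealthState.POST_CBVD:
        base -= utility_model.decrement("post_cbvd")
    return float(np.clip(base - extra_disutility, 0.0, 1.0))


def _regression_terms(reg: CostRegression, table: pd.DataFrame,
                      age_column_offset: np.ndarray | float = 0.0) -> np.ndarray:
    """Covariate part (no spline) of a cost regression, per row."""
    out = np.full(len(table), reg.intercept)
    for name, coef in reg.coefficients:
        if name in ("age_at_entry", "age_at_event"):
            out += coef * (table["age"].to_numpy(float) + age_column_offset - 40.0)
        elif name in table.columns:
            out += coef * table[name].to_numpy(float)
        else:
            raise KeyError(f"cost covariate {name!r} not in cohort table")
    return out


def accumulate_cohort(trace: CohortTrace, table: pd.DataFrame, modifiers,
                      utility_model: UtilityModel, cost_model: CostModel,
                      rate: float) -> pd.DataFrame:
    """Vectorised lifetime outcomes for every cohort row.

    ``modifiers`` supplies the treatment extras (drug + monitoring schedule,
    expected diabetes cost, screening, pill disutility) applied to alive
    occupancy while treated; the identity modifier contributes nothing.
    """
    n = len(table)
    if trace.occupancy.shape[0] != n:
        raise ValueError("trace and cohort table sizes differ")
    T = trace.horizon
    male = (table["sex"].to_numpy() == "male").astype(float)
    age0 = table["age"].to_numpy(float)
    cycles = trace.cycles

    dec = dict(utility_model.event_decrements)
    pill = float(getattr(modifiers, "extra_annual_disutility", 0.0) or 0.0)
    treated = bool(getattr(modifiers, "treated", False))
    extra_first = float(getattr(modifiers, "extra_annual_cost_first_year", 0.0) or 0.0)
    extra_sub = float(getattr(modifiers, "extra_annual_cost_subsequent", 0.0) or 0.0)
    diab = float(getattr(modifiers, "diabetes_expected_cost", 0.0) or 0.0)
    screening = float(getattr(modifiers, "screening_cost", 0.0) or 0.0)

    pre_terms = _regression_terms(cost_model.pre_event, table)  # [n]
    pre_reg = cost_model.pre_event
    post_regs = dict(cost_model.post_event)
    post_terms = {k: _regression_terms(post_regs[k], table) for k in post_regs}
    # post-event costs also shift with age at event: add coef * e per entry cycle
    post_age_coef = {
        k: dict(post_regs[k].coefficients).get("age_at_event", 0.0) for k in post_regs
    }
    # spline of time-since-event, precomputed on the integer grid
    grid = np.arange(T, dtype=float)
    post_spline = {
        k: (spline_curve(grid, post_regs[k].spline_knots, post_regs[k].spline_coefficients)
            if post_regs[k].spline_coefficients else np.zeros(T))
        for k in post_regs
    }
    pre_spline = (spline_curve(grid, pre_reg.spline_knots, pre_reg.spline_coefficients)
                  if pre_reg.spline_coefficients else np.zeros(T))

    life_years = np.zeros(n)
    qalys = np.zeros(n)
    cost = np.zeros(n)

    for t in range(T):
        active = (t < cycles).astype(float)
        if not active.any():
            break
        disc = discount_factor(t, rate)
        occ = trace.occupancy[:, t, :]
        occ_free = occ[:, HealthState.CVD_FREE]
        alive = occ_free + occ[:, HealthState.POST_CHD] + occ[:, HealthState.POST_CBVD]
        life_years += active * alive

        base_u = utility_model.baseline(male, age0 + t)
        u_free = np.clip(base_u - pill, 0.0, 1.0)
        q_t = occ_free * u_free
        c_t = occ_free * np.clip(pre_terms + pre_spline[t], 0.0, None)
        for name, state in _POST_STATES.items():
            u_post = np.clip(base_u - dec[name] - pill, 0.0, 1.0)
            q_t += occ[:, state] * u_post
            P = trace.post_by_entry[state][t]  # [n, T] by entry cycle
            if t > 0:
                e = np.arange(t)
                u_since = t - e - 1  # integer time since event at cycle start
                c_post = (post_terms[name][:, None]
                          + post_age_coef[name] * e[None, :]
                          + post_spline[name][u_since][None, :])
                c_t += (P[:, :t] * np.clip(c_post, 0.0, None)).sum(axis=1)
        rec = trace.recurrent[:, t]
        q_t = np.clip(q_t - rec * utility_model.recurrent_event_decrement, 0.0, None)
        c_t += rec * cost_model.recurrent_event_cost
        if treated:
            extra = extra_first if t == 0 else extra_sub
            c_t = c_t + alive * (extra + diab)
        qalys += active * disc * q_t
        cost += active * disc * c_t

    if treated and screening:
        cost += screening  # charged once at entry, year 0 (undiscounted)

    ev = {f"ev_{k}": trace.events[:, :, j].sum(axis=1) for j, k in enumerate(PRIMARY_CAUSES)}
    return pd.DataFrame({"life_years": life_years, "qalys": qalys, "cost": cost, **ev},
                        index=table.index)


def accumulate(trace: CohortTrace, profile, modifiers, utility_model: UtilityModel,
               cost_model: CostModel, rate: float) -> LifetimeOutcome:
    """Single-profile convenience wrapper around :func:`accumulate_cohort`.

    ``trace`` must be the full-detail (cohort) trace for exactly this profile;
    a horizon/shape mismatch is an error.
    """
    if hasattr(profile, "as_dict"):
        profile = profile.as_dict()
    table = pd.DataFrame([dict(profile)])
    if trace.occupancy.shape[0] != 1:
        raise ValueError("accumulate expects a single-row trace; use accumulate_cohort")
    out = accumulate_cohort(trace, table, modifiers, utility_model, cost_model, rate)
    row = out.iloc[0]
    return LifetimeOutcome(
        life_years=float(row["life_years"]),
        qalys=float(row["qalys"]),
        cost=float(row["cost"]),
        first_events_by_type={k: float(row[f"ev_{k}"]) for k in PRIMARY_CAUSES},
    )
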