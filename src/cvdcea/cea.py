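"""Incremental cost-effectiveness analysis: ICER, NNT, dominance, CE plane.

Conventions follow the usual decision-analytic reporting: the ICER is the
incremental discounted cost over the incremental discounted QALYs against a
named reference strategy; a strategy that is more expensive *and* less
effective than the reference is "Dominated", one that is cheaper and more
effective is "Dominant" (reported with its negative ratio and a flag).
Number needed to treat (NNT) is the number of treated individuals per
expected first CVD event prevented.  Rounding happens only at report
formatting (1 decimal place), never inside the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DOMINATED = "Dominated"
DOMINANT = "Dominant"
UNDEFINED = "Undefined"

__all__ = [
    "StrategyResult",
    "icer",
    "icer_label",
    "nnt",
    "incremental_table",
    "ce_plane",
    "DOMINATED",
    "DOMINANT",
    "UNDEFINED",
]


@dataclass(frozen=True)
class StrategyResult:
    """One row of the incremental table (vs. the named reference)."""

    name: str
    reference_name: str
    sample_size: int
    number_treated: int
    events_prevented: float
    nnt: float | str
    life_years_gained: float
    qalys_gained: float
    incremental_cost: float
    icer: float | str
    dominant: bool = False


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost per QALY gained, or a dominance label.

    ``delta_qaly > 0`` gives the plain ratio; more expensive and less
    effective is ``"Dominated"``; cheaper and more effective is the (negative)
    ratio, flagged Dominant by callers; ``delta_qaly == 0`` is undefined.
    """
    if delta_qaly > 0:
        return delta_cost / delta_qaly
    if delta_qaly < 0:
        if delta_cost > 0:
            return DOMINATED
        return delta_cost / delta_qaly  # cheaper and less effective: a ratio, SW quadrant
    return UNDEFINED


def icer_label(delta_cost: float, delta_qaly: float) -> str:
    """Human-readable form, 1 d.p., matching the report formatting."""
    val = icer(delta_cost, delta_qaly)
    return val if isinstance(val, str) else f"{val:,.1f}"


def nnt(number_treated: float, events_prevented: float) -> float | str:
    """Treated individuals per first CVD event prevented."""
    if events_prevented <= 0:
        return UNDEFINED
    return number_treated / events_prevented


def _totals(outcomes: pd.DataFrame, cvd_event_cols) -> tuple[float, float, float, float]:
    return (
        float(outcomes["cost"].sum()),
        float(outcomes["qalys"].sum()),
        float(outcomes["life_years"].sum()),
        float(outcomes[cvd_event_cols].to_numpy().sum()),
    )


def incremental_table(
    per_individual_outcomes: dict[str, pd.DataFrame],
    reference: str,
    number_treated: dict[str, int],
    sample_size: int,
    include_fatal_events: bool = True,
) -> list[StrategyResult]:
    """Sum per-individual outcomes and difference them against the reference.

    Every strategy must have been evaluated on the identical cohort (same
    index); ``number_treated`` is the eligible (treated) count per strategy.
    """
    if reference not in per_individual_outcomes:
        raise KeyError(f"reference {reference!r} not among strategies")
    ref_df = per_individual_outcomes[reference]
    cvd_cols = ["ev_nonfatal_chd", "ev_nonfatal_cbvd"] + (
        ["ev_fatal_cvd"] if include_fatal_events else []
    )
    ref_cost, ref_qaly, ref_ly, ref_events = _totals(ref_df, cvd_cols)

    results: list[StrategyResult] = []
    for name, df in per_individual_outcomes.items():
        if name == reference:
            continue
        if len(df) != len(ref_df) or not df.index.equals(ref_df.index):
            raise ValueError(f"strategy {name!r} evaluated on a different cohort")
        cost, qaly, ly, events = _totals(df, cvd_cols)
        d_cost, d_qaly = cost - ref_cost, qaly - ref_qaly
        prevented = ref_events - events
        ratio = icer(d_cost, d_qaly)
        results.append(StrategyResult(
            name=name,
            reference_name=reference,
            sample_size=sample_size,
            number_treated=int(number_treated.get(name, 0)),
            events_prevented=prevented,
            nnt=nnt(number_treated.get(name, 0), prevented),
            life_years_gained=ly - ref_ly,
            qalys_gained=d_qaly,
            incremental_cost=d_cost,
            icer=ratio,
            dominant=(not isinstance(ratio, str)) and d_cost < 0 and d_qaly > 0,
        ))
    return results


def results_frame(results: list[StrategyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "strategy": r.name,
            "reference": r.reference_name,
            "sample_size": r.sample_size,
            "number_treated": r.number_treated,
            "events_prevented": r.events_prevented,
            "nnt": r.nnt if isinstance(r.nnt, str) else round(r.nnt, 1),
            "life_years_gained": round(r.life_years_gained, 1),
            "qalys_gained": round(r.qalys_gained, 1),
            "incremental_cost": round(r.incremental_cost, 1),
            "icer": r.icer if isinstance(r.icer, str) else round(r.icer, 1),
            "dominant": r.dominant,
        })
    return pd.DataFrame(rows)


def ce_plane(results: list[StrategyResult], threshold: float) -> pd.DataFrame:
    """Cost-effectiveness plane points with a cost-effective flag.

    A strategy is flagged cost-effective when it is not dominated and its
    ICER is strictly below the willingness-to-pay threshold (dominant
    strategies always qualify).
    """
    if not results:
        raise ValueError("no results")
    rows = []
    for r in results:
        if r.icer == DOMINATED or r.icer == UNDEFINED:
            flag = False
        elif r.dominant:
            flag = True
        elif r.qalys_gained < 0:
            flag = False  # SW quadrant: less effective, treated as not cost-effective
        else:
            flag = float(r.icer) < threshold
        rows.append({
            "strategy": r.name,
            "delta_qalys": r.qalys_gained,
            "delta_cost": r.incremental_cost,
            "threshold": threshold,
            "cost_effective": flag,
        })
    return pd.DataFrame(rows)
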