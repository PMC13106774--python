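"""Parameter uncertainty: distribution fitting, PSA, CEAC, and tornado DSA.

Probabilistic sensitivity analysis draws every uncertain parameter once per
iteration (shared across strategies), re-runs the full deterministic pipeline,
and records total discounted cost and QALYs per strategy.  Cohort traces stay
deterministic inside each iteration — uncertainty is parameter-level only, so
first-order simulation noise does not contaminate the ICERs.

Distribution fitting starts from the printed base case and 95% CI using
moment matching (sd = CI width / 3.92; beta on the proportion scale, gamma by
shape/scale moments, lognormal by matched meanlog/sdlog, negated first for
negative-support parameters).  Where the printed CI is too asymmetric for the
moment fit to reproduce it, the fit is refined with the family's support
transform (shift/scale), solving for shape parameters that keep the mean
exact while matching the CI endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cea import icer
from .hazards import run_cohort
from .interventions import build_cohort_modifiers
from .outcomes import accumulate_cohort
from .params import ParameterSet, UncertainValue

__all__ = [
    "DistributionFit",
    "fit_distribution",
    "parameter_registry",
    "apply_draw",
    "run_psa",
    "PsaDraws",
    "ceac",
    "psa_increments",
    "tornado",
    "TornadoRow",
]

_Z95 = 3.919927969080108  # 2 * 1.959964 — CI width in SD units


# ---------------------------------------------------------------------------
# distribution fitting


@dataclass(frozen=True)
class DistributionFit:
    """A sampling recipe: family + shape parameters + support transform.

    The draw is ``x = shift + scale * y`` (then negated if ``negate``), with
    ``y`` from the named family.  ``fixed`` is a point mass at ``shift``.
    """

    family: str
    params: tuple[tuple[str, float], ...]
    shift: float = 0.0
    scale: float = 1.0
    negate: bool = False

    def _dist(self):
        p = dict(self.params)
        if self.family == "beta":
            return stats.beta(p["a"], p["b"], loc=self.shift, scale=self.scale)
        if self.family == "gamma":
            return stats.gamma(p["shape"], loc=self.shift, scale=p["scale"])
        if self.family == "lognormal":
            return stats.lognorm(p["sdlog"], loc=self.shift, scale=np.exp(p["meanlog"]))
        if self.family == "uniform":
            return stats.uniform(self.shift, self.scale)
        raise ValueError(f"no distribution for family {self.family!r}")

    def mean(self) -> float:
        if self.family == "fixed":
            return self.shift
        m = float(self._dist().mean())
        return -m if self.negate else m

    def ppf(self, q) -> float | np.ndarray:
        if self.family == "fixed":
            return np.full_like(np.asarray(q, dtype=float), self.shift) + 0.0
        if self.negate:
            out = -self._dist().ppf(1.0 - np.asarray(q, dtype=float))
        else:
            out = self._dist().ppf(q)
        return out

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "fixed":
            return self.shift if size is None else np.full(size, self.shift)
        y = self._dist().rvs(size=size, random_state=rng)
        return -y if self.negate else y


def _moment_fit(family: str, m: float, sd: float) -> DistributionFit:
    if family == "beta":
        scale = 100.0 if m > 1.0 else 1.0
        mp, sp = m / scale, sd / scale
        nu = mp * (1 - mp) / sp**2 - 1.0
        if nu <= 0:
            raise ValueError("beta moment fit infeasible (sd too large)")
        return DistributionFit("beta", (("a", mp * nu), ("b", (1 - mp) * nu)), 0.0, scale)
    if family == "gamma":
        return DistributionFit("gamma", (("shape", (m / sd) ** 2), ("scale", sd**2 / m)))
    if family == "lognormal":
        s2 = np.log1p((sd / m) ** 2)
        return DistributionFit(
            "lognormal", (("meanlog", np.log(m) - s2 / 2.0), ("sdlog", np.sqrt(s2)))
        )
    raise ValueError(f"no moment fit for family {family!r}")


def _ci_deviation(fit: DistributionFit, lo: float, hi: float) -> float:
    q = fit.ppf(np.array([0.025, 0.975]))
    if fit.negate:
        q = np.sort(q)
    width = hi - lo
    devs = [abs(q[0] - lo) / max(abs(lo), width), abs(q[1] - hi) / max(abs(hi), width)]
    return float(max(devs))


def _calibrated_fit(family: str, m: float, lo: float, hi: float) -> DistributionFit:
    """Solve shape + shift so the mean is exact and the CI endpoints match."""
    z = stats.norm.ppf(0.975)

    if family == "gamma":
        def resid(x):
            logk, s = x
            k = np.exp(logk)
            theta = (m - s) / k
            if theta <= 0:
                return [1e3, 1e3]
            d = stats.gamma(k, loc=s, scale=theta)
            return [(d.ppf(0.025) - lo) / (hi - lo), (d.ppf(0.975) - hi) / (hi - lo)]
        sol = optimize.least_squares(resid, [np.log(4.0), max(0.0, 2 * lo - m)],
                                     bounds=([-6, -abs(m)], [12, 0.999 * min(m, lo)]),
                                     xtol=1e-14, ftol=1e-14)
        k = float(np.exp(sol.x[0]))
        s = float(sol.x[1])
        return DistributionFit("gamma", (("shape", k), ("scale", (m - s) / k)), shift=s)

    if family == "lognormal":
        def resid(x):
            sdlog, s = x
            if m - s <= 0 or sdlog <= 0:
                return [1e3, 1e3]
            meanlog = np.log(m - s) - sdlog**2 / 2.0
            qlo = s + np.exp(meanlog - z * sdlog)
            qhi = s + np.exp(meanlog + z * sdlog)
            return [(qlo - lo) / (hi - lo), (qhi - hi) / (hi - lo)]
        sol = optimize.least_squares(resid, [0.3, max(0.0, 2 * lo - m)],
                                     bounds=([1e-4, -abs(m)], [5.0, 0.999 * min(m, lo)]),
                                     xtol=1e-14, ftol=1e-14)
        sdlog, s = float(sol.x[0]), float(sol.x[1])
        return DistributionFit(
            "lognormal",
            (("meanlog", np.log(m - s) - sdlog**2 / 2.0), ("sdlog", sdlog)),
            shift=s,
        )

    if family == "beta":
        width = hi - lo
        def resid(x):
            loga, logb, lo_s = x
            a, b = np.exp(loga), np.exp(logb)
            hi_s = lo_s + (m - lo_s) * (a + b) / a  # support upper end from exact mean
            if hi_s <= max(m, hi):
                return [1e3, 1e3]
            d = stats.beta(a, b, loc=lo_s, scale=hi_s - lo_s)
            return [(d.ppf(0.025) - lo) / width, (d.ppf(0.975) - hi) / width]
        sol = optimize.least_squares(
            resid, [np.log(3.0), np.log(3.0), lo - 0.5 * width],
            bounds=([-4, -4, lo - 20 * width], [8, 8, lo - 1e-9 * max(width, 1.0)]),
            xtol=1e-14, ftol=1e-14)
        a, b = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
        lo_s = float(sol.x[2])
        hi_s = lo_s + (m - lo_s) * (a + b) / a
        return DistributionFit("beta", (("a", a), ("b", b)), shift=lo_s, scale=hi_s - lo_s)

    raise ValueError(f"no calibrated fit for family {family!r}")


def fit_distribution(u: UncertainValue, ci_tolerance: float = 0.05) -> DistributionFit:
    """Fit the sampling distribution implied by a Table-2-style row.

    Point masses are returned for ``fixed`` and degenerate (zero-width) rows.
    Negative-support rows (e.g. a protective diabetes risk change) are fitted
    on the negated scale and sampled back through the negate transform.
    """
    if u.family == "fixed":
        return DistributionFit("fixed", (), shift=u.mean)
    sd = u.width / _Z95
    if sd <= 0:
        warnings.warn(f"zero-width CI for mean {u.mean}; degenerate point-mass fit",
                      stacklevel=2)
        return DistributionFit("fixed", (), shift=u.mean)
    if u.family == "uniform":
        return DistributionFit("uniform", (), shift=u.ci_low, scale=u.width)

    negate = u.family in ("gamma", "lognormal") and u.mean < 0
    m, lo, hi = (-u.mean, -u.ci_high, -u.ci_low) if negate else (u.mean, u.ci_low, u.ci_high)

    try:
        fit = _moment_fit(u.family, m, sd)
    except ValueError:
        fit = None
    if fit is None or _ci_deviation(fit, lo, hi) > ci_tolerance:
        try:
            cal = _calibrated_fit(u.family, m, lo, hi)
            if fit is None or _ci_deviation(cal, lo, hi) < _ci_deviation(fit, lo, hi):
                fit = cal
        except Exception:
            pass
    if fit is None:
        raise ValueError(f"could not fit {u.family} distribution to {u}")
    return replace(fit, negate=negate)


# ---------------------------------------------------------------------------
# parameter registry and draws


@dataclass(frozen=True)
class PsaParameter:
    """One uncertain model input: an id, its distribution row, and bounds."""

    id: str
    uv: UncertainValue
    strategy: str | None = None  # None = shared across strategies
    kind: str = "table"  # "table" or "discount"


def parameter_registry(params: ParameterSet, strategies: Iterable[str] | None = None
                       ) -> list[PsaParameter]:
    """All uncertain parameters, per-strategy effects first, shared ones after."""
    out: list[PsaParameter] = []
    active = [s for s in params.interventions if s.active]
    if strategies is not None:
        wanted = set(strategies)
        active = [s for s in active if s.name in wanted]
    for s in active:
        out.append(PsaParameter(f"nonhdl_reduction[{s.name}]", s.nonhdl_reduction, s.name))
        out.append(PsaParameter(f"hdl_increase[{s.name}]", s.hdl_increase, s.name))
        out.append(PsaParameter(f"diabetes_ari[{s.name}]", s.diabetes_ari, s.name))
        out.append(PsaParameter(f"drug_cost[{s.name}]", s.drug_cost, s.name))
    rr = params.rr_per_mmol
    out.append(PsaParameter("rr_nonfatal_chd", rr.nonfatal_chd))
    out.append(PsaParameter("rr_nonfatal_cbvd", rr.nonfatal_cbvd))
    out.append(PsaParameter("rr_fatal_cvd", rr.fatal_cvd))
    for name in ("pill_disutility", "monitoring_first_year", "monitoring_subsequent",
                 "risk_assessment", "diabetes_annual"):
        uv = params.shared_uncertain.get(name)
        if uv is not None:
            out.append(PsaParameter(name, uv))
    return out


def apply_draw(params: ParameterSet, draw: Mapping[str, float]) -> ParameterSet:
    """New parameter set with drawn values substituted as point masses."""
    def fx(v: float) -> UncertainValue:
        return UncertainValue.fixed(float(v))

    new_specs = []
    for s in params.interventions:
        if not s.active:
            new_specs.append(s)
            continue
        kw = {}
        for field_name, pid in (
            ("nonhdl_reduction", f"nonhdl_reduction[{s.name}]"),
            ("hdl_increase", f"hdl_increase[{s.name}]"),
            ("diabetes_ari", f"diabetes_ari[{s.name}]"),
            ("drug_cost", f"drug_cost[{s.name}]"),
        ):
            if pid in draw:
                kw[field_name] = fx(draw[pid])
        if "pill_disutility" in draw:
            kw["pill_disutility"] = fx(max(draw["pill_disutility"], 0.0))
        if "monitoring_first_year" in draw:
            kw["monitoring_cost_first_year"] = fx(max(draw["monitoring_first_year"], 0.0))
        if "monitoring_subsequent" in draw:
            kw["monitoring_cost_subsequent"] = fx(max(draw["monitoring_subsequent"], 0.0))
        if "risk_assessment" in draw:
            kw["risk_assessment_cost"] = max(float(draw["risk_assessment"]), 0.0)
        new_specs.append(replace(s, **kw))

    rr = params.rr_per_mmol
    rr_kw = {}
    for name, pid in (("nonfatal_chd", "rr_nonfatal_chd"),
                      ("nonfatal_cbvd", "rr_nonfatal_cbvd"),
                      ("fatal_cvd", "rr_fatal_cvd")):
        if pid in draw:
            rr_kw[name] = fx(float(np.clip(draw[pid], 1e-6, 1.0)))
    new_rr = replace(rr, **rr_kw) if rr_kw else rr

    new_cost = params.cost_model
    if "diabetes_annual" in draw:
        new_cost = replace(new_cost, diabetes_annual=max(float(draw["diabetes_annual"]), 0.0))

    out = replace(params, interventions=tuple(new_specs), rr_per_mmol=new_rr,
                  cost_model=new_cost)
    if "discount_rate" in draw:
        out = replace(out, discount_rate=float(draw["discount_rate"]))
    return out


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PsaDraws:
    """Per-iteration totals (discounted cost, QALYs, CVD events) per strategy."""

    totals: pd.DataFrame  # columns: iteration, strategy, cost, qalys, events
    parameters: pd.DataFrame  # columns: iteration, parameter, value
    seed: int


def _strategy_totals(cohort_df, treated_idx, base_outcomes, params, spec, horizon):
    """Total (cost, qalys, cvd events) with the strategy applied to the treated."""
    include_fatal = params.options.get("events_include_fatal", True)
    cvd_cols = ["ev_nonfatal_chd", "ev_nonfatal_cbvd"] + (
        ["ev_fatal_cvd"] if include_fatal else [])
    base_cost = float(base_outcomes["cost"].sum())
    base_q = float(base_outcomes["qalys"].sum())
    base_ev = float(base_outcomes[cvd_cols].to_numpy().sum())
    if not spec.active or len(treated_idx) == 0:
        return base_cost, base_q, base_ev
    sub = cohort_df.loc[treated_idx]
    mods = build_cohort_modifiers(sub, spec, params.rr_per_mmol,
                                  params.cost_model.diabetes_annual,
                                  params.options.get("apply_hdl_shift", True))
    trace = run_cohort(sub, params, mods, horizon)
    out = accumulate_cohort(trace, sub, mods, params.utility_model,
                            params.cost_model, params.discount_rate)
    d_cost = float(out["cost"].sum()) - float(base_outcomes.loc[treated_idx, "cost"].sum())
    d_q = float(out["qalys"].sum()) - float(base_outcomes.loc[treated_idx, "qalys"].sum())
    d_ev = (float(out[cvd_cols].to_numpy().sum())
            - float(base_outcomes.loc[treated_idx, cvd_cols].to_numpy().sum()))
    return base_cost + d_cost, base_q + d_q, base_ev + d_ev


def run_psa(cohort, params: ParameterSet, n_iter: int, seed: int,
            treated_idx=None, horizon: int | None = None) -> PsaDraws:
    """Monte Carlo over the parameter distributions.

    Each iteration draws every uncertain parameter once (shared across
    strategies), re-evaluates all strategies on the same cohort, and stores
    total discounted cost/QALYs and expected CVD events.  Reproducible:
    iteration *i* uses the *i*-th spawn of ``SeedSequence(seed)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    from .assign import eligibility_mask  # local import to avoid cycles

    table = cohort.table if hasattr(cohort, "table") else cohort
    if treated_idx is None:
        mask = eligibility_mask(table, params.risk_threshold, params.assign)
        treated_idx = table.index[mask]

    registry = parameter_registry(params)
    fits = {p.id: fit_distribution(p.uv) for p in registry}

    base_trace = run_cohort(table, params, None, horizon)
    from .interventions import HazardModifiers
    base_out = accumulate_cohort(base_trace, table, HazardModifiers.identity(),
                                 params.utility_model, params.cost_model,
                                 params.discount_rate)

    rows = []
    prows = []
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng(streams[it])
        draw = {p.id: float(fits[p.id].sample(rng)) for p in registry}
        for pid, v in draw.items():
            prows.append({"iteration": it, "parameter": pid, "value": v})
        p_it = apply_draw(params, draw)
        for spec in p_it.interventions:
            cost, q, ev = _strategy_totals(table, treated_idx, base_out, p_it, spec, horizon)
            rows.append({"iteration": it, "strategy": spec.name,
                         "cost": cost, "qalys": q, "events": ev})
    return PsaDraws(pd.DataFrame(rows), pd.DataFrame(prows), seed)


def psa_increments(draws: PsaDraws, reference: str) -> pd.DataFrame:
    """Per-iteration (delta_cost, delta_qalys, events_prevented) vs a reference."""
    piv_c = draws.totals.pivot(index="iteration", columns="strategy", values="cost")
    piv_q = draws.totals.pivot(index="iteration", columns="strategy", values="qalys")
    piv_e = draws.totals.pivot(index="iteration", columns="strategy", values="events")
    if reference not in piv_c.columns:
        raise KeyError(reference)
    rows = []
    for strat in piv_c.columns:
        if strat == reference:
            continue
        rows.append(pd.DataFrame({
            "iteration": piv_c.index,
            "strategy": strat,
            "delta_cost": piv_c[strat] - piv_c[reference],
            "delta_qalys": piv_q[strat] - piv_q[reference],
            "events_prevented": piv_e[reference] - piv_e[strat],
        }))
    return pd.concat(rows, ignore_index=True)


def ceac(draws: PsaDraws, wtp_grid) -> pd.DataFrame:
    """Probability each strategy maximises net monetary benefit at each WTP.

    NMB = wtp * QALYs - cost; ties share the probability equally, so the
    probabilities across compared strategies sum to one at every grid point.
    """
    piv_c = draws.totals.pivot(index="iteration", columns="strategy", values="cost")
    piv_q = draws.totals.pivot(index="iteration", columns="strategy", values="qalys")
    if piv_c.empty:
        raise ValueError("no draws")
    strategies = list(piv_c.columns)
    C = piv_c.to_numpy()
    Q = piv_q.to_numpy()
    rows = []
    for wtp in np.atleast_1d(np.asarray(wtp_grid, dtype=float)):
        nmb = wtp * Q - C
        best = nmb.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        row = {"wtp": float(wtp)}
        row.update({s: float(p) for s, p in zip(strategies, probs)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity (tornado)


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def range(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def tornado(cohort, params: ParameterSet, bounds: Mapping[str, tuple[float, float]] | None = None,
            strategy: str | None = None, reference: str = "No intervention",
            horizon: int | None = None) -> list[TornadoRow]:
    """One-way sweep of each parameter to its CI endpoints.

    For each parameter alone set to its low then high bound (all else base
    case) the headline ICER of ``strategy`` vs ``reference`` is recomputed.
    Rows are sorted by ICER range, widest first.  Bounds default to the
    parameter CIs (and the configured range for the discount rate).
    """
    from .assign import eligibility_mask
    from .interventions import HazardModifiers

    table = cohort.table if hasattr(cohort, "table") else cohort
    if strategy is None:
        strategy = next(s.name for s in params.interventions if s.active)
    mask = eligibility_mask(table, params.risk_threshold, params.assign)
    treated_idx = table.index[mask]

    registry = [p for p in parameter_registry(params, strategies=[strategy, reference])
                if p.uv.family != "fixed" or p.uv.width > 0]
    sweep: list[tuple[str, float, float]] = []
    for p in registry:
        lo, hi = (bounds or {}).get(p.id, (p.uv.ci_low, p.uv.ci_high))
        sweep.append((p.id, lo, hi))
    dlo, dhi = (bounds or {}).get("discount_rate", params.discount_rate_range)
    sweep.append(("discount_rate", dlo, dhi))

    def _icer_for(p_case: ParameterSet) -> float:
        base_trace = run_cohort(table.loc[treated_idx], p_case, None, horizon)
        base_out = accumulate_cohort(base_trace, table.loc[treated_idx],
                                     HazardModifiers.identity(), p_case.utility_model,
                                     p_case.cost_model, p_case.discount_rate)
        ref_cost, ref_q = float(base_out["cost"].sum()), float(base_out["qalys"].sum())
        if reference != "No intervention":
            rc, rq, _ = _strategy_totals(table.loc[treated_idx], treated_idx, base_out,
                                         p_case, p_case.intervention(reference), horizon)
            ref_cost, ref_q = rc, rq
        sc, sq, _ = _strategy_totals(table.loc[treated_idx], treated_idx, base_out,
                                     p_case, p_case.intervention(strategy), horizon)
        val = icer(sc - ref_cost, sq - ref_q)
        return float(val) if not isinstance(val, str) else float("nan")

    rows = []
    for pid, lo, hi in sweep:
        vals = []
        for v in (lo, hi):
            p_case = apply_draw(params, {pid: v})
            vals.append(_icer_for(p_case))
        rows.append(TornadoRow(pid, float(lo), float(hi), vals[0], vals[1]))
    rows.sort(key=lambda r: (np.isnan(r.range), -(0.0 if np.isnan(r.range) else r.range)))
    return rows
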