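"""Multi-state natural-history engine with Gompertz competing-risk hazards.

Individuals start free of cardiovascular disease (CVD) and, in annual cycles,
face four competing first events — non-fatal coronary heart disease (CHD),
non-fatal cerebrovascular disease (CBVD), fatal CVD, and fatal non-CVD — each
driven by a cause-specific Gompertz hazard ``h(t) = exp(beta·x) * exp(gamma*t)``
whose linear predictor uses the ASSIGN risk factors.  Survivors of a non-fatal
event move to a chronic post-event state where an all-cause Gompertz model
(covariates: age at first event, deprivation, family history) governs death and
a probit model governs recurrent events.  The engine propagates expected state
occupancy (a deterministic Markov trace), not stochastic walkers; parameter
uncertainty is handled by the :mod:`cvdcea.uncertainty` module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "HealthState",
    "GompertzModel",
    "CycleTransition",
    "MarkovTrace",
    "CohortTrace",
    "gompertz_hazard",
    "cumulative_hazard",
    "competing_cycle_probabilities",
    "secondary_event_probability",
    "run_markov",
    "run_cohort",
    "MAX_AGE",
    "PRIMARY_CAUSES",
    "CVD_CAUSES",
]

#: simulation stops once attained age reaches this (lifetime-horizon proxy)
MAX_AGE = 110.0

#: order of the four competing first events
PRIMARY_CAUSES = ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd", "noncvd_death")
#: the three first events counted as primary CVD events
CVD_CAUSES = ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd")

_GAMMA_EPS = 1e-8


class HealthState(IntEnum):
    """States of the transition diagram; DEAD_* are absorbing."""

    CVD_FREE = 0
    POST_CHD = 1
    POST_CBVD = 2
    DEAD_CVD = 3
    DEAD_NONCVD = 4
    DEAD_AFTER_EVENT = 5


ALIVE_STATES = (HealthState.CVD_FREE, HealthState.POST_CHD, HealthState.POST_CBVD)


@dataclass(frozen=True)
class GompertzModel:
    """Cause-specific Gompertz hazard: ``h(t) = exp(beta·x) * exp(gamma t)``.

    ``gamma = 0`` gives the exponential (constant-rate) limit.  ``beta`` is
    stored as a plain list so parameter sets compare field-for-field.
    """

    covariate_names: tuple[str, ...]
    beta: tuple[float, ...]
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if len(self.covariate_names) != len(self.beta):
            raise ValueError(
                f"covariate_names ({len(self.covariate_names)}) and beta "
                f"({len(self.beta)}) lengths differ"
            )
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")

    def linear_predictor(self, covariates: Mapping[str, float]) -> float:
        x = _covariate_vector(self.covariate_names, covariates)
        return float(np.dot(np.asarray(self.beta), x))


def _covariate_vector(names: Sequence[str], covariates: Mapping[str, float]) -> np.ndarray:
    vals = []
    for name in names:
        if name == "intercept":
            vals.append(1.0)
            continue
        if name not in covariates:
            raise KeyError(f"missing covariate {name!r}")
        vals.append(float(covariates[name]))
    return np.asarray(vals)


def gompertz_hazard(model: GompertzModel, covariates: Mapping[str, float], t: float) -> float:
    """Instantaneous rate ``exp(beta·x) * exp(gamma t)`` (per year)."""
    return float(np.exp(model.linear_predictor(covariates)) * np.exp(model.gamma * t))


def _cumhaz_scale(gamma: float, t0, t1):
    """``integral_{t0}^{t1} exp(gamma s) ds`` with a series fallback near 0.

    The closed form ``(e^{g t1} - e^{g t0})/g`` cancels catastrophically for
    tiny ``gamma``; below ``|gamma| < 1e-8`` the integrand is expanded to
    first order, accurate to well beyond 1e-10 there.
    """
    dt = np.asarray(t1, dtype=float) - np.asarray(t0, dtype=float)
    if abs(gamma) < _GAMMA_EPS:
        return dt * (1.0 + gamma * (np.asarray(t0, dtype=float) + np.asarray(t1, dtype=float)) / 2.0)
    return np.exp(gamma * np.asarray(t0, dtype=float)) * np.expm1(gamma * dt) / gamma


def cumulative_hazard(
    model: GompertzModel, covariates: Mapping[str, float], t0: float, t1: float
) -> float:
    """Integrated hazard over ``[t0, t1]``: ``(lambda/gamma)(e^{g t1}-e^{g t0})``."""
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    lam = np.exp(model.linear_predictor(covariates))
    return float(lam * _cumhaz_scale(model.gamma, t0, t1))


@dataclass
class CycleTransition:
    """One cycle's exit probabilities under competing cause-specific hazards."""

    probabilities: dict[str, float]
    stay: float

    def __post_init__(self) -> None:
        total = self.stay + sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")


def competing_cycle_probabilities(
    models: Mapping[str, GompertzModel],
    covariates: Mapping[str, float],
    t0: float,
    cycle_length: float = 1.0,
) -> CycleTransition:
    """Exact competing-risk split of one cycle.

    With per-cause cumulative hazards ``H_k`` over the cycle and ``H = sum H_k``,
    the probability of exiting to cause *k* is ``(H_k/H) (1 - e^{-H})`` and the
    stay probability ``e^{-H}`` — the standard constant-cause-ratio allocation,
    exact when the cause-specific hazards are proportional over the cycle.
    """
    if not models:
        raise ValueError("at least one cause required")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    hs = {k: cumulative_hazard(m, covariates, t0, t0 + cycle_length) for k, m in models.items()}
    total = sum(hs.values())
    if total == 0.0:
        return CycleTransition({k: 0.0 for k in hs}, 1.0)
    stay = float(np.exp(-total))
    leave = -float(np.expm1(-total))
    probs = {k: h / total * leave for k, h in hs.items()}
    # guard the 1e-12 simplex invariant against rounding
    stay = 1.0 - sum(probs.values())
    return CycleTransition(probs, stay)


def secondary_event_probability(
    probit_coefficients: Mapping[str, float], covariates: Mapping[str, float]
) -> float:
    """Recurrent-event probability ``Phi(beta·x)`` from the probit model."""
    lp = 0.0
    for name, coef in probit_coefficients.items():
        if name == "intercept":
            lp += coef
        else:
            lp += coef * float(covariates[name])
    return float(ndtr(lp))


# ---------------------------------------------------------------------------
# trace containers


@dataclass
class CohortTrace:
    """Expected state occupancy for a cohort, one annual cycle at a time.

    ``occupancy[i, t, s]`` is individual *i*'s probability of being in state
    *s* at the **start** of cycle *t*; ``events[i, t, k]`` the expected number
    of first events of type *k* occurring during cycle *t* (assigned at cycle
    end).  ``post_by_entry[state][t, i, e]`` resolves chronic-state occupancy
    by the cycle *e* at whose end the first event happened, which downstream
    costing needs (post-event costs depend on time since event and age at
    event).  ``cycles[i]`` is the number of simulated cycles for individual
    *i* (the lifetime horizon capped at age 110).
    """

    occupancy: np.ndarray  # [n, T+1, n_states]
    events: np.ndarray  # [n, T, 4] in PRIMARY_CAUSES order
    recurrent: np.ndarray  # [n, T] expected recurrent events per cycle
    post_by_entry: dict[HealthState, np.ndarray]  # [T+1, n, T]
    cycles: np.ndarray  # [n] per-individual horizon in cycles
    ages_at_entry: np.ndarray  # [n]
    horizon: int

    def row(self, i: int) -> "MarkovTrace":
        T = int(self.cycles[i])
        ev = pd.DataFrame(self.events[i, :T, :], columns=list(PRIMARY_CAUSES))
        return MarkovTrace(
            occupancy=self.occupancy[i, : T + 1, :].copy(),
            events=ev,
            horizon=T,
            recurrent=self.recurrent[i, :T].copy(),
        )


@dataclass
class MarkovTrace:
    """Single-individual view of a :class:`CohortTrace`."""

    occupancy: np.ndarray  # [T+1, n_states]
    events: pd.DataFrame  # per-cycle expected incident first events by type
    horizon: int
    recurrent: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def expected_first_events(self) -> pd.Series:
        return self.events.sum(axis=0)

    def to_csv(self, path) -> None:
        """Dump the cycle-by-state occupancy matrix (debugging aid)."""
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in HealthState])
        df.index.name = "cycle"
        df.to_csv(path)


# ---------------------------------------------------------------------------
# engine


_PRIMARY_COVARIATES = (
    "age",
    "male",
    "sbp",
    "tc",
    "hdl",
    "cigs_per_day",
    "diabetes",
    "family_history_cvd",
    "simd",
)


def _design_matrix(cohort: pd.DataFrame, names: Sequence[str], age_offset: float,
                   hdl_shift: np.ndarray | None) -> np.ndarray:
    """Design matrix for a primary model at a given cycle (age advances)."""
    n = len(cohort)
    cols = []
    for name in names:
        if name == "intercept":
            cols.append(np.ones(n))
        elif name == "age":
            cols.append(cohort["age"].to_numpy(float) + age_offset)
        elif name == "male":
            cols.append((cohort["sex"].to_numpy() == "male").astype(float))
        elif name == "hdl":
            h = cohort["hdl"].to_numpy(float)
            if hdl_shift is not None:
                h = h + hdl_shift
            cols.append(h)
        else:
            cols.append(cohort[name].to_numpy(float))
    return np.column_stack(cols)


def run_cohort(
    cohort: pd.DataFrame,
    params,
    modifiers=None,
    horizon: int | None = None,
) -> CohortTrace:
    """Propagate expected occupancy for every cohort row.

    Parameters
    ----------
    cohort : DataFrame with the risk-profile columns of :mod:`cvdcea.cohort`.
    params : :class:`cvdcea.params.ParameterSet`.
    modifiers : :class:`cvdcea.interventions.HazardModifiers` or ``None``.
        Relative-risk multipliers on the three first CVD events plus an HDL
        shift entering the post-treatment linear predictors.  ``None`` (or the
        identity modifier) means natural history.
    horizon : maximum number of annual cycles; defaults to age 110 for the
        youngest member.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    ages = cohort["age"].to_numpy(float)
    per_row_T = np.maximum(1, np.ceil(np.minimum(
        np.inf if horizon is None else horizon, MAX_AGE - ages))).astype(int)
    if horizon is not None:
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        per_row_T = np.minimum(per_row_T, horizon)
    T = int(per_row_T.max())

    rr = np.ones((n, 3))
    hdl_shift = None
    if modifiers is not None:
        for j, cause in enumerate(CVD_CAUSES):
            rr[:, j] = modifiers.rr_by_transition.get(cause, 1.0)
        if getattr(modifiers, "hdl_shift", 0.0) is not None:
            shift = np.asarray(modifiers.hdl_shift, dtype=float)
            if shift.ndim == 0:
                shift = np.full(n, float(shift))
            if np.any(shift != 0.0):
                hdl_shift = shift

    primary = [params.gompertz_primary[c] for c in PRIMARY_CAUSES]
    time_scale_entry = params.options.get("time_scale", "entry") == "entry"

    # fixed pieces of the secondary (post-event) mortality models
    simd = cohort["simd"].to_numpy(float)
    fh = cohort["family_history_cvd"].to_numpy(float)

    def _secondary_lambda(model: GompertzModel, entry_cycles: np.ndarray) -> np.ndarray:
        """lambda[i, e] = exp(beta·x) with age-at-event = age_i + e (+1 cycle lag)."""
        lp = np.zeros((n, len(entry_cycles)))
        for name, b in zip(model.covariate_names, model.beta):
            if name == "intercept":
                lp += b
            elif name == "age_at_event":
                lp += b * (ages[:, None] + entry_cycles[None, :])
            elif name == "simd":
                lp += b * simd[:, None]
            elif name == "family_history_cvd":
                lp += b * fh[:, None]
            else:
                raise KeyError(f"unsupported secondary covariate {name!r}")
        return np.exp(lp)

    entry_grid = np.arange(T, dtype=float)
    sec_lam = {
        HealthState.POST_CHD: _secondary_lambda(params.gompertz_secondary["post_chd"], entry_grid),
        HealthState.POST_CBVD: _secondary_lambda(params.gompertz_secondary["post_cbvd"], entry_grid),
    }
    sec_gamma = {
        HealthState.POST_CHD: params.gompertz_secondary["post_chd"].gamma,
        HealthState.POST_CBVD: params.gompertz_secondary["post_cbvd"].gamma,
    }

    # probit recurrent-event probability by entry cycle: Phi(b·x(age at event))
    pc = params.probit_secondary
    probit_lp = (
        pc.get("intercept", 0.0)
        + pc.get("age_at_event", 0.0) * (ages[:, None] + entry_grid[None, :])
        + pc.get("simd", 0.0) * simd[:, None]
        + pc.get("family_history_cvd", 0.0) * fh[:, None]
    )
    p_recurrent = ndtr(probit_lp)  # [n, T]

    occupancy = np.zeros((n, T + 1, len(HealthState)))
    occupancy[:, 0, HealthState.CVD_FREE] = 1.0
    events = np.zeros((n, T, len(PRIMARY_CAUSES)))
    recurrent = np.zeros((n, T))
    post_entry = {
        HealthState.POST_CHD: np.zeros((T + 1, n, T)),
        HealthState.POST_CBVD: np.zeros((T + 1, n, T)),
    }

    pfree = np.ones(n)
    post_now = {HealthState.POST_CHD: np.zeros((n, T)), HealthState.POST_CBVD: np.zeros((n, T))}
    dead = {s: np.zeros(n) for s in (HealthState.DEAD_CVD, HealthState.DEAD_NONCVD,
                                     HealthState.DEAD_AFTER_EVENT)}

    for t in range(T):
        active = (t < per_row_T).astype(float)

        # --- first events from CVD_FREE (competing risks over this cycle)
        H = np.zeros((n, len(PRIMARY_CAUSES)))
        for k, model in enumerate(primary):
            X = _design_matrix(cohort, model.covariate_names, float(t), hdl_shift)
            lam = np.exp(X @ np.asarray(model.beta))
            if k < 3:
                lam = lam * rr[:, k]
            t0 = float(t) if time_scale_entry else 0.0
            H[:, k] = lam * _cumhaz_scale(model.gamma, t0, t0 + 1.0)
        Htot = H.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            leave = -np.expm1(-Htot)
            frac = np.where(Htot[:, None] > 0, H / np.where(Htot[:, None] > 0, Htot[:, None], 1.0), 0.0)
        p_exit = frac * leave[:, None] * active[:, None]
        stay = 1.0 - p_exit.sum(axis=1)

        events[:, t, :] = pfree[:, None] * p_exit

        # --- post-event mortality for existing chronic occupancy (entries e < t)
        for state in (HealthState.POST_CHD, HealthState.POST_CBVD):
            P = post_now[state]
            if t > 0:
                e = np.arange(t, dtype=float)
                # time since event at cycle start: t - e - 1 (event at end of cycle e)
                u0 = t - e - 1.0
                Hs = sec_lam[state][:, :t] * _cumhaz_scale(sec_gamma[state], u0, u0 + 1.0)[None, :]
                qs = -np.expm1(-Hs) * active[:, None]
                died = (P[:, :t] * qs).sum(axis=1)
                dead[HealthState.DEAD_AFTER_EVENT] += died
                P[:, :t] *= 1.0 - qs
                # recurrent events among those surviving the cycle
                recurrent[:, t] += (P[:, :t] * p_recurrent[:, :t]).sum(axis=1) * active

        # --- apply first-event flows
        new_chd = pfree * p_exit[:, 0]
        new_cbvd = pfree * p_exit[:, 1]
        dead[HealthState.DEAD_CVD] += pfree * p_exit[:, 2]
        dead[HealthState.DEAD_NONCVD] += pfree * p_exit[:, 3]
        pfree = pfree * stay
        post_now[HealthState.POST_CHD][:, t] = new_chd
        post_now[HealthState.POST_CBVD][:, t] = new_cbvd

        occupancy[:, t + 1, HealthState.CVD_FREE] = pfree
        for state in (HealthState.POST_CHD, HealthState.POST_CBVD):
            occupancy[:, t + 1, state] = post_now[state].sum(axis=1)
            post_entry[state][t + 1] = post_now[state]
        for state, v in dead.items():
            occupancy[:, t + 1, state] = v

    return CohortTrace(
        occupancy=occupancy,
        events=events,
        recurrent=recurrent,
        post_by_entry=post_entry,
        cycles=per_row_T,
        ages_at_entry=ages,
        horizon=T,
    )


def run_markov(profile, params, modifiers=None, horizon: int | None = None) -> MarkovTrace:
    """Lifetime expected-occupancy trace for one risk profile.

    ``profile`` may be a mapping or a :class:`cvdcea.cohort.RiskProfile`;
    ``modifiers`` an identity-or-treatment :class:`HazardModifiers`.
    """
    if horizon is not None and horizon < 1:
        raise ValueError("horizon must be >= 1")
    if hasattr(profile, "as_dict"):
        profile = profile.as_dict()
    df = pd.DataFrame([dict(profile)])
    trace = run_cohort(df, params, modifiers=modifiers, horizon=horizon)
    return trace.row(0)
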