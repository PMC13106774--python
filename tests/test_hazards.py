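"""Gompertz hazards, competing-risk cycle probabilities, and the Markov engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from cvdcea.cohort import generate_cohort
from cvdcea.hazards import (
    CVD_CAUSES,
    GompertzModel,
    HealthState,
    PRIMARY_CAUSES,
    competing_cycle_probabilities,
    cumulative_hazard,
    gompertz_hazard,
    run_cohort,
    run_markov,
    secondary_event_probability,
)
from cvdcea.interventions import HazardModifiers


def _model(loglam: float, gamma: float) -> GompertzModel:
    return GompertzModel(("intercept",), (loglam,), gamma)


COVS: dict[str, float] = {}


class TestGompertzHazard:
    def test_zero_linear_predictor_zero_shape_gives_unit_rate(self):
        assert gompertz_hazard(_model(0.0, 0.0), COVS, t=3.0) == 1.0

    def test_exponential_limit(self):
        assert gompertz_hazard(_model(np.log(0.01), 0.0), COVS, 5.0) == pytest.approx(0.01)

    def test_shape_growth(self):
        # lambda=0.01, gamma=0.1, t=10 -> 0.01 * e
        h = gompertz_hazard(_model(np.log(0.01), 0.1), COVS, 10.0)
        assert h == pytest.approx(0.01 * np.e, rel=1e-12)
        # cross-check: numerical log-derivative of the survival function
        m = _model(np.log(0.01), 0.1)
        eps = 1e-6
        H = lambda t: cumulative_hazard(m, COVS, 0.0, t)
        assert h == pytest.approx((H(10 + eps) - H(10 - eps)) / (2 * eps), rel=1e-6)

    def test_missing_covariate_is_named(self):
        m = GompertzModel(("intercept", "age"), (-2.0, 0.1), 0.0)
        with pytest.raises(KeyError, match="age"):
            gompertz_hazard(m, {}, 0.0)


class TestCumulativeHazard:
    def test_exponential_limit(self):
        m = _model(np.log(0.02), 0.0)
        assert cumulative_hazard(m, COVS, 0.0, 1.0) == pytest.approx(0.02, rel=1e-14)

    def test_no_catastrophic_cancellation_near_zero_shape(self):
        m = _model(np.log(0.02), 1e-12)
        assert cumulative_hazard(m, COVS, 0.0, 1.0) == pytest.approx(0.02, rel=1e-9)

    def test_matches_adaptive_quadrature(self):
        m = _model(np.log(0.01), 0.09)
        H = cumulative_hazard(m, COVS, 3.0, 4.0)
        ref, err = integrate.quad(lambda t: gompertz_hazard(m, COVS, t), 3.0, 4.0,
                                  epsabs=1e-13, epsrel=1e-13)
        assert abs(H - ref) < 1e-10

    @given(loglam=st.floats(-8, 0), gamma=st.floats(-0.2, 0.2),
           t0=st.floats(0, 50), dt=st.floats(0.1, 5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_quadrature_agreement_property(self, loglam, gamma, t0, dt):
        m = _model(loglam, gamma)
        H = cumulative_hazard(m, COVS, t0, t0 + dt)
        ref, _ = integrate.quad(lambda t: gompertz_hazard(m, COVS, t), t0, t0 + dt,
                                epsabs=1e-12, epsrel=1e-12)
        assert H == pytest.approx(ref, abs=max(1e-10, 1e-9 * ref))

    def test_gamma_to_zero_limit_agrees_with_exponential(self):
        m0 = _model(np.log(0.05), 0.0)
        m1 = _model(np.log(0.05), 1e-10)
        for t0, t1 in [(0, 1), (5, 6), (0, 30)]:
            a = cumulative_hazard(m0, COVS, t0, t1)
            b = cumulative_hazard(m1, COVS, t0, t1)
            assert b == pytest.approx(a, rel=1e-8)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            cumulative_hazard(_model(0.0, 0.0), COVS, 2.0, 1.0)


def _microstep_oracle(lams, gammas, t0, cycle, dt=1e-4):
    """Discrete-time competing-risk simulation on a fine grid."""
    k = len(lams)
    alive = 1.0
    exit_p = np.zeros(k)
    steps = int(round(cycle / dt))
    ts = t0 + dt * np.arange(steps)
    hs = np.array([lam * np.exp(g * (ts + dt / 2)) for lam, g in zip(lams, gammas)])
    step_total = hs.sum(axis=0) * dt
    surv_step = np.exp(-step_total)
    for j in range(steps):
        total = step_total[j]
        leave = -np.expm1(-total)
        exit_p += alive * leave * (hs[:, j] * dt / total if total > 0 else 0.0)
        alive *= surv_step[j]
    return exit_p, alive


class TestCompetingCycleProbabilities:
    def test_all_hazards_zero_stays_put(self):
        models = {"a": _model(-np.inf, 0.0)}
        tr = competing_cycle_probabilities(models, COVS, 0.0)
        assert tr.stay == 1.0 and tr.probabilities["a"] == 0.0

    def test_single_cause_reduction(self):
        tr = competing_cycle_probabilities({"a": _model(np.log(0.01), 0.0)}, COVS, 0.0)
        assert tr.probabilities["a"] == pytest.approx(1 - np.exp(-0.01), rel=1e-12)

    def test_two_causes_share_by_hazard_ratio_and_sum_to_one(self):
        models = {"a": _model(np.log(0.04), 0.0), "b": _model(np.log(0.02), 0.0)}
        tr = competing_cycle_probabilities(models, COVS, 0.0)
        assert tr.probabilities["a"] == pytest.approx(2 * tr.probabilities["b"], rel=1e-12)
        assert tr.stay + sum(tr.probabilities.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_microstep_simulation_on_random_fixtures(self, rng):
        # cause-specific hazards proportional within the cycle (one shared
        # Gompertz shape per fixture), the regime the cycle split is exact for
        # and the one the transition models use
        for _ in range(20):
            k = rng.integers(1, 5)
            lams = np.exp(rng.uniform(-6, -1.5, size=k))
            gammas = np.full(k, rng.uniform(-0.1, 0.12))
            t0 = float(rng.uniform(0, 20))
            models = {f"c{i}": _model(np.log(lams[i]), gammas[i]) for i in range(k)}
            tr = competing_cycle_probabilities(models, COVS, t0)
            ref_p, ref_stay = _microstep_oracle(lams, gammas, t0, 1.0)
            assert tr.stay == pytest.approx(ref_stay, rel=2e-3)
            for i in range(k):
                # agreement to 3 significant figures
                assert tr.probabilities[f"c{i}"] == pytest.approx(ref_p[i], rel=2e-3)

    def test_empty_models_and_bad_cycle_rejected(self):
        with pytest.raises(ValueError):
            competing_cycle_probabilities({}, COVS, 0.0)
        with pytest.raises(ValueError):
            competing_cycle_probabilities({"a": _model(0, 0)}, COVS, 0.0, cycle_length=0.0)


class TestSecondaryEventProbability:
    def test_probit_zero_gives_half(self):
        assert secondary_event_probability({"intercept": 0.0}, {}) == pytest.approx(0.5)

    def test_probit_lower_tail(self):
        p = secondary_event_probability({"intercept": -1.959964}, {})
        assert p == pytest.approx(0.025, rel=1e-4)

    def test_fixture_matches_independent_cdf(self):
        coefs = {"intercept": -2.0, "age_at_event": 0.01, "simd": 0.005,
                 "family_history_cvd": 0.2}
        covs = {"age_at_event": 70.0, "simd": 30.0, "family_history_cvd": 1.0}
        lp = -2.0 + 0.7 + 0.15 + 0.2
        assert secondary_event_probability(coefs, covs) == pytest.approx(
            stats.norm.cdf(lp), rel=1e-12)


class TestMarkovEngine:
    def test_zero_hazards_stay_point_mass_on_cvd_free(self, scotland, profile):
        import dataclasses
        zeroed = {k: GompertzModel(("intercept",), (-np.inf,), 0.0)
                  for k in PRIMARY_CAUSES}
        params = dataclasses.replace(scotland, gompertz_primary=zeroed)
        tr = run_markov(profile, params, horizon=20)
        assert np.allclose(tr.occupancy[:, HealthState.CVD_FREE], 1.0)
        assert tr.events.to_numpy().sum() == 0.0

    def test_identity_modifiers_equal_no_modifiers(self, scotland, profile):
        a = run_markov(profile, scotland, None, horizon=30)
        b = run_markov(profile, scotland, HazardModifiers.identity(), horizon=30)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_rows_stochastic_and_death_monotone_for_random_profiles(self, scotland):
        t = generate_cohort(100, scotland.generator, seed=21).table
        trace = run_cohort(t, scotland, None)
        sums = trace.occupancy.sum(axis=2)
        assert np.abs(sums - 1.0).max() < 1e-9
        dead = trace.occupancy[:, :, 3:].sum(axis=2)
        assert (np.diff(dead, axis=1) >= -1e-12).all()

    def test_protective_rr_never_decreases_life_years(self, scotland, profile):
        import pandas as pd
        df = pd.DataFrame([profile.as_dict()])
        base = run_cohort(df, scotland, None)
        mods = HazardModifiers(rr_by_transition={c: 0.6 for c in CVD_CAUSES})
        treated = run_cohort(df, scotland, mods)
        ly_base = base.occupancy[0, :, :3].sum()
        ly_treated = treated.occupancy[0, :, :3].sum()
        assert ly_treated >= ly_base

    def test_horizon_validation(self, scotland, profile):
        with pytest.raises(ValueError):
            run_markov(profile, scotland, horizon=0)

    def test_gamma_zero_engine_agrees_with_pure_exponential_rates(self, scotland, profile):
        """With all shapes zero and age frozen, each cycle is a homogeneous
        exponential competing-risk step; compare against a direct
        implementation built from constant per-cycle rates."""
        import dataclasses
        import pandas as pd

        lam = {"nonfatal_chd": 0.012, "nonfatal_cbvd": 0.008,
               "fatal_cvd": 0.006, "noncvd_death": 0.015}
        primary = {k: GompertzModel(("intercept",), (np.log(v),), 0.0)
                   for k, v in lam.items()}
        sec = {k: GompertzModel(("intercept",), (np.log(0.06),), 0.0)
               for k in ("post_chd", "post_cbvd")}
        params = dataclasses.replace(scotland, gompertz_primary=primary,
                                     gompertz_secondary=sec)
        T = 25
        tr = run_cohort(pd.DataFrame([profile.as_dict()]), params, None, horizon=T)

        # independent exponential-rates recursion
        Ltot = sum(lam.values())
        stay = np.exp(-Ltot)
        q_sec = 1 - np.exp(-0.06)
        pfree = 1.0
        post = {"post_chd": [], "post_cbvd": []}  # occupancy per entry cycle
        occ = np.zeros((T + 1, 6))
        occ[0, 0] = 1.0
        dead_cvd = dead_noncvd = dead_after = 0.0
        for t in range(T):
            leave = 1 - stay
            for name in post:
                died = sum(post[name]) * q_sec
                dead_after += died
                post[name] = [p * (1 - q_sec) for p in post[name]]
            post["post_chd"].append(pfree * leave * lam["nonfatal_chd"] / Ltot)
            post["post_cbvd"].append(pfree * leave * lam["nonfatal_cbvd"] / Ltot)
            dead_cvd += pfree * leave * lam["fatal_cvd"] / Ltot
            dead_noncvd += pfree * leave * lam["noncvd_death"] / Ltot
            pfree *= stay
            occ[t + 1] = [pfree, sum(post["post_chd"]), sum(post["post_cbvd"]),
                          dead_cvd, dead_noncvd, dead_after]
        np.testing.assert_allclose(tr.occupancy[0], occ, atol=1e-8)

    def test_expected_events_match_monte_carlo_walkers(self, scotland, profile, rng):
        """Individual-level stochastic walkers agree with the expected-value
        trace on lifetime first-event counts (within 3 standard errors)."""
        import pandas as pd

        df = pd.DataFrame([profile.as_dict()])
        T = 30
        trace = run_cohort(df, scotland, None, horizon=T)
        expected = trace.events[0].sum(axis=0)  # per-cause lifetime counts [4]

        n_walk = 60000
        state = np.zeros(n_walk, dtype=int)  # 0 free, 1 post, 2 dead
        counts = np.zeros(len(PRIMARY_CAUSES))
        covs = profile.as_dict()
        for t in range(T):
            free = state == 0
            if not free.any():
                break
            models = {k: scotland.gompertz_primary[k] for k in PRIMARY_CAUSES}
            cv = {**covs, "age": covs["age"] + t,
                  "male": 1.0 if covs["sex"] == "male" else 0.0}
            tr = competing_cycle_probabilities(models, cv, float(t))
            probs = [tr.probabilities[k] for k in PRIMARY_CAUSES] + [tr.stay]
            draws = rng.choice(len(probs), size=int(free.sum()), p=np.array(probs))
            for j in range(len(PRIMARY_CAUSES)):
                counts[j] += (draws == j).sum()
            new_state = np.where(draws == len(PRIMARY_CAUSES), 0, 2)
            state[free] = new_state
        mc = counts / n_walk
        for j, cause in enumerate(PRIMARY_CAUSES):
            p = expected[j]
            se = np.sqrt(max(p * (1 - p), 1e-12) / n_walk)
            assert abs(mc[j] - p) < 3.5 * se, cause
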