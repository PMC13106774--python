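"""Distribution fitting, PSA reproducibility, CEAC, and tornado DSA."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cvdcea.cohort import generate_cohort
from cvdcea.params import UncertainValue
from cvdcea.uncertainty import (
    PsaDraws,
    apply_draw,
    ceac,
    fit_distribution,
    parameter_registry,
    psa_increments,
    run_psa,
    tornado,
)


class TestFitDistribution:
    def test_gamma_fit_reproduces_mean_to_1e6(self):
        fit = fit_distribution(UncertainValue(13.44, 8.99, 23.99, "gamma"))
        assert fit.mean() == pytest.approx(13.44, abs=1e-6)

    def test_zero_width_ci_gives_point_mass(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_distribution(UncertainValue(0.5, 0.5, 0.5, "beta"))
        assert fit.family == "fixed"
        rng = np.random.default_rng(0)
        assert (fit.sample(rng, 10) == 0.5).all()

    def test_lognormal_ari_monte_carlo_mean(self, rng):
        # positive-support absolute-risk-increase row
        fit = fit_distribution(UncertainValue(0.5, 0.1, 1.0, "lognormal"))
        x = fit.sample(rng, 10**6)
        assert np.mean(x) == pytest.approx(0.5, rel=0.01)
        assert (x > -0.51).all()

    def test_negative_support_lognormal_negates(self, rng):
        fit = fit_distribution(UncertainValue(-4.6, -6.1, -4.2, "lognormal"))
        assert fit.negate
        x = fit.sample(rng, 10**5)
        assert (x < 0).all()
        assert np.mean(x) == pytest.approx(-4.6, rel=0.01)
        lo, hi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(-6.1, rel=0.05)
        assert hi == pytest.approx(-4.2, rel=0.05)

    def test_mean_zero_range_bounded_effect_fit(self, rng):
        # combined-therapy diabetes effect: mean 0 over (-4.6, 0.5)
        fit = fit_distribution(UncertainValue(0.0, -4.6, 0.5, "beta"))
        assert fit.mean() == pytest.approx(0.0, abs=1e-6)
        x = fit.sample(rng, 10**5)
        assert np.mean(x) == pytest.approx(0.0, abs=0.02)

    def test_sampled_quantiles_bracket_stated_ci(self, rng):
        # self-consistency: empirical quantiles of the fit's own draws
        u = UncertainValue(26.0, 15.0, 35.0, "beta")
        fit = fit_distribution(u)
        x = fit.sample(rng, 10**4)
        lo, hi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(15.0, rel=0.05)
        assert hi == pytest.approx(35.0, rel=0.05)

    def test_fixed_family_passthrough(self):
        fit = fit_distribution(UncertainValue.fixed(7.0))
        assert fit.mean() == 7.0


def _tiny(scotland, n=60, seed=23):
    return generate_cohort(n, scotland.generator, seed=seed)


def _point_mass_params(params):
    """All uncertain rows collapsed to their base case."""
    def pm(uv):
        return UncertainValue.fixed(uv.mean)
    specs = tuple(
        dataclasses.replace(
            s,
            nonhdl_reduction=pm(s.nonhdl_reduction), hdl_increase=pm(s.hdl_increase),
            diabetes_ari=pm(s.diabetes_ari), pill_disutility=pm(s.pill_disutility),
            drug_cost=pm(s.drug_cost),
            monitoring_cost_first_year=pm(s.monitoring_cost_first_year),
            monitoring_cost_subsequent=pm(s.monitoring_cost_subsequent),
        )
        for s in params.interventions
    )
    rr = dataclasses.replace(
        params.rr_per_mmol,
        nonfatal_chd=pm(params.rr_per_mmol.nonfatal_chd),
        nonfatal_cbvd=pm(params.rr_per_mmol.nonfatal_cbvd),
        fatal_cvd=pm(params.rr_per_mmol.fatal_cvd),
        any_cvd=pm(params.rr_per_mmol.any_cvd),
    )
    shared = {k: pm(v) for k, v in params.shared_uncertain.items()}
    return dataclasses.replace(params, interventions=specs, rr_per_mmol=rr,
                               shared_uncertain=shared)


class TestRunPsa:
    def test_point_mass_distributions_reproduce_base_case_exactly(self, scotland):
        coh = _tiny(scotland)
        pm = _point_mass_params(scotland)
        draws = run_psa(coh, pm, n_iter=1, seed=5)
        from cvdcea.model import CvdPolicyModel
        res = CvdPolicyModel(coh, pm).fit()
        for r in res.strategy_results:
            row = psa_increments(draws, "No intervention")
            got = row[row.strategy == r.name].iloc[0]
            assert got.delta_cost == pytest.approx(r.incremental_cost, abs=1e-9)
            assert got.delta_qalys == pytest.approx(r.qalys_gained, abs=1e-9)

    def test_same_seed_identical_draws(self, scotland):
        coh = _tiny(scotland, n=40)
        a = run_psa(coh, scotland, n_iter=3, seed=9)
        b = run_psa(coh, scotland, n_iter=3, seed=9)
        pd.testing.assert_frame_equal(a.totals, b.totals)
        pd.testing.assert_frame_equal(a.parameters, b.parameters)
        c = run_psa(coh, scotland, n_iter=3, seed=10)
        assert not a.totals.equals(c.totals)

    def test_parameter_draw_means_converge_to_base_case(self, scotland, rng):
        # law-of-large-numbers check on the sampling layer alone
        for p in parameter_registry(scotland):
            if p.uv.family == "fixed" or p.uv.width == 0:
                continue
            fit = fit_distribution(p.uv)
            n = 10**4
            x = fit.sample(rng, n)
            sd = float(np.std(x))
            tol = max(0.01 * abs(p.uv.mean), 3.2 * sd / np.sqrt(n))
            assert np.mean(x) == pytest.approx(p.uv.mean, abs=tol), p.id

    def test_n_iter_validation(self, scotland):
        with pytest.raises(ValueError):
            run_psa(_tiny(scotland, n=5), scotland, n_iter=0, seed=1)


class TestCeac:
    def _draws(self, data):
        rows = []
        for it, per in enumerate(data):
            for strat, (c, q) in per.items():
                rows.append({"iteration": it, "strategy": strat, "cost": c,
                             "qalys": q, "events": 0.0})
        return PsaDraws(pd.DataFrame(rows), pd.DataFrame(), 0)

    def test_single_strategy_probability_one_everywhere(self):
        draws = self._draws([{"A": (100.0, 1.0)}, {"A": (50.0, 2.0)}])
        curve = ceac(draws, [0.0, 1e4, 1e5])
        assert (curve["A"] == 1.0).all()

    def test_zero_wtp_picks_cost_minimiser(self):
        draws = self._draws([{"A": (100.0, 10.0), "B": (50.0, 1.0)}] * 3)
        curve = ceac(draws, [0.0])
        assert curve["B"].iloc[0] == 1.0 and curve["A"].iloc[0] == 0.0

    def test_dominant_strategy_wins_at_every_wtp(self):
        draws = self._draws([{"A": (50.0, 10.0), "B": (100.0, 5.0)}] * 4)
        curve = ceac(draws, [0.0, 5000.0, 1e5])
        assert (curve["A"] == 1.0).all()

    def test_probabilities_sum_to_one_with_ties_split(self):
        draws = self._draws([{"A": (100.0, 5.0), "B": (100.0, 5.0), "C": (200.0, 1.0)}] * 2)
        curve = ceac(draws, np.linspace(0, 5e4, 7))
        sums = curve.drop(columns="wtp").sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert np.allclose(curve["A"], curve["B"])  # tied strategies share

    def test_psa_ceac_probabilities_sum_to_one(self, scotland):
        coh = _tiny(scotland, n=40)
        draws = run_psa(coh, scotland, n_iter=5, seed=2)
        curve = ceac(draws, np.linspace(0, 4e4, 9))
        assert np.allclose(curve.drop(columns="wtp").sum(axis=1), 1.0)


class TestTornado:
    def test_endpoint_swap_symmetry_and_zero_width_sorted_last(self, scotland):
        coh = _tiny(scotland, n=50)
        bounds = {"drug_cost[Statins]": (8.99, 23.99)}
        rows = tornado(coh, scotland, strategy="Statins")
        ids = [r.parameter for r in rows]
        assert "drug_cost[Statins]" in ids
        swapped = tornado(coh, scotland,
                          bounds={pid: ((b := dict((r.parameter, (r.low, r.high))
                                                   for r in rows))[pid][1], b[pid][0])
                                  for pid in ids},
                          strategy="Statins")
        by_id = {r.parameter: r for r in rows}
        for r in swapped:
            orig = by_id[r.parameter]
            assert r.icer_at_low == pytest.approx(orig.icer_at_high, rel=1e-9)
            assert r.icer_at_high == pytest.approx(orig.icer_at_low, rel=1e-9)
            assert r.range == pytest.approx(orig.range, rel=1e-9)
        # ranges sorted descending
        ranges = [r.range for r in rows if not np.isnan(r.range)]
        assert ranges == sorted(ranges, reverse=True)

    def test_drug_cost_upward_strictly_increases_icer(self, scotland):
        coh = _tiny(scotland, n=50)
        rows = {r.parameter: r for r in tornado(coh, scotland, strategy="Statins")}
        r = rows["drug_cost[Statins]"]
        assert r.icer_at_high > r.icer_at_low

    def test_zero_width_bounds_give_zero_range_sorted_last(self, scotland):
        coh = _tiny(scotland, n=40)
        rows = tornado(coh, scotland, strategy="Statins",
                       bounds={"drug_cost[Statins]": (13.44, 13.44)})
        by_id = {r.parameter: r for r in rows}
        assert by_id["drug_cost[Statins]"].range == pytest.approx(0.0, abs=1e-9)
        finite = [r for r in rows if not np.isnan(r.range)]
        assert finite[-1].range <= finite[0].range
        assert by_id["drug_cost[Statins]"] in finite[-2:]

    def test_discount_rate_included(self, scotland):
        coh = _tiny(scotland, n=40)
        rows = {r.parameter: r for r in tornado(coh, scotland, strategy="Berberine")}
        assert "discount_rate" in rows


class TestApplyDraw:
    def test_draw_substitutes_point_values(self, scotland):
        draw = {"drug_cost[Statins]": 20.0, "rr_nonfatal_chd": 0.8,
                "diabetes_annual": 400.0, "discount_rate": 0.02}
        p = apply_draw(scotland, draw)
        assert p.intervention("Statins").drug_cost.mean == 20.0
        assert p.rr_per_mmol.nonfatal_chd.mean == 0.8
        assert p.cost_model.diabetes_annual == 400.0
        assert p.discount_rate == 0.02
        # untouched fields keep their base case
        assert p.intervention("Berberine").drug_cost == \
            scotland.intervention("Berberine").drug_cost
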