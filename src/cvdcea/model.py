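"""Model / Results objects tying the pipeline together.

:class:`CvdPolicyModel` is built from a cohort table plus a validated
parameter set; ``fit()`` runs the lifetime microsimulation for every strategy
and returns a :class:`CeaResults` carrying the incremental table, per-
individual outcomes, and reporting helpers.  Probabilistic and deterministic
sensitivity analyses hang off the model as ``run_psa()`` and ``tornado()``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import cea as _cea
from .assign import assign_scores
from .cohort import Cohort, generate_cohort
from .hazards import run_cohort
from .interventions import HazardModifiers, build_cohort_modifiers, strategy_catalog
from .outcomes import accumulate_cohort
from .params import ParameterSet, load_parameters, bundled_config_path
from .uncertainty import PsaDraws, ceac as _ceac, psa_increments, run_psa, tornado

__all__ = ["CvdPolicyModel", "CeaResults", "PsaResults"]


class CvdPolicyModel:
    """Lifetime cost-effectiveness model for a cohort of risk profiles.

    Parameters
    ----------
    cohort : :class:`cvdcea.cohort.Cohort` or DataFrame with the documented
        risk-profile columns.
    params : validated :class:`cvdcea.params.ParameterSet`.
    """

    def __init__(self, cohort, params: ParameterSet):
        self.table = (cohort.table if isinstance(cohort, Cohort) else cohort).reset_index(drop=True)
        if len(self.table) == 0:
            raise ValueError("empty cohort")
        self.params = params
        self._scores = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_config(cls, config_path=None, region: str = "scotland",
                    cohort=None, n: int = 3869, seed: int = 0) -> "CvdPolicyModel":
        """Build from a YAML config; generates a synthetic cohort if none given."""
        params = load_parameters(config_path or bundled_config_path(region))
        if cohort is None:
            cohort = generate_cohort(n, params.generator, seed)
        return cls(cohort, params)

    # -- risk scoring -------------------------------------------------------

    @property
    def scores(self) -> pd.DataFrame:
        if self._scores is None:
            self._scores = assign_scores(self.table, self.params.assign)
        return self._scores

    def eligible(self, threshold: float | None = None) -> pd.Series:
        thr = self.params.risk_threshold if threshold is None else threshold
        return self.scores["risk_10yr"] >= thr

    def eligible_fractions(self) -> dict[str, float]:
        r = self.scores["risk_10yr"]
        return {"ge_20pct": float((r >= 20).mean()), "ge_10pct": float((r >= 10).mean())}

    # -- fitting ------------------------------------------------------------

    def fit(self, reference: str = "No intervention", threshold: float | None = None,
            horizon: int | None = None) -> "CeaResults":
        """Run every strategy and difference against ``reference``."""
        params = self.params
        thr = params.risk_threshold if threshold is None else threshold
        mask = self.eligible(thr)
        treated_idx = self.table.index[mask]

        base_trace = run_cohort(self.table, params, None, horizon)
        base_out = accumulate_cohort(base_trace, self.table, HazardModifiers.identity(),
                                     params.utility_model, params.cost_model,
                                     params.discount_rate)

        per_strategy: dict[str, pd.DataFrame] = {}
        number_treated: dict[str, int] = {}
        for name, spec in strategy_catalog(params):
            if not spec.active:
                per_strategy[name] = base_out
                number_treated[name] = 0
                continue
            number_treated[name] = int(len(treated_idx))
            out = base_out.copy()
            if len(treated_idx):
                sub = self.table.loc[treated_idx]
                mods = build_cohort_modifiers(sub, spec, params.rr_per_mmol,
                                              params.cost_model.diabetes_annual,
                                              params.options.get("apply_hdl_shift", True))
                trace = run_cohort(sub, params, mods, horizon)
                sub_out = accumulate_cohort(trace, sub, mods, params.utility_model,
                                            params.cost_model, params.discount_rate)
                out.loc[treated_idx] = sub_out
            per_strategy[name] = out

        results = _cea.incremental_table(
            per_strategy, reference, number_treated, sample_size=len(self.table),
            include_fatal_events=params.options.get("events_include_fatal", True),
        )
        return CeaResults(
            model=self, reference=reference, threshold=thr,
            strategy_results=results, per_individual=per_strategy,
            number_treated=number_treated, treated_index=treated_idx,
        )

    # -- uncertainty --------------------------------------------------------

    def run_psa(self, n_iter: int = 1000, seed: int = 1,
                threshold: float | None = None, horizon: int | None = None) -> "PsaResults":
        params = self.params
        thr = params.risk_threshold if threshold is None else threshold
        treated_idx = self.table.index[self.eligible(thr)]
        draws = run_psa(self.table, params, n_iter, seed,
                        treated_idx=treated_idx, horizon=horizon)
        return PsaResults(draws=draws, model=self, threshold=thr)

    def tornado(self, strategy: str | None = None, reference: str = "No intervention",
                bounds=None, horizon: int | None = None) -> pd.DataFrame:
        rows = tornado(self.table, self.params, bounds=bounds, strategy=strategy,
                       reference=reference, horizon=horizon)
        return pd.DataFrame([
            {"parameter": r.parameter, "low": r.low, "high": r.high,
             "icer_at_low": r.icer_at_low, "icer_at_high": r.icer_at_high,
             "range": r.range}
            for r in rows
        ])


@dataclass
class CeaResults:
    """Fitted incremental cost-effectiveness results."""

    model: CvdPolicyModel
    reference: str
    threshold: float
    strategy_results: list
    per_individual: Mapping[str, pd.DataFrame]
    number_treated: Mapping[str, int]
    treated_index: pd.Index

    @property
    def table(self) -> pd.DataFrame:
        """Report-shaped table (counts and money at 1 d.p.)."""
        return _cea.results_frame(self.strategy_results)

    def ce_plane(self, wtp: float | None = None) -> pd.DataFrame:
        wtp = self.model.params.wtp_threshold if wtp is None else wtp
        return _cea.ce_plane(self.strategy_results, wtp)

    def summary(self) -> str:
        buf = io.StringIO()
        p = self.model.params
        n = len(self.model.table)
        buf.write("Cost-effectiveness of primary CVD prevention strategies\n")
        buf.write("=" * 72 + "\n")
        buf.write(f"Cohort size:        {n}\n")
        buf.write(f"Eligibility:        10-year risk >= {self.threshold:g}% "
                  f"({len(self.treated_index)} treated)\n")
        buf.write(f"Reference strategy: {self.reference}\n")
        buf.write(f"Price region:       {p.price_region}   "
                  f"discount {100 * p.discount_rate:.1f}%/yr   "
                  f"WTP {p.wtp_threshold:,.0f}/QALY\n")
        if p.provenance == "placeholder":
            buf.write("NOTE: placeholder regression coefficients — absolute "
                      "levels are illustrative.\n")
        buf.write("-" * 72 + "\n")
        buf.write(self.table.to_string(index=False))
        buf.write("\n")
        return buf.getvalue()

    def plot_ce_plane(self, path=None, wtp: float | None = None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        wtp = self.model.params.wtp_threshold if wtp is None else wtp
        plane = self.ce_plane(wtp)
        fig, ax = plt.subplots(figsize=(6, 5))
        for _, row in plane.iterrows():
            ax.scatter(row["delta_qalys"], row["delta_cost"], label=row["strategy"])
        lim = max(1.0, plane["delta_qalys"].abs().max() * 1.2)
        xs = np.linspace(-lim, lim, 50)
        ax.plot(xs, wtp * xs, "b--", lw=1, label=f"{wtp:,.0f}/QALY")
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel(f"Incremental QALYs vs {self.reference}")
        ax.set_ylabel("Incremental cost (GBP)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


@dataclass
class PsaResults:
    """Probabilistic sensitivity analysis output."""

    draws: PsaDraws
    model: CvdPolicyModel
    threshold: float

    def increments(self, reference: str = "No intervention") -> pd.DataFrame:
        return psa_increments(self.draws, reference)

    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        if wtp_grid is None:
            wtp_grid = np.arange(0.0, 50001.0, 1000.0)
        return _ceac(self.draws, wtp_grid)

    def summary_table(self, reference: str = "No intervention") -> pd.DataFrame:
        """Mean and 2.5/97.5 percentile intervals of the PSA increments."""
        inc = self.increments(reference)
        rows = []
        for strat, g in inc.groupby("strategy", sort=False):
            row = {"strategy": strat, "reference": reference}
            for col in ("delta_cost", "delta_qalys", "events_prevented"):
                row[f"{col}_mean"] = g[col].mean()
                row[f"{col}_lo"] = g[col].quantile(0.025)
                row[f"{col}_hi"] = g[col].quantile(0.975)
            rows.append(row)
        return pd.DataFrame(rows)

    def plot_ceac(self, path=None, wtp_grid=None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        curve = self.ceac(wtp_grid)
        fig, ax = plt.subplots(figsize=(6, 4))
        for col in curve.columns:
            if col == "wtp":
                continue
            ax.plot(curve["wtp"], curve[col], label=col)
        ax.axvline(self.model.params.wtp_threshold, color="b", ls="--", lw=1)
        ax.set_xlabel("Willingness to pay (GBP/QALY)")
        ax.set_ylabel("P(optimal strategy)")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
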