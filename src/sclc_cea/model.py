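"""Model/Results surface tying the survival, cohort, valuation and CEA layers.

:class:`CostEffectivenessModel` is constructed from a :class:`ModelConfig`
(the published parameter table plus regimen defaults); ``fit()`` runs the
partitioned-survival cohort model for the three strategies and returns a
:class:`CEResults` carrying totals, the incremental table, the efficiency
frontier and per-strategy diagnostics, with sensitivity analyses hanging off
the results object.

>>> from sclc_cea import CostEffectivenessModel
>>> res = CostEffectivenessModel.default().fit()
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .cea import CEOutcome
from .cohort import build_trace
from .config import ModelConfig, default_config, load_config
from .valuation import value_strategy

__all__ = ["CostEffectivenessModel", "CEResults"]

#: pairwise comparisons reported in the incremental table
COMPARISONS = (("DEP", "AEP"), ("AEP", "EP"), ("DEP", "EP"))


class CostEffectivenessModel:
    """Three-strategy cost-effectiveness model for first-line ES-SCLC care."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.settings = config.build_settings()
        self.curves = config.build_curves()
        self.strategies = config.build_strategies()
        self.care_costs = config.build_care_costs()
        self.utilities = config.build_utilities()

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "CostEffectivenessModel":
        return cls(load_config(path))

    @classmethod
    def default(cls) -> "CostEffectivenessModel":
        return cls(default_config())

    # -- fitting ------------------------------------------------------------
    def build_traces(self) -> dict:
        return {arm: build_trace(c["pfs"], c["os"], self.settings)
                for arm, c in self.curves.items()}

    def fit(self, itemised: bool = True) -> "CEResults":
        """Run the cohort model and value every strategy."""
        traces = self.build_traces()
        values = {
            arm: value_strategy(traces[arm], self.strategies[arm],
                                self.care_costs, self.utilities, self.settings,
                                itemised=itemised)
            for arm in traces
        }
        return CEResults(self, traces, values)


class CEResults:
    """Fitted base case: totals, increments, dominance and diagnostics."""

    def __init__(self, model: CostEffectivenessModel, traces: dict, values: dict):
        self.model = model
        self.traces = traces
        self.values = values
        comparisons = [c for c in COMPARISONS
                       if c[0] in values and c[1] in values]
        self.outcome = CEOutcome(list(values.values()), comparisons)

    # -- accessors ----------------------------------------------------------
    def cost(self, arm: str) -> float:
        return self.values[arm].cost

    def qaly(self, arm: str) -> float:
        return self.values[arm].qaly

    @property
    def totals(self) -> pd.DataFrame:
        frame = self.outcome.totals.copy()
        frame["life_years"] = [self.values[a].life_years for a in frame["strategy"]]
        return frame

    @property
    def incremental(self) -> pd.DataFrame:
        return self.outcome.incremental

    def icer(self, intervention: str, comparator: str):
        return self.outcome.comparison(intervention, comparator)

    def frontier(self) -> pd.DataFrame:
        return self.outcome.frontier()

    def nmb(self, wtp: Optional[float] = None) -> pd.Series:
        if wtp is None:
            wtp = self.model.settings.wtp_per_qaly
        return self.outcome.nmb(wtp)

    def cost_ledger(self, arm: str) -> pd.DataFrame:
        """Itemised per-cycle cost ledger (category totals sum to the total)."""
        ledger = self.values[arm].ledger
        if ledger is None:
            raise ValueError("model was fitted with itemised=False")
        return ledger

    # -- sensitivity entry points (delegate to the sensitivity module) ------
    def run_psa(self, n_draws: Optional[int] = None, seed: Optional[int] = None):
        from . import sensitivity
        cfg = self.model.config
        return sensitivity.run_psa(
            cfg,
            n_draws=n_draws if n_draws is not None else cfg.psa.n_draws,
            seed=seed if seed is not None else cfg.psa.seed,
        )

    def run_dsa(self, comparison=("AEP", "EP")):
        from . import sensitivity
        return sensitivity.one_way_dsa(self.model.config, comparison)

    def price_threshold(self, drug: str, comparison, wtp: Optional[float] = None,
                        tolerance: float = 500.0) -> float:
        from . import sensitivity
        if wtp is None:
            wtp = self.model.settings.wtp_per_qaly
        return sensitivity.price_threshold(self.model.config, drug, comparison,
                                           wtp, tolerance)

    def scenario_until_progression(self) -> "CEResults":
        from . import sensitivity
        return sensitivity.scenario_until_progression(self.model.config)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        wtp = self.model.settings.wtp_per_qaly
        lines = ["Cost-effectiveness results (discounted, "
                 f"{self.model.settings.horizon_years:.0f}-year horizon)",
                 "=" * 66,
                 f"{'strategy':<10}{'cost ($)':>14}{'QALY':>10}{'life-years':>12}"
                 f"{'NMB ($)':>16}"]
        nmb = self.nmb(wtp)
        for _, row in self.totals.iterrows():
            lines.append(f"{row['strategy']:<10}{row['cost']:>14,.0f}"
                         f"{row['qaly']:>10.3f}{row['life_years']:>12.3f}"
                         f"{nmb[row['strategy']]:>16,.0f}")
        lines += ["-" * 66,
                  f"{'comparison':<14}{'Δcost ($)':>14}{'ΔQALY':>10}"
                  f"{'ICER ($/QALY)':>20}"]
        for _, row in self.incremental.iterrows():
            label = f"{row['intervention']} vs {row['comparator']}"
            icer_txt = (f"{row['icer']:,.0f}" if row["status"] == "icer"
                        else row["status"])
            lines.append(f"{label:<14}{row['delta_cost']:>14,.0f}"
                         f"{row['delta_qaly']:>10.3f}{icer_txt:>20}")
        lines.append("=" * 66)
        lines.append(f"willingness-to-pay: ${wtp:,.0f}/QALY")
        return "\n".join(lines)

    def __repr__(self):
        totals = ", ".join(f"{a}: ${v.cost:,.0f}/{v.qaly:.3f} QALY"
                           for a, v in self.values.items())
        return f"<CEResults {totals}>"
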