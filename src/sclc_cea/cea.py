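"""Incremental cost-effectiveness: ICERs, dominance and the efficiency frontier."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ICERResult", "icer", "frontier", "net_monetary_benefit", "CEOutcome"]


@dataclass(frozen=True)
class ICERResult:
    """Pairwise comparison of an intervention against a comparator.

    ``status`` is one of ``icer`` (positive QALY gain at positive cost),
    ``dominant`` (at least as effective, no dearer, not identical),
    ``dominated`` (no QALY gain at extra cost) or ``indifferent`` (identical).
    ``value`` is Δcost/ΔQALY and only meaningful when status == "icer".
    """

    delta_cost: float
    delta_qaly: float
    status: str
    value: float = math.nan

    def __str__(self):
        if self.status == "icer":
            return f"{self.value:,.0f}/QALY"
        return self.status


def icer(intervention, comparator) -> ICERResult:
    """Classify the (cost, qaly) pair of an intervention against a comparator.

    Sign conventions: Δ = intervention − comparator.  ΔQALY>0 with ΔC>0 gives
    an ICER; ΔQALY≥0 with ΔC≤0 (not both zero) is dominance of the
    intervention; ΔQALY<0 with ΔC>0 — or no QALY gain at extra cost — is
    dominance of the comparator; both deltas zero is indifference.  ΔQALY<0
    with ΔC<0 is reported as the comparator's ICER case seen from the other
    side (an ICER of savings per QALY forgone).
    """
    dc = float(intervention[0]) - float(comparator[0])
    dq = float(intervention[1]) - float(comparator[1])
    if not (math.isfinite(dc) and math.isfinite(dq)):
        raise ValueError("costs and QALYs must be finite")
    if dc == 0 and dq == 0:
        return ICERResult(dc, dq, "indifferent")
    if dq >= 0 and dc <= 0:
        return ICERResult(dc, dq, "dominant")
    if dq <= 0 and dc >= 0:
        return ICERResult(dc, dq, "dominated")
    # dq and dc share sign and are non-zero: a genuine trade-off
    return ICERResult(dc, dq, "icer", dc / dq)


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = WTP * QALY - cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * qaly - cost


def frontier(strategies: Sequence[tuple]) -> pd.DataFrame:
    """Cost-effectiveness frontier of ``(name, cost, qaly)`` triples.

    Sorts by cost, removes strictly dominated strategies, then removes
    extendedly dominated ones (non-monotone sequential ICERs).  Returns the
    efficient strategies in cost order with the ICER of each against its
    predecessor on the frontier (NaN for the cheapest).  Strategies tied on
    both cost and QALY are kept.
    """
    if not strategies:
        raise ValueError("need at least one strategy")
    frame = pd.DataFrame(list(strategies), columns=["strategy", "cost", "qaly"])
    frame = frame.sort_values(["cost", "qaly"], ascending=[True, False],
                              kind="mergesort").reset_index(drop=True)
    # strict dominance: anything with qaly <= a cheaper strategy's qaly
    keep, best_q = [], -np.inf
    for row in frame.itertuples():
        if row.qaly > best_q or (row.qaly == best_q and row.cost == keep_cost):
            keep.append(row.Index)
            best_q, keep_cost = row.qaly, row.cost
    frame = frame.loc[keep].reset_index(drop=True)
    # extended dominance: drop points until sequential ICERs are non-decreasing
    changed = True
    while changed and len(frame) > 2:
        changed = False
        ratios = np.diff(frame["cost"]) / np.diff(frame["qaly"])
        for i in range(len(ratios) - 1):
            if ratios[i] > ratios[i + 1]:  # middle point extendedly dominated
                frame = frame.drop(index=frame.index[i + 1]).reset_index(drop=True)
                changed = True
                break
    dq = np.diff(frame["qaly"])
    icers = np.full(len(frame), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        icers[1:] = np.where(dq > 0, np.diff(frame["cost"]) / dq, np.nan)
    frame["icer_vs_previous"] = icers
    return frame


class CEOutcome:
    """Totals and pairwise incremental analysis for a set of strategies."""

    def __init__(self, values, comparisons: Optional[Sequence[tuple]] = None):
        """``values``: sequence of objects with .name/.cost/.qaly (StrategyValue).

        ``comparisons``: pairs of strategy names to report incrementally; by
        default every strategy against every cheaper-listed predecessor.
        """
        self.values = {v.name: v for v in values}
        if comparisons is None:
            names = list(self.values)
            comparisons = [(b, a) for i, a in enumerate(names)
                           for b in names[i + 1:]]
        self.comparisons = list(comparisons)

    def total(self, name: str) -> tuple:
        v = self.values[name]
        return (v.cost, v.qaly)

    def comparison(self, intervention: str, comparator: str) -> ICERResult:
        return icer(self.total(intervention), self.total(comparator))

    @property
    def totals(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.name, v.cost, v.qaly) for v in self.values.values()],
            columns=["strategy", "cost", "qaly"],
        )

    @property
    def incremental(self) -> pd.DataFrame:
        rows = []
        for b, a in self.comparisons:
            res = self.comparison(b, a)
            rows.append((b, a, res.delta_cost, res.delta_qaly, res.status, res.value))
        return pd.DataFrame(rows, columns=[
            "intervention", "comparator", "delta_cost", "delta_qaly",
            "status", "icer"])

    def frontier(self) -> pd.DataFrame:
        return frontier([(v.name, v.cost, v.qaly) for v in self.values.values()])

    def nmb(self, wtp: float) -> pd.Series:
        return pd.Series({name: net_monetary_benefit(v.cost, v.qaly, wtp)
                          for name, v in self.values.items()})
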