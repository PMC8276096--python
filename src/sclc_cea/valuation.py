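"""Costing and utility valuation of a cohort trace for one treatment strategy.

Cost categories follow the payer-perspective ledger of the analysis: first-line
drug acquisition and intravenous administration, one-time first-line
adverse-event (AE) management, routine follow-up (monthly physician visit,
three-monthly imaging), second-line topotecan (drug, administration, one-time
AE cost for the treated fraction of progressors), supportive care for
progressed patients not on topotecan, and a one-time death-associated cost.

Doses are computed for a reference patient (body surface area 1.8 m^2,
creatinine clearance 70 ml/min) with linear per-mg pricing and no vial
rounding; carboplatin uses the Calvert formula ``dose = AUC * (CrCl + 25)``.

QALYs weight state person-time by the PFS/PS utilities, with the treatment
AE disutility subtracted from the PFS utility during active first-line
treatment cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_MONTH, CohortTrace, ModelSettings

__all__ = [
    "FlatDose", "PerBSADose", "CalvertDose", "RegimenLine", "StrategySpec",
    "CareCosts", "Utilities", "drug_cost_per_cycle", "administration_cost",
    "accrue_costs", "accrue_qalys", "StrategyValue", "value_strategy",
]


# --------------------------------------------------------------------------
# dose rules
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class FlatDose:
    mg: float

    def mg_per_cycle(self, settings: ModelSettings) -> float:
        return self.mg


@dataclass(frozen=True)
class PerBSADose:
    mg_per_m2: float
    days_per_cycle: int = 1

    def mg_per_cycle(self, settings: ModelSettings) -> float:
        return self.mg_per_m2 * settings.body_surface_area * self.days_per_cycle


@dataclass(frozen=True)
class CalvertDose:
    """Carboplatin dosing: mg = AUC * (creatinine clearance + 25)."""

    auc: float

    def mg_per_cycle(self, settings: ModelSettings) -> float:
        return self.auc * (settings.creatinine_clearance + 25.0)


@dataclass(frozen=True)
class RegimenLine:
    """One drug in a regimen: a dose rule plus a per-mg acquisition price."""

    drug: str
    dose: object
    price_per_mg: float
    infusions_per_cycle: int = 1

    def __post_init__(self):
        if self.price_per_mg < 0:
            raise ValueError("price must be non-negative")
        if not hasattr(self.dose, "mg_per_cycle"):
            raise ValueError(f"unknown dose rule {self.dose!r}")


@dataclass(frozen=True)
class CareCosts:
    """Non-drug unit costs (USD), defaults from the 2020 US payer estimates."""

    admin_first_hour: float = 142.55
    admin_additional_hour: float = 30.68
    monthly_physician_visit: float = 148.33
    three_monthly_imaging: float = 122.71
    monthly_supportive_care: float = 637.00
    death_cost: float = 9_433.00

    def __post_init__(self):
        if any(getattr(self, f) < 0 for f in self.__dataclass_fields__):
            raise ValueError("care costs must be non-negative")


@dataclass(frozen=True)
class Utilities:
    u_pfs: float = 0.673
    u_ps: float = 0.473

    def __post_init__(self):
        if not (0 <= self.u_pfs <= 1 and 0 <= self.u_ps <= 1):
            raise ValueError("utilities must lie in [0, 1]")


@dataclass(frozen=True)
class StrategySpec:
    """A first-line treatment arm plus its downstream care pathway."""

    name: str
    chemo: Sequence[RegimenLine] = ()
    chemo_cycles: int = 4
    ici: Optional[RegimenLine] = None
    ici_cycles: int = 7
    ici_until_progression: bool = False
    induction_infusion_hours: int = 3
    maintenance_infusion_hours: int = 1
    ae_cost_first_line: float = 0.0
    ae_disutility: float = 0.0
    disutility_cycles: Optional[int] = None  # default: first-line duration at median cycles
    subsequent_therapy_proportion: float = 0.0
    subsequent: Optional[RegimenLine] = None
    topotecan_max_cycles: int = 4
    ae_cost_second_line: float = 0.0

    def __post_init__(self):
        if not 0 <= self.subsequent_therapy_proportion <= 1:
            raise ValueError("subsequent therapy proportion must lie in [0, 1]")
        if min(self.ae_cost_first_line, self.ae_cost_second_line) < 0:
            raise ValueError("AE costs must be non-negative")

    @property
    def first_line_cycles(self) -> int:
        """Planned first-line duration at the median cycle counts."""
        return max(self.chemo_cycles, self.ici_cycles if self.ici else 0)

    def with_until_progression(self) -> "StrategySpec":
        """Scenario variant: first-line ICI continues until progression."""
        if self.ici is None:
            return self
        return replace(self, ici_until_progression=True,
                       disutility_cycles=self.disutility_cycles
                       if self.disutility_cycles is not None
                       else self.first_line_cycles)


# --------------------------------------------------------------------------
# unit-cost building blocks
# --------------------------------------------------------------------------
def drug_cost_per_cycle(line: RegimenLine, settings: ModelSettings) -> float:
    """mg per cycle from the dose rule times the per-mg price."""
    return line.dose.mg_per_cycle(settings) * line.price_per_mg


def administration_cost(infusion_hours: int, costs: CareCosts) -> float:
    """IV administration fee: first hour plus each additional hour."""
    if infusion_hours < 0:
        raise ValueError("infusion hours must be non-negative")
    if infusion_hours == 0:
        return 0.0
    return costs.admin_first_hour + (infusion_hours - 1) * costs.admin_additional_hour


# --------------------------------------------------------------------------
# per-cycle schedules
# --------------------------------------------------------------------------
def _first_line_schedules(trace: CohortTrace, strategy: StrategySpec,
                          costs: CareCosts, settings: ModelSettings):
    """Per-cycle (1..n) first-line drug and administration unit costs."""
    n = trace.n_cycles
    k = np.arange(1, n + 1)
    chemo_active = k <= strategy.chemo_cycles if strategy.chemo else np.zeros(n, bool)
    if strategy.ici is not None:
        ici_active = (np.ones(n, bool) if strategy.ici_until_progression
                      else k <= strategy.ici_cycles)
    else:
        ici_active = np.zeros(n, bool)

    chemo_cost = sum(drug_cost_per_cycle(l, settings) for l in strategy.chemo)
    ici_cost = drug_cost_per_cycle(strategy.ici, settings) if strategy.ici else 0.0
    drug = chemo_active * chemo_cost + ici_active * ici_cost

    admin = np.where(
        chemo_active, administration_cost(strategy.induction_infusion_hours, costs),
        np.where(ici_active,
                 administration_cost(strategy.maintenance_infusion_hours, costs), 0.0),
    )
    return drug, admin


def _progression_entrants(trace: CohortTrace) -> np.ndarray:
    """New progressors per cycle 1..n, read off the PFS curve decrements."""
    return np.maximum(0.0, -np.diff(trace.pfs))


def _topotecan_occupancy(trace: CohortTrace, cap: int) -> np.ndarray:
    """Occupancy eligible for topotecan at each cycle 1..n.

    Each progression cohort is treated for up to ``cap`` cycles after entry;
    the running sum of the last ``cap`` entrant cohorts is limited by the
    progressed-state occupancy actually alive at that cycle.
    """
    entrants = _progression_entrants(trace)
    window = np.convolve(entrants, np.ones(max(cap, 0)))[: len(entrants)]
    return np.minimum(window, trace.ps[1:])


# --------------------------------------------------------------------------
# accrual
# --------------------------------------------------------------------------
def accrue_costs(trace: CohortTrace, strategy: StrategySpec, costs: CareCosts,
                 settings: ModelSettings, itemised: bool = False):
    """Discounted total cost of the strategy over the trace.

    With ``itemised=True`` returns ``(total, ledger)`` where ``ledger`` is a
    per-cycle, per-category DataFrame whose amounts sum to the total.
    """
    n = trace.n_cycles
    df = trace.discount[1:]
    pfs = trace.pfs[1:]
    ps = trace.ps[1:]
    alive = pfs + ps
    months_per_cycle = settings.cycle_months

    drug_unit, admin_unit = _first_line_schedules(trace, strategy, costs, settings)
    ledger = {
        "first_line_drug": drug_unit * pfs * df,
        "first_line_admin": admin_unit * pfs * df,
        "ae_first_line": np.zeros(n),
        "followup": (costs.monthly_physician_visit + costs.three_monthly_imaging / 3.0)
        * months_per_cycle * alive * df,
        "topotecan_drug": np.zeros(n),
        "topotecan_admin": np.zeros(n),
        "ae_second_line": np.zeros(n),
        "supportive_care": np.zeros(n),
        "death": costs.death_cost * trace.new_deaths[1:] * df,
    }
    # one-time first-line AE management cost, incurred in the first cycle
    ledger["ae_first_line"][0] = strategy.ae_cost_first_line * df[0]

    p = strategy.subsequent_therapy_proportion
    topo_occ = _topotecan_occupancy(trace, strategy.topotecan_max_cycles)
    if strategy.subsequent is not None and p > 0:
        topo_drug = drug_cost_per_cycle(strategy.subsequent, settings)
        topo_admin = strategy.subsequent.infusions_per_cycle * administration_cost(
            1, costs)
        entrants = _progression_entrants(trace)
        ledger["topotecan_drug"] = topo_drug * p * topo_occ * df
        ledger["topotecan_admin"] = topo_admin * p * topo_occ * df
        ledger["ae_second_line"] = strategy.ae_cost_second_line * p * entrants * df
        on_topo = p * topo_occ
    else:
        on_topo = np.zeros(n)

    ledger["supportive_care"] = (costs.monthly_supportive_care * months_per_cycle
                                 * np.maximum(ps - on_topo, 0.0) * df)

    total = float(sum(arr.sum() for arr in ledger.values()))
    if not itemised:
        return total
    frames = pd.DataFrame(ledger, index=pd.RangeIndex(1, n + 1, name="cycle"))
    long = frames.stack().rename("amount").reset_index()
    long.columns = ["cycle", "category", "amount"]
    long["strategy"] = strategy.name
    return total, long


def accrue_qalys(trace: CohortTrace, strategy: StrategySpec, utilities: Utilities,
                 settings: ModelSettings) -> float:
    """Discounted QALY total with the AE disutility during first-line cycles."""
    n = trace.n_cycles
    k = np.arange(1, n + 1)
    dis_cycles = (strategy.disutility_cycles if strategy.disutility_cycles is not None
                  else strategy.first_line_cycles)
    # the decrement cannot push the on-treatment utility below zero
    u_on_treatment = max(utilities.u_pfs - strategy.ae_disutility, 0.0)
    u_pfs = np.where(k <= dis_cycles, u_on_treatment, utilities.u_pfs)
    per_cycle = (u_pfs * trace.pfs[1:] + utilities.u_ps * trace.ps[1:])
    return float(np.sum(per_cycle * trace.discount[1:]) * settings.cycle_years)


@dataclass(frozen=True)
class StrategyValue:
    """Valuation of one strategy: discounted totals plus diagnostics."""

    name: str
    cost: float
    qaly: float
    life_years: float
    ledger: pd.DataFrame = field(repr=False, default=None)


def value_strategy(trace: CohortTrace, strategy: StrategySpec, costs: CareCosts,
                   utilities: Utilities, settings: ModelSettings,
                   itemised: bool = False) -> StrategyValue:
    """Cost and QALY totals for one strategy over its trace."""
    from .cohort import person_time

    if itemised:
        total, ledger = accrue_costs(trace, strategy, costs, settings, itemised=True)
    else:
        total, ledger = accrue_costs(trace, strategy, costs, settings), None
    return StrategyValue(
        name=strategy.name,
        cost=total,
        qaly=accrue_qalys(trace, strategy, utilities, settings),
        life_years=person_time(trace, "alive", discounted=False),
        ledger=ledger,
    )
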