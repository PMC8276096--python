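"""Structured model configuration: schema, loading, and domain-object builders.

The configuration mirrors the published parameter table of the analysis —
survival distribution parameters, hazard ratios, per-mg drug prices, cost
aggregates, utilities, disutilities and proportions — plus the handful of
regimen details (cycle counts, infusion hours, dosing rules) the model needs
but the main text leaves to standard practice.  Every such gap is an explicit
key, so "reproduce the published table" and "recalibrate" are both auditable
edits of the same file.

Validation is strict (unknown keys rejected, bounds enforced) via pydantic.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import List, Literal, Optional, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import ModelSettings
from .survival import (ExtrapolatedCurve, ExtrapolationPolicy,
                       HazardAdjustedSurvival, ParametricSurvival)
from .valuation import (CalvertDose, CareCosts, FlatDose, PerBSADose,
                        RegimenLine, StrategySpec, Utilities)

__all__ = ["ModelConfig", "load_config", "default_config", "load_hazard_table"]

ARMS = ("EP", "AEP", "DEP")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SurvivalCurveCfg(_Strict):
    family: Literal["weibull", "loglogistic", "exponential", "lognormal", "gompertz"]
    params: List[float]

    def build(self) -> ParametricSurvival:
        return ParametricSurvival(self.family, tuple(self.params))


class ArmSurvivalCfg(_Strict):
    os: SurvivalCurveCfg
    pfs: SurvivalCurveCfg


class HRCfg(_Strict):
    """Indirect-comparison hazard ratios of the durvalumab arm vs the
    atezolizumab arm (S_DEP = S_AEP ** HR)."""

    os: float = Field(gt=0)
    pfs: float = Field(gt=0)


class ExtrapolationCfg(_Strict):
    cutoff_months: float = Field(24.0, ge=0)
    os_mode: Literal["parametric_continuation", "external_hazard_table"] = (
        "parametric_continuation")
    pfs_mode: Literal["parametric_continuation"] = "parametric_continuation"
    hazard_table: Optional[List[Tuple[float, float]]] = None
    hazard_table_csv: Optional[str] = None

    def os_policy(self) -> ExtrapolationPolicy:
        table = self.hazard_table
        if table is None and self.hazard_table_csv:
            table = load_hazard_table(self.hazard_table_csv)
        return ExtrapolationPolicy(self.cutoff_months, self.os_mode, table)

    def pfs_policy(self) -> ExtrapolationPolicy:
        return ExtrapolationPolicy(self.cutoff_months, "parametric_continuation")


class SettingsCfg(_Strict):
    cycle_days: float = Field(21.0, gt=0)
    horizon_years: float = Field(10.0, gt=0)
    annual_discount_rate: float = Field(0.03, ge=0)
    wtp_per_qaly: float = Field(100_000.0, ge=0)
    body_surface_area: float = Field(1.8, gt=0)
    creatinine_clearance: float = Field(70.0, gt=0)
    half_cycle_correction: bool = False

    def build(self) -> ModelSettings:
        return ModelSettings(**self.model_dump())


class PricesCfg(_Strict):
    """Per-mg drug acquisition prices (USD)."""

    atezolizumab: float = Field(ge=0)
    durvalumab: float = Field(ge=0)
    etoposide: float = Field(ge=0)
    carboplatin: float = Field(ge=0)
    topotecan: float = Field(ge=0)


class CareCostsCfg(_Strict):
    admin_first_hour: float = Field(ge=0)
    admin_additional_hour: float = Field(ge=0)
    monthly_physician_visit: float = Field(ge=0)
    three_monthly_imaging: float = Field(ge=0)
    monthly_supportive_care: float = Field(ge=0)
    death_cost: float = Field(ge=0)

    def build(self) -> CareCosts:
        return CareCosts(**self.model_dump())


class AECostsCfg(_Strict):
    """One-time grade III/IV adverse-event management cost aggregates (USD)."""

    aep: float = Field(ge=0)
    dep: float = Field(ge=0)
    ep: float = Field(ge=0)
    topotecan: float = Field(ge=0)


class UtilitiesCfg(_Strict):
    pfs: float = Field(ge=0, le=1)
    ps: float = Field(ge=0, le=1)

    def build(self) -> Utilities:
        return Utilities(self.pfs, self.ps)


class DisutilitiesCfg(_Strict):
    aep: float = Field(ge=0, le=1)
    dep: float = Field(ge=0, le=1)
    ep: float = Field(ge=0, le=1)


class ProportionsCfg(_Strict):
    """Proportion of progressors receiving subsequent topotecan, per arm."""

    aep: float = Field(ge=0, le=1)
    dep: float = Field(ge=0, le=1)
    ep: float = Field(ge=0, le=1)


class TreatmentCfg(_Strict):
    chemo_cycles: int = Field(4, ge=0)
    etoposide_mg_per_m2: float = Field(100.0, gt=0)
    etoposide_days_per_cycle: int = Field(3, ge=1)
    carboplatin_auc: float = Field(5.0, gt=0)
    atezolizumab_mg: float = Field(1200.0, gt=0)
    durvalumab_mg: float = Field(1500.0, gt=0)
    ici_cycles_aep: int = Field(7, ge=0)
    ici_cycles_dep: int = Field(7, ge=0)
    ici_until_progression: bool = False
    chemoimmuno_infusion_hours: int = Field(4, ge=0)
    chemo_infusion_hours: int = Field(3, ge=0)
    maintenance_infusion_hours: int = Field(1, ge=0)
    topotecan_mg_per_m2_per_day: float = Field(1.5, gt=0)
    topotecan_days_per_cycle: int = Field(5, ge=1)
    topotecan_max_cycles: int = Field(4, ge=0)


class SensitivityParamCfg(_Strict):
    """One deterministic/probabilistic sensitivity parameter.

    ``binding`` is a dotted path into this configuration (for example
    ``prices.atezolizumab``); the baseline is read from the bound value.
    """

    name: str
    binding: str
    low: float
    high: float
    distribution: Literal["gamma", "beta", "lognormal", "fixed"]

    @model_validator(mode="after")
    def _ordered(self):
        if self.low > self.high:
            raise ValueError(f"{self.name}: low must not exceed high")
        return self


class PSACfg(_Strict):
    n_draws: int = Field(10_000, ge=1)
    seed: int = Field(20210629, ge=0)


class ModelConfig(_Strict):
    settings: SettingsCfg = SettingsCfg()
    survival: dict[str, ArmSurvivalCfg]
    dep_hr: HRCfg
    extrapolation: ExtrapolationCfg = ExtrapolationCfg()
    prices: PricesCfg
    care_costs: CareCostsCfg
    ae_costs: AECostsCfg
    utilities: UtilitiesCfg
    disutilities: DisutilitiesCfg
    subsequent_proportion: ProportionsCfg
    treatment: TreatmentCfg = TreatmentCfg()
    sensitivity: List[SensitivityParamCfg] = []
    psa: PSACfg = PSACfg()

    @model_validator(mode="after")
    def _check_survival(self):
        if set(self.survival) != {"aep", "ep"}:
            raise ValueError("survival block must define exactly 'aep' and 'ep'")
        for arm in self.survival.values():
            arm.os.build()   # raises on invalid parameters
            arm.pfs.build()
        return self

    # -- domain builders ----------------------------------------------------
    def build_settings(self) -> ModelSettings:
        return self.settings.build()

    def build_curves(self) -> dict:
        """Extrapolation-bound OS and PFS curves for the three arms."""
        os_pol, pfs_pol = self.extrapolation.os_policy(), self.extrapolation.pfs_policy()
        aep_os = self.survival["aep"].os.build()
        aep_pfs = self.survival["aep"].pfs.build()
        ep_os = self.survival["ep"].os.build()
        ep_pfs = self.survival["ep"].pfs.build()
        return {
            "EP": {"os": ExtrapolatedCurve(ep_os, os_pol),
                   "pfs": ExtrapolatedCurve(ep_pfs, pfs_pol)},
            "AEP": {"os": ExtrapolatedCurve(aep_os, os_pol),
                    "pfs": ExtrapolatedCurve(aep_pfs, pfs_pol)},
            "DEP": {"os": ExtrapolatedCurve(
                        HazardAdjustedSurvival(aep_os, self.dep_hr.os), os_pol),
                    "pfs": ExtrapolatedCurve(
                        HazardAdjustedSurvival(aep_pfs, self.dep_hr.pfs), pfs_pol)},
        }

    def build_strategies(self) -> dict:
        t = self.treatment
        chemo = (
            RegimenLine("etoposide",
                        PerBSADose(t.etoposide_mg_per_m2, t.etoposide_days_per_cycle),
                        self.prices.etoposide),
            RegimenLine("carboplatin", CalvertDose(t.carboplatin_auc),
                        self.prices.carboplatin),
        )
        topo = RegimenLine(
            "topotecan",
            PerBSADose(t.topotecan_mg_per_m2_per_day, t.topotecan_days_per_cycle),
            self.prices.topotecan,
            infusions_per_cycle=t.topotecan_days_per_cycle,
        )
        common = dict(chemo=chemo, chemo_cycles=t.chemo_cycles, subsequent=topo,
                      topotecan_max_cycles=t.topotecan_max_cycles,
                      ae_cost_second_line=self.ae_costs.topotecan,
                      maintenance_infusion_hours=t.maintenance_infusion_hours)
        strategies = {
            "EP": StrategySpec(
                name="EP", induction_infusion_hours=t.chemo_infusion_hours,
                ae_cost_first_line=self.ae_costs.ep,
                ae_disutility=self.disutilities.ep,
                subsequent_therapy_proportion=self.subsequent_proportion.ep,
                **common),
            "AEP": StrategySpec(
                name="AEP",
                ici=RegimenLine("atezolizumab", FlatDose(t.atezolizumab_mg),
                                self.prices.atezolizumab),
                ici_cycles=t.ici_cycles_aep,
                ici_until_progression=t.ici_until_progression,
                induction_infusion_hours=t.chemoimmuno_infusion_hours,
                ae_cost_first_line=self.ae_costs.aep,
                ae_disutility=self.disutilities.aep,
                subsequent_therapy_proportion=self.subsequent_proportion.aep,
                **common),
            "DEP": StrategySpec(
                name="DEP",
                ici=RegimenLine("durvalumab", FlatDose(t.durvalumab_mg),
                                self.prices.durvalumab),
                ici_cycles=t.ici_cycles_dep,
                ici_until_progression=t.ici_until_progression,
                induction_infusion_hours=t.chemoimmuno_infusion_hours,
                ae_cost_first_line=self.ae_costs.dep,
                ae_disutility=self.disutilities.dep,
                subsequent_therapy_proportion=self.subsequent_proportion.dep,
                **common),
        }
        return strategies

    def build_care_costs(self) -> CareCosts:
        return self.care_costs.build()

    def build_utilities(self) -> Utilities:
        return self.utilities.build()

    # -- path access (sensitivity bindings) ---------------------------------
    def get_by_path(self, path: str):
        node = self
        for key in path.split("."):
            if isinstance(node, BaseModel):
                if key not in type(node).model_fields:
                    raise KeyError(f"binding path {path!r}: no field {key!r}")
                node = getattr(node, key)
            elif isinstance(node, dict):
                node = node[key]
            else:
                raise KeyError(f"binding path {path!r}: cannot descend into {node!r}")
        return node

    def with_value(self, path: str, value) -> "ModelConfig":
        """A new config with the value at the dotted ``path`` replaced."""
        self.get_by_path(path)  # raise early on bad paths
        data = self.model_dump()
        node = data
        keys = path.split(".")
        for key in keys[:-1]:
            node = node[key]
        node[keys[-1]] = value
        return ModelConfig(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plainify(self.model_dump()), sort_keys=False)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    return obj


def load_hazard_table(path: str) -> list:
    """Read a background-hazard CSV with columns time_months,monthly_hazard."""
    frame = pd.read_csv(path)
    expected = ["time_months", "monthly_hazard"]
    if list(frame.columns) != expected:
        raise ValueError(f"hazard table must have columns {expected}")
    return [tuple(row) for row in frame.itertuples(index=False)]


def load_config(path) -> ModelConfig:
    """Load and schema-validate a YAML model configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ModelConfig(**data)


def default_config() -> ModelConfig:
    """The packaged baseline configuration (published parameter table)."""
    text = resources.files("sclc_cea").joinpath("data/default_config.yaml").read_text()
    return ModelConfig(**yaml.safe_load(text))
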