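"""Deterministic and probabilistic sensitivity analyses.

* one-way (tornado) analysis re-running the model at each parameter's low and
  high value;
* bisection search for the drug price reduction that brings an ICER down to
  the willingness-to-pay threshold;
* probabilistic sensitivity analysis (PSA): joint independent sampling of all
  non-fixed parameters (gamma for costs, beta for utilities and proportions,
  lognormal for hazard ratios — 95% ranges moment-matched), repeated model
  evaluation, and the cost-effectiveness acceptability curve (CEAC);
* the scenario in which first-line immunotherapy continues until progression.

Survival distribution parameters are deliberately not varied: the published
table carries no uncertainty ranges for them, so only the two indirect
hazard ratios move the survival side of the model.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cea import icer as _icer
from .config import ModelConfig, SensitivityParamCfg
from .model import CEResults, CostEffectivenessModel

__all__ = [
    "ParamSpec", "PSAResult", "one_way_dsa", "price_threshold",
    "sample_param", "run_psa", "ceac", "scenario_until_progression",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ParamSpec:
    """A sensitivity parameter resolved against a configuration."""

    name: str
    binding: str
    baseline: float
    low: float
    high: float
    distribution: str

    def __post_init__(self):
        if not self.low <= self.baseline <= self.high:
            raise ValueError(
                f"{self.name}: baseline {self.baseline} outside "
                f"[{self.low}, {self.high}]")
        if self.distribution == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta range must lie in [0, 1]")
        if self.distribution == "lognormal" and self.low <= 0:
            raise ValueError(f"{self.name}: lognormal range must be positive")

    @property
    def se(self) -> float:
        """Standard error implied by reading [low, high] as a 95% interval."""
        return (self.high - self.low) / (2 * _Z95)


def resolve_params(config: ModelConfig) -> list:
    """Bind the config's sensitivity block to baselines read off the config."""
    out = []
    for p in config.sensitivity:
        baseline = float(config.get_by_path(p.binding))
        out.append(ParamSpec(p.name, p.binding, baseline, p.low, p.high,
                             p.distribution))
    return out


def _evaluate(config: ModelConfig) -> CEResults:
    return CostEffectivenessModel(config).fit(itemised=False)


def _pair_icer(results: CEResults, comparison) -> tuple:
    res = results.icer(*comparison)
    return (res.value if res.status == "icer" else math.nan, res.status)


# --------------------------------------------------------------------------
# one-way deterministic sensitivity
# --------------------------------------------------------------------------
def one_way_dsa(config: ModelConfig, comparison=("AEP", "EP"),
                params: Optional[Sequence[ParamSpec]] = None) -> pd.DataFrame:
    """Tornado table: the comparison's ICER at each parameter's low and high.

    Dominance outcomes are encoded as NaN ICERs with the dominance label in
    the status columns, so spreads involving dominance stay qualitative.
    Rows are sorted by spread, widest first (NaN spreads last).
    """
    if params is None:
        params = resolve_params(config)
    rows = []
    for p in params:
        icer_lo, status_lo = _pair_icer(
            _evaluate(config.with_value(p.binding, p.low)), comparison)
        icer_hi, status_hi = _pair_icer(
            _evaluate(config.with_value(p.binding, p.high)), comparison)
        rows.append((p.name, p.low, p.high, icer_lo, icer_hi,
                     status_lo, status_hi, abs(icer_hi - icer_lo)))
    frame = pd.DataFrame(rows, columns=[
        "parameter", "low_value", "high_value", "icer_low", "icer_high",
        "status_low", "status_high", "spread"])
    return frame.sort_values("spread", ascending=False,
                             na_position="last").reset_index(drop=True)


# --------------------------------------------------------------------------
# price-reduction threshold
# --------------------------------------------------------------------------
def price_threshold(config: ModelConfig, drug: str, comparison,
                    wtp: float, tolerance: float = 500.0,
                    max_iter: int = 60) -> float:
    """Price-reduction fraction m at which ICER(comparison) hits the WTP.

    Bisects a multiplier m in [0, 1] applied as price*(1-m) until the
    comparison's ICER is within ``tolerance`` $/QALY of ``wtp``.  Raises if
    the baseline ICER is already below the threshold or no root exists in
    [0, 1] (reduction unattainable).
    """
    binding = f"prices.{drug}"
    base_price = float(config.get_by_path(binding))

    def icer_at(m: float) -> float:
        res = _evaluate(config.with_value(binding, base_price * (1.0 - m)))
        value, status = _pair_icer(res, comparison)
        if status == "dominant":
            return -math.inf  # intervention saves money: below any threshold
        if status == "dominated":
            return math.inf
        return value

    f0 = icer_at(0.0)
    if abs(f0 - wtp) < tolerance:
        return 0.0
    if f0 < wtp:
        raise ValueError(f"baseline ICER {f0:,.0f} is not above WTP {wtp:,.0f}")
    if icer_at(1.0) > wtp:
        raise ValueError("ICER stays above WTP even at a free drug: unattainable")
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = icer_at(mid)
        if abs(val - wtp) < tolerance:
            return mid
        if val > wtp:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("price threshold bisection did not converge")


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------
def sample_param(spec: ParamSpec, rng: np.random.Generator, size=None):
    """Draw from the parameter's distribution, moment-matched to its range.

    gamma: shape = mu^2/sigma^2, scale = sigma^2/mu;
    beta: alpha = mu*nu, beta = (1-mu)*nu with nu = mu(1-mu)/sigma^2 - 1;
    lognormal: median = baseline, sdlog = (ln high - ln low) / (2*1.96);
    fixed: the baseline, always.
    """
    mu, se = spec.baseline, spec.se
    if spec.distribution == "fixed" or se == 0.0:
        return np.full(size, mu) if size is not None else mu
    if spec.distribution == "gamma":
        shape = mu**2 / se**2
        return rng.gamma(shape, se**2 / mu, size=size)
    if spec.distribution == "beta":
        var = se**2
        if var >= mu * (1 - mu):
            raise ValueError(
                f"{spec.name}: beta moment matching infeasible "
                f"(variance {var:.4g} >= mu(1-mu) = {mu * (1 - mu):.4g})")
        nu = mu * (1 - mu) / var - 1
        return rng.beta(mu * nu, (1 - mu) * nu, size=size)
    if spec.distribution == "lognormal":
        sdlog = (math.log(spec.high) - math.log(spec.low)) / (2 * _Z95)
        return rng.lognormal(math.log(mu), sdlog, size=size)
    raise ValueError(f"unknown distribution {spec.distribution!r}")


@dataclass
class PSAResult:
    """Per-draw (cost, QALY) pairs for every strategy."""

    draws: pd.DataFrame  # columns: draw, strategy, cost, qaly
    seed: int
    n_draws: int

    def pivot(self, field: str) -> pd.DataFrame:
        return self.draws.pivot(index="draw", columns="strategy", values=field)

    def prob_cost_effective(self, intervention: str, comparator: str,
                            wtp: float) -> float:
        """Fraction of draws where the intervention's NMB beats the comparator's."""
        cost = self.pivot("cost")
        qaly = self.pivot("qaly")
        nmb = wtp * qaly - cost
        return float(np.mean(nmb[intervention] > nmb[comparator]))

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False, float_format="%.6f")


def run_psa(config: ModelConfig, n_draws: int, seed: int,
            params: Optional[Sequence[ParamSpec]] = None) -> PSAResult:
    """Monte-Carlo PSA: joint independent parameter draws, full re-evaluation.

    Deterministic for a fixed seed: parameters are sampled in the order they
    appear in the config's sensitivity block from one PCG64 stream.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if params is None:
        params = resolve_params(config)
    rng = np.random.default_rng(seed)
    samples = {p.binding: np.asarray(sample_param(p, rng, size=n_draws))
               for p in params}

    base_data = config.model_dump()
    records = []
    for i in range(n_draws):
        data = copy.deepcopy(base_data)
        for p in params:
            node = data
            keys = p.binding.split(".")
            for key in keys[:-1]:
                node = node[key]
            node[keys[-1]] = float(samples[p.binding][i])
        try:
            results = _evaluate(ModelConfig(**data))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        for arm, value in results.values.items():
            records.append((i, arm, value.cost, value.qaly))
    frame = pd.DataFrame(records, columns=["draw", "strategy", "cost", "qaly"])
    return PSAResult(frame, seed=seed, n_draws=n_draws)


def ceac(psa: PSAResult, wtp_grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At each WTP the probability that each strategy has the maximal net
    monetary benefit; exact ties split equally, so rows sum to one.
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0, 300_001, 5_000)
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    cost = psa.pivot("cost").to_numpy()
    qaly = psa.pivot("qaly").to_numpy()
    names = list(psa.pivot("cost").columns)
    rows = []
    for wtp in wtp_grid:
        nmb = wtp * qaly - cost
        best = nmb.max(axis=1, keepdims=True)
        winners = (nmb == best)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        rows.extend((wtp, name, prob) for name, prob in zip(names, probs))
    return pd.DataFrame(rows, columns=["wtp", "strategy", "probability"])


# --------------------------------------------------------------------------
# scenario: first-line ICI until progression
# --------------------------------------------------------------------------
def scenario_until_progression(config: ModelConfig) -> CEResults:
    """Re-run the base case with ICI duration set to until-progression.

    Only the ICI cost accrual window changes (drug plus administration costs
    follow PFS occupancy for all cycles); the QALY side, including the
    disutility window at the median treatment duration, is untouched, as is
    the EP strategy.
    """
    return CostEffectivenessModel(
        config.with_value("treatment.ici_until_progression", True)).fit()
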