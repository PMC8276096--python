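"""Synthetic two-arm trial data with known ground truth.

Emulates the ingredients of a published survival comparison so that the
curve-reconstruction and fitting machinery can be exercised end-to-end
without patient-level data: parametric event times (inverse-transform
sampled), uniform accrual, administrative censoring at a maximum follow-up,
and optional random dropout.  The Kaplan-Meier estimator here doubles as the
oracle for reconstruction round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .reconstruct import DigitizedKM, PseudoIPD
from .survival import HazardAdjustedSurvival, ParametricSurvival

__all__ = ["TrialSimSpec", "simulate_arm", "simulate_trial", "km_estimator",
           "make_fixture_suite"]


@dataclass(frozen=True)
class TrialSimSpec:
    """Design of a synthetic two-arm trial.

    Arm 1 events come from ``arm1``; arm 2 either from ``arm2`` or from
    ``arm1`` adjusted by ``hr_arm2`` (proportional hazards).  Patients enter
    uniformly over ``accrual_months`` and are administratively censored at
    ``max_followup_months`` after trial start; ``dropout_rate`` is an
    exponential per-month dropout hazard.
    """

    n_per_arm: int
    arm1: ParametricSurvival
    arm2: Optional[ParametricSurvival] = None
    hr_arm2: Optional[float] = None
    accrual_months: float = 0.0
    max_followup_months: float = np.inf
    dropout_rate: float = 0.0
    seed: int = 0
    labels: tuple = ("arm1", "arm2")

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be at least 1")
        if self.max_followup_months <= 0:
            raise ValueError("max follow-up must be positive")
        if self.dropout_rate < 0 or self.accrual_months < 0:
            raise ValueError("rates and windows must be non-negative")
        if self.arm2 is not None and self.hr_arm2 is not None:
            raise ValueError("specify arm2 either directly or through hr_arm2")

    def arm_curve(self, index: int):
        if index == 0:
            return self.arm1
        if self.arm2 is not None:
            return self.arm2
        if self.hr_arm2 is not None:
            return HazardAdjustedSurvival(self.arm1, self.hr_arm2)
        return self.arm1


def simulate_arm(curve, n: int, rng: np.random.Generator, accrual: float,
                 max_followup: float, dropout_rate: float, label: str
                 ) -> pd.DataFrame:
    event_times = curve.inverse_survival(rng.uniform(size=n))
    entry = rng.uniform(0.0, accrual, size=n) if accrual > 0 else np.zeros(n)
    admin = np.maximum(max_followup - entry, 1e-9)
    if dropout_rate > 0:
        dropout = rng.exponential(1.0 / dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(admin, dropout)
    observed = np.minimum(event_times, censor)
    event = (event_times <= censor).astype(int)
    return pd.DataFrame({"time_months": observed, "event": event, "arm": label})


def simulate_trial(spec: TrialSimSpec) -> PseudoIPD:
    """Simulate both arms; deterministic for a fixed spec (including seed)."""
    rng = np.random.default_rng(spec.seed)
    frames = [
        simulate_arm(spec.arm_curve(i), spec.n_per_arm, rng, spec.accrual_months,
                     spec.max_followup_months, spec.dropout_rate, spec.labels[i])
        for i in range(2)
    ]
    return PseudoIPD(pd.concat(frames, ignore_index=True))


def km_estimator(ipd: PseudoIPD, arm: Optional[str] = None,
                 risk_times: Optional[Sequence[float]] = None) -> DigitizedKM:
    """Product-limit estimate of one arm with a number-at-risk table.

    Ties are handled in the standard way (events before censorings at equal
    times).  ``risk_times`` defaults to a 3-month grid spanning follow-up.
    """
    frame = ipd.records
    if arm is not None:
        frame = frame[frame["arm"] == arm]
    elif frame["arm"].nunique() > 1:
        raise ValueError("multiple arms present; pass arm=...")
    if frame.empty:
        raise ValueError("no records for the requested arm")
    label = frame["arm"].iloc[0]
    kmf = KaplanMeierFitter()
    kmf.fit(frame["time_months"], frame["event"])
    surv = kmf.survival_function_
    coords = list(zip(surv.index.to_numpy(float), surv.iloc[:, 0].to_numpy(float)))
    if coords[0][0] > 0:
        coords.insert(0, (0.0, 1.0))
    t_max = float(frame["time_months"].max())
    if risk_times is None:
        risk_times = np.arange(0.0, t_max + 3.0, 3.0)
    times = np.asarray(list(risk_times), dtype=float)
    obs = frame["time_months"].to_numpy()
    n_risk = [(int(np.sum(obs >= t))) for t in times]
    return DigitizedKM(
        arm_label=str(label),
        coords=coords,
        risk_table=list(zip(times, n_risk)),
        total_events=int(frame["event"].sum()),
    )


def make_fixture_suite(seed: int, outdir) -> dict:
    """Write a reproducible CSV fixture bundle; returns specs and file paths.

    Covers a clean exponential trial, a Weibull trial at the pooled
    chemotherapy OS parameters, a log-logistic trial at the chemo-immuno OS
    parameters, a heavily censored trial, and a tiny-n edge case.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    suite = {
        "exponential_clean": TrialSimSpec(
            n_per_arm=1000, arm1=ParametricSurvival("exponential", (np.log(2) / 12,)),
            hr_arm2=2.0, seed=int(rng.integers(2**31))),
        "weibull_ep_os": TrialSimSpec(
            n_per_arm=2000,
            arm1=ParametricSurvival("weibull", (0.016073, 1.593409)),
            max_followup_months=36.0, accrual_months=12.0,
            seed=int(rng.integers(2**31))),
        "loglogistic_aep_os": TrialSimSpec(
            n_per_arm=2000,
            arm1=ParametricSurvival("loglogistic", (0.003072, 2.297440)),
            max_followup_months=36.0, accrual_months=12.0,
            seed=int(rng.integers(2**31))),
        "heavy_censoring": TrialSimSpec(
            n_per_arm=500,
            arm1=ParametricSurvival("weibull", (0.016073, 1.593409)),
            max_followup_months=12.0, accrual_months=6.0, dropout_rate=0.05,
            seed=int(rng.integers(2**31))),
        "tiny_n": TrialSimSpec(
            n_per_arm=5, arm1=ParametricSurvival("exponential", (np.log(2) / 12,)),
            max_followup_months=6.0, seed=int(rng.integers(2**31))),
    }
    paths = {}
    for name, spec in suite.items():
        ipd = simulate_trial(spec)
        path = outdir / f"{name}.csv"
        ipd.records.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path
    truth = pd.DataFrame(
        [(name, spec.arm1.family,
          *(spec.arm1.params + (np.nan,) * (2 - len(spec.arm1.params))))
         for name, spec in suite.items()],
        columns=["fixture", "family", "param1", "param2"])
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    paths["ground_truth"] = truth_path
    return {"specs": suite, "paths": paths}
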