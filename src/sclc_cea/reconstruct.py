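"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival comparisons rarely ship patient-level data; what is
available is the KM curve itself (digitized to (time, survival) steps) and
the numbers-at-risk table printed beneath it.  The interval-solving
algorithm here (in the Guyot tradition of KM reconstruction) recovers
event and censoring times that reconcile the digitized drops with the
decline in the at-risk counts: censorings are spread uniformly within each
risk-table interval and their number iterated until the implied number at
risk matches the published one; events are placed at the digitized step
times.  The reconstructed data can then be re-fitted with censoring-aware
parametric maximum likelihood, model families ranked by AIC/BIC, arms
pooled, and indirect hazard ratios formed by the Bucher contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .survival import FAMILIES, ParametricSurvival

__all__ = [
    "DigitizedKM", "PseudoIPD", "FitResult", "IndirectHR",
    "reconstruct_ipd", "fit_parametric", "select_best", "pool_ipd",
    "bucher_indirect_hr",
]

_Z95 = 1.959963984540054


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class DigitizedKM:
    """A digitized KM curve plus its numbers-at-risk table for one arm."""

    arm_label: str
    coords: Sequence[tuple]       # (time_months, survival), first = (0, 1.0)
    risk_table: Sequence[tuple]   # (time_months, number at risk)
    total_events: Optional[int] = None

    def __post_init__(self):
        coords = [(float(t), float(s)) for t, s in self.coords]
        risk = [(float(t), int(n)) for t, n in self.risk_table]
        if not coords or not risk:
            raise ValueError("coords and risk_table must be non-empty")
        if coords[0] != (0.0, 1.0):
            raise ValueError("first coordinate must be (0, 1.0)")
        times = [t for t, _ in coords]
        survs = [s for _, s in coords]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("coordinate times must be non-decreasing")
        for i, (a, b) in enumerate(zip(survs, survs[1:])):
            if b > a + 1e-12:
                raise ValueError(f"survival increases at coordinate {i + 1}")
        if any(not 0 <= s <= 1 for s in survs):
            raise ValueError("survival must lie in [0, 1]")
        rtimes = [t for t, _ in risk]
        rcounts = [n for _, n in risk]
        if any(b <= a for a, b in zip(rtimes, rtimes[1:])):
            raise ValueError("risk-table times must be strictly increasing")
        for i, (a, b) in enumerate(zip(rcounts, rcounts[1:])):
            if b > a:
                raise ValueError(f"number at risk increases in interval {i}")
        if any(n < 0 for n in rcounts):
            raise ValueError("numbers at risk must be non-negative")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "risk_table", risk)

    def to_frames(self):
        curve = pd.DataFrame(self.coords, columns=["time_months", "survival"])
        risk = pd.DataFrame(self.risk_table, columns=["time_months", "n_risk"])
        return curve, risk


@dataclass(frozen=True)
class PseudoIPD:
    """Individual event/censor records: time_months, event flag, arm label."""

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        frame = pd.DataFrame(self.records).reset_index(drop=True)
        missing = {"time_months", "event", "arm"} - set(frame.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        if frame.empty:
            raise ValueError("records must be non-empty")
        if (frame["time_months"] <= 0).any():
            raise ValueError("times must be positive")
        if not frame["event"].isin((0, 1)).all():
            raise ValueError("event flag must be 0 or 1")
        object.__setattr__(self, "records", frame)

    def __len__(self):
        return len(self.records)

    @property
    def arms(self):
        return list(self.records["arm"].unique())

    def arm(self, label: str) -> "PseudoIPD":
        sub = self.records[self.records["arm"] == label]
        if sub.empty:
            raise ValueError(f"no records for arm {label!r}")
        return PseudoIPD(sub)

    @property
    def n_events(self) -> int:
        return int(self.records["event"].sum())

    def to_csv(self, path):
        self.records.to_csv(path, index=False, float_format="%.6f")


# --------------------------------------------------------------------------
# reconstruction
# --------------------------------------------------------------------------
def _walk_interval(steps, censor_times, n_start, s_start):
    """Process one risk-table interval with a fixed censoring schedule.

    Walks events (digitized steps) and censorings in time order, tracking the
    at-risk count and the reconstructed KM value.  Returns the event times,
    applied censor times, and the end-of-interval at-risk count and KM value.
    """
    merged = [(t, "event", s) for t, s in steps]
    merged += [(t, "censor", None) for t in censor_times]
    merged.sort(key=lambda item: (item[0], item[1] == "censor"))
    n_t, s_rec = n_start, s_start
    event_times, applied_censors = [], []
    for t, kind, s_target in merged:
        if kind == "censor":
            if n_t > 0:
                n_t -= 1
                applied_censors.append(t)
            continue
        if n_t <= 0 or s_rec <= 0:
            continue
        d = int(round(n_t * (1.0 - s_target / s_rec)))
        d = min(max(d, 0), n_t)
        if d > 0:
            s_rec *= 1.0 - d / n_t
            n_t -= d
            event_times.extend([t] * d)
    return event_times, applied_censors, n_t, s_rec


def reconstruct_ipd(km: DigitizedKM) -> PseudoIPD:
    """Recreate event/censor times consistent with a digitized KM curve.

    Within each risk-table interval the number of censorings is iterated
    until the reconstructed number at risk at the next risk time equals the
    published one; censor times are spread uniformly over the interval and
    events are placed at the digitized step times.  Beyond the last risk
    time no censoring is assumed unless ``total_events`` forces a final
    rebalancing of the tail.
    """
    rtimes = [t for t, _ in km.risk_table]
    rcounts = [n for _, n in km.risk_table]
    coords = [(t, s) for t, s in km.coords if t >= rtimes[0]]
    last_coord_time = km.coords[-1][0]
    t_end = max(last_coord_time, rtimes[-1])

    event_times: list = []
    censor_times: list = []
    n_cur = rcounts[0]
    s_cur = 1.0
    n_intervals = len(rtimes)
    for i in range(n_intervals):
        t_lo = rtimes[i]
        last = i + 1 >= n_intervals
        t_hi = t_end + 1e-9 if last else rtimes[i + 1]
        # digitized steps fall in [t_lo, t_hi); a step exactly at a risk time
        # belongs to the interval it opens (subjects with events at t are
        # still counted at risk at t)
        steps = [(t, s) for t, s in coords if t_lo <= t < t_hi and t > 0]
        target = None if last else rcounts[i + 1]
        c = 0
        prev_diff = None
        for _ in range(200):
            sched = [t_lo + (j + 0.5) * (t_hi - t_lo) / c for j in range(c)]
            ev, cens, n_end, s_end = _walk_interval(steps, sched, n_cur, s_cur)
            if target is None:
                break
            diff = n_end - target
            if diff == 0 or (c == 0 and diff < 0) or diff == prev_diff:
                break
            prev_diff = diff
            c = max(0, c + diff)
        else:
            raise ValueError(
                f"could not reconcile interval {i} ({t_lo}-{t_hi} months) "
                "with the risk table")
        event_times.extend(ev)
        censor_times.extend(cens)
        n_cur, s_cur = n_end, s_end

    if km.total_events is not None:
        event_times, censor_times = _rebalance_tail(
            event_times, censor_times, km.total_events, n_cur, last_coord_time)
        n_cur = rcounts[0] - len(event_times) - len(censor_times)
    # whoever is still at risk leaves the study at the end of follow-up
    censor_times.extend([t_end] * max(n_cur, 0))

    records = pd.DataFrame({
        "time_months": np.concatenate([event_times, censor_times])
        if event_times or censor_times else np.array([]),
        "event": np.concatenate([np.ones(len(event_times)),
                                 np.zeros(len(censor_times))]),
        "arm": km.arm_label,
    })
    if records.empty:
        raise ValueError("reconstruction produced no records")
    return PseudoIPD(records.sort_values("time_months").reset_index(drop=True))


def _rebalance_tail(event_times, censor_times, total_events, n_left, t_last):
    """Adjust the reconstruction so the overall event count matches.

    Missing events are drawn from the still-at-risk tail (placed at the last
    digitized time); surplus events at the latest times are converted to
    censorings.
    """
    event_times = sorted(event_times)
    censor_times = list(censor_times)
    diff = total_events - len(event_times)
    if diff > 0:
        add = min(diff, n_left)
        event_times.extend([t_last] * add)
        n_left -= add
    elif diff < 0:
        for _ in range(-diff):
            if not event_times:
                break
            censor_times.append(event_times.pop())
    return event_times, censor_times


# --------------------------------------------------------------------------
# parametric fitting and selection
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class FitResult:
    """A censoring-aware maximum-likelihood fit of one survival family."""

    family: str
    params: tuple
    log_likelihood: float
    aic: float
    bic: float
    n_used: int
    data_key: tuple = field(default=(), compare=False)

    @property
    def n_params(self) -> int:
        return FAMILIES[self.family]

    def curve(self) -> ParametricSurvival:
        return ParametricSurvival(self.family, self.params)


def _loglik(curve: ParametricSurvival, t, event) -> float:
    with np.errstate(over="ignore"):
        ll = float(np.sum(np.where(event == 1, curve.log_density_at(t),
                                   curve.log_survival_at(t))))
    return ll if math.isfinite(ll) else -np.inf


def _seed_params(family: str, t, event):
    """Method-of-moments style starting points, several per family."""
    d = max(int(event.sum()), 1)
    rate = d / float(t.sum())
    t_ev = t[event == 1]
    med = float(np.median(t_ev)) if len(t_ev) else float(np.median(t))
    med = max(med, 1e-6)
    if family == "exponential":
        return [(rate,)]
    if family == "weibull":
        return [(math.log(2) / med**g, g) for g in (0.7, 1.0, 1.5, 2.5)]
    if family == "loglogistic":
        return [(med**-k, k) for k in (0.8, 1.2, 2.0, 3.0)]
    if family == "lognormal":
        logs = np.log(t_ev if len(t_ev) > 1 else t)
        mu, sigma = float(np.mean(logs)), max(float(np.std(logs)), 0.2)
        return [(mu, sigma), (math.log(med), 1.0)]
    if family == "gompertz":
        return [(a, rate) for a in (0.01, 0.05, 0.2)]
    raise ValueError(f"unknown family {family!r}")


def fit_parametric(ipd: PseudoIPD, family: str) -> FitResult:
    """Fit one parametric family to (possibly censored) pseudo-IPD by MLE.

    The log-likelihood is the usual censored-data form, sum of log f(t) over
    events plus log S(t) over censored records.  Optimisation runs in
    log-parameter space (the lognormal location stays unconstrained) from
    several method-of-moments starting points, keeping the best optimum, so
    the result is deterministic given the data.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    frame = ipd.records
    t = frame["time_months"].to_numpy(float)
    event = frame["event"].to_numpy(int)
    n = len(t)
    d = int(event.sum())
    if d == 0:
        raise ValueError("all records censored: cannot fit event-time model")
    if d < 2:
        raise ValueError("need at least 2 events to fit a parametric model")

    def key():
        return (n, d, round(float(t.sum()), 6))

    if family == "exponential":
        rate = d / float(t.sum())
        curve = ParametricSurvival("exponential", (rate,))
        ll = _loglik(curve, t, event)
        return FitResult("exponential", (rate,), ll, 2 * 1 - 2 * ll,
                         1 * math.log(n) - 2 * ll, n, key())

    unconstrained_first = family == "lognormal"

    def pack(params):
        if unconstrained_first:
            return np.array([params[0], math.log(params[1])])
        return np.log(np.asarray(params))

    def unpack(x):
        if unconstrained_first:
            return (float(x[0]), float(np.exp(x[1])))
        return tuple(float(v) for v in np.exp(x))

    def neg_ll(x):
        try:
            curve = ParametricSurvival(family, unpack(x))
        except (ValueError, OverflowError):
            return np.inf
        return -_loglik(curve, t, event)

    best = None
    n_fail = 0
    for seed in _seed_params(family, t, event):
        res = optimize.minimize(neg_ll, pack(seed), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 4000})
        if not math.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError(
            f"{family} fit failed from all {n_fail} starting points")
    params = unpack(best.x)
    ll = -float(best.fun)
    k = FAMILIES[family]
    return FitResult(family, params, ll, 2 * k - 2 * ll,
                     k * math.log(n) - 2 * ll, n, key())


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Minimum-AIC fit; ties broken by BIC, then parameter count, then name.

    All candidates must have been fitted to the same data (same size and
    event structure), otherwise their information criteria are not
    comparable and a ``ValueError`` is raised.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    keys = {f.data_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different data")
    return min(fits, key=lambda f: (f.aic, f.bic, f.n_params, f.family))


def rank_fits(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Full AIC/BIC ranking table for reporting."""
    best = select_best(fits)  # validates comparability
    frame = pd.DataFrame(
        [(f.family, f.log_likelihood, f.aic, f.bic, f.family == best.family)
         for f in fits],
        columns=["family", "log_likelihood", "aic", "bic", "selected"])
    return frame.sort_values("aic", kind="mergesort").reset_index(drop=True)


def pool_ipd(a: PseudoIPD, b: PseudoIPD, pooled_label: str) -> PseudoIPD:
    """Concatenate two reconstructed datasets under one pooled arm label."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot pool an empty dataset")
    merged = pd.concat([a.records, b.records], ignore_index=True).copy()
    merged["arm"] = pooled_label
    return PseudoIPD(merged)


# --------------------------------------------------------------------------
# indirect comparison
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class IndirectHR:
    """A Bucher-adjusted indirect hazard ratio with its 95% interval."""

    hr: float
    ci_low: float
    ci_high: float
    se_log: float

    def __post_init__(self):
        if not self.ci_low <= self.hr <= self.ci_high:
            raise ValueError("CI must bracket the hazard ratio")


def _se_from_ci(ci: tuple) -> float:
    lo, hi = float(ci[0]), float(ci[1])
    if lo <= 0 or hi <= 0:
        raise ValueError("CI bounds must be positive")
    if hi < lo:
        raise ValueError("CI bounds inverted")
    return (math.log(hi) - math.log(lo)) / (2 * _Z95)


def bucher_indirect_hr(hr_b_vs_c: tuple, hr_a_vs_c: tuple) -> IndirectHR:
    """Indirect HR of B vs A from two trials sharing comparator C.

    On the log scale the common-comparator effect cancels:
    log HR(B vs A) = log HR(B vs C) - log HR(A vs C), with variances adding.
    Inputs are ``(hr, (ci_low, ci_high))`` pairs with 95% intervals.
    """
    hr_b, ci_b = hr_b_vs_c
    hr_a, ci_a = hr_a_vs_c
    if hr_b <= 0 or hr_a <= 0:
        raise ValueError("hazard ratios must be positive")
    se = math.hypot(_se_from_ci(ci_b), _se_from_ci(ci_a))
    log_hr = math.log(hr_b) - math.log(hr_a)
    return IndirectHR(
        hr=math.exp(log_hr),
        ci_low=math.exp(log_hr - _Z95 * se),
        ci_high=math.exp(log_hr + _Z95 * se),
        se_log=se,
    )
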