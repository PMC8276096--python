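# Methods

## Model structure

The cohort model is a partitioned-survival realisation of the three-state
(progression-free / progressed / dead) structure used throughout advanced
oncology cost-utility work. With only marginal PFS and OS curves published,
per-state exit rates are under-identified, so state occupancy is taken
directly from the curves at each cycle boundary — `pfs = S_PFS`,
`ps = max(0, S_OS − S_PFS)`, `dead = 1 − S_OS` — which conserves occupancy
to machine precision by construction. A conditional per-interval event
probability (`1 − S(t1)/S(t0)`) is available for transition-matrix variants
but is not used by the base case.

Cycles are 21 days (one chemotherapy cycle); the 10-year horizon gives 174
cycles (first boundary past 10 years). Membership is evaluated at cycle end
with no half-cycle correction; a trapezoidal `half_cycle_correction` flag
exists but defaults off. Sensitivity of results to the discretisation is a
tested invariant (halving the cycle length moves life-years by < 2%).
Monthly quantities convert at 30.4375 days/month; discounting is
`1.03^(−k·21/365.25)` per cycle k.

## Survival inputs

* AEP arm: log-logistic `S(t) = 1/(1+θ·t^κ)`, OS (θ=0.003072, κ=2.297440),
  PFS (θ=0.008895, κ=2.852489).
* EP arm (pooled chemotherapy): Weibull `S(t) = exp(−λ·t^γ)`, OS
  (λ=0.016073, γ=1.593409), PFS (λ=0.042826, γ=1.712046).
* DEP arm: `S_DEP(t) = S_AEP(t)^HR` with indirect hazard ratios 1.04 (OS)
  and 1.01 (PFS).

The time unit is months: these parameterisations reproduce the source
trials' medians (≈12.4 / 5.2 months AEP OS/PFS, ≈10.6 / 5.1 months pooled
EP OS/PFS), which the test suite asserts. Parameters must be positive and
curves are validated to be monotone with S(0)=1.

Long-term behaviour is governed by an extrapolation policy with a 24-month
cutoff. PFS always continues the fitted curve. OS continues the fitted
curve by default, or — when a background-hazard table is supplied as
`time_months,monthly_hazard` CSV — switches at the cutoff to a
piecewise-constant external hazard (registry-style background mortality),
with the composite curve continuous at the cutoff. The external table
*replaces* the parametric hazard beyond the cutoff rather than capping it,
and is applied on top of the already HR-adjusted curve so that background
mortality is arm-independent. The source analysis drew this tail from SEER
registry data published only in its supplement; no surrogate is bundled, so
the default configuration continues the parametric curves (see
*Fidelity*, below).

## Treatment strategies and costs

All arms: 4 induction cycles of etoposide 100 mg/m² on days 1–3 plus
carboplatin AUC 5 (Calvert dose = AUC·(CrCl+25) mg) for a reference patient
with BSA 1.8 m² and CrCl 70 ml/min; per-mg 2020 US prices, linear pricing,
no vial rounding. The ICI arms add a flat-dose antibody (atezolizumab
1,200 mg at $7.83/mg; durvalumab 1,500 mg at $7.60/mg) every cycle for a
median-duration default of 7 cycles per arm (induction infusions 4 h,
chemotherapy-only 3 h, maintenance 1 h; first-hour/additional-hour fees).
The published analysis states it used per-arm median treatment cycles
without printing them; 7 cycles is the configurable stand-in.

Other accruals per cycle: one-time first-line AE-management aggregate in
cycle 1; monthly physician visit plus one-third of the three-monthly
imaging fee for alive occupancy; second-line topotecan (1.5 mg/m²,
days 1–5, five 1-hour infusions, capped at 4 cycles) for the published
proportion of progressors, with the one-time second-line AE cost charged at
progression; monthly supportive care for progressed occupancy not on
topotecan; and a death-associated cost per incremental death. Progression
entrants are read off the PFS decrements, and the topotecan-treated pool is
the running sum of the last 4 entrant cohorts clipped by current PS
occupancy — an approximation forced by the partitioned structure (no
individual follow-up within PS).

QALYs weight occupancy by utilities 0.673 (PFS) and 0.473 (PS); the
treatment AE disutility (0.090/0.094/0.112) is subtracted from the PFS
utility during first-line cycles, floored at zero. In the
until-progression scenario only the ICI cost window widens (drug +
administration follow PFS occupancy for all cycles); the disutility window
deliberately stays at the median-cycle duration, so scenario QALYs equal
base-case QALYs.

## Sensitivity analyses

One-way analysis re-runs the full model at each parameter's low/high
(published 95% CIs for utilities, disutilities, proportions and hazard
ratios; ±25% otherwise), reporting the comparison ICER and spread;
dominance outcomes are encoded as NaN with a status column rather than a
numeric sentinel. The PSA draws all 27 parameters jointly and
independently per draw — gamma for costs and patient constants
(shape = μ²/σ²), beta for utilities and proportions (moment-matched),
lognormal for hazard ratios (median at baseline) — with σ implied by
reading each range as a 95% interval. Survival distribution parameters
carry no published uncertainty and are held fixed; only the two hazard
ratios move the survival side. Draws come from one seeded PCG64 stream in
config order, making every output byte-reproducible. Price thresholds are
found by bisecting a multiplier m∈[0,1] on the drug's per-mg price until
the ICER is within $500/QALY of the willingness-to-pay.

## KM reconstruction and fitting

`reconstruct_ipd` implements the interval-solving approach associated with
Guyot/Hoyle: within each numbers-at-risk interval, censorings are assumed
uniform and their count iterated until the implied number at risk matches
the published count at the next risk time; events are placed at the
digitized step times with multiplicities chosen to track the digitized
curve; a digitized step exactly at a risk time belongs to the interval it
opens (subjects with events at t are still at risk at t); patients
remaining after the last interval are censored at the end of follow-up; an
optional total-events count triggers a final tail rebalancing.

Fitting is censored maximum likelihood (Σ events log f + Σ censored log S)
in log-parameter space from several method-of-moments starting points
(deterministic given the data), for exponential (closed form), Weibull,
log-logistic, log-normal and Gompertz families; ranking is by AIC with
BIC/parsimony/name tie-breaks, and candidates must share the same data
fingerprint. The implementation is cross-checked in the test suite against
lifelines' independent fitters (after parameterisation conversion) to
~1e−3 relative agreement. Bucher indirect hazard ratios subtract log-HRs
of two trials sharing a comparator, adding variances from the 95% CIs.

## Synthetic trials

The generator emulates what the real inputs were: two-arm phase-III-like
trials with parametric event times (inverse-transform), uniform accrual
over an entry window, administrative censoring at maximum follow-up and
optional exponential dropout. Defaults in the fixture suite use the
published Weibull/log-logistic parameters, n = 2,000 per arm and follow-up
chosen to yield ≈20% administrative censoring — sizes at which
reconstruction and fitting recover the generating family and parameters
within 15%. The generator does not emulate informative censoring,
digitization noise in the KM coordinates, or between-trial heterogeneity,
so passing tests demonstrate correctness of the machinery, not robustness
to those real-data artefacts.

## Numerical choices

Bisection tolerances: $500/QALY (price threshold), 1e−10 (medians).
MLE restarts capped at the seed list; non-finite likelihoods discarded.
PFS curves crossing above OS are clamped to OS (count kept on the trace).
A zero survival denominator in conditional probabilities returns 1
(absorbing). Frontier construction removes strict then extended dominance;
equal sequential ICERs (collinear strategies) are all retained; NMB ties
split equally in the CEAC.

## Fidelity to the published analysis, and limitations

Two supplement-only inputs cannot be reproduced from the main text: the
registry-based OS tail beyond 24 months and the per-arm median ICI dosing
schedule. Both are explicit configuration knobs, left at neutral defaults
(parametric continuation; 7 q3w cycles per arm). Consequences, all
computed by this package and asserted at band in `tests/test_acceptance.py`:
the chemotherapy arm's totals sit above the published cost and below the
published QALY (the heavier real-world OS tail raises published QALYs,
and the published EP cost is lower than the sum of the cost categories the
analysis describes, under any tail we can construct from the main text);
the DEP−AEP cost gap is larger than published (equal 7-cycle q3w dosing in
both ICI arms); and the PSA cost-effectiveness probabilities vs
chemotherapy are ≈0 — under the published distributions the ΔNMB draw
spread (sd ≈ $8k) is far too small to reach positive territory from a mean
of ≈ −$46k, so the published 6.6%/4.1% imply a draw spread the published
ranges do not generate. The qualitative findings — chemotherapy cheapest,
DEP dominated by AEP, both ICERs several times the $100,000/QALY
threshold, carboplatin price immaterial, conclusions unchanged in the
until-progression scenario — all reproduce, and the scenario costs land
within ~2% of the published figures.
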