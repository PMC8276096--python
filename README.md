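# sclc-cea

Cost-effectiveness modelling of first-line chemo-immunotherapy for
extensive-stage small-cell lung cancer (ES-SCLC), from a US payer
perspective: atezolizumab + etoposide/platinum (AEP) and durvalumab +
etoposide/platinum (DEP) against etoposide/platinum chemotherapy alone (EP).

The package is aimed at health-economics researchers who want a fully
scripted, configurable re-implementation of this class of oncology
cost-utility analyses — every parameter lives in a YAML file, every number in
the output is recomputed from it, and the survival-input machinery
(Kaplan–Meier curve reconstruction, parametric fitting, indirect comparison)
is part of the tested code rather than a one-off preprocessing step.

## The model

A three-state partitioned-survival cohort model (progression-free `PFS`,
progressed `PS`, dead) on 21-day cycles over a 10-year horizon. State
occupancy is read off marginal parametric curves:

    pfs(t) = S_PFS(t),   ps(t) = max(0, S_OS(t) − S_PFS(t)),   dead(t) = 1 − S_OS(t)

with log-logistic curves `S(t) = 1/(1+θ·t^κ)` for the AEP arm, Weibull
curves `S(t) = exp(−λ·t^γ)` for the pooled EP arm (time in months), and the
DEP arm derived by proportional hazards, `S_DEP(t) = S_AEP(t)^HR`, using
indirect (Bucher) hazard ratios. Costs (drug acquisition by flat, per-BSA or
Calvert dosing; IV administration; adverse-event aggregates; follow-up;
second-line topotecan; supportive and death-associated care) and utilities
(0.673 / 0.473 with on-treatment disutilities) accrue per cycle, discounted
at 3% per year. Strategies are compared by incremental cost-effectiveness
ratio (ICER = Δcost/ΔQALY), dominance and net monetary benefit
(NMB = WTP·QALY − cost) at a willingness-to-pay of $100,000/QALY.

Around the cohort engine:

* **`reconstruct`** — pseudo individual-patient data from digitized KM
  coordinates plus numbers-at-risk tables (Guyot-style interval solving),
  censoring-aware maximum-likelihood fitting of five parametric families,
  AIC/BIC model selection, arm pooling and Bucher indirect hazard ratios.
* **`sensitivity`** — one-way (tornado) analysis, price-reduction threshold
  search by bisection, 10,000-draw probabilistic sensitivity analysis
  (gamma/beta/lognormal, moment-matched to 95% ranges) with CEAC, and the
  scenario in which immunotherapy continues until progression.
* **`simulate`** — synthetic two-arm trials with known ground truth
  (inverse-transform event times, uniform accrual, administrative
  censoring), used as the oracle for the reconstruction pipeline.

## Worked example

```python
from sclc_cea import CostEffectivenessModel

results = CostEffectivenessModel.default().fit()
print(results.summary())
```

```
Cost-effectiveness results (discounted, 10-year horizon)
==================================================================
strategy        cost ($)      QALY  life-years         NMB ($)
EP                33,225     0.513       0.970          18,104
AEP               89,519     0.695       1.373         -19,982
DEP               98,706     0.672       1.324         -31,511
------------------------------------------------------------------
comparison         Δcost ($)     ΔQALY       ICER ($/QALY)
DEP vs AEP             9,188    -0.023           dominated
AEP vs EP             56,294     0.182             309,191
DEP vs EP             65,481     0.159             412,717
==================================================================
willingness-to-pay: $100,000/QALY
```

Reading: chemotherapy alone is cheapest; both chemo-immunotherapies gain
roughly 0.16–0.18 QALYs over it but at ICERs far above $100,000/QALY, so
neither is cost-effective at that threshold; DEP is dominated by AEP (more
expensive *and* less effective, because durvalumab costs more per cycle and
the indirect hazard ratios of 1.04/1.01 put its curves slightly below the
atezolizumab arm's).

Everything hangs off the results object or the config:

```python
results.cost_ledger("EP")            # itemised per-cycle cost ledger
results.run_dsa(("AEP", "EP"))       # tornado table
results.price_threshold("atezolizumab", ("AEP", "EP"))   # -> 0.707
psa = results.run_psa(n_draws=10_000, seed=1)
psa.prob_cost_effective("AEP", "EP", 100_000)
results.scenario_until_progression().summary()
```

or from the shell:

```bash
sclc-cea base-case --out results/base_case
sclc-cea psa --n-draws 10000 --seed 1 --out results/psa
sclc-cea threshold --out results/threshold
sclc-cea reconstruct --curve km.csv --risk-table risk.csv --out results/rec
```

Every run writes plain CSV/JSON plus the fully resolved configuration, and
is byte-reproducible for a fixed seed. To change an assumption (ICI cycle
counts, extrapolation mode, any price or utility), copy
`src/sclc_cea/data/default_config.yaml`, edit, and pass `--config`.

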