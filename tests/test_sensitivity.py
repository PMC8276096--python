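"""One-way DSA, price thresholds, PSA sampling/reproducibility, CEAC, scenario."""

import math

import numpy as np
import pandas as pd
import pytest

from sclc_cea import (CostEffectivenessModel, ceac, one_way_dsa,
                      price_threshold, run_psa, sample_param,
                      scenario_until_progression)
from sclc_cea.sensitivity import ParamSpec, PSAResult, resolve_params


@pytest.fixture(scope="module")
def base_icer(results):
    return results.icer("AEP", "EP").value


# --------------------------------------------------------------------------
# parameter specs and sampling
# --------------------------------------------------------------------------
def test_resolve_params_reads_baselines_from_config(config):
    params = {p.binding: p for p in resolve_params(config)}
    assert params["prices.atezolizumab"].baseline == 7.83
    assert params["utilities.pfs"].baseline == 0.673
    assert params["dep_hr.os"].baseline == 1.04
    assert len(params) == len(config.sensitivity)


def test_param_spec_validation():
    with pytest.raises(ValueError, match="outside"):
        ParamSpec("x", "p.x", 5.0, 6.0, 7.0, "gamma")
    with pytest.raises(ValueError, match="beta"):
        ParamSpec("x", "p.x", 1.2, 1.0, 1.4, "beta")
    with pytest.raises(ValueError, match="positive"):
        ParamSpec("x", "p.x", 1.0, -0.5, 1.4, "lognormal")


def test_fixed_distribution_returns_baseline(rng):
    spec = ParamSpec("x", "p.x", 3.0, 3.0, 3.0, "fixed")
    assert sample_param(spec, rng) == 3.0
    assert np.all(sample_param(spec, rng, size=10) == 3.0)


def test_gamma_sampling_moment_matched(rng):
    spec = ParamSpec("price", "p.x", 7.83, 5.87, 9.78, "gamma")
    draws = sample_param(spec, rng, size=100_000)
    assert np.mean(draws) == pytest.approx(7.83, rel=0.01)
    assert np.std(draws) == pytest.approx(spec.se, rel=0.02)
    assert np.all(draws > 0)


def test_beta_sampling_moment_matched_and_bounded(rng):
    spec = ParamSpec("u", "p.x", 0.673, 0.538, 0.808, "beta")
    draws = sample_param(spec, rng, size=100_000)
    assert np.mean(draws) == pytest.approx(0.673, rel=0.01)
    assert np.all((draws > 0) & (draws < 1))
    # a mean near the boundary with a wide range cannot be moment-matched
    infeasible = ParamSpec("u", "p.x", 0.01, 0.0, 0.9, "beta")
    with pytest.raises(ValueError, match="infeasible"):
        sample_param(infeasible, rng)


def test_lognormal_sampling_median_is_baseline(rng):
    spec = ParamSpec("hr", "p.x", 1.04, 0.83, 1.25, "lognormal")
    draws = sample_param(spec, rng, size=100_000)
    assert np.median(draws) == pytest.approx(1.04, rel=0.02)
    sdlog = (math.log(1.25) - math.log(0.83)) / (2 * 1.959963984540054)
    assert np.std(np.log(draws)) == pytest.approx(sdlog, rel=0.02)


# --------------------------------------------------------------------------
# one-way DSA
# --------------------------------------------------------------------------
def test_zero_width_ranges_reproduce_base_icer(config, base_icer):
    params = [
        ParamSpec(p.name, p.binding, p.baseline, p.baseline, p.baseline, "fixed")
        for p in resolve_params(config)[:6]
    ]
    table = one_way_dsa(config, ("AEP", "EP"), params=params)
    assert np.allclose(table["spread"], 0.0)
    assert np.allclose(table["icer_low"], base_icer)
    assert np.allclose(table["icer_high"], base_icer)


def test_icer_monotone_in_ici_price(config):
    table = one_way_dsa(config, ("AEP", "EP"))
    row = table[table["parameter"] == "Atezolizumab price per mg"].iloc[0]
    assert row["icer_low"] < row["icer_high"]
    assert row["spread"] > 0


def test_carboplatin_price_negligible(config, base_icer):
    """+/-25% on the carboplatin price moves the ICER by well under 1%."""
    table = one_way_dsa(config, ("AEP", "EP"))
    row = table[table["parameter"] == "Carboplatin price per mg"].iloc[0]
    assert abs(row["icer_high"] - row["icer_low"]) / base_icer < 0.01


def test_unknown_binding_rejected(config):
    bad = [ParamSpec("ghost", "prices.nonexistent", 1.0, 0.5, 1.5, "gamma")]
    with pytest.raises(KeyError, match="binding"):
        one_way_dsa(config, ("AEP", "EP"), params=bad)


# --------------------------------------------------------------------------
# price threshold
# --------------------------------------------------------------------------
def test_price_threshold_verified_by_rerun(config):
    wtp = 100_000.0
    m = price_threshold(config, "atezolizumab", ("AEP", "EP"), wtp)
    assert 0.0 < m < 1.0
    base_price = config.prices.atezolizumab
    check = CostEffectivenessModel(
        config.with_value("prices.atezolizumab", base_price * (1 - m))
    ).fit(itemised=False)
    assert abs(check.icer("AEP", "EP").value - wtp) < 500.0


def test_price_threshold_zero_at_wtp_equal_baseline(config, base_icer):
    m = price_threshold(config, "atezolizumab", ("AEP", "EP"),
                        wtp=base_icer, tolerance=500.0)
    assert m == pytest.approx(0.0, abs=0.01)


def test_price_threshold_requires_icer_above_wtp(config, base_icer):
    with pytest.raises(ValueError, match="not above"):
        price_threshold(config, "atezolizumab", ("AEP", "EP"),
                        wtp=base_icer * 2)


# --------------------------------------------------------------------------
# PSA
# --------------------------------------------------------------------------
def test_all_fixed_psa_degenerates_to_base_case(config, results):
    params = [
        ParamSpec(p.name, p.binding, p.baseline, p.baseline, p.baseline, "fixed")
        for p in resolve_params(config)
    ]
    psa = run_psa(config, n_draws=5, seed=1, params=params)
    for arm in ("EP", "AEP", "DEP"):
        sub = psa.draws[psa.draws["strategy"] == arm]
        assert np.allclose(sub["cost"], results.cost(arm))
        assert np.allclose(sub["qaly"], results.qaly(arm))


def test_psa_seed_reproducibility_byte_for_byte(config, tmp_path):
    a = run_psa(config, n_draws=40, seed=7)
    b = run_psa(config, n_draws=40, seed=7)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa)
    b.to_csv(pb)
    assert pa.read_bytes() == pb.read_bytes()
    c = run_psa(config, n_draws=40, seed=8)
    assert not a.draws.equals(c.draws)


def test_psa_draw_shape_and_positivity(config):
    psa = run_psa(config, n_draws=25, seed=3)
    assert len(psa.draws) == 25 * 3
    assert set(psa.draws["strategy"]) == {"EP", "AEP", "DEP"}
    assert (psa.draws["cost"] > 0).all()
    assert (psa.draws["qaly"] > 0).all()


def _toy_psa(n=400, seed=0):
    """Fixture PSA where strategy B always costs more and yields more QALYs."""
    rng = np.random.default_rng(seed)
    cost_a = rng.normal(1000.0, 50.0, n)
    qaly_a = rng.normal(1.0, 0.05, n)
    rows = []
    for i in range(n):
        rows.append((i, "A", cost_a[i], qaly_a[i]))
        rows.append((i, "B", cost_a[i] + abs(rng.normal(500.0, 50.0)),
                     qaly_a[i] + abs(rng.normal(0.2, 0.02))))
    return PSAResult(pd.DataFrame(rows, columns=["draw", "strategy", "cost",
                                                 "qaly"]), seed, n)


def test_ceac_normalises_and_is_monotone_for_ordered_pair():
    psa = _toy_psa()
    grid = np.arange(0, 20_001, 1_000)
    curve = ceac(psa, grid)
    wide = curve.pivot(index="wtp", columns="strategy", values="probability")
    assert np.allclose(wide.sum(axis=1), 1.0)
    assert ((curve["probability"] >= 0) & (curve["probability"] <= 1)).all()
    # B costs more and gains more in every draw: P(B) non-decreasing in WTP
    assert np.all(np.diff(wide["B"]) >= 0)
    assert wide["A"].iloc[0] == 1.0  # at WTP 0 the cheaper strategy wins


def test_ceac_single_strategy_probability_one():
    psa = _toy_psa(n=50)
    only = PSAResult(psa.draws[psa.draws["strategy"] == "A"], 0, 50)
    curve = ceac(only, [0, 50_000])
    assert np.allclose(curve["probability"], 1.0)


def test_ceac_empty_grid_rejected(config):
    psa = _toy_psa(n=10)
    with pytest.raises(ValueError):
        ceac(psa, [])


# --------------------------------------------------------------------------
# scenario
# --------------------------------------------------------------------------
def test_scenario_until_progression_structure(config, results):
    scenario = scenario_until_progression(config)
    # EP has no ICI line: identical cost and QALY
    assert scenario.cost("EP") == pytest.approx(results.cost("EP"), rel=1e-12)
    assert scenario.qaly("EP") == pytest.approx(results.qaly("EP"), rel=1e-12)
    # ICI arms accrue strictly more drug cost, with unchanged QALYs
    for arm in ("AEP", "DEP"):
        assert scenario.cost(arm) > results.cost(arm)
        assert scenario.qaly(arm) == pytest.approx(results.qaly(arm), rel=1e-12)
    # AEP still dominates DEP in the scenario
    assert scenario.icer("DEP", "AEP").status == "dominated"
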