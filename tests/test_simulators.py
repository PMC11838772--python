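"""Ground-truth properties of the synthetic-data generators."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import trajedit as te
from trajedit.simulators import (
    DEFAULT_TUMOR_CONFIG,
    TumorPatient,
    _tumor_step,
    _volume,
)


def test_noiseless_ratios_equal_rates_exactly():
    world = te.MultiplicativeWorld(n_variables=4, n_entities=6, n_steps=10,
                                   n_conditions=2, sigma=0.0, seed=1)
    ds = te.simulate_multiplicative(world)
    for tr in ds.trajectories:
        r = ds.rates[ds.entity_conditions[tr.entity_id]]
        ratios = tr.values[:, 1:] / tr.values[:, :-1]
        assert np.allclose(ratios, r[:, None], rtol=1e-12)


def test_kstep_true_concept_is_rate_power():
    world = te.MultiplicativeWorld(n_variables=3, n_entities=2, n_steps=12,
                                   sigma=0.0, seed=2)
    ds = te.simulate_multiplicative(world)
    tr = ds.trajectories[0]
    r = ds.rates[ds.entity_conditions[tr.entity_id]]
    k = 5
    assert np.allclose(ds.true_concept(tr.entity_id, 3, 3 + k), r**k)
    assert np.allclose(tr.values[:, 3 + k] / tr.values[:, 3], r**k, rtol=1e-12)


def test_unit_rates_give_constant_trajectories():
    world = te.MultiplicativeWorld(n_variables=2, n_entities=3, n_steps=8,
                                   n_conditions=1, sigma=0.0,
                                   rate_low=1.0, rate_high=1.0, seed=3)
    ds = te.simulate_multiplicative(world)
    for tr in ds.trajectories:
        assert np.allclose(tr.values, tr.values[:, :1])


def test_simulator_is_bit_deterministic():
    world = te.MultiplicativeWorld(n_entities=5, n_steps=8, sigma=0.3, seed=4)
    a = te.simulate_multiplicative(world)
    b = te.simulate_multiplicative(world)
    for ta, tb in zip(a.trajectories, b.trajectories):
        assert np.array_equal(ta.values, tb.values)
    for tok in a.table.tokens():
        assert np.array_equal(a.table.lookup(tok), b.table.lookup(tok))


def test_counterfactual_pair_shares_history_bitwise():
    world = te.MultiplicativeWorld(n_variables=3, n_steps=20, sigma=0.2, seed=5)
    a, b = te.simulate_counterfactual_pair(world, 17, "cond_0", "cond_1", 8)
    assert np.array_equal(a.values[:, :8], b.values[:, :8])
    assert not np.array_equal(a.values[:, 8:], b.values[:, 8:])
    sa, sb = te.simulate_counterfactual_pair(world, 17, "cond_0", "cond_0", 8)
    assert np.array_equal(sa.values, sb.values)  # same condition -> identical


def test_counterfactual_pair_noiseless_log_ratio():
    world = te.MultiplicativeWorld(n_variables=2, n_steps=15, sigma=0.0, seed=6)
    a, b = te.simulate_counterfactual_pair(world, 3, "cond_0", "cond_1", 5)
    rates = world.rates()
    dlog = np.log(rates["cond_0"]) - np.log(rates["cond_1"])
    for k in range(1, 10):
        got = np.log(a.values[:, 5 - 1 + k]) - np.log(b.values[:, 5 - 1 + k])
        assert np.allclose(got, k * dlog, atol=1e-10)


def test_tumor_unconfounded_assignment_is_uncorrelated():
    world = te.TumorWorld(n_patients=40, n_steps=30, gamma=0.0, seed=7)
    ds = te.simulate_tumor(world)
    assert abs(te.assignment_volume_correlation(ds)) < 0.05  # 1200 patient-steps


def test_tumor_confounding_is_monotone_in_gamma():
    corrs = []
    for gamma in (0.0, 1.0, 2.0, 4.0):
        ds = te.simulate_tumor(te.TumorWorld(n_patients=40, n_steps=30,
                                             gamma=gamma, seed=7))
        corrs.append(te.assignment_volume_correlation(ds))
    assert all(b >= a for a, b in zip(corrs, corrs[1:]))
    assert corrs[-1] > 0.1


def test_tumor_strong_confounding_treated_have_larger_volumes():
    ds = te.simulate_tumor(te.TumorWorld(n_patients=40, n_steps=30, gamma=10.0, seed=8))
    treated, untreated = [], []
    for tr in ds.trajectories:
        toks = ds.treatments[tr.entity_id]
        for t, tok in enumerate(toks):
            lo = max(0, t - 2)
            (treated if tok != "none" else untreated).append(tr.values[0, lo:t + 1].mean())
    stat = mannwhitneyu(treated, untreated, alternative="greater")
    assert stat.pvalue < 1e-6


def test_untreated_noiseless_growth_is_monotone_toward_capacity():
    cfg = dict(DEFAULT_TUMOR_CONFIG)
    K = _volume(cfg["d_max_cm"])
    pat = TumorPatient(rho=0.1, beta_c=0.03, alpha_r=0.04, beta_r=0.004,
                       v0=_volume(6.0), noise=np.zeros(200))
    v, c = pat.v0, 0.0
    prev = v
    for t in range(200):
        v, c, _ = _tumor_step(pat, cfg, K, v, c, "none", 0.0)
        assert v > prev or np.isclose(v, K, rtol=1e-3)
        prev = v
    assert v == pytest.approx(K, rel=1e-2)


def test_tumor_step_clamps_at_volume_floor():
    cfg = dict(DEFAULT_TUMOR_CONFIG)
    pat = TumorPatient(rho=0.1, beta_c=10.0, alpha_r=0.04, beta_r=0.004,
                       v0=1.0, noise=np.zeros(4))
    v, c, clamped = _tumor_step(pat, cfg, _volume(13.0), 1.0, 20.0, "chemo", 0.0)
    assert clamped and v == cfg["volume_floor"]


def test_benchmark_split_single_sliding_combinatorics():
    ds = te.simulate_tumor(te.TumorWorld(n_patients=3, n_steps=20, gamma=1.0, seed=9))
    tasks = te.make_benchmark_split(ds, "single-sliding", tau_max=5)
    assert len(tasks) == 3 * 5  # one plan per offset per patient
    plans = {t.plan for t in tasks if t.entity_id == "patient_0000"}
    assert all(sum(tok == "chemo" for tok in p) == 1 for p in plans)
    with pytest.raises(ValueError, match="horizon"):
        te.make_benchmark_split(ds, "single-sliding", tau_max=25)


def test_benchmark_truth_matches_resimulation_bitwise():
    ds = te.simulate_tumor(te.TumorWorld(n_patients=2, n_steps=15, gamma=0.5, seed=10))
    tasks = te.make_benchmark_split(ds, "random", tau_max=3, seed=1)
    for task in tasks:
        again = te.resimulate_tumor(ds, task.entity_id, task.history_end, list(task.plan))
        assert np.array_equal(task.truth, again)


def test_resimulation_of_observed_plan_reproduces_factual_arm():
    ds = te.simulate_tumor(te.TumorWorld(n_patients=2, n_steps=15, gamma=0.5, seed=11))
    tr = ds.trajectories[0]
    toks = ds.treatments[tr.entity_id]
    redo = te.resimulate_tumor(ds, tr.entity_id, 5, toks[5:10])
    assert np.allclose(redo[0], tr.values[0, 6:11], rtol=1e-12)
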