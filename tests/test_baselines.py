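"""SimpleLinear ablation, VAR baseline, and autoregressive rollout."""

import numpy as np
import pytest

import trajedit as te
from trajedit.baselines import autoregressive_conditional_forecast


def test_simple_linear_is_identity_and_all_ones_concept(tiny_model):
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.uniform(0.01, 1.0, size=4)
        assert np.array_equal(te.simple_linear_forecast(x), x)
        assert np.array_equal(
            te.simple_linear_forecast(x), tiny_model.decode_concept(np.ones(4), x)
        )


def test_simple_linear_exact_on_constant_world():
    world = te.MultiplicativeWorld(
        n_variables=2, n_entities=5, n_steps=8, n_conditions=1,
        sigma=0.0, rate_low=1.0, rate_high=1.0, seed=0,
    )
    ds = te.simulate_multiplicative(world)
    errs = [
        np.abs(te.simple_linear_forecast(tr.values[:, t]) - tr.values[:, t + 1]).max()
        for tr in ds.trajectories
        for t in range(tr.n_times - 1)
    ]
    assert max(errs) == 0.0


def _linear_world(A, T=40, n=20, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    V = A.shape[0]
    trajectories = []
    for e in range(n):
        x = np.empty((V, T))
        x[:, 0] = rng.uniform(1, 2, size=V)
        for t in range(T - 1):
            x[:, t + 1] = A @ x[:, t] + noise * rng.normal(size=V)
        trajectories.append(
            te.Trajectory(f"e{e}", [f"v{i}" for i in range(V)], np.arange(T), x,
                          np.ones((V, T), dtype=bool))
        )
    return trajectories


def test_var_recovers_known_transition_matrix():
    A = np.array([[0.9, 0.1], [-0.2, 0.8]])
    model = te.fit_var(_linear_world(A), p=1)
    assert np.max(np.abs(model.coefs[0] - A)) <= 1e-6
    assert np.max(np.abs(model.intercept)) <= 1e-6


def test_var_on_white_noise_shrinks_to_zero():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, 10_000))
    tr = te.Trajectory("e", ["a", "b"], np.arange(10_000), x,
                       np.ones_like(x, dtype=bool))
    model = te.fit_var([tr], p=1)
    assert np.max(np.abs(model.coefs)) < 0.05


def test_var_lag_exceeding_length_raises():
    trs = _linear_world(np.eye(1), T=4, n=1)
    with pytest.raises(ValueError, match="lag order"):
        te.fit_var(trs, p=4)


def test_var_matches_normal_equations_and_statsmodels():
    A = np.array([[0.7, 0.2], [0.0, 0.5]])
    trs = _linear_world(A, T=60, n=1, noise=0.05, seed=3)
    model = te.fit_var(trs, p=1)
    # brute-force normal equations on the same pooled design
    X = np.stack([np.concatenate([trs[0].values[:, t - 1], [1.0]]) for t in range(1, 60)])
    Y = np.stack([trs[0].values[:, t] for t in range(1, 60)])
    B = np.linalg.solve(X.T @ X, X.T @ Y)
    assert np.max(np.abs(model.coefs[0] - B[:2].T)) <= 1e-8
    # independent implementation: statsmodels VAR on the single series
    from statsmodels.tsa.api import VAR as SmVAR

    sm = SmVAR(trs[0].values.T).fit(maxlags=1, trend="c")
    assert np.allclose(model.coefs[0], sm.coefs[0], atol=1e-6)
    assert np.allclose(model.intercept, sm.intercept, atol=1e-6)


def test_var_rollout_base_case_and_stability_regimes():
    hist = np.array([[1.0, 1.1], [2.0, 1.9]])
    expanding = te.VarModel(1, np.array([[[1.3, 0.0], [0.0, 1.2]]]), np.zeros(2))
    roll = te.var_rollout(expanding, hist, 1)
    assert np.allclose(roll[:, 0], expanding.predict_next(hist))
    # spectral radius > 1: norms eventually grow monotonically
    norms = np.linalg.norm(te.var_rollout(expanding, hist, 30), axis=0)
    assert np.all(np.diff(norms[5:]) > 0)
    # spectral radius < 1, zero intercept: decay toward 0
    contracting = te.VarModel(1, np.array([[[0.5, 0.1], [0.0, 0.4]]]), np.zeros(2))
    decay = te.var_rollout(contracting, hist, 40)
    assert np.linalg.norm(decay[:, -1]) < 1e-6


def test_var_rollout_overflow_becomes_inf_marker():
    blowup = te.VarModel(1, np.array([[[1e200]]]), np.zeros(1))
    roll = te.var_rollout(blowup, np.array([[1e200]]), 4)
    assert np.isinf(roll[0, -1])  # run continues, divergence is reported


def test_var_json_roundtrip():
    m = te.VarModel(2, np.arange(8, dtype=float).reshape(2, 2, 2), np.array([1.0, -1.0]))
    m2 = te.VarModel.from_json(m.to_json())
    assert m2.p == 2
    assert np.array_equal(m2.coefs, m.coefs)
    assert np.array_equal(m2.intercept, m.intercept)


def test_autoregressive_rollout_counts_and_purity(tiny_model, tiny_dataset, tiny_scaler):
    tr = tiny_dataset.trajectories[0]
    tok = tiny_dataset.entity_conditions[tr.entity_id]
    vals, mask = tr.values.copy(), tr.mask.copy()

    # gap=1 reduces to a single forward call
    before = tiny_model.decode_count
    final, inter = autoregressive_conditional_forecast(tiny_model, tr, 4, tok, 1, tiny_scaler)
    assert tiny_model.decode_count - before == 1
    direct, _ = tiny_model.forecast(te.EditRequest(tr.entity_id, 4, tok, 5), tr, tiny_scaler)
    assert np.array_equal(final, direct)

    # gap=g calls the one-step model exactly g times; input untouched
    before = tiny_model.decode_count
    final, inter = autoregressive_conditional_forecast(tiny_model, tr, 4, tok, 5, tiny_scaler)
    assert tiny_model.decode_count - before == 5
    assert inter.shape == (3, 5)
    assert np.array_equal(tr.values, vals)
    assert np.array_equal(tr.mask, mask)


def test_rollout_error_compounds_on_ramp_but_direct_does_not(tiny_dataset, tiny_scaler):
    """A biased one-step forecaster drifts further with every rollout step,
    while a one-step delayed call applies its (single) error once."""

    class BiasedStepper:
        """Stub one-step model: predicts truth * 1.05 from the last value."""

        def __init__(self):
            self.decode_count = 0

        def forecast(self, req, tr, scaler):
            self.decode_count += 1
            return tr.values[:, req.history_end] * 1.05, np.ones(tr.n_variables)

    tr = tiny_dataset.trajectories[0].copy()
    tr.values[:] = 1.0  # flat truth: any multiplicative bias compounds
    stub = BiasedStepper()
    _, inter = autoregressive_conditional_forecast(stub, tr, 3, None, 6, tiny_scaler)
    errors = np.abs(inter - 1.0).mean(axis=0)
    assert np.all(np.diff(errors) > 0)  # strictly growing with rollout depth
    assert errors[0] == pytest.approx(0.05, rel=1e-9)
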