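"""Counterfactual prediction, balancing, and concept intervention."""

import numpy as np
import pytest

import trajedit as te
from trajedit.counterfactual import extend_trajectory

from conftest import identity_scaler


def test_tau_one_equals_single_forecast(tiny_model, tiny_dataset, tiny_scaler):
    tr = tiny_dataset.trajectories[2]
    tok = tiny_dataset.entity_conditions[tr.entity_id]
    out = te.tau_step_predict(tiny_model, tr, 5, [tok], tiny_scaler)
    direct, _ = tiny_model.forecast(te.EditRequest(tr.entity_id, 5, tok, 6), tr, tiny_scaler)
    assert np.array_equal(out[:, 0], direct)


def test_tau_step_composition(tiny_model, tiny_dataset, tiny_scaler):
    """Predicting a+b steps equals predicting a, extending, then b more."""
    tr = tiny_dataset.trajectories[1]
    tok = tiny_dataset.entity_conditions[tr.entity_id]
    plan = [tok, None, tok, tok, None]
    full = te.tau_step_predict(tiny_model, tr, 4, plan, tiny_scaler)
    part = te.tau_step_predict(tiny_model, tr, 4, plan[:2], tiny_scaler)
    work = tr.copy()
    work.values[:, 5:7] = part
    work.mask[:, 5:7] = True
    rest = te.tau_step_predict(tiny_model, work, 6, plan[2:], tiny_scaler)
    assert np.allclose(full[:, 2:], rest, atol=1e-12)
    assert np.array_equal(full[:, :2], part)


def test_divergent_plans_diverge(tiny_model, tiny_dataset, tiny_scaler):
    tr = tiny_dataset.trajectories[3]
    a = te.tau_step_predict(tiny_model, tr, 4, ["cond_0"] * 5, tiny_scaler)
    b = te.tau_step_predict(tiny_model, tr, 4, ["cond_1"] * 5, tiny_scaler)
    assert np.max(np.abs(a - b)) > 0


def test_balanced_train_lambda_zero_is_plain_training(tiny_dataset, tiny_scaler):
    triples = tiny_dataset.training_triples(3, {1})
    cfg = te.TrainConfig(max_epochs=2, patience=2, seed=6)
    m1 = te.ConceptEditor(tiny_dataset.trajectories[0].variables, tiny_dataset.table,
                          d_h=8, seed=6)
    _, rep1 = te.train(m1, triples, tiny_scaler, cfg)
    m2 = te.ConceptEditor(tiny_dataset.trajectories[0].variables, tiny_dataset.table,
                          d_h=8, seed=6)
    _, rep2 = te.balanced_train(m2, triples, tiny_scaler, cfg, lam=0.0)
    assert rep1.train_losses == rep2.train_losses
    for k in m1.params:
        assert np.array_equal(m1.params[k].data, m2.params[k].data)


def test_balanced_train_single_treatment_warns(tiny_dataset, tiny_scaler):
    triples = [
        (tr, te.EditRequest(req.entity_id, req.history_end, "cond_0", req.target_index))
        for tr, req in tiny_dataset.training_triples(3, {1})
    ]
    cfg = te.TrainConfig(max_epochs=1, patience=1, seed=6)
    m = te.ConceptEditor(tiny_dataset.trajectories[0].variables, tiny_dataset.table,
                         d_h=8, seed=6)
    with pytest.warns(UserWarning, match="balancing skipped"):
        te.balanced_train(m, triples, tiny_scaler, cfg, lam=1.0)


def test_intervene_concept_locality():
    c = np.array([1.2, 0.8, 1.0])
    spec = te.InterventionSpec({"glucose": 0.5}, horizon=3)
    out = te.intervene_concept(c, spec, ["glucose", "wbc", "sodium"])
    assert out[0] == pytest.approx(0.6)
    assert out[1] == c[1] and out[2] == c[2]  # untargeted entries bit-unchanged
    ident = te.intervene_concept(c, te.InterventionSpec({"wbc": 1.0}),
                                 ["glucose", "wbc", "sodium"])
    assert np.array_equal(ident, c)
    with pytest.raises(ValueError, match="unknown"):
        te.intervene_concept(c, te.InterventionSpec({"xyz": 2.0}), ["glucose"])


def test_halving_concept_halves_exactly_that_prediction(tiny_model, tiny_dataset):
    scaler = identity_scaler(tiny_dataset.trajectories[0].variables)
    tr = tiny_dataset.trajectories[0]
    tok = tiny_dataset.entity_conditions[tr.entity_id]
    req = te.EditRequest(tr.entity_id, 5, tok, 6)
    pred, c = tiny_model.forecast(req, tr, scaler)
    spec = te.InterventionSpec({tr.variables[0]: 0.5})
    c_int = te.intervene_concept(c, spec, tr.variables)
    x_last = scaler.apply(tr.values[:, 5:6])[:, 0]
    pred_int = scaler.invert(tiny_model.decode_concept(c_int, x_last))
    assert pred_int[0] == pytest.approx(0.5 * pred[0], rel=1e-12)
    assert np.array_equal(pred_int[1:], pred[1:])


class AllOnesEditor(te.ConceptEditor):
    """Stub whose concept is always 1 (last observation carried forward)."""

    def encode_concept(self, h_x, delta, h_s):
        from trajedit.autodiff import Tensor

        return Tensor(np.ones((h_x.shape[0], len(self.variables))))


def test_sustained_halving_gives_geometric_decay(tiny_dataset):
    variables = tiny_dataset.trajectories[0].variables
    scaler = identity_scaler(variables)
    model = AllOnesEditor(variables, tiny_dataset.table, d_h=8, seed=0)
    tr = tiny_dataset.trajectories[0].copy()
    tr.values[:] = 1.0
    spec = te.InterventionSpec({variables[0]: 0.5}, horizon=6)
    gen = te.intervened_rollout(model, tr, 4, spec, scaler)
    assert np.allclose(gen.values[0], 0.5 ** np.arange(1, 7), rtol=1e-12)
    assert np.allclose(gen.values[1:], 1.0)


def test_identity_intervention_equals_plain_rollout(tiny_model, tiny_dataset, tiny_scaler):
    tr = tiny_dataset.trajectories[2]
    variables = tr.variables
    spec1 = te.InterventionSpec({variables[0]: 1.0}, horizon=5)
    gen = te.intervened_rollout(tiny_model, tr, 4, spec1, tiny_scaler)
    plain = te.tau_step_predict(tiny_model, tr, 4, [None] * 5, tiny_scaler)
    assert np.allclose(gen.values, plain, atol=1e-12)
    # history preserved
    assert gen.n_times == 5


def coupled_dataset(seed=0, n=40, T=15):
    """Variable b is driven by lagged variable a: the coupling a model can learn.

    The driver a carries fresh per-step noise and b relaxes toward it, so
    b's next value cannot be predicted from b's own history alone — the
    model must read a's current level.
    """
    rng = np.random.default_rng(seed)
    trajectories = []
    for e in range(n):
        a = np.empty(T)
        b = np.empty(T)
        a[0] = rng.uniform(1, 2)
        b[0] = rng.uniform(1, 2)
        for t in range(T - 1):
            a[t + 1] = a[t] * np.exp(0.3 * rng.standard_normal())
            b[t + 1] = 0.2 * b[t] + 0.8 * a[t]
        vals = np.stack([a, b])
        trajectories.append(
            te.Trajectory(f"e{e}", ["a", "b"], np.arange(T), vals,
                          np.ones_like(vals, dtype=bool))
        )
    return trajectories


def test_indirect_effect_through_coupling():
    """Intervening only on the driver changes the driven variable's rollout."""
    trajectories = coupled_dataset()
    scaler = te.fit_scaling(trajectories)
    table = te.ConditionTable.random(["c"], d_z=4, rng=np.random.default_rng(0))
    model = te.ConceptEditor(["a", "b"], table, d_h=24, seed=1)
    triples = [
        (tr, te.EditRequest(tr.entity_id, w.history_end, None, w.target_index))
        for tr in trajectories
        for w in te.make_edit_windows(tr, 3, {1})
    ]
    cfg = te.TrainConfig(max_epochs=60, patience=60, seed=1, learning_rate=2e-2,
                         batch_size=64)
    model, _ = te.train(model, triples, scaler, cfg)
    tr = trajectories[0]
    base = te.intervened_rollout(model, tr, 8, te.InterventionSpec({"a": 1.0}, 5), scaler)
    halved = te.intervened_rollout(model, tr, 8, te.InterventionSpec({"a": 0.5}, 5), scaler)
    assert np.max(np.abs(halved.values[1] - base.values[1])) > 0.01  # b responds to a


def test_cohort_similarity_identities():
    times = np.arange(4)
    mask = np.ones((2, 4), dtype=bool)
    ref = te.Trajectory("r", ["x", "y"], times,
                        np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8]]), mask)
    same = te.cohort_similarity(ref, ref)
    assert same == pytest.approx(1.0)
    means = ref.copy()
    means.values = np.repeat(ref.values.mean(axis=1, keepdims=True), 4, axis=1)
    assert te.cohort_similarity(means, ref) == pytest.approx(0.0)
    anti = ref.copy()
    anti.values = ref.values[:, ::-1].copy()
    assert te.cohort_similarity(anti, ref) < 0


def test_cohort_similarity_zero_variance_is_nan():
    times = np.arange(3)
    mask = np.ones((1, 3), dtype=bool)
    flat = te.Trajectory("r", ["x"], times, np.full((1, 3), 2.0), mask)
    gen = te.Trajectory("g", ["x"], times, np.array([[1.0, 2, 3]]), mask)
    assert np.isnan(te.cohort_similarity(gen, flat))


def test_extend_trajectory_appends_unobserved_steps(tiny_dataset):
    tr = tiny_dataset.trajectories[0]
    ext = extend_trajectory(tr, 3)
    assert ext.n_times == tr.n_times + 3
    assert not ext.mask[:, -3:].any()
    assert np.array_equal(ext.times[-3:], tr.times[-1] + np.arange(1, 4))
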