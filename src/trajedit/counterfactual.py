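"""Counterfactual prediction, adversarial balancing, and concept intervention.

* :func:`tau_step_predict` estimates tau-step-ahead counterfactual outcomes
  under a planned treatment sequence by iterating the one-step conditional
  forecast, conditioning each step on the next planned treatment.
* :func:`balanced_train` adds a treatment-classifier head connected to the
  history representation h_x through a gradient-reversal unit, so the encoder
  is pushed toward treatment-invariant (balanced) representations while the
  main Huber objective is unchanged.  With lambda = 0 it is exactly plain
  training.
* :func:`intervene_concept` / :func:`intervened_rollout` edit entries of the
  learned temporal concept directly (e.g. halve one variable's rate) and
  simulate the resulting counterfactual trajectory; because the decoder is
  multiplicative, scaling a concept entry by f scales exactly that variable's
  one-step prediction by f.
* :func:`cohort_similarity` scores a generated trajectory against a reference
  with a pooled, variance-normalized R^2.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import grad_reverse, softmax_cross_entropy
from .data import EditRequest, ScalingSpec, Trajectory
from .model import ConceptEditor, collate, huber_loss
from .nn import Adam, Affine
from .training import TrainConfig, TrainReport, Triple, evaluate, split_by_entity, train

logger = logging.getLogger(__name__)


def extend_trajectory(trajectory: Trajectory, n_extra: int) -> Trajectory:
    """Append ``n_extra`` future time points (unobserved) to a copy."""
    tr = trajectory.copy()
    if np.issubdtype(tr.times.dtype, np.datetime64):
        step = tr.times[-1] - tr.times[-2]
    else:
        step = tr.times[-1] - tr.times[-2]
    extra_times = tr.times[-1] + step * np.arange(1, n_extra + 1)
    tr.times = np.concatenate([tr.times, extra_times])
    tr.values = np.concatenate([tr.values, np.zeros((tr.n_variables, n_extra))], axis=1)
    tr.mask = np.concatenate(
        [tr.mask, np.zeros((tr.values.shape[0], n_extra), dtype=bool)], axis=1
    )
    return tr


def tau_step_predict(
    model: ConceptEditor,
    trajectory: Trajectory,
    history_end: int,
    planned: list[str | None],
    scaler: ScalingSpec,
) -> np.ndarray:
    """Iterated one-step conditional forecasts under a planned treatment plan.

    Step k conditions on ``planned[k]`` and appends its prediction to the
    rolling history; returns (V, tau) raw-unit predictions.  The input
    trajectory is untouched.
    """
    tau = len(planned)
    if tau < 1:
        raise ValueError("planned treatment sequence must have length tau >= 1")
    work = trajectory.copy()
    if history_end + tau >= work.n_times:
        work = extend_trajectory(work, history_end + tau - work.n_times + 1)
    out = np.empty((trajectory.n_variables, tau))
    for k, token in enumerate(planned):
        t_i = history_end + k
        req = EditRequest(work.entity_id, t_i, token, t_i + 1)
        pred, _ = model.forecast(req, work, scaler)
        out[:, k] = pred
        work.values[:, t_i + 1] = pred
        work.mask[:, t_i + 1] = True
    return out


def history_representations(
    model: ConceptEditor, triples: list[Triple], scaler: ScalingSpec, batch_size: int = 256
) -> np.ndarray:
    """h_x vectors for a triple list (for probing treatment information)."""
    outs = []
    for i in range(0, len(triples), batch_size):
        batch = collate(triples[i : i + batch_size], scaler)
        _, _, h_x = model.forward_with_representation(batch)
        outs.append(h_x.data.copy())
    return np.concatenate(outs)


#: relative weight of the adversarial term; ``lam`` multiplies this, so
#: lam = 1 exerts a moderate, accuracy-preserving amount of pressure
ADVERSARIAL_WEIGHT = 0.1


def balanced_train(
    model: ConceptEditor,
    triples: list[Triple],
    scaler: ScalingSpec,
    config: TrainConfig,
    lam: float = 1.0,
    head_learning_rate: float = 3e-2,
    checkpoint_metric=None,
) -> tuple[ConceptEditor, TrainReport]:
    """Train with an adversarial treatment classifier on h_x.

    The classifier predicts the assigned treatment token from the history
    representation; its gradient reaches the encoder through a
    gradient-reversal unit, pushing h_x toward treatment invariance.
    ``lam = 0`` disables balancing and is bit-identical to
    :func:`~trajedit.training.train` under the same seed.

    Three stabilizers, all standard for adversarial balancing:

    * the reversal strength ramps up over training,
      lam_t = lam * W * (2 / (1 + exp(-10 p)) - 1) with p the progress and W
      a fixed relative weight — switching the adversary on abruptly drives
      representations into a confidently-wrong (anti-predictive) regime;
    * the classifier head gets its own, faster optimizer so it tracks the
      moving representations;
    * the returned checkpoint is the best-validation epoch *within the
      fully-ramped final third* — selecting by forecast loss alone would
      systematically prefer the least-balanced early epochs.

    ``checkpoint_metric`` (model -> float, lower is better) replaces the
    one-step validation loss for that selection; iterated-prediction tasks
    are better selected by an iterated-prediction metric, since the epoch
    with the best one-step loss is not necessarily the best roll-forward
    model.

    The trained adversary is attached to the model as
    ``model.treatment_head`` (with ``model.treatment_vocab``).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    vocab = sorted({req.condition for _, req in triples if req.condition is not None})
    if lam == 0 and checkpoint_metric is None:
        return train(model, triples, scaler, config)
    if len(vocab) < 2:
        warnings.warn("single-treatment dataset: balancing skipped", stacklevel=2)
        return train(model, triples, scaler, config)
    tok_idx = {t: i for i, t in enumerate(vocab)}

    head_params: dict = {}
    head_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    head = Affine(head_params, "treat_head", model.d_h, len(vocab), head_rng)

    rng = np.random.default_rng(config.seed)
    train_set, val_set = split_by_entity(triples, config.val_fraction, config.seed)
    if not val_set:
        val_set = train_set
    opt = Adam(model.params, lr=config.learning_rate)
    opt_head = Adam(head_params, lr=head_learning_rate)
    report = TrainReport()
    best_val = np.inf
    best_blob: tuple | None = None
    restore_from = (2 * config.max_epochs) // 3
    from .nn import clone_params, load_params
    from .training import _epoch_loss, _resample_gaps

    for epoch in range(config.max_epochs):
        progress = (epoch + 1) / config.max_epochs
        lam_t = lam * ADVERSARIAL_WEIGHT * (2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0)
        epoch_triples = _resample_gaps(train_set, config.horizon_set, rng)
        order = rng.permutation(len(epoch_triples))
        epoch_triples = [epoch_triples[i] for i in order]
        running, seen = 0.0, 0
        for bi in range(0, len(epoch_triples), config.batch_size):
            chunk = epoch_triples[bi : bi + config.batch_size]
            batch = collate(chunk, scaler)
            labels = np.array([tok_idx[req.condition] for _, req in chunk])
            opt.zero_grad()
            opt_head.zero_grad()
            pred, _, h_x = model.forward_with_representation(batch)
            main = huber_loss(batch.y, pred, batch.y_mask, config.huber_delta)
            adv = softmax_cross_entropy(head(grad_reverse(h_x, lam_t)), labels)
            loss = main + adv
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {bi}")
            loss.backward()
            opt.step()
            opt_head.step()
            k = batch.y_mask.sum()
            running += float(main.data) * k
            seen += k
        report.train_losses.append(running / max(seen, 1))
        val_loss = _epoch_loss(model, val_set, scaler, config)
        report.val_losses.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            report.best_epoch = epoch
        if epoch >= restore_from:
            score = checkpoint_metric(model) if checkpoint_metric else val_loss
            if best_blob is None or score <= best_blob[0]:
                best_blob = (score, clone_params(model.params), clone_params(head_params))
    if best_blob is not None:
        load_params(model.params, best_blob[1])
        load_params(head_params, best_blob[2])
    model.treatment_head = head
    model.treatment_vocab = vocab
    report.final_metrics = evaluate(model, val_set, scaler).overall
    return model, report


@dataclass
class InterventionSpec:
    """Per-variable multiplicative factors on the concept, and a rollout length."""

    factors: dict[str, float]
    horizon: int = 10

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("rollout length must be >= 1")
        for k, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"intervention factor for {k!r} must be > 0")

    def to_json(self) -> str:
        return json.dumps({"factors": self.factors, "horizon": self.horizon}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "InterventionSpec":
        d = json.loads(text)
        return cls(d["factors"], d.get("horizon", 10))


def intervene_concept(
    concept: np.ndarray, spec: InterventionSpec, variables: list[str]
) -> np.ndarray:
    """c^I: targeted entries multiplied by their factors, others bit-unchanged."""
    unknown = set(spec.factors) - set(variables)
    if unknown:
        raise ValueError(f"intervention targets unknown variables: {sorted(unknown)}")
    out = np.asarray(concept, dtype=np.float64).copy()
    for name, f in spec.factors.items():
        out[variables.index(name)] *= f
    return out


def intervened_rollout(
    model: ConceptEditor,
    trajectory: Trajectory,
    history_end: int,
    spec: InterventionSpec,
    scaler: ScalingSpec,
    condition: str | None = None,
) -> Trajectory:
    """Generate a counterfactual trajectory of length ``spec.horizon``.

    Each step recomputes the concept from the rolling history, re-applies the
    intervention factors (a persistent intervention), decodes, and appends.
    The original history is untouched; the returned trajectory holds only the
    generated steps.
    """
    work = trajectory.copy()
    need = history_end + spec.horizon - work.n_times + 1
    if need > 0:
        work = extend_trajectory(work, need)
    V = work.n_variables
    gen = np.empty((V, spec.horizon))
    for k in range(spec.horizon):
        t_i = history_end + k
        req = EditRequest(work.entity_id, t_i, condition, t_i + 1)
        _, concept = model.forecast(req, work, scaler)
        c_int = intervene_concept(concept, spec, work.variables)
        x_last = np.where(
            work.mask[:, t_i],
            scaler.apply(work.values[:, t_i : t_i + 1])[:, 0],
            0.0,
        )
        pred_scaled = model.decode_concept(c_int, x_last)
        pred = scaler.invert(pred_scaled)
        gen[:, k] = pred
        work.values[:, t_i + 1] = pred
        work.mask[:, t_i + 1] = True
    times = work.times[history_end + 1 : history_end + spec.horizon + 1]
    return Trajectory(
        f"{trajectory.entity_id}::generated",
        list(work.variables),
        times,
        gen,
        np.ones_like(gen, dtype=bool),
    )


def cohort_similarity(
    generated: Trajectory,
    reference: Trajectory,
    shared_variables: list[str] | None = None,
) -> float:
    """Pooled variance-normalized R^2 of reference against generated values.

    Trajectories are aligned by step index and truncated to the common
    length; each shared variable is scaled by the reference's standard
    deviation before pooling.  Returns NaN when the reference has no variance.
    """
    if shared_variables is None:
        shared_variables = [v for v in generated.variables if v in reference.variables]
    if not shared_variables:
        raise ValueError("no shared variables to compare")
    L = min(generated.n_times, reference.n_times)
    ss_res, ss_tot = 0.0, 0.0
    for name in shared_variables:
        g = generated.values[generated.variables.index(name), :L]
        r = reference.values[reference.variables.index(name), :L]
        sd = r.std()
        if sd == 0:
            return float("nan")
        ss_res += (((r - g) / sd) ** 2).sum()
        ss_tot += (((r - r.mean()) / sd) ** 2).sum()
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot
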