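"""Supervised training of the concept editor, plus evaluation metrics.

Training minimizes the mean Huber loss (delta = 1) over mask-true targets in
the scaled working range.  Immediate and delayed editing share one forward
path; only the gap between history end and target differs.  When the horizon
set has several gaps, a gap is drawn uniformly per example each epoch.

Evaluation reports MAE, RMSE and R^2 in raw (unscaled) units over mask-true
cells, with per-gap and per-target-step breakdowns.  A zero-variance truth
makes R^2 undefined; it is reported as NaN, never raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EditRequest, ScalingSpec, Trajectory
from .model import Batch, ConceptEditor, collate, huber_loss
from .nn import Adam, clone_params, load_params

Triple = tuple[Trajectory, EditRequest]


@dataclass
class TrainConfig:
    learning_rate: float = 5e-3
    batch_size: int = 128
    max_epochs: int = 60
    patience: int = 8
    horizon_set: tuple[int, ...] = (1,)
    seed: int = 0
    huber_delta: float = 1.0
    val_fraction: float = 0.2

    def __post_init__(self):
        if not self.horizon_set:
            raise ValueError("horizon_set must be nonempty")
        if min(self.horizon_set) < 1:
            raise ValueError("horizons must be positive")

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["horizon_set"] = list(self.horizon_set)
        return json.dumps(d, indent=2)


@dataclass
class TrainReport:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    final_metrics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=float)


def split_by_entity(
    triples: list[Triple], val_fraction: float, seed: int
) -> tuple[list[Triple], list[Triple]]:
    """Entity-level train/validation split (no entity appears in both)."""
    ids = sorted({tr.entity_id for tr, _ in triples})
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_val = max(1, int(round(val_fraction * len(ids)))) if len(ids) > 1 else 0
    val_ids = set(ids[:n_val])
    train = [t for t in triples if t[0].entity_id not in val_ids]
    val = [t for t in triples if t[0].entity_id in val_ids]
    assert not ({tr.entity_id for tr, _ in train} & {tr.entity_id for tr, _ in val})
    return train, val


def _resample_gaps(
    triples: list[Triple], horizon_set: tuple[int, ...], rng: np.random.Generator
) -> list[Triple]:
    if len(horizon_set) == 1:
        return triples
    out = []
    hs = np.asarray(sorted(horizon_set))
    for tr, req in triples:
        feasible = hs[req.history_end + hs < tr.n_times]
        g = int(rng.choice(feasible)) if feasible.size else req.gap
        out.append((tr, EditRequest(req.entity_id, req.history_end, req.condition,
                                    req.history_end + g)))
    return out


def _epoch_loss(model: ConceptEditor, triples: list[Triple], scaler: ScalingSpec,
                cfg: TrainConfig) -> float:
    total, n = 0.0, 0
    for i in range(0, len(triples), cfg.batch_size):
        batch = collate(triples[i : i + cfg.batch_size], scaler)
        pred, _ = model.forward_batch(batch)
        loss = huber_loss(batch.y, pred, batch.y_mask, cfg.huber_delta)
        k = batch.y_mask.sum()
        total += float(loss.data) * k
        n += k
    return total / max(n, 1)


def train(
    model: ConceptEditor,
    triples: list[Triple],
    scaler: ScalingSpec,
    config: TrainConfig,
) -> tuple[ConceptEditor, TrainReport]:
    """Train on edit triples; early-stops on entity-held-out validation loss.

    Deterministic given ``config.seed``; returns the best-validation
    checkpoint loaded back into ``model``.
    """
    rng = np.random.default_rng(config.seed)
    train_set, val_set = split_by_entity(triples, config.val_fraction, config.seed)
    if not val_set:
        val_set = train_set
    opt = Adam(model.params, lr=config.learning_rate)
    report = TrainReport()
    best_val = np.inf
    best_blob = clone_params(model.params)
    since_best = 0
    for epoch in range(config.max_epochs):
        epoch_triples = _resample_gaps(train_set, config.horizon_set, rng)
        order = rng.permutation(len(epoch_triples))
        epoch_triples = [epoch_triples[i] for i in order]
        running, seen = 0.0, 0
        for bi in range(0, len(epoch_triples), config.batch_size):
            batch = collate(epoch_triples[bi : bi + config.batch_size], scaler)
            opt.zero_grad()
            pred, _ = model.forward_batch(batch)
            loss = huber_loss(batch.y, pred, batch.y_mask, config.huber_delta)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting at {bi}"
                )
            loss.backward()
            opt.step()
            k = batch.y_mask.sum()
            running += float(loss.data) * k
            seen += k
        report.train_losses.append(running / max(seen, 1))
        val_loss = _epoch_loss(model, val_set, scaler, config)
        report.val_losses.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_blob = clone_params(model.params)
            report.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    load_params(model.params, best_blob)
    report.final_metrics = evaluate(model, val_set, scaler).overall
    return model, report


def compute_metrics(truth: np.ndarray, pred: np.ndarray) -> dict:
    """MAE, RMSE and R^2 over flat arrays; R^2 is NaN when truth has no variance."""
    truth = np.asarray(truth, dtype=np.float64).ravel()
    pred = np.asarray(pred, dtype=np.float64).ravel()
    err = truth - pred
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = float("nan")
    else:
        r2 = 1.0 - float((err**2).sum()) / ss_tot
    return {"mae": mae, "rmse": rmse, "r2": r2}


@dataclass
class EvalReport:
    overall: dict
    per_gap: pd.DataFrame
    per_step: pd.DataFrame
    truth: np.ndarray
    pred: np.ndarray
    gaps: np.ndarray
    concepts: np.ndarray

    def to_csv(self, path) -> None:
        self.per_gap.to_csv(path, index=False)


def predict_batch(
    model: ConceptEditor, triples: list[Triple], scaler: ScalingSpec, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw-unit (truth, pred, mask, gaps, steps, concepts) for a triple list."""
    truths, preds, masks, gaps, steps, concepts = [], [], [], [], [], []
    for i in range(0, len(triples), batch_size):
        chunk = triples[i : i + batch_size]
        batch = collate(chunk, scaler)
        pred, c = model.forward_batch(batch)
        preds.append(scaler.invert(pred.data.T).T)
        truths.append(np.stack([tr.values[:, r.target_index] for tr, r in chunk]))
        masks.append(batch.y_mask)
        gaps.append(batch.gaps)
        steps.append(np.array([r.target_index for _, r in chunk]))
        concepts.append(c.data)
    return (
        np.concatenate(truths),
        np.concatenate(preds),
        np.concatenate(masks),
        np.concatenate(gaps),
        np.concatenate(steps),
        np.concatenate(concepts),
    )


def evaluate(model: ConceptEditor, triples: list[Triple], scaler: ScalingSpec) -> EvalReport:
    """Raw-unit metrics over mask-true cells, with per-gap/per-step breakdown."""
    truth, pred, mask, gaps, steps, concepts = predict_batch(model, triples, scaler)
    sel = mask.astype(bool)
    overall = compute_metrics(truth[sel], pred[sel])
    gap_rows, step_rows = [], []
    for g in np.unique(gaps):
        m = (gaps == g)[:, None] & sel
        row = compute_metrics(truth[m], pred[m])
        gap_rows.append({"gap": int(g), "n": int(m.sum()), **row})
    for s in np.unique(steps):
        m = (steps == s)[:, None] & sel
        row = compute_metrics(truth[m], pred[m])
        step_rows.append({"target_step": int(s), "n": int(m.sum()), **row})
    return EvalReport(
        overall, pd.DataFrame(gap_rows), pd.DataFrame(step_rows),
        truth, pred, gaps, concepts,
    )


def implied_rates(
    model: ConceptEditor, triples: list[Triple], scaler: ScalingSpec
) -> np.ndarray:
    """Learned concepts expressed as raw-space multiplicative rates.

    The model's concepts live in the scaled working range, where the ratio
    interpretation is exact; mapping the prediction back to raw units and
    dividing by the raw value at t_i expresses the same learned rate on the
    scale of the data, so it can be compared with generative ground truth.
    """
    _, pred, _, _, _, _ = predict_batch(model, triples, scaler)
    x_last = np.stack([tr.values[:, r.history_end] for tr, r in triples])
    return pred / np.maximum(np.abs(x_last), 1e-12) * np.sign(x_last)
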