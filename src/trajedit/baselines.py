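"""Baselines and ablations: last-observation identity, VAR, and rollout.

* ``simple_linear_forecast`` is the all-ones-concept ablation: the temporal
  concept is fixed at 1 so the prediction is the last observation carried
  forward, for any target time and condition.
* ``VarModel`` is a pooled ordinary-least-squares vector autoregression fit
  across entities; it ignores conditions entirely (unconditional baseline).
* ``autoregressive_conditional_forecast`` rolls any one-step conditional
  forecaster forward step by step, feeding predictions back — the path a
  non-concept model must take to reach a delayed target.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .data import EditRequest, ScalingSpec, Trajectory
from .model import ConceptEditor

logger = logging.getLogger(__name__)


def simple_linear_forecast(x_last: np.ndarray) -> np.ndarray:
    """All-ones temporal concept: the prediction is x_last, unchanged."""
    return np.asarray(x_last, dtype=np.float64).copy()


@dataclass
class VarModel:
    """VAR(p): x_t = intercept + sum_k A_k x_{t-k}, pooled OLS across entities."""

    p: int
    coefs: np.ndarray      # (p, V, V)
    intercept: np.ndarray  # (V,)

    def predict_next(self, history: np.ndarray) -> np.ndarray:
        """One-step prediction from history (V, >=p), most recent column last."""
        x = self.intercept.copy()
        for k in range(self.p):
            x += self.coefs[k] @ history[:, -(k + 1)]
        return x

    def to_json(self) -> str:
        return json.dumps(
            {"p": self.p, "coefs": self.coefs.tolist(), "intercept": self.intercept.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "VarModel":
        d = json.loads(text)
        return cls(d["p"], np.array(d["coefs"]), np.array(d["intercept"]))


def fit_var(trajectories: list[Trajectory], p: int = 1) -> VarModel:
    """Pooled least-squares VAR(p) over fully observed, regular trajectories."""
    if p < 1:
        raise ValueError("lag order must be >= 1")
    V = trajectories[0].n_variables
    rows, targets = [], []
    for tr in trajectories:
        if not tr.mask.all():
            raise ValueError(f"fit_var requires fully observed data ({tr.entity_id!r})")
        if p > tr.n_times - 1:
            raise ValueError(
                f"lag order {p} exceeds usable length {tr.n_times - 1} for {tr.entity_id!r}"
            )
        for t in range(p, tr.n_times):
            lags = [tr.values[:, t - k] for k in range(1, p + 1)]
            rows.append(np.concatenate(lags + [np.ones(1)]))
            targets.append(tr.values[:, t])
    X = np.stack(rows)
    Y = np.stack(targets)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("VAR design is rank deficient; using pseudo-inverse solution")
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    coefs = np.stack([B[k * V : (k + 1) * V].T for k in range(p)])
    return VarModel(p, coefs, B[-1])


def var_rollout(model: VarModel, history: np.ndarray, steps: int) -> np.ndarray:
    """Iterate the fitted recurrence ``steps`` times, feeding predictions back.

    Returns (V, steps).  Overflow produces infinite markers (the divergence of
    an unstable VAR at long horizons is itself a documented behavior), and the
    rollout keeps going.
    """
    if history.shape[1] < model.p:
        raise ValueError(f"history must hold at least p={model.p} steps")
    buf = history[:, -model.p :].astype(np.float64).copy()
    out = np.empty((history.shape[0], steps))
    with np.errstate(over="ignore", invalid="ignore"):
        for s in range(steps):
            nxt = model.predict_next(buf)
            nxt = np.where(np.isnan(nxt), np.inf, nxt)
            out[:, s] = nxt
            buf = np.concatenate([buf[:, 1:], nxt[:, None]], axis=1)
    return out


def autoregressive_conditional_forecast(
    model: ConceptEditor,
    trajectory: Trajectory,
    history_end: int,
    condition: str | None,
    gap: int,
    scaler: ScalingSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Reach t_i + gap by applying a one-step forecaster ``gap`` times.

    At every step the condition token is supplied and the prediction is
    appended to a rolling copy of the history; the input trajectory is never
    mutated.  Returns (final prediction, (V, gap) intermediates), raw units.
    """
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if history_end + gap >= trajectory.n_times:
        raise ValueError("target beyond trajectory horizon")
    work = trajectory.copy()
    intermediates = np.empty((trajectory.n_variables, gap))
    for k in range(gap):
        t_i = history_end + k
        req = EditRequest(work.entity_id, t_i, condition, t_i + 1)
        pred, _ = model.forecast(req, work, scaler)
        intermediates[:, k] = pred
        work.values[:, t_i + 1] = pred
        work.mask[:, t_i + 1] = True
    return intermediates[:, -1], intermediates
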