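"""The concept-bottleneck sequence editor.

Given a history x_{:,t0:ti}, a condition token s and a target time t_j, the
model composes four parts:

* sequence encoder F (gated recurrent or self-attention) -> h_x,
* condition adapter H: frozen z_s -> h_s,
* concept encoder E: c = GELU(FFN(h_x * (Delta(t_i,t_j) + h_s))), a length-V
  temporal concept interpreted as per-variable multiplicative rates of change
  between t_i and t_j,
* concept decoder G: x_hat_{:,tj} = c * x_{:,ti} (element-wise).

The forecast is a single forward pass regardless of the gap t_j - t_i: the
decoder is applied exactly once, which is what makes delayed editing one-step.
All arithmetic happens in the scaled working range [eps_pos, 1] (see
:mod:`trajedit.data`); every concept entry is bounded below by the GELU
infimum (about -0.16997).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, constant, gelu, huber
from .data import EditRequest, ScalingSpec, Trajectory
from .encoding import (
    ConditionAdapter,
    ConditionTable,
    TimeEncoder,
    combine_time_condition,
    time_delta,
)
from .nn import Affine, AttentionEncoder, GRUEncoder, ParamDict, clone_params, load_params


class ConfigurationError(ValueError):
    pass


@dataclass
class Batch:
    """A collated batch of edit windows in the scaled working range."""

    X: np.ndarray          # (B, L, V) scaled history values, left-padded
    M: np.ndarray          # (B, L, V) observation mask
    valid: np.ndarray      # (B, L) step validity (padding = False)
    hist_times: np.ndarray  # (B, L) timestamps (int64 steps or datetime64)
    t_i: np.ndarray        # (B,) timestamps of history end
    t_j: np.ndarray        # (B,) timestamps of target
    tokens: list           # (B,) condition tokens (str or None)
    x_last: np.ndarray     # (B, V) scaled values at t_i
    y: np.ndarray          # (B, V) scaled target values (zeros where unobserved)
    y_mask: np.ndarray     # (B, V)
    gaps: np.ndarray       # (B,) integer gap t_j - t_i in steps


class ConceptEditor:
    """Controllable sequence editor with a temporal-concept bottleneck.

    Parameters
    ----------
    variables:
        Ordered variable names (length V).
    table:
        Frozen condition-embedding table.
    d_h:
        Hidden dimension shared by all submodules.
    encoder:
        "gru" (default) or "attention".
    use_ffn:
        Whether the concept encoder projects d_h -> V with an affine layer.
        When False, d_h must equal V.
    bottleneck:
        With False, the concept bottleneck and multiplicative decoder are
        replaced by a plain regression head h -> V; this is the
        autoregressive comparator used in ablations.
    """

    def __init__(
        self,
        variables: list[str],
        table: ConditionTable,
        d_h: int = 64,
        encoder: str = "gru",
        use_ffn: bool = True,
        bottleneck: bool = True,
        seed: int = 0,
    ):
        V = len(variables)
        if not use_ffn and d_h != V:
            raise ConfigurationError(
                f"without the concept FFN the hidden dimension ({d_h}) must "
                f"equal the number of variables ({V})"
            )
        self.variables = list(variables)
        self.d_h = d_h
        self.encoder_kind = encoder
        self.use_ffn = use_ffn
        self.bottleneck = bottleneck
        self.seed = seed
        self.params: ParamDict = {}
        rng = np.random.default_rng(seed)
        self.time_encoder = TimeEncoder(self.params, d_h, rng)
        self.adapter = ConditionAdapter(self.params, table, d_h, rng)
        d_in = 2 * V + d_h  # (values, mask, time embedding) per step
        if encoder == "gru":
            self.encoder = GRUEncoder(self.params, "enc", d_in, d_h, rng)
        elif encoder == "attention":
            self.encoder = AttentionEncoder(self.params, "enc", d_in, d_h, rng)
        else:
            raise ConfigurationError(f"unknown encoder {encoder!r}")
        if use_ffn or not bottleneck:
            self.ffn = Affine(self.params, "concept.ffn", d_h, V, rng)
        else:
            self.ffn = None
        self.decode_count = 0  # decoder invocations, for the one-step contract
        self.treatment_head = None  # set by balanced_train (lam > 0)
        self.treatment_vocab: list[str] | None = None

    # -- submodules ---------------------------------------------------------
    def encode_sequence(self, X: np.ndarray, M: np.ndarray, valid: np.ndarray,
                        hist_times: np.ndarray) -> Tensor:
        """h_x for a batch: left-padded (B, L, V) values/mask + (B, L) times."""
        if not valid.any(axis=1).all():
            raise ValueError("encode_sequence: some window has no valid steps")
        B, L, V = X.shape
        h_time = self.time_encoder.encode(hist_times.reshape(-1)).reshape(B, L, self.d_h)
        steps = []
        for t in range(L):
            steps.append(
                concat(
                    [
                        constant(X[:, t, :]),
                        constant(M[:, t, :].astype(np.float64)),
                        h_time[:, t, :],
                    ],
                    axis=-1,
                )
            )
        return self.encoder(steps, valid)

    def encode_concept(self, h_x: Tensor, delta: Tensor, h_s: Tensor) -> Tensor:
        """Temporal concept c = GELU(FFN(h_x * (delta + h_s)))."""
        u = h_x * combine_time_condition(delta, h_s)
        if self.ffn is not None:
            u = self.ffn(u)
        return gelu(u)

    def decode_concept(self, c, x_last):
        """x_hat = c * x_last, element-wise; exactly one multiplicative step."""
        c_data = c.data if isinstance(c, Tensor) else np.asarray(c, dtype=np.float64)
        xl = np.asarray(x_last, dtype=np.float64)
        if c_data.shape[-1] != xl.shape[-1]:
            raise ValueError(f"length mismatch: concept {c_data.shape} vs x_last {xl.shape}")
        self.decode_count += 1
        if isinstance(c, Tensor):
            return c * constant(xl)
        return c_data * xl

    # -- forward ------------------------------------------------------------
    def forward_batch(self, batch: Batch) -> tuple[Tensor, Tensor]:
        """(prediction, concept) tensors of shape (B, V) in the working range."""
        pred, c, _ = self.forward_with_representation(batch)
        return pred, c

    def forward_with_representation(self, batch: Batch) -> tuple[Tensor, Tensor, Tensor]:
        """As :meth:`forward_batch` but also returns the history summary h_x."""
        h_x = self.encode_sequence(batch.X, batch.M, batch.valid, batch.hist_times)
        delta = time_delta(self.time_encoder, batch.t_i, batch.t_j)
        h_s = self.adapter.adapt(batch.tokens)
        if self.bottleneck:
            c = self.encode_concept(h_x, delta, h_s)
            pred = self.decode_concept(c, batch.x_last)
        else:
            # plain regression head: no concept, no multiplicative decode
            u = h_x * combine_time_condition(delta, h_s)
            pred = self.ffn(u)
            c = constant(np.ones_like(pred.data))
        return pred, c, h_x

    def forecast(
        self, request: EditRequest, trajectory: Trajectory, scaler: ScalingSpec
    ) -> tuple[np.ndarray, np.ndarray]:
        """One-step conditional forecast for a single edit request.

        Returns ``(prediction, concept)`` where the prediction is in *raw*
        units (scaling inverted) and the concept is the working-range rate
        vector actually used by the decoder.  The input trajectory is never
        mutated.
        """
        request.validate(trajectory)
        batch = collate([(trajectory, request)], scaler)
        pred, c = self.forward_batch(batch)
        raw = scaler.invert(pred.data[0])
        return raw, c.data[0].copy()

    # -- checkpointing -------------------------------------------------------
    def config(self) -> dict:
        return {
            "variables": self.variables,
            "d_h": self.d_h,
            "encoder": self.encoder_kind,
            "use_ffn": self.use_ffn,
            "bottleneck": self.bottleneck,
            "seed": self.seed,
        }

    def save(self, path_prefix: str, scaler: ScalingSpec | None = None) -> None:
        np.savez(f"{path_prefix}.npz", **clone_params(self.params))
        side = self.config()
        if scaler is not None:
            side["scaling"] = json.loads(scaler.to_json())
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(side, fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str, table: ConditionTable) -> tuple["ConceptEditor", ScalingSpec | None]:
        with open(f"{path_prefix}.json") as fh:
            side = json.load(fh)
        model = cls(
            side["variables"],
            table,
            d_h=side["d_h"],
            encoder=side["encoder"],
            use_ffn=side["use_ffn"],
            bottleneck=side["bottleneck"],
            seed=side["seed"],
        )
        blob = np.load(f"{path_prefix}.npz")
        load_params(model.params, {k: blob[k] for k in blob.files})
        scaler = None
        if "scaling" in side:
            scaler = ScalingSpec.from_json(json.dumps(side["scaling"]))
        return model, scaler


def huber_loss(
    truth: np.ndarray,
    prediction: Tensor | np.ndarray,
    mask: np.ndarray | None = None,
    delta_param: float = 1.0,
) -> Tensor:
    """Mean Huber loss over mask-true coordinates (delta defaults to 1)."""
    if delta_param <= 0:
        raise ValueError("delta_param must be positive")
    pred = prediction if isinstance(prediction, Tensor) else constant(prediction)
    if mask is not None and not np.asarray(mask).any():
        raise ValueError("huber_loss: all-false mask leaves no supervised targets")
    residual = constant(np.asarray(truth, dtype=np.float64)) - pred
    return huber(residual, delta=delta_param, weights=None if mask is None else np.asarray(mask))


def oracle_concept(x_last: np.ndarray, x_target: np.ndarray, eps_pos: float = 0.01) -> np.ndarray:
    """The exact concept x_target / x_last (denominator clamped at eps_pos)."""
    return np.asarray(x_target) / np.maximum(np.asarray(x_last), eps_pos)


def collate(
    items: list[tuple[Trajectory, EditRequest]],
    scaler: ScalingSpec,
    max_len: int | None = None,
) -> Batch:
    """Collate (trajectory, request) pairs into a left-padded scaled batch."""
    B = len(items)
    V = items[0][0].n_variables
    lens = [req.history_end + 1 for _, req in items]
    L = min(max(lens), max_len) if max_len else max(lens)
    X = np.zeros((B, L, V))
    M = np.zeros((B, L, V), dtype=bool)
    valid = np.zeros((B, L), dtype=bool)
    first = items[0][0].times_as_datetime()
    hist_times = np.full((B, L), first[0])
    t_i = np.empty(B, dtype=hist_times.dtype)
    t_j = np.empty(B, dtype=hist_times.dtype)
    x_last = np.zeros((B, V))
    y = np.zeros((B, V))
    y_mask = np.zeros((B, V), dtype=bool)
    gaps = np.zeros(B, dtype=np.int64)
    tokens = []
    for b, (tr, req) in enumerate(items):
        n = min(req.history_end + 1, L)
        start = req.history_end + 1 - n
        sv = scaler.apply(tr.values[:, start : req.history_end + 1])
        m = tr.mask[:, start : req.history_end + 1]
        sv = np.where(m, sv, 0.0)
        X[b, L - n :, :] = sv.T
        M[b, L - n :, :] = m.T
        valid[b, L - n :] = True
        times = tr.times_as_datetime()
        hist_times[b, L - n :] = times[start : req.history_end + 1]
        t_i[b] = times[req.history_end]
        t_j[b] = times[req.target_index]
        x_last[b] = np.where(
            tr.mask[:, req.history_end],
            scaler.apply(tr.values[:, req.history_end : req.history_end + 1])[:, 0],
            0.0,
        )
        yv = scaler.apply(tr.values[:, req.target_index : req.target_index + 1])[:, 0]
        ym = tr.mask[:, req.target_index]
        y[b] = np.where(ym, yv, 0.0)
        y_mask[b] = ym
        gaps[b] = req.gap
        tokens.append(req.condition)
    return Batch(X, M, valid, hist_times, t_i, t_j, tokens, x_last, y, y_mask, gaps)
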