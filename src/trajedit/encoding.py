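"""Time positional embeddings, time-delta embeddings, and the condition adapter.

A timestamp t is embedded as the element-wise sum of four components: a
fixed sinusoidal embedding of the year and learned lookup tables over month
(12), day-of-month (31) and hour (24).  Sub-hour resolution is deliberately
not encoded.  Integer step indices are interpreted as hours from a fixed
epoch, so simulated step data acquires calendar semantics for free.

All embedding entries are snapped to multiples of 2^-26 so that the delta
algebra Delta(a,b) = h_b - h_a satisfies antisymmetry and additivity
bit-exactly (a float64 holds sums of a few such values without rounding).

Conditions are fixed (frozen) vectors z_s from a :class:`ConditionTable`;
the learned adapter maps them into the model's hidden space, h_s = H(z_s).
A reserved null token carries a *learned* embedding so "no condition" stays
distinguishable from an all-zero pretrained vector.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .autodiff import Tensor, constant, embedding, gelu, parameter, snap_to_grid
from .data import STEP_EPOCH
from .nn import Affine, ParamDict, fan_in_uniform

NULL_TOKEN = "<null>"

_GRID = 2.0**-26


def calendar_fields(times: np.ndarray) -> tuple[np.ndarray, ...]:
    """(year, month_idx 0-11, day_idx 0-30, hour_idx 0-23) for datetime64
    timestamps or integer step indices (hours from the epoch)."""
    times = np.asarray(times)
    if not np.issubdtype(times.dtype, np.datetime64):
        times = STEP_EPOCH + times.astype(np.int64).astype("timedelta64[h]")
    ts = pd.DatetimeIndex(times.astype("datetime64[s]"))
    return (
        ts.year.to_numpy(np.float64),
        ts.month.to_numpy(np.intp) - 1,
        ts.day.to_numpy(np.intp) - 1,
        ts.hour.to_numpy(np.intp),
    )


def sinusoidal(position: np.ndarray, d: int, base: float = 10000.0) -> np.ndarray:
    """Standard alternating sin/cos positional code with geometric wavelengths."""
    position = np.asarray(position, dtype=np.float64).reshape(-1, 1)
    half = (d + 1) // 2
    freqs = base ** (-np.arange(half) * 2.0 / d)
    ang = position * freqs
    out = np.empty((position.shape[0], 2 * half))
    out[:, 0::2] = np.sin(ang)
    out[:, 1::2] = np.cos(ang)
    return out[:, :d]


class TimeEncoder:
    """h_t = sinusoidal(year) + E_month[m] + E_date[d] + E_hour[h], all d_h."""

    def __init__(self, params: ParamDict, d_h: int, rng: np.random.Generator,
                 prefix: str = "time"):
        self.d_h = d_h
        self.month = parameter(fan_in_uniform(rng, (12, d_h)))
        self.date = parameter(fan_in_uniform(rng, (31, d_h)))
        self.hour = parameter(fan_in_uniform(rng, (24, d_h)))
        params[f"{prefix}.month"] = self.month
        params[f"{prefix}.date"] = self.date
        params[f"{prefix}.hour"] = self.hour

    def encode(self, times: np.ndarray) -> Tensor:
        """Embed an array of timestamps -> Tensor (n, d_h)."""
        year, month, day, hour = calendar_fields(times)
        year_part = np.round(sinusoidal(year, self.d_h) / _GRID) * _GRID
        h = (
            constant(year_part)
            + snap_to_grid(embedding(self.month, month), _GRID)
            + snap_to_grid(embedding(self.date, day), _GRID)
            + snap_to_grid(embedding(self.hour, hour), _GRID)
        )
        return h

    def encode_one(self, t) -> Tensor:
        return self.encode(np.asarray([t]))


def time_delta(encoder: TimeEncoder, t_i, t_j) -> Tensor:
    """Delta(t_i, t_j) = h_{t_j} - h_{t_i} (arrays or scalars)."""
    t_i = np.atleast_1d(np.asarray(t_i))
    t_j = np.atleast_1d(np.asarray(t_j))
    return encoder.encode(t_j) - encoder.encode(t_i)


def combine_time_condition(delta: Tensor, h_s: Tensor) -> Tensor:
    """Time- and condition-specific embedding: element-wise sum."""
    if delta.shape[-1] != h_s.shape[-1]:
        raise ValueError(f"dimension mismatch: {delta.shape} vs {h_s.shape}")
    return delta + h_s


class ConditionTable:
    """Frozen token -> embedding map, with a reserved null token.

    The table stands in for a frozen pretrained embedding model; its vectors
    are never updated during training.
    """

    def __init__(self, embeddings: dict[str, np.ndarray]):
        if not embeddings:
            raise ValueError("empty condition table")
        dims = {np.asarray(v).shape for v in embeddings.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {dims}")
        self.d_z = next(iter(dims))[0]
        self.embeddings = {k: np.asarray(v, dtype=np.float64).copy() for k, v in embeddings.items()}
        if NULL_TOKEN not in self.embeddings:
            self.embeddings[NULL_TOKEN] = np.zeros(self.d_z)

    def tokens(self) -> list[str]:
        return sorted(self.embeddings)

    def lookup(self, token: str | None) -> np.ndarray:
        key = NULL_TOKEN if token is None else token
        if key not in self.embeddings:
            raise KeyError(
                f"unknown condition token {token!r}; known tokens: {self.tokens()}"
            )
        return self.embeddings[key]

    @classmethod
    def random(cls, tokens: list[str], d_z: int, rng: np.random.Generator) -> "ConditionTable":
        """Fixed random Gaussian embeddings, one per token (plus null)."""
        return cls({t: rng.normal(size=d_z) for t in tokens})

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"token": self.tokens()}
            | {f"z{i}": [self.embeddings[t][i] for t in self.tokens()] for i in range(self.d_z)}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionTable":
        df = pd.read_csv(path)
        if "token" not in df.columns or df.shape[1] < 2:
            raise ValueError("condition table needs a 'token' column plus embedding columns")
        emb_cols = [c for c in df.columns if c != "token"]
        return cls({str(r["token"]): r[emb_cols].to_numpy(np.float64) for _, r in df.iterrows()})


class ConditionAdapter:
    """Learned map H: z_s -> h_s (affine + GELU); null token embedding is learned.

    The affine bias is initialized at 1 so h_s starts with O(1) entries:
    h_s gates the history representation multiplicatively in the concept
    encoder, and a near-zero initial gate would throttle the encoder's
    gradient (the same reasoning as initializing LSTM forget-gate biases
    high).
    """

    def __init__(self, params: ParamDict, table: ConditionTable, d_h: int,
                 rng: np.random.Generator, prefix: str = "adapter"):
        self.table = table
        self.lin = Affine(params, f"{prefix}.lin", table.d_z, d_h, rng)
        self.lin.b.data[:] = 1.0
        self.z_null = parameter(fan_in_uniform(rng, (1, table.d_z)))
        params[f"{prefix}.z_null"] = self.z_null

    def adapt(self, tokens: list[str | None]) -> Tensor:
        """h_s for a batch of tokens -> Tensor (B, d_h)."""
        is_null = np.array([t is None or t == NULL_TOKEN for t in tokens], dtype=np.float64)
        Z_fixed = np.stack(
            [
                np.zeros(self.table.d_z) if n else self.table.lookup(t)
                for t, n in zip(tokens, is_null)
            ]
        )
        nullmask = constant(is_null[:, None])
        Z = constant(Z_fixed) + nullmask * self.z_null
        return gelu(self.lin(Z))
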