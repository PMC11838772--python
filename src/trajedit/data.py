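"""Data model and IO for multivariate longitudinal trajectories.

A :class:`Trajectory` stores one entity's V x T matrix of continuous
measurements together with timestamps and an observation mask.  Trajectories
are exchanged as long-format delimited text (entity, time, variable, value,
optional observed flag); pandas handles all parsing and gzip transparency.

Because the decoder of the editing model is multiplicative, raw values are
mapped into a strictly positive working range [eps_pos, 1] by a per-variable
affine :class:`ScalingSpec` before modeling; all metrics are computed after
inverting the scaling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("entity_id", "time", "variable", "value", "observed")

#: integer step indices are interpreted as hours from this epoch
STEP_EPOCH = np.datetime64("2000-01-01T00:00")


@dataclass
class Trajectory:
    """One entity's multivariate longitudinal record.

    values/mask are (V, T); times are either int64 step indices or
    datetime64; times must be strictly increasing and variable names unique.
    """

    entity_id: str
    variables: list[str]
    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        V, T = self.values.shape
        if V < 1 or T < 2:
            raise ValueError(
                f"trajectory {self.entity_id!r} needs V >= 1 and T >= 2, got {V}x{T}"
            )
        if len(self.variables) != V or len(set(self.variables)) != V:
            raise ValueError(f"trajectory {self.entity_id!r}: variable names must be unique")
        if self.times.shape != (T,):
            raise ValueError(f"trajectory {self.entity_id!r}: times/values shape mismatch")
        if not np.all(self.times[1:] > self.times[:-1]):
            raise ValueError(f"trajectory {self.entity_id!r}: times must be strictly increasing")
        if self.mask.shape != (V, T):
            raise ValueError(f"trajectory {self.entity_id!r}: mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError(f"trajectory {self.entity_id!r}: non-finite observed values")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.entity_id,
            list(self.variables),
            self.times.copy(),
            self.values.copy(),
            self.mask.copy(),
        )

    def times_as_datetime(self) -> np.ndarray:
        """Timestamps as datetime64; integer steps count hours from the epoch."""
        if np.issubdtype(self.times.dtype, np.datetime64):
            return self.times.astype("datetime64[m]")
        return STEP_EPOCH + self.times.astype("timedelta64[h]")


@dataclass
class EditRequest:
    """An edit: history up to index ``history_end``, condition token (or
    None), and the index of the target time ``target_index``."""

    entity_id: str
    history_end: int
    condition: str | None
    target_index: int

    def validate(self, trajectory: Trajectory) -> None:
        if not (0 <= self.history_end < self.target_index < trajectory.n_times):
            raise ValueError(
                f"edit request for {self.entity_id!r}: need 0 <= history_end "
                f"< target_index < T, got {self.history_end}, {self.target_index}"
            )
        if not trajectory.mask[:, : self.history_end + 1].any():
            raise ValueError(f"edit request for {self.entity_id!r}: empty observed history")

    @property
    def gap(self) -> int:
        return self.target_index - self.history_end


@dataclass
class ScalingSpec:
    """Per-variable affine map onto the working range [eps_pos, 1].

    scaled = (raw - offset) * scale + eps_pos; constant variables map to the
    midpoint 0.5 with unit scale so the inverse stays well defined.
    """

    variables: list[str]
    offset: np.ndarray
    scale: np.ndarray
    eps_pos: float = 0.01
    constant: np.ndarray = field(default=None)  # bool per variable

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if self.constant is None:
            self.constant = np.zeros(len(self.variables), dtype=bool)
        self.constant = np.asarray(self.constant, dtype=bool)
        if np.any(self.scale <= 0):
            raise ValueError("ScalingSpec: scale must be positive per variable")

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Scale a (V, ...) array of raw values into the working range."""
        off = self.offset.reshape(-1, *([1] * (values.ndim - 1)))
        sc = self.scale.reshape(-1, *([1] * (values.ndim - 1)))
        return (values - off) * sc + self.eps_pos

    def invert(self, scaled: np.ndarray) -> np.ndarray:
        off = self.offset.reshape(-1, *([1] * (scaled.ndim - 1)))
        sc = self.scale.reshape(-1, *([1] * (scaled.ndim - 1)))
        return (scaled - self.eps_pos) / sc + off

    def transform(self, trajectory: Trajectory) -> Trajectory:
        out = trajectory.copy()
        out.values = self.apply(out.values)
        out.values[~out.mask] = 0.0
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": self.variables,
                "offset": self.offset.tolist(),
                "scale": self.scale.tolist(),
                "eps_pos": self.eps_pos,
                "constant": self.constant.astype(int).tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalingSpec":
        d = json.loads(text)
        return cls(
            variables=d["variables"],
            offset=np.array(d["offset"]),
            scale=np.array(d["scale"]),
            eps_pos=d["eps_pos"],
            constant=np.array(d["constant"], dtype=bool),
        )


def fit_scaling(trajectories: list[Trajectory], eps_pos: float = 0.01) -> ScalingSpec:
    """Fit a per-variable min-max map onto [eps_pos, 1] across entities.

    Constant variables map to the midpoint 0.5.  Raises if any variable has
    zero observed values.
    """
    if eps_pos <= 0 or eps_pos >= 1:
        raise ValueError("eps_pos must lie in (0, 1)")
    variables = list(trajectories[0].variables)
    V = len(variables)
    vmin = np.full(V, np.inf)
    vmax = np.full(V, -np.inf)
    seen = np.zeros(V, dtype=bool)
    for tr in trajectories:
        if list(tr.variables) != variables:
            raise ValueError("all trajectories must share the same variable order")
        for v in range(V):
            obs = tr.values[v, tr.mask[v]]
            if obs.size:
                seen[v] = True
                vmin[v] = min(vmin[v], obs.min())
                vmax[v] = max(vmax[v], obs.max())
    if not seen.all():
        missing = [variables[i] for i in np.flatnonzero(~seen)]
        raise ValueError(f"variables with no observed values: {missing}")
    constant = vmax == vmin
    scale = np.where(constant, 1.0, (1.0 - eps_pos) / np.where(constant, 1.0, vmax - vmin))
    # constant variable: scaled = (x - x0) + (0.5 - eps_pos) + eps_pos = 0.5
    offset = np.where(constant, vmin - (0.5 - eps_pos), vmin)
    return ScalingSpec(variables, offset, scale, eps_pos, constant)


@dataclass(frozen=True)
class EditWindow:
    """A training/evaluation triple: history [0, t_i], target index, gap."""

    history_end: int
    target_index: int
    gap: int


def make_edit_windows(
    trajectory: Trajectory, min_history: int, horizon_set: set[int]
) -> list[EditWindow]:
    """Enumerate (history, target, gap) triples for a trajectory.

    ``gap == 1`` is immediate editing; larger gaps are delayed editing.  A
    history end t_i qualifies if at least ``min_history`` of the steps
    0..t_i have any observed variable.  Too-short trajectories yield an
    empty list rather than an error.
    """
    if min_history < 1:
        raise ValueError("min_history must be >= 1")
    observed_step = trajectory.mask.any(axis=0)
    cum_obs = np.cumsum(observed_step)
    T = trajectory.n_times
    out: list[EditWindow] = []
    for t_i in range(T - 1):
        if cum_obs[t_i] < min_history:
            continue
        for g in sorted(horizon_set):
            if g < 1:
                raise ValueError("horizons must be positive")
            if t_i + g < T:
                out.append(EditWindow(t_i, t_i + g, g))
    return out


# --- long/wide format IO -----------------------------------------------------


def read_trajectories(
    path, schema: tuple[str, ...] = LONG_COLUMNS[:4], observed_col: str | None = "observed"
) -> list[Trajectory]:
    """Read long-format delimited text into one Trajectory per entity.

    Missing (entity, time, variable) cells get mask=False and a 0.0
    placeholder.  Duplicate rows raise; non-numeric values raise with the
    offending row number; entities with fewer than two time points are
    skipped with a logged warning.
    """
    ent_c, time_c, var_c, val_c = schema
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (ent_c, time_c, var_c, val_c):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    numeric = pd.to_numeric(df[val_c], errors="coerce")
    bad = numeric.isna() & df[val_c].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric value at data row {row}: {df[val_c].iloc[row]!r}")
    df = df.assign(**{val_c: numeric})
    dup = df.duplicated(subset=[ent_c, time_c, var_c], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"duplicate row for entity={r[ent_c]!r} time={r[time_c]!r} "
            f"variable={r[var_c]!r}"
        )
    if observed_col and observed_col in df.columns:
        obs = df[observed_col].astype(bool)
    else:
        obs = df[val_c].notna()
    df = df.assign(__obs=obs)

    variables = sorted(df[var_c].astype(str).unique())
    time_vals = df[time_c]
    if pd.api.types.is_numeric_dtype(time_vals):
        df = df.assign(**{time_c: time_vals.astype(np.int64)})
    else:
        df = df.assign(**{time_c: pd.to_datetime(time_vals).to_numpy()})

    out: list[Trajectory] = []
    for ent, grp in df.groupby(ent_c, sort=True):
        times = np.sort(grp[time_c].unique())
        if times.size < 2:
            logger.warning("entity %r has fewer than 2 time points; skipped", ent)
            continue
        V, T = len(variables), times.size
        values = np.zeros((V, T))
        mask = np.zeros((V, T), dtype=bool)
        t_idx = {t: i for i, t in enumerate(times)}
        v_idx = {v: i for i, v in enumerate(variables)}
        for _, r in grp.iterrows():
            i, j = v_idx[str(r[var_c])], t_idx[r[time_c]]
            if bool(r["__obs"]) and pd.notna(r[val_c]):
                values[i, j] = float(r[val_c])
                mask[i, j] = True
        out.append(Trajectory(str(ent), variables, times, values, mask))
    return out


def write_trajectories(trajectories: list[Trajectory], path, extra: dict | None = None) -> None:
    """Write trajectories as long-format CSV (only mask-true cells as observed).

    ``extra`` adds constant columns (e.g. a provenance column) to every row.
    """
    rows = []
    for tr in trajectories:
        for v, name in enumerate(tr.variables):
            for t in range(tr.n_times):
                rows.append(
                    {
                        "entity_id": tr.entity_id,
                        "time": tr.times[t],
                        "variable": name,
                        "value": tr.values[v, t] if tr.mask[v, t] else np.nan,
                        "observed": bool(tr.mask[v, t]),
                    }
                )
    df = pd.DataFrame(rows)
    if extra:
        for k, val in extra.items():
            df[k] = val
    df.to_csv(path, index=False)


def write_wide(trajectories: list[Trajectory], path) -> None:
    """Wide-format export: one row per entity-time, one column per variable."""
    rows = []
    for tr in trajectories:
        for t in range(tr.n_times):
            row = {"entity_id": tr.entity_id, "time": tr.times[t]}
            for v, name in enumerate(tr.variables):
                row[name] = tr.values[v, t] if tr.mask[v, t] else np.nan
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
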