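"""Synthetic-data generators with known ground truth.

Two worlds make every other module testable without external data:

* :class:`MultiplicativeWorld` — trajectories whose per-step dynamics are
  element-wise multiplicative with condition-dependent rate vectors, so the
  true temporal concept between any two steps is known exactly (the product
  of the per-step rates).  Matched factual/counterfactual pairs share the
  noise stream bit-exactly before the divergence step.
* :class:`TumorWorld` — daily tumor volume under chemo/radiotherapy following
  a pharmacokinetic-pharmacodynamic update, with treatment assignment biased
  by the recent tumor burden through a confounding strength gamma (gamma = 0
  is unconfounded randomization).  Counterfactual arms re-run the same
  patient and noise stream under an alternative planned treatment sequence.

Everything is deterministic given the world seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data import EditRequest, Trajectory
from .encoding import NULL_TOKEN, ConditionTable

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# multiplicative world
# --------------------------------------------------------------------------


@dataclass
class MultiplicativeWorld:
    """x_{t+1} = r_{s} * x_t * exp(sigma * eta_t), eta standard normal.

    Per-condition rates are drawn once per world from U(rate_low, rate_high);
    the null condition has milder rates U(0.98, 1.02).  The condition applies
    from step 0 (factual/counterfactual pairs control divergence explicitly).
    """

    n_variables: int = 5
    n_entities: int = 200
    n_steps: int = 30
    n_conditions: int = 3
    sigma: float = 0.0
    rate_low: float = 0.9
    rate_high: float = 1.1
    x0_low: float = 1.0
    x0_high: float = 10.0
    d_z: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.rate_low <= 0:
            raise ValueError("rates must be bounded away from 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def tokens(self) -> list[str]:
        return [f"cond_{i}" for i in range(self.n_conditions)]

    def rates(self) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        r = {
            tok: rng.uniform(self.rate_low, self.rate_high, size=self.n_variables)
            for tok in self.tokens
        }
        r[NULL_TOKEN] = rng.uniform(0.98, 1.02, size=self.n_variables)
        return r

    def condition_table(self) -> ConditionTable:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 202]))
        return ConditionTable.random(self.tokens, self.d_z, rng)


@dataclass
class MultiplicativeDataset:
    world: MultiplicativeWorld
    trajectories: list[Trajectory]
    entity_conditions: dict[str, str]
    rates: dict[str, np.ndarray]
    table: ConditionTable

    def true_concept(self, entity_id: str, t_i: int, t_j: int) -> np.ndarray:
        """Exact k-step concept: the element-wise product of per-step rates."""
        r = self.rates[self.entity_conditions[entity_id]]
        return r ** (t_j - t_i)

    def training_triples(
        self, min_history: int, horizon_set: set[int]
    ) -> list[tuple[Trajectory, EditRequest]]:
        from .data import make_edit_windows

        out = []
        for tr in self.trajectories:
            tok = self.entity_conditions[tr.entity_id]
            for w in make_edit_windows(tr, min_history, horizon_set):
                out.append(
                    (tr, EditRequest(tr.entity_id, w.history_end, tok, w.target_index))
                )
        return out


def _entity_noise(world: MultiplicativeWorld, entity_seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([world.seed, 303, entity_seed]))
    return rng.standard_normal((world.n_variables, world.n_steps - 1))


def _entity_x0(world: MultiplicativeWorld, entity_seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([world.seed, 404, entity_seed]))
    return rng.uniform(world.x0_low, world.x0_high, size=world.n_variables)


def _evolve(
    world: MultiplicativeWorld,
    x0: np.ndarray,
    noise: np.ndarray,
    rate_schedule: list[np.ndarray],
) -> np.ndarray:
    V, T = world.n_variables, world.n_steps
    vals = np.empty((V, T))
    vals[:, 0] = x0
    for t in range(T - 1):
        vals[:, t + 1] = rate_schedule[t] * vals[:, t] * np.exp(world.sigma * noise[:, t])
    return vals


def simulate_multiplicative(world: MultiplicativeWorld) -> MultiplicativeDataset:
    """Generate the world's trajectories with known per-condition rates."""
    rates = world.rates()
    rng = np.random.default_rng(np.random.SeedSequence([world.seed, 505]))
    assignments = rng.integers(0, world.n_conditions, size=world.n_entities)
    trajectories, conditions = [], {}
    for e in range(world.n_entities):
        tok = world.tokens[assignments[e]]
        vals = _evolve(
            world, _entity_x0(world, e), _entity_noise(world, e),
            [rates[tok]] * (world.n_steps - 1),
        )
        eid = f"entity_{e:04d}"
        trajectories.append(
            Trajectory(eid, [f"var_{v}" for v in range(world.n_variables)],
                       np.arange(world.n_steps), vals, np.ones_like(vals, dtype=bool))
        )
        conditions[eid] = tok
    return MultiplicativeDataset(world, trajectories, conditions, rates, world.condition_table())


def simulate_counterfactual_pair(
    world: MultiplicativeWorld,
    entity_seed: int,
    condition_a: str,
    condition_b: str,
    divergence_time: int,
) -> tuple[Trajectory, Trajectory]:
    """Two arms sharing history bit-exactly before ``divergence_time``.

    Both evolve under ``condition_a`` before the divergence step; arm b then
    switches to ``condition_b`` while reusing the same post-divergence noise
    draws, so the factual/counterfactual contrast is exact.
    """
    if not (0 < divergence_time < world.n_steps):
        raise ValueError("divergence_time must lie inside the horizon")
    rates = world.rates()
    x0 = _entity_x0(world, entity_seed)
    noise = _entity_noise(world, entity_seed)
    sched_a = [rates[condition_a]] * (world.n_steps - 1)
    sched_b = [
        rates[condition_a] if t + 1 < divergence_time else rates[condition_b]
        for t in range(world.n_steps - 1)
    ]
    names = [f"var_{v}" for v in range(world.n_variables)]
    times = np.arange(world.n_steps)
    va = _evolve(world, x0, noise, sched_a)
    vb = _evolve(world, x0, noise, sched_b)
    mask = np.ones_like(va, dtype=bool)
    return (
        Trajectory(f"pair_{entity_seed:04d}_a", names, times, va, mask),
        Trajectory(f"pair_{entity_seed:04d}_b", names, times.copy(), vb, mask.copy()),
    )


# --------------------------------------------------------------------------
# tumor world
# --------------------------------------------------------------------------

#: All constants of the tumor simulator, shipped as a versioned config and
#: recorded in each dataset's metadata.
DEFAULT_TUMOR_CONFIG = {
    "d_max_cm": 13.0,            # max tumor diameter; sets carrying capacity
    "rho_range": [0.05, 0.15],   # per-day logistic growth rate
    "beta_c_range": [0.02, 0.04],  # chemo sensitivity (per unit concentration)
    "alpha_r_range": [0.03, 0.05],  # linear radio sensitivity (per Gy)
    "beta_r_fraction": 0.1,      # beta_r = fraction * alpha_r (per Gy^2)
    "chemo_dose": 5.0,           # units per administration
    "radio_dose": 2.0,           # Gy per fraction
    "chemo_half_life_days": 1.0,
    "init_diameter_range": [6.0, 12.0],  # cm
    "recent_window": 3,          # days averaged for treatment assignment
    "assign_diameter_ref": 9.0,  # cm; assignment score is centered here
    "assign_diameter_scale": 3.0,  # cm; one unit of assignment score
    "volume_floor": 0.01,        # cm^3 clamp
}

TREATMENT_TOKENS = ["none", "chemo", "radio"]


def _volume(diameter: float) -> float:
    return (np.pi / 6.0) * diameter**3


def _diameter(volume: np.ndarray) -> np.ndarray:
    return (6.0 * np.asarray(volume) / np.pi) ** (1.0 / 3.0)


@dataclass
class TumorWorld:
    """PK-PD tumor growth under biased treatment assignment.

    V(t+1) = V(t) * (1 + rho log(K/V(t)) - beta_c C(t) - (alpha_r d(t) +
    beta_r d(t)^2) + eps_t); chemo concentration C decays exponentially and
    jumps by a fixed dose on administration; radio delivers dose d at
    treatment times.  Each day a treatment is assigned with probability
    sigmoid(gamma * (recent mean diameter - d_ref) / d_scale), split evenly
    between chemo and radio — gamma controls time-varying confounding
    (gamma = 0 is a fair coin regardless of tumor burden).
    """

    n_patients: int = 100
    n_steps: int = 30
    gamma: float = 0.0
    noise: float = 0.02
    regime: str = "biased"  # "biased" (assignment rule) or "random" (p=0.5)
    d_z: int = 16
    seed: int = 0
    config: dict = field(default_factory=lambda: dict(DEFAULT_TUMOR_CONFIG))

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def condition_table(self) -> ConditionTable:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 606]))
        return ConditionTable.random(TREATMENT_TOKENS, self.d_z, rng)


@dataclass
class TumorPatient:
    rho: float
    beta_c: float
    alpha_r: float
    beta_r: float
    v0: float
    noise: np.ndarray  # (n_steps,) increments reused by counterfactual arms


@dataclass
class TumorDataset:
    world: TumorWorld
    trajectories: list[Trajectory]  # variables: tumor_volume, chemo_concentration
    treatments: dict[str, list[str]]  # per entity, token applied at each step t
    patients: dict[str, TumorPatient]
    table: ConditionTable
    metadata: dict
    n_clamped: int = 0

    def training_triples(self, min_history: int = 3) -> list[tuple[Trajectory, EditRequest]]:
        """Immediate windows; the condition is the treatment driving t_i -> t_i+1."""
        from .data import make_edit_windows

        out = []
        for tr in self.trajectories:
            toks = self.treatments[tr.entity_id]
            for w in make_edit_windows(tr, min_history, {1}):
                out.append(
                    (tr, EditRequest(tr.entity_id, w.history_end, toks[w.history_end],
                                     w.target_index))
                )
        return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_patient(world: TumorWorld, idx: int) -> TumorPatient:
    cfg = world.config
    rng = np.random.default_rng(np.random.SeedSequence([world.seed, 707, idx]))
    alpha = rng.uniform(*cfg["alpha_r_range"])
    return TumorPatient(
        rho=rng.uniform(*cfg["rho_range"]),
        beta_c=rng.uniform(*cfg["beta_c_range"]),
        alpha_r=alpha,
        beta_r=cfg["beta_r_fraction"] * alpha,
        v0=_volume(rng.uniform(*cfg["init_diameter_range"])),
        noise=rng.normal(0.0, world.noise, size=world.n_steps),
    )


def _tumor_step(
    patient: TumorPatient, cfg: dict, K: float, v: float, conc: float,
    token: str, eps: float,
) -> tuple[float, float, bool]:
    """One transition (v, conc) -> (v', conc') under a treatment token."""
    decay = 0.5 ** (1.0 / cfg["chemo_half_life_days"])
    conc = conc * decay + (cfg["chemo_dose"] if token == "chemo" else 0.0)
    dose = cfg["radio_dose"] if token == "radio" else 0.0
    growth = (
        1.0
        + patient.rho * np.log(K / v)
        - patient.beta_c * conc
        - (patient.alpha_r * dose + patient.beta_r * dose**2)
        + eps
    )
    v_new = v * growth
    clamped = v_new < cfg["volume_floor"]
    return max(v_new, cfg["volume_floor"]), conc, clamped


def simulate_tumor(world: TumorWorld) -> TumorDataset:
    """Simulate patients day by day; treatment assignment may be confounded."""
    cfg = world.config
    K = _volume(cfg["d_max_cm"])
    assign_rng = np.random.default_rng(np.random.SeedSequence([world.seed, 808]))
    trajectories, treatments, patients = [], {}, {}
    n_clamped = 0
    for i in range(world.n_patients):
        pat = _draw_patient(world, i)
        T = world.n_steps
        vol = np.empty(T)
        # observed concentration is the pre-dose (morning) level, so the
        # day's own treatment is never encoded in the day's covariates
        conc_series = np.empty(T)
        toks: list[str] = []
        decay = 0.5 ** (1.0 / cfg["chemo_half_life_days"])
        v, c = pat.v0, 0.0
        for t in range(T):
            vol[t] = v
            conc_series[t] = c * decay
            if world.regime == "random":
                p_treat = 0.5
            else:
                lo = max(0, t - cfg["recent_window"] + 1)
                dbar = _diameter(vol[lo : t + 1]).mean()
                p_treat = _sigmoid(
                    world.gamma
                    * (dbar - cfg["assign_diameter_ref"]) / cfg["assign_diameter_scale"]
                )
            treat = assign_rng.random() < p_treat
            token = ("chemo" if assign_rng.random() < 0.5 else "radio") if treat else "none"
            toks.append(token)
            if t < T - 1:
                v, c, clamped = _tumor_step(pat, cfg, K, v, c, token, pat.noise[t])
                n_clamped += clamped
        eid = f"patient_{i:04d}"
        vals = np.stack([vol, conc_series])
        trajectories.append(
            Trajectory(eid, ["tumor_volume", "chemo_concentration"],
                       np.arange(T), vals, np.ones_like(vals, dtype=bool))
        )
        treatments[eid] = toks
        patients[eid] = pat
    if n_clamped:
        logger.warning("tumor simulator clamped %d volume underflows", n_clamped)
    meta = {"config": cfg, "gamma": world.gamma, "noise": world.noise,
            "regime": world.regime, "seed": world.seed,
            "update_rule": "V(t+1)=V(t)*(1+rho*log(K/V)-beta_c*C-(alpha_r*d+beta_r*d^2)+eps)"}
    return TumorDataset(world, trajectories, treatments, patients,
                        world.condition_table(), meta, n_clamped)


def resimulate_tumor(
    dataset: TumorDataset, entity_id: str, start_step: int, planned: list[str]
) -> np.ndarray:
    """Ground-truth counterfactual arm: same patient and noise stream, with
    the planned treatment tokens replacing the observed ones from
    ``start_step`` on.  Returns (2, len(planned)) volume/concentration."""
    pat = dataset.patients[entity_id]
    cfg = dataset.world.config
    K = _volume(cfg["d_max_cm"])
    tr = next(t for t in dataset.trajectories if t.entity_id == entity_id)
    toks = dataset.treatments[entity_id]
    v = tr.values[0, start_step]
    decay = 0.5 ** (1.0 / cfg["chemo_half_life_days"])
    # reconstruct concentration just before the start step's dose
    c = 0.0
    for t in range(start_step):
        c = c * decay + (cfg["chemo_dose"] if toks[t] == "chemo" else 0.0)
    out = np.empty((2, len(planned)))
    for k, token in enumerate(planned):
        t = start_step + k
        v, c, _ = _tumor_step(pat, cfg, K, v, c, token, pat.noise[t])
        out[0, k] = v
        out[1, k] = c * decay  # next morning's pre-dose level
    return out


def planned_concentration(
    dataset: TumorDataset, entity_id: str, history_end: int, plan: list[str]
) -> np.ndarray:
    """Pre-dose chemo concentration at each step after ``history_end`` under a
    planned treatment sequence.

    Under a plan, the concentration channel is a deterministic function of
    the doses (known pharmacokinetics), i.e. part of the treatment input
    rather than an outcome; counterfactual evaluation therefore feeds this
    known series instead of a model's guess.
    """
    cfg = dataset.world.config
    decay = 0.5 ** (1.0 / cfg["chemo_half_life_days"])
    toks = dataset.treatments[entity_id]
    c = 0.0
    for t in range(history_end + 1):
        c = c * decay + (cfg["chemo_dose"] if toks[t] == "chemo" else 0.0)
    out = np.empty(len(plan))
    for k, tok in enumerate(plan):
        c = c * decay + (cfg["chemo_dose"] if tok == "chemo" else 0.0)
        out[k] = c * decay  # next morning's pre-dose level
    return out


@dataclass(frozen=True)
class CounterfactualTask:
    entity_id: str
    history_end: int
    plan: tuple[str, ...]
    truth: np.ndarray  # (2, tau) volume/concentration under the plan


def make_benchmark_split(
    dataset: TumorDataset,
    regime: str,
    tau_max: int,
    history_end: int | None = None,
    n_random_plans: int = 2,
    seed: int = 0,
) -> list[CounterfactualTask]:
    """Counterfactual evaluation tasks with simulator ground truth.

    single-sliding: one plan per offset, applying chemo at that offset and
    nothing elsewhere.  random: plans drawn uniformly over the token set.
    """
    T = dataset.world.n_steps
    if history_end is None:
        history_end = T - tau_max - 1
    if history_end < 1 or history_end + tau_max >= T:
        raise ValueError("tau_max extends beyond the simulated horizon")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 909]))
    tasks = []
    for tr in dataset.trajectories:
        if regime == "single-sliding":
            plans = [
                tuple("chemo" if k == off else "none" for k in range(tau_max))
                for off in range(tau_max)
            ]
        elif regime == "random":
            plans = [
                tuple(rng.choice(TREATMENT_TOKENS) for _ in range(tau_max))
                for _ in range(n_random_plans)
            ]
        else:
            raise ValueError(f"unknown regime {regime!r}")
        for plan in plans:
            truth = resimulate_tumor(dataset, tr.entity_id, history_end, list(plan))
            tasks.append(CounterfactualTask(tr.entity_id, history_end, plan, truth))
    return tasks


def assignment_volume_correlation(dataset: TumorDataset) -> float:
    """Point-biserial correlation between treatment indicator and the recent
    mean volume across all patient-steps (the confounding diagnostic)."""
    cfg = dataset.world.config
    xs, ys = [], []
    for tr in dataset.trajectories:
        vol = tr.values[0]
        toks = dataset.treatments[tr.entity_id]
        for t in range(len(toks)):
            lo = max(0, t - cfg["recent_window"] + 1)
            xs.append(vol[lo : t + 1].mean())
            ys.append(1.0 if toks[t] != "none" else 0.0)
    xs, ys = np.asarray(xs), np.asarray(ys)
    if ys.std() == 0 or xs.std() == 0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1])


def save_world_config(world, path) -> None:
    d = {k: v for k, v in world.__dict__.items()}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, default=str)
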