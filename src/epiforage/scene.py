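"""The visual-foraging scene: generative model, environment, and trial loop.

The scene contains a small number of stimuli (default 4), each of which can
take one of a few identities (default 3) and can change identity between
saccades with a volatility governed by a transition precision ``omega``. The
agent's eye can fixate any stimulus location or a central fixation cross
(default 5 locations). Two outcome modalities are generated: a *what* outcome
reporting the identity of the foveated stimulus (with a null level seen at
the cross) through a likelihood whose sensory precision ``zeta`` depends on
the fixated location, and a *where* outcome that is an exact identity mapping
of eye position (proprioception). Prior preferences are uniform in every
modality, so all simulated behaviour is purely epistemic: saccades are driven
by expected information gain alone.

The agent's believed precisions and the environment's true precisions are
independently configurable (defaults equal), which supports both belief
manipulations (streetlight effect, inhibition of return) and parameter
recovery from simulated traces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CategoricalTable,
    GenerativeModel,
    InitialBelief,
    PolicySpace,
    PrecisionSet,
    PreferenceVector,
    TransitionTable,
    validate_model,
)
from .inference import (
    expected_free_energy,
    select_action,
    update_policy_posterior,
    update_state_beliefs,
)

__all__ = [
    "SceneConfig",
    "Environment",
    "TrialRecord",
    "build_scene_model",
    "diagonally_dominant",
    "environment_step",
    "run_trial",
]

CROSS = 0  # location index of the fixation cross


def diagonally_dominant(n: int, p_stay: float) -> np.ndarray:
    """Base transition matrix with stay probability ``p_stay`` and the
    residual mass spread uniformly over the other states (strictly positive,
    so it supports omega modulation)."""
    if not (0 < p_stay < 1):
        raise ValueError("p_stay must lie strictly between 0 and 1")
    off = (1.0 - p_stay) / (n - 1)
    return np.full((n, n), off) + (p_stay - off) * np.eye(n)


@dataclass
class SceneConfig:
    """Configuration of the foraging scene.

    ``zeta_by_location`` holds the believed sensory precision per fixation
    location (entry 0 is the cross, where the what-outcome is uninformative
    and precision is irrelevant). ``omega_by_stimulus`` holds the believed
    transition precision (inverse volatility) per stimulus; ``np.inf`` means
    a believed identity transition (zero volatility). ``true_zeta`` /
    ``true_omega`` default to the believed values.
    """

    n_stimuli: int = 4
    n_identities: int = 3
    n_locations: int | None = None  # default n_stimuli + 1
    zeta_by_location: list[float] | None = None  # default 2.0 everywhere
    omega_by_stimulus: list[float] | None = None  # default 1.0 everywhere
    true_zeta_by_location: list[float] | None = None
    true_omega_by_stimulus: list[float] | None = None
    p_correct: float = 0.9
    stay_probability: float = 0.6
    trial_length: int = 19
    gamma: float = 16.0
    action_mode: str = "sample"
    iters: int = 16
    step: float = 0.5  # filtering slices converge fast; descent holds for any step <= 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations is None:
            self.n_locations = self.n_stimuli + 1
        if self.n_locations != self.n_stimuli + 1:
            raise ValueError("layout requires n_locations == n_stimuli + 1")
        if self.zeta_by_location is None:
            self.zeta_by_location = [1.0] + [2.0] * self.n_stimuli
        if self.omega_by_stimulus is None:
            self.omega_by_stimulus = [1.0] * self.n_stimuli
        if len(self.zeta_by_location) != self.n_locations:
            raise ValueError("zeta_by_location must have one entry per location")
        if len(self.omega_by_stimulus) != self.n_stimuli:
            raise ValueError("omega_by_stimulus must have one entry per stimulus")

    @property
    def eye_factor(self) -> int:
        return self.n_stimuli

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = [float(x) if isinstance(x, (int, float, np.floating)) else x for x in v]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**d)


def _scene_precisions(config: SceneConfig, zeta, omega) -> PrecisionSet:
    return PrecisionSet(
        zeta=np.asarray(zeta, dtype=float),
        zeta_factor=config.eye_factor,
        zeta_modalities=(0,),
        omega=np.asarray(list(omega) + [1.0], dtype=float),  # eye factor is precision-neutral
    )


def build_scene_model(
    config: SceneConfig,
    zeta: list[float] | None = None,
    omega: list[float] | None = None,
) -> GenerativeModel:
    """Construct the scene's generative model.

    Hidden factors: one identity factor per stimulus plus the eye position.
    Modalities: *what* (identities + a null level for the cross) and *where*
    (identity mapping from eye position). Override ``zeta`` / ``omega`` to
    build the environment's true model when it differs from the agent's.
    """
    ns, ni, nl = config.n_stimuli, config.n_identities, config.n_locations
    sizes = [ni] * ns + [nl]
    n_what = ni + 1  # identities + null (cross)

    A_what = np.zeros([n_what] + sizes)
    base_col = np.full(ni, (1.0 - config.p_correct) / (ni - 1))
    for loc in range(nl):
        eye_ix = [slice(None)] * ns + [loc]
        if loc == CROSS:
            A_what[tuple([ni] + eye_ix)] = 1.0
        else:
            stim = loc - 1
            for ident in range(ni):
                col = base_col.copy()
                col[ident] = config.p_correct
                for o in range(ni):
                    ix = [o] + [slice(None)] * ns + [loc]
                    ix[1 + stim] = ident
                    A_what[tuple(ix)] = col[o]

    A_where = np.zeros([nl] + sizes)
    for loc in range(nl):
        A_where[tuple([loc] + [slice(None)] * ns + [loc])] = 1.0

    B_stim = diagonally_dominant(ni, config.stay_probability)[:, :, None]
    B_eye = np.zeros((nl, nl, nl))
    for a in range(nl):
        B_eye[a, :, a] = 1.0

    D_eye = np.zeros(nl)
    D_eye[CROSS] = 1.0

    model = GenerativeModel(
        A=CategoricalTable([A_what, A_where], ["what", "where"]),
        B=TransitionTable([B_stim.copy() for _ in range(ns)] + [B_eye], [f"fixate_{j}" for j in range(nl)]),
        C=PreferenceVector.uniform([n_what, nl]),
        D=InitialBelief([np.full(ni, 1.0 / ni) for _ in range(ns)] + [D_eye]),
        precision=_scene_precisions(
            config,
            zeta if zeta is not None else config.zeta_by_location,
            omega if omega is not None else config.omega_by_stimulus,
        ),
        policies=PolicySpace.single_step(nl),
        gamma_prior=config.gamma,
    )
    report = validate_model(model)
    if not report:
        raise ValueError(f"inconsistent scene model: {report.violations}")
    return model


# ---------------------------------------------------------------------------
# environment (generative process)
# ---------------------------------------------------------------------------


@dataclass
class Environment:
    """The generative process: true states plus the tables used to sample outcomes."""

    true_model: GenerativeModel
    identities: np.ndarray
    eye: int
    rng: np.random.Generator
    _Amod: list[np.ndarray] = field(default_factory=list, repr=False)
    _Bmod: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        mod = self.true_model.modulated()
        self._Amod = mod.A.values
        self._Bmod = mod.B.values

    @classmethod
    def from_config(cls, config: SceneConfig, rng: np.random.Generator) -> "Environment":
        true_model = build_scene_model(
            config,
            zeta=config.true_zeta_by_location or config.zeta_by_location,
            omega=config.true_omega_by_stimulus or config.omega_by_stimulus,
        )
        identities = rng.integers(0, config.n_identities, size=config.n_stimuli)
        return cls(true_model=true_model, identities=identities, eye=CROSS, rng=rng)

    @property
    def state(self) -> tuple[int, ...]:
        return tuple(self.identities) + (self.eye,)

    def observe(self) -> tuple[int, ...]:
        """Sample one outcome per modality from the true (modulated) likelihood."""
        out = []
        for Am in self._Amod:
            col = Am[(slice(None),) + self.state]
            out.append(int(self.rng.choice(Am.shape[0], p=col / col.sum())))
        return tuple(out)


def environment_step(env: Environment, action: int) -> tuple[tuple[int, ...], Environment]:
    """Advance the generative process by one saccade.

    The eye moves deterministically to the commanded location; every stimulus
    identity transitions by sampling its true ω-modulated transition column;
    outcomes are sampled from the true ζ-modulated likelihood.
    """
    n_actions = env.true_model.n_actions
    if not (0 <= action < n_actions):
        raise ValueError(f"invalid action {action}; scene has {n_actions} locations")
    for f in range(len(env.identities)):
        col = env._Bmod[f][:, env.identities[f], 0]
        env.identities[f] = int(env.rng.choice(col.shape[0], p=col / col.sum()))
    env.eye = int(action)
    return env.observe(), env


# ---------------------------------------------------------------------------
# trial loop
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """Everything recorded from one simulated trial.

    One entry per saccade: the action taken, resulting eye position, sampled
    outcomes, per-policy expected free energy at decision time, the marginal
    posterior per factor after the belief update, and the slice free energy.
    """

    config: SceneConfig
    seed: int
    actions: list[int] = field(default_factory=list)
    eye_positions: list[int] = field(default_factory=list)
    outcomes: list[tuple[int, ...]] = field(default_factory=list)
    G: list[np.ndarray] = field(default_factory=list)
    beliefs: list[list[np.ndarray]] = field(default_factory=list)
    F: list[float] = field(default_factory=list)
    initial_outcomes: tuple[int, ...] | None = None
    initial_beliefs: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def saccade_trace(self) -> list[int]:
        return list(self.eye_positions)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(len(self.actions)):
            row: dict = {
                "t": t,
                "action": self.actions[t],
                "eye": self.eye_positions[t],
                "o_what": self.outcomes[t][0],
                "o_where": self.outcomes[t][1],
                "F": self.F[t],
            }
            for k, g in enumerate(self.G[t]):
                row[f"G_{k}"] = g
            for f, q in enumerate(self.beliefs[t]):
                for l, val in enumerate(q):
                    row[f"q_f{f}_l{l}"] = val
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {
            "config": self.config.to_dict(),
            "seed": int(self.seed),
            "initial_outcomes": list(self.initial_outcomes) if self.initial_outcomes else None,
            "initial_beliefs": [list(map(float, q)) for q in (self.initial_beliefs or [])],
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, csv_path: str | Path) -> "TrialRecord":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, float_precision="round_trip")
        side = json.loads(csv_path.with_suffix(".json").read_text())
        config = SceneConfig.from_dict(side["config"])
        rec = cls(config=config, seed=side["seed"])
        g_cols = sorted([c for c in df.columns if c.startswith("G_")], key=lambda c: int(c[2:]))
        sizes = [config.n_identities] * config.n_stimuli + [config.n_locations]
        for _, row in df.iterrows():
            rec.actions.append(int(row["action"]))
            rec.eye_positions.append(int(row["eye"]))
            rec.outcomes.append((int(row["o_what"]), int(row["o_where"])))
            rec.F.append(float(row["F"]))
            rec.G.append(np.array([row[c] for c in g_cols]))
            rec.beliefs.append(
                [np.array([row[f"q_f{f}_l{l}"] for l in range(n)]) for f, n in enumerate(sizes)]
            )
        if side.get("initial_outcomes") is not None:
            rec.initial_outcomes = tuple(side["initial_outcomes"])
        if side.get("initial_beliefs"):
            rec.initial_beliefs = [np.array(q) for q in side["initial_beliefs"]]
        return rec


def _filter_step(
    mod: GenerativeModel,
    prior: list[np.ndarray],
    outcomes: tuple[int, ...],
    iters: int,
    step: float,
) -> tuple[list[np.ndarray], float]:
    """One Bayesian-filtering belief update: the predictive prior plays the
    role of the initial-state prior for a single-slice variational update."""
    slice_model = replace(mod, D=InitialBelief([p.copy() for p in prior]))
    beliefs, _, F = update_state_beliefs(
        slice_model, [outcomes], policy=[0], iters=iters, step=step, n_steps=1
    )
    return beliefs.s[0], float(F[-1])


def run_trial(
    model: GenerativeModel,
    env: Environment,
    trial_length: int | None = None,
    seed: int | None = None,
    *,
    config: SceneConfig | None = None,
    action_mode: str | None = None,
    record_beliefs: bool = True,
) -> TrialRecord:
    """Simulate one foraging trial: alternate perception and action.

    At every step the agent evaluates the expected free energy of each
    single-saccade policy from its current (filtered) beliefs, forms the
    policy posterior ``softmax(-gamma G)``, emits an action, receives
    outcomes from the environment, and assimilates them by minimizing
    variational free energy over the current time slice (the predictive
    prior is the believed ω-modulated transition applied to the previous
    posterior, so beliefs about unobserved volatile stimuli relax toward
    uniform at the closed-form geometric rate).
    """
    if config is None:
        config = SceneConfig()
    T = trial_length if trial_length is not None else config.trial_length
    mode = action_mode if action_mode is not None else config.action_mode
    rng = np.random.default_rng(seed if seed is not None else config.seed)

    mod = model.modulated()
    nf = model.n_factors
    gamma = model.gamma_prior
    policies = model.policies

    rec = TrialRecord(config=config, seed=int(seed) if seed is not None else config.seed)

    # initial observation at the starting eye position
    o0 = env.observe()
    qs, _ = _filter_step(mod, [d.copy() for d in mod.D.values], o0, config.iters, config.step)
    rec.initial_outcomes = o0
    rec.initial_beliefs = [q.copy() for q in qs]

    for _ in range(T):
        G = np.array([expected_free_energy(mod, qs, seq).G for seq in policies.policies])
        pp = update_policy_posterior(np.zeros_like(G), G, gamma)
        action = select_action(pp, policies, mode=mode, rng=rng)
        outcomes, env = environment_step(env, action)
        prior = [
            mod.B.values[f][:, :, action % mod.B.values[f].shape[2]] @ qs[f] for f in range(nf)
        ]
        qs, F_slice = _filter_step(mod, prior, outcomes, config.iters, config.step)

        rec.actions.append(action)
        rec.eye_positions.append(env.eye)
        rec.outcomes.append(outcomes)
        rec.G.append(np.asarray(G, dtype=float))
        rec.F.append(F_slice)
        rec.beliefs.append([q.copy() for q in qs] if record_beliefs else [])
    return rec


def simulate_trials(
    config: SceneConfig,
    n_trials: int,
    base_seed: int | None = None,
) -> list[TrialRecord]:
    """Run many independent seeded trials of the configured scene."""
    base = config.seed if base_seed is None else base_seed
    model = build_scene_model(config)
    records = []
    for ss in np.random.SeedSequence(base).spawn(n_trials):
        child = np.random.default_rng(ss)
        env = Environment.from_config(config, child)
        trial_seed = int(ss.generate_state(1)[0] % (2**31))
        records.append(run_trial(model, env, config.trial_length, trial_seed, config=config))
    return records
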