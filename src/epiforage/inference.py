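"""Variational inference for discrete-state active inference.

Perception is implemented as minimization of variational free energy under a
mean-field posterior factorized over policies, time points and hidden-state
factors. Each factor/time marginal is updated from three messages: the
expected log-transition from the past (or the initial prior), the expected
log-transition from the future, and the mean-field expectation of the
log-likelihood of observed outcomes — all evaluated under the
precision-modulated tables (ζ on the likelihood, ω on transitions). Updates
are damped in log space (the auxiliary "depolarization" variable) and
normalized through a softmax, and the recorded free energy is non-increasing
across sweeps.

Policies are scored by their accumulated free energy F and expected free
energy G, combined in a softmax posterior ``softmax(-F - gamma * G)`` whose
inverse temperature gamma (policy precision) can itself be updated toward a
fixed point of the free energy.

An exhaustive-enumeration oracle over state trajectories provides exact
posteriors for small models, used to validate the variational scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    GenerativeModel,
    PrecisionSet,
    safe_log,
)

__all__ = [
    "Observation",
    "BeliefState",
    "Depolarization",
    "PolicyPosterior",
    "EFEDecomposition",
    "EFEResult",
    "update_state_beliefs",
    "expected_outcomes",
    "expected_free_energy",
    "enumerate_efe",
    "update_policy_posterior",
    "update_gamma",
    "infer_gamma",
    "select_action",
    "bayesian_model_average",
    "exact_posterior_oracle",
    "forward_backward_posterior",
    "factor_pair_marginal",
    "softmax",
]


def softmax(x: np.ndarray) -> np.ndarray:
    z = np.asarray(x, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    return float(-np.sum(np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)))


def _contract_except(t: np.ndarray, qs: list[np.ndarray], keep: int) -> np.ndarray:
    """Contract a state-space tensor with every factor belief except ``keep``.

    Contracting axes in descending order leaves every lower axis index in
    place, so factor ``f``'s axis is always at position ``f`` at its turn.
    """
    out = t
    for f in range(len(qs) - 1, -1, -1):
        if f == keep:
            continue
        out = np.tensordot(out, qs[f], axes=(f, 0))
    return out


def _contract_all(t: np.ndarray, qs: list[np.ndarray]) -> float:
    out = t
    for f in range(len(qs) - 1, -1, -1):
        out = np.tensordot(out, qs[f], axes=(f, 0))
    return float(out)


@dataclass
class Observation:
    """Observed outcome indices, time x modality."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=int))

    @classmethod
    def coerce(cls, obs) -> "Observation":
        if isinstance(obs, Observation):
            return obs
        return cls(np.asarray(obs, dtype=int))

    @classmethod
    def from_onehot(cls, vectors) -> "Observation":
        """Build from one-hot outcome vectors, time x modality x levels."""
        return cls(
            np.array([[int(np.argmax(v)) for v in row] for row in vectors], dtype=int)
        )

    def validate(self, n_outcomes: tuple[int, ...]) -> None:
        for m, n in enumerate(n_outcomes):
            col = self.indices[:, m]
            if col.size and (col.min() < 0 or col.max() >= n):
                raise ValueError(f"observation index out of range for modality {m}")

    @property
    def n_times(self) -> int:
        return self.indices.shape[0]


@dataclass
class BeliefState:
    """Posterior expectations over hidden states, time x factor, for one policy."""

    s: list[list[np.ndarray]]

    def marginal(self, tau: int) -> list[np.ndarray]:
        return self.s[tau]

    @property
    def n_times(self) -> int:
        return len(self.s)


@dataclass
class Depolarization:
    """Log-belief auxiliary variables and per-sweep state prediction errors."""

    v: list[list[np.ndarray]]
    epsilon: list[float] = field(default_factory=list)


@dataclass
class PolicyPosterior:
    """Posterior over policies with its free-energy ingredients."""

    pi: np.ndarray
    F: np.ndarray
    G: np.ndarray
    gamma: float
    beta: float = 0.0
    beta0: float = 0.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.beta == 0.0:
            self.beta = 1.0 / self.gamma if self.gamma > 0 else float("inf")
        if self.beta0 == 0.0:
            self.beta0 = self.beta


@dataclass
class EFEDecomposition:
    """Per-policy expected free energy split into its interpretable parts.

    ``pragmatic`` is the expected log preference of predicted outcomes;
    ``epistemic`` is the expected information gain (salience), the mutual
    information between predicted states and predicted outcomes; ``ambiguity``
    is the expected entropy of the likelihood columns. They satisfy
    ``epistemic = H(predicted outcomes) - ambiguity`` and
    ``G = -pragmatic - epistemic``.
    """

    pragmatic: float
    epistemic: float
    ambiguity: float

    @property
    def G(self) -> float:
        return -self.pragmatic - self.epistemic


@dataclass
class EFEResult:
    """Expected free energy per future time step, with decompositions."""

    G_per_tau: np.ndarray
    decompositions: list[EFEDecomposition]
    predicted_states: list[list[np.ndarray]]

    @property
    def G(self) -> float:
        return float(self.G_per_tau.sum())


# ---------------------------------------------------------------------------
# state inference
# ---------------------------------------------------------------------------


def _log_tables(model: GenerativeModel):
    mod = model.modulated()
    lnA = [safe_log(a) for a in mod.A.values]
    lnB = [safe_log(b) for b in mod.B.values]
    lnD = [safe_log(d) for d in mod.D.values]
    return mod, lnA, lnB, lnD


def _free_energy_from_logs(
    qs: list[list[np.ndarray]],
    obs: Observation,
    policy: np.ndarray,
    lnA: list[np.ndarray],
    lnB: list[np.ndarray],
    lnD: list[np.ndarray],
    n_modalities: int,
) -> float:
    F = 0.0
    for tau in range(len(qs)):
        for f, q in enumerate(qs[tau]):
            F += float(np.sum(np.where(q > 0, q * np.log(np.where(q > 0, q, 1.0)), 0.0)))
            if tau == 0:
                F -= float(q @ lnD[f])
            else:
                a = int(policy[min(tau - 1, len(policy) - 1)])
                Bfa = lnB[f][:, :, a % lnB[f].shape[2]]
                F -= float(q @ (Bfa @ qs[tau - 1][f]))
        if tau < obs.n_times:
            for m in range(n_modalities):
                F -= _contract_all(lnA[m][obs.indices[tau, m]], qs[tau])
    return F


def free_energy(
    model: GenerativeModel,
    beliefs: BeliefState,
    observations,
    policy: np.ndarray,
) -> float:
    """Mean-field variational free energy of a belief trajectory (nats)."""
    obs = Observation.coerce(observations)
    _, lnA, lnB, lnD = _log_tables(model)
    return _free_energy_from_logs(
        beliefs.s, obs, np.atleast_1d(np.asarray(policy, dtype=int)), lnA, lnB, lnD, model.n_modalities
    )


def update_state_beliefs(
    model: GenerativeModel,
    observations,
    policy,
    iters: int = 16,
    step: float = 0.25,
    n_steps: int | None = None,
    tol: float = 1e-6,
    init: BeliefState | None = None,
    window: int | None = None,
) -> tuple[BeliefState, Depolarization, np.ndarray]:
    """Gradient descent on variational free energy for one policy.

    Sweeps over time points and factors, updating each marginal from its
    transition messages (past and future, under the ω-modulated transitions)
    and the ζ-modulated likelihood of observed outcomes, with a damped
    log-space step followed by softmax normalization. Returns the converged
    beliefs, the depolarization traces, and the free energy recorded after
    every sweep (non-increasing to within ``tol``).

    ``window`` restricts re-smoothing to a moving window of time slices:
    with ``window=1`` the update is pure Bayesian filtering — each slice's
    prior is the ω-modulated transition applied to the frozen previous
    posterior, so with an uninformative likelihood the beliefs equal the
    transition-propagated prior exactly. ``None`` (default) re-smooths the
    whole trajectory.
    """
    if window is not None and window == 1:
        return _filtering_update(model, observations, policy, iters, step, n_steps, tol)
    if window is not None:
        raise ValueError("window must be None (full trajectory) or 1 (filtering)")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if not (0.0 < step <= 1.0):
        raise ValueError("step must lie in (0, 1]")
    obs = Observation.coerce(observations)
    obs.validate(model.n_outcomes)
    policy = np.atleast_1d(np.asarray(policy, dtype=int))
    if n_steps is None:
        n_steps = max(obs.n_times, len(policy) + 1)
    mod, lnA, lnB, lnD = _log_tables(model)
    nf = model.n_factors

    def action_at(tau: int) -> int:
        return int(policy[min(tau - 1, len(policy) - 1)]) if len(policy) else 0

    if init is not None:
        qs = [[q.copy() for q in row] for row in init.s]
    else:
        # forward-propagated prior initialization
        qs = [[d.copy() for d in mod.D.values]]
        for tau in range(1, n_steps):
            a = action_at(tau)
            qs.append(
                [mod.B.values[f][:, :, a % mod.B.values[f].shape[2]] @ qs[tau - 1][f] for f in range(nf)]
            )
    v = [[safe_log(q) for q in row] for row in qs]

    beliefs = BeliefState(qs)
    depol = Depolarization(v)
    F_trace: list[float] = []
    for it in range(iters):
        eps = 0.0
        for tau in range(n_steps):
            for f in range(nf):
                if tau == 0:
                    msg = lnD[f].copy()
                else:
                    a = action_at(tau)
                    msg = lnB[f][:, :, a % lnB[f].shape[2]] @ qs[tau - 1][f]
                if tau + 1 < n_steps:
                    a = action_at(tau + 1)
                    msg = msg + lnB[f][:, :, a % lnB[f].shape[2]].T @ qs[tau + 1][f]
                if tau < obs.n_times:
                    for m in range(model.n_modalities):
                        msg = msg + _contract_except(lnA[m][obs.indices[tau, m]], qs[tau], f)
                resid = msg - v[tau][f]
                resid = resid - resid.mean()
                eps = max(eps, float(np.abs(resid).max()))
                v[tau][f] = (1.0 - step) * v[tau][f] + step * msg
                q = softmax(v[tau][f])
                qs[tau][f] = q
                v[tau][f] = np.log(q)  # keep v and q consistent (softmax(v) == q)
        depol.epsilon.append(eps)
        F_trace.append(
            _free_energy_from_logs(qs, obs, policy, lnA, lnB, lnD, model.n_modalities)
        )
        if len(F_trace) > 1 and abs(F_trace[-1] - F_trace[-2]) < tol:
            break
    if len(F_trace) > 1 and F_trace[-1] > F_trace[0] + 1e-6 * len(F_trace):
        warnings.warn(
            "update_state_beliefs: free energy increased; returning last iterate "
            "(consider a smaller step size)",
            RuntimeWarning,
        )
    return beliefs, depol, np.asarray(F_trace)


def _filtering_update(
    model: GenerativeModel,
    observations,
    policy,
    iters: int,
    step: float,
    n_steps: int | None,
    tol: float,
) -> tuple[BeliefState, Depolarization, np.ndarray]:
    """Window-1 (pure filtering) belief propagation: predictive priors are the
    ω-modulated transitions applied to the frozen previous posterior."""
    obs = Observation.coerce(observations)
    obs.validate(model.n_outcomes)
    policy = np.atleast_1d(np.asarray(policy, dtype=int))
    if n_steps is None:
        n_steps = max(obs.n_times, len(policy) + 1)
    mod, lnA, lnB, lnD = _log_tables(model)
    nf = model.n_factors

    qs: list[list[np.ndarray]] = []
    v: list[list[np.ndarray]] = []
    eps_trace: list[float] = []
    F_slices: list[float] = []
    for tau in range(n_steps):
        if tau == 0:
            prior = [d.copy() for d in mod.D.values]
        else:
            a = int(policy[min(tau - 1, len(policy) - 1)]) if len(policy) else 0
            prior = [
                mod.B.values[f][:, :, a % mod.B.values[f].shape[2]] @ qs[tau - 1][f]
                for f in range(nf)
            ]
        ln_prior = [safe_log(p) for p in prior]
        row = [p.copy() for p in prior]
        vrow = [lp.copy() for lp in ln_prior]
        last_F = None
        for _ in range(iters):
            eps = 0.0
            for f in range(nf):
                msg = ln_prior[f].copy()
                if tau < obs.n_times:
                    for m in range(model.n_modalities):
                        msg = msg + _contract_except(lnA[m][obs.indices[tau, m]], row, f)
                resid = msg - vrow[f]
                resid = resid - resid.mean()
                eps = max(eps, float(np.abs(resid).max()))
                vrow[f] = (1.0 - step) * vrow[f] + step * msg
                q = softmax(vrow[f])
                row[f] = q
                vrow[f] = np.log(q)
            F = sum(
                float(np.sum(np.where(q > 0, q * (np.log(np.where(q > 0, q, 1.0)) - lp), 0.0)))
                for q, lp in zip(row, ln_prior)
            )
            if tau < obs.n_times:
                for m in range(model.n_modalities):
                    F -= _contract_all(lnA[m][obs.indices[tau, m]], row)
            if last_F is not None and abs(F - last_F) < tol:
                last_F = F
                break
            last_F = F
            eps_trace.append(eps)
        qs.append(row)
        v.append(vrow)
        F_slices.append(last_F if last_F is not None else 0.0)
    return BeliefState(qs), Depolarization(v, eps_trace), np.asarray(F_slices)


def expected_outcomes(
    beliefs: list[np.ndarray] | BeliefState,
    model: GenerativeModel,
    policy=None,
    tau: int = -1,
) -> list[np.ndarray]:
    """Predicted outcome distribution per modality under current beliefs.

    Applies the ζ-modulated likelihood to the factorized state expectation
    (at time ``tau`` if a full ``BeliefState`` is given).
    """
    if isinstance(beliefs, BeliefState):
        qs = beliefs.s[tau]
    else:
        qs = list(beliefs)
    mod = model.modulated()
    out = []
    for m in range(model.n_modalities):
        t = mod.A.values[m]
        for f in range(len(qs) - 1, -1, -1):
            t = np.tensordot(t, qs[f], axes=(1 + f, 0))
        out.append(t / t.sum())
    return out


def expected_free_energy(
    model: GenerativeModel,
    beliefs: list[np.ndarray] | BeliefState,
    policy,
    tau: int = -1,
) -> EFEResult:
    """Expected free energy of a policy, accumulated over future time steps.

    Starting from the current factorized beliefs, states are propagated
    through the ω-modulated transitions for each action of the policy; at
    every future step the predicted outcome distribution (through the
    ζ-modulated likelihood) yields a pragmatic term (expected log preference)
    and an epistemic term (mutual information between predicted states and
    outcomes, summed over modalities):

        G(pi, tau) = -pragmatic - epistemic.

    With uniform preferences the pragmatic term is constant across policies,
    so policy selection is purely epistemic.
    """
    actions = np.atleast_1d(np.asarray(policy, dtype=int))
    if actions.size == 0:
        raise ValueError("expected_free_energy: empty policy (horizon 0)")
    if isinstance(beliefs, BeliefState):
        qs = [q.copy() for q in beliefs.s[tau]]
    else:
        qs = [np.asarray(q, dtype=float).copy() for q in beliefs]
    mod = model.modulated()
    nf = model.n_factors

    G = np.zeros(actions.size)
    decomps: list[EFEDecomposition] = []
    predicted: list[list[np.ndarray]] = []
    for k, a in enumerate(actions):
        qs = [mod.B.values[f][:, :, a % mod.B.values[f].shape[2]] @ qs[f] for f in range(nf)]
        predicted.append([q.copy() for q in qs])
        pragmatic = 0.0
        epistemic = 0.0
        ambiguity = 0.0
        for m in range(model.n_modalities):
            Amod = mod.A.values[m]
            t = Amod
            for f in range(nf - 1, -1, -1):
                t = np.tensordot(t, qs[f], axes=(1 + f, 0))
            Qo = t
            # expected entropy of likelihood columns (ambiguity)
            with np.errstate(divide="ignore", invalid="ignore"):
                H_cols = -np.sum(np.where(Amod > 0, Amod * np.log(np.where(Amod > 0, Amod, 1.0)), 0.0), axis=0)
            amb = _contract_all(H_cols, qs)
            epi = _entropy(Qo) - amb
            pragmatic += float(Qo @ model.C.values[m])
            epistemic += epi
            ambiguity += amb
        decomps.append(EFEDecomposition(pragmatic, epistemic, ambiguity))
        G[k] = -pragmatic - epistemic
    return EFEResult(G, decomps, predicted)


def enumerate_efe(
    model: GenerativeModel,
    beliefs: list[np.ndarray],
    policy,
) -> EFEResult:
    """Expected free energy by brute-force enumeration of joint states/outcomes.

    Test oracle: propagates the joint state distribution explicitly and
    computes the epistemic term as a double sum over joint states and outcomes
    (mutual information by definition), independently of the entropy-difference
    shortcut used by :func:`expected_free_energy`.
    """
    actions = np.atleast_1d(np.asarray(policy, dtype=int))
    mod = model.modulated()
    sizes = model.factor_sizes
    nf = len(sizes)
    # joint over configurations
    p = np.ones(sizes)
    for f, q in enumerate(beliefs):
        shape = [1] * nf
        shape[f] = sizes[f]
        p = p * np.asarray(q).reshape(shape)

    G = np.zeros(actions.size)
    decomps = []
    predicted = []
    for k, a in enumerate(actions):
        for f in range(nf):
            Bfa = mod.B.values[f][:, :, a % mod.B.values[f].shape[2]]
            p = np.moveaxis(np.tensordot(Bfa, p, axes=(1, f)), 0, f)
        predicted.append([p.sum(axis=tuple(g for g in range(nf) if g != f)) for f in range(nf)])
        pragmatic = epistemic = ambiguity = 0.0
        flat = p.reshape(-1)
        for m in range(model.n_modalities):
            Am = mod.A.values[m].reshape(mod.A.values[m].shape[0], -1)
            joint = Am * flat[None, :]  # p(o, s)
            po = joint.sum(axis=1)
            ps = flat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = joint / (po[:, None] * ps[None, :])
                mi = np.sum(np.where(joint > 0, joint * np.log(np.where(joint > 0, ratio, 1.0)), 0.0))
                amb = -np.sum(np.where(joint > 0, joint * np.log(np.where(Am > 0, Am, 1.0)), 0.0))
            pragmatic += float(po @ model.C.values[m])
            epistemic += float(mi)
            ambiguity += float(amb)
        decomps.append(EFEDecomposition(pragmatic, epistemic, ambiguity))
        G[k] = -pragmatic - epistemic
    return EFEResult(G, decomps, predicted)


# ---------------------------------------------------------------------------
# policy inference
# ---------------------------------------------------------------------------


def update_policy_posterior(F: np.ndarray, G: np.ndarray, gamma: float) -> PolicyPosterior:
    """Softmax policy posterior ``pi = softmax(-F - gamma * G)``."""
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if F.shape != G.shape:
        raise ValueError(f"F and G length mismatch: {F.shape} vs {G.shape}")
    pi = softmax(-F - gamma * G)
    return PolicyPosterior(pi=pi, F=F, G=G, gamma=gamma)


def update_gamma(
    pi: np.ndarray,
    pi0: np.ndarray,
    G: np.ndarray,
    beta: float,
    beta0: float,
    step: float = 1.0,
    beta_min: float = 1e-6,
) -> float:
    """One damped update of the policy precision gamma = 1/beta.

    The inverse precision beta moves toward its prior value plus the
    difference between the posterior- and prior-policy averages of the
    expected free energy. At the fixed point the post- and pre-update policy
    posteriors coincide and beta rests at ``beta0 + (pi - pi0) @ G``.
    """
    if beta <= 0 or beta0 <= 0:
        raise ValueError("beta and beta0 must be positive")
    target = beta0 + float((np.asarray(pi) - np.asarray(pi0)) @ np.asarray(G))
    beta_new = beta + step * (target - beta)
    if beta_new <= beta_min:
        warnings.warn("update_gamma: beta clipped at beta_min", RuntimeWarning)
        beta_new = beta_min
    return 1.0 / beta_new


def infer_gamma(
    F: np.ndarray,
    G: np.ndarray,
    beta0: float,
    iters: int = 32,
    step: float = 0.5,
    tol: float = 1e-10,
) -> float:
    """Iterate gamma updates to their fixed point for fixed F and G."""
    beta = beta0
    for _ in range(iters):
        gamma = 1.0 / beta
        pi = softmax(-np.asarray(F) - gamma * np.asarray(G))
        pi0 = softmax(-gamma * np.asarray(G))
        new_gamma = update_gamma(pi, pi0, G, beta, beta0, step=step)
        if abs(1.0 / new_gamma - beta) < tol:
            beta = 1.0 / new_gamma
            break
        beta = 1.0 / new_gamma
    return 1.0 / beta


def select_action(
    pp: PolicyPosterior,
    policies,
    mode: str = "map",
    rng: np.random.Generator | None = None,
) -> int:
    """Choose the next action from a policy posterior.

    ``map`` takes the first action of the highest-probability policy (ties
    broken toward the lowest policy index); ``sample`` draws from the marginal
    distribution over next actions using ``rng``.
    """
    seqs = policies.policies if hasattr(policies, "policies") else np.atleast_2d(policies)
    first = seqs[:, 0]
    if mode == "map":
        return int(first[int(np.argmax(pp.pi))])
    if mode == "sample":
        if rng is None:
            raise ValueError("sample mode requires an rng")
        n_actions = int(first.max()) + 1
        marg = np.zeros(n_actions)
        np.add.at(marg, first, pp.pi)
        marg = marg / marg.sum()
        return int(rng.choice(n_actions, p=marg))
    raise ValueError(f"unknown action-selection mode: {mode!r}")


def bayesian_model_average(
    per_policy: list[BeliefState], pi: np.ndarray
) -> list[list[np.ndarray]]:
    """Marginal beliefs: the pi-weighted mixture of per-policy beliefs."""
    pi = np.asarray(pi, dtype=float)
    n_times = per_policy[0].n_times
    nf = len(per_policy[0].s[0])
    out = []
    for tau in range(n_times):
        row = []
        for f in range(nf):
            q = np.zeros_like(per_policy[0].s[tau][f])
            for p, b in zip(pi, per_policy):
                q = q + p * b.s[tau][f]
            row.append(q)
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# exact oracle
# ---------------------------------------------------------------------------


def exact_posterior_oracle(
    model: GenerativeModel,
    observations,
    policy,
    gamma: float | None = None,
    policies: list | None = None,
    max_trajectories: int = 100_000,
):
    """Exact posteriors by exhaustive enumeration of state trajectories.

    Returns ``(marginals, log_evidence)`` where ``marginals[tau][f]`` is the
    exact smoothing posterior for factor ``f`` at time ``tau`` under the given
    policy, and ``log_evidence`` is the exact log marginal likelihood of the
    observations (so the exact accumulated free energy is its negative).
    Refuses when the trajectory space exceeds ``max_trajectories``.
    """
    obs = Observation.coerce(observations)
    policy = np.atleast_1d(np.asarray(policy, dtype=int))
    mod = model.modulated()
    sizes = model.factor_sizes
    T = obs.n_times
    n_configs = int(np.prod(sizes))
    if n_configs**T > max_trajectories:
        raise ValueError(
            f"state-trajectory space {n_configs}^{T} exceeds {max_trajectories}; oracle refuses"
        )
    configs = list(np.ndindex(*sizes))
    with np.errstate(divide="ignore"):
        logD = np.array([sum(np.log(mod.D.values[f][c[f]]) for f in range(len(sizes))) for c in configs])
        loglik = np.zeros((T, n_configs))
        for tau in range(T):
            for j, c in enumerate(configs):
                loglik[tau, j] = sum(
                    np.log(mod.A.values[m][(obs.indices[tau, m],) + c])
                    for m in range(model.n_modalities)
                )
        logB = np.zeros((T, n_configs, n_configs))  # tau -> (next, prev)
        for tau in range(1, T):
            a = int(policy[min(tau - 1, len(policy) - 1)])
            for jn, cn in enumerate(configs):
                for jp, cp in enumerate(configs):
                    logB[tau, jn, jp] = sum(
                        np.log(mod.B.values[f][cn[f], cp[f], a % mod.B.values[f].shape[2]])
                        for f in range(len(sizes))
                    )

    # enumerate all trajectories
    trajs = np.array(list(np.ndindex(*([n_configs] * T))), dtype=int)  # (n_traj, T)
    logp = logD[trajs[:, 0]] + loglik[0, trajs[:, 0]]
    for tau in range(1, T):
        logp = logp + logB[tau, trajs[:, tau], trajs[:, tau - 1]] + loglik[tau, trajs[:, tau]]
    finite = logp > -np.inf
    from scipy.special import logsumexp

    log_evidence = float(logsumexp(logp[finite]))
    w = np.zeros_like(logp)
    w[finite] = np.exp(logp[finite] - log_evidence)

    marginals = []
    for tau in range(T):
        row = [np.zeros(n) for n in sizes]
        for j in range(n_configs):
            mass = w[trajs[:, tau] == j].sum()
            for f in range(len(sizes)):
                row[f][configs[j][f]] += mass
        marginals.append(row)
    return marginals, log_evidence


def forward_backward_posterior(
    model: GenerativeModel,
    observations,
    policy,
    max_configs: int = 512,
):
    """Exact smoothing marginals by forward-backward on the joint chain.

    Treats the full state configuration as a single chain variable (feasible
    while the joint configuration count stays small), giving the exact
    posterior marginals per factor and time, the exact pairwise joint over
    consecutive configurations, and the exact log evidence. Unlike the
    mean-field scheme this does not overcount evidence through temporal
    ties, so it is the preferred inference route for parameter estimation
    from recorded traces.
    """
    obs = Observation.coerce(observations)
    policy = np.atleast_1d(np.asarray(policy, dtype=int))
    mod = model.modulated()
    sizes = model.factor_sizes
    nf = len(sizes)
    n_configs = int(np.prod(sizes))
    if n_configs > max_configs:
        raise ValueError(f"joint configuration space {n_configs} exceeds {max_configs}")
    T = obs.n_times

    # joint transition per action and joint emission per time
    def joint_T(a: int) -> np.ndarray:
        out = np.ones((1, 1))
        for f in range(nf):
            Bfa = mod.B.values[f][:, :, a % mod.B.values[f].shape[2]]
            out = np.kron(out, Bfa)
        return out

    lik = np.ones((T, n_configs))
    for m in range(model.n_modalities):
        Am = mod.A.values[m].reshape(mod.A.values[m].shape[0], -1)
        for tau in range(T):
            lik[tau] *= Am[obs.indices[tau, m]]
    # an observation that is impossible under the working model (every config
    # at zero likelihood) must not zero the normalizer: the floor turns such a
    # step into a prediction-only update instead of NaN posteriors
    lik = np.maximum(lik, 1e-300)
    prior = np.ones(1)
    for f in range(nf):
        prior = np.kron(prior, mod.D.values[f])

    Ts = [joint_T(int(policy[min(tau - 1, len(policy) - 1)]) if len(policy) else 0) for tau in range(1, T)]
    alpha = np.zeros((T, n_configs))
    c = np.zeros(T)
    a0 = prior * lik[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for tau in range(1, T):
        a = (Ts[tau - 1] @ alpha[tau - 1]) * lik[tau]
        c[tau] = a.sum()
        alpha[tau] = a / c[tau]
    beta = np.ones((T, n_configs))
    for tau in range(T - 2, -1, -1):
        beta[tau] = Ts[tau].T @ (beta[tau + 1] * lik[tau + 1]) / c[tau + 1]
    gamma_j = alpha * beta
    gamma_j /= gamma_j.sum(axis=1, keepdims=True)

    marginals = []
    for tau in range(T):
        g = gamma_j[tau].reshape(sizes)
        marginals.append(
            [g.sum(axis=tuple(k for k in range(nf) if k != f)) for f in range(nf)]
        )
    pairwise = []
    for tau in range(1, T):
        xi = Ts[tau - 1] * np.outer(beta[tau] * lik[tau], alpha[tau - 1]) / c[tau]
        xi /= xi.sum()
        pairwise.append(xi)  # (next config, previous config)
    return marginals, pairwise, float(np.sum(np.log(c)))


def factor_pair_marginal(xi: np.ndarray, sizes: tuple[int, ...], factor: int) -> np.ndarray:
    """Contract a joint pairwise configuration table to one factor's pair table."""
    nf = len(sizes)
    t = xi.reshape(tuple(sizes) + tuple(sizes))
    axes = tuple(k for k in range(nf) if k != factor) + tuple(
        nf + k for k in range(nf) if k != factor
    )
    return t.sum(axis=axes)


def oracle_policy_posterior(
    model: GenerativeModel,
    observations,
    policies,
    gamma: float,
    G: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact policy posterior ``softmax(-F - gamma G)`` with enumerated F.

    ``F`` per policy is the negative exact log evidence of the observations
    under that policy. If ``G`` is not given it is taken as zero (purely
    retrospective posterior). Returns ``(pi, F)``.
    """
    seqs = policies.policies if hasattr(policies, "policies") else np.atleast_2d(policies)
    F = np.array(
        [-exact_posterior_oracle(model, observations, seq)[1] for seq in seqs]
    )
    if G is None:
        G = np.zeros_like(F)
    logits = -F - gamma * np.asarray(G)
    e = np.exp(logits - logits.max())
    return e / e.sum(), F
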