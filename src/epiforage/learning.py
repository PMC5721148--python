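"""Bayes-optimal gradient updates for the precision parameters ζ and ω.

Because the precision-modulated likelihood and transition tables are Gibbs
measures, the derivative of the variational free energy with respect to a
precision parameter takes an exponential-family form: the posterior-expected
base log-probability of what was observed (or inferred), minus its
expectation under the current modulated table (the partition-function
derivative). The gradients vanish exactly at the stationary point — when the
current precision estimate makes the modulated table consistent with the
statistics of the data — and are identically zero for flat (uninformative)
columns, where the precision is unidentifiable.

Estimates are updated by gradient ascent in the log-precision domain, which
preserves positivity without clipping, optionally regularized by a Gaussian
prior on the log precision (``prior_mean``, ``prior_rate``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model import GenerativeModel, safe_log
from .inference import BeliefState, Observation, update_state_beliefs

__all__ = [
    "PrecisionBelief",
    "PrecisionError",
    "zeta_gradient",
    "omega_gradient",
    "ascend_precision",
    "recover_from_trace",
    "recovery_report",
]


@dataclass
class PrecisionBelief:
    """A point belief about one precision parameter with its ascent history."""

    estimate: float
    prior_mean: float = 1.0
    prior_rate: float = 1.0
    step: float = 0.05
    trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.estimate <= 0:
            raise ValueError("precision estimate must be positive")
        if not self.trace:
            self.trace = [self.estimate]

    def prior_log_gradient(self, value: float) -> float:
        """d/d(ln value) of the Gaussian prior on the log precision."""
        return self.prior_rate * (np.log(self.prior_mean) - np.log(value))


@dataclass
class PrecisionError:
    """Signed free-energy gradients for the precision parameters (nats).

    ``zeta_error[j]`` is the average per-observation gradient of the evidence
    bound with respect to ζ at level ``j`` of the ζ-bearing factor;
    ``omega_error[f]`` the per-transition gradient for factor ``f``. A
    positive error increases the estimate under gradient ascent.
    ``zeta_events`` / ``omega_events`` give the evidence counts behind each
    average (zero for unvisited locations or single-step traces).
    """

    zeta_error: np.ndarray | None = None
    omega_error: np.ndarray | None = None
    zeta_events: np.ndarray | None = None
    omega_events: np.ndarray | None = None


def _beliefs_list(beliefs) -> list[list[np.ndarray]]:
    if isinstance(beliefs, BeliefState):
        return beliefs.s
    return beliefs


def _joint_weights(qs: list[np.ndarray]) -> np.ndarray:
    """Flattened mean-field joint over state configurations."""
    p = np.array(1.0)
    for q in qs:
        p = np.multiply.outer(p, q)
    return p.reshape(-1)


def _level_index(sizes: tuple[int, ...], factor: int) -> np.ndarray:
    """Level of ``factor`` for each flattened state configuration."""
    grids = np.indices(sizes)
    return grids[factor].reshape(-1)


def _zeta_partition_term(lnflat: np.ndarray, zeta_of_config: np.ndarray) -> np.ndarray:
    """E under the ζ-modulated column of the base log-likelihood, per config."""
    logits = zeta_of_config[None, :] * lnflat
    logits = logits - logits.max(axis=0, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=0, keepdims=True)
    return (p * lnflat).sum(axis=0)


def zeta_gradient(
    model: GenerativeModel,
    beliefs,
    observations,
    prior: PrecisionBelief | None = None,
) -> PrecisionError:
    """Free-energy gradient with respect to the sensory precision ζ.

    For every observed outcome the gradient contribution is the
    posterior-expected base log-likelihood of that outcome minus its
    expectation under the ζ-modulated likelihood (the partition-function
    derivative), accumulated per level of the ζ-bearing factor and averaged
    over the evidence count. Unvisited levels receive no evidence and a zero
    gradient; uniform likelihood columns contribute exactly zero (ζ there is
    unidentifiable).
    """
    prec = model.precision
    if prec.zeta is None or prec.zeta_factor is None:
        raise ValueError("model has no zeta parameterization")
    obs = Observation.coerce(observations)
    qs_t = _beliefs_list(beliefs)
    sizes = model.factor_sizes
    factor = prec.zeta_factor
    lev = _level_index(sizes, factor)
    n_levels = sizes[factor]
    modalities = prec.zeta_modalities or tuple(range(model.n_modalities))
    zeta_of_config = prec.zeta[lev]

    grad = np.zeros(n_levels)
    events = np.zeros(n_levels)
    for m in modalities:
        lnflat = safe_log(model.A.values[m].reshape(model.A.values[m].shape[0], -1))
        eterm = _zeta_partition_term(lnflat, zeta_of_config)
        for tau in range(min(obs.n_times, len(qs_t))):
            w = _joint_weights(qs_t[tau])
            contrib = w * (lnflat[obs.indices[tau, m]] - eterm)
            np.add.at(grad, lev, contrib)
            np.add.at(events, lev, w)
    avg = np.divide(grad, events, out=np.zeros_like(grad), where=events > 1e-12)
    if prior is not None:
        with np.errstate(divide="ignore"):
            avg = avg + np.where(
                events > 1e-12,
                prior.prior_rate * (np.log(prior.prior_mean) - np.log(prec.zeta)) / prec.zeta,
                0.0,
            )
    return PrecisionError(zeta_error=avg, zeta_events=events)


def omega_gradient(
    model: GenerativeModel,
    beliefs,
    prior: PrecisionBelief | None = None,
    action_sequence=None,
) -> PrecisionError:
    """Free-energy gradient with respect to the transition precision ω.

    For each factor, every consecutive pair of belief vectors contributes the
    expected base log-transition of the inferred (mean-field) state pair
    minus its expectation under the ω-modulated transition. A single-time
    trace yields no transitions and a zero gradient; uniform base columns
    contribute exactly zero. Factors held at symbolic infinite precision are
    skipped (gradient zero, no evidence).
    """
    prec = model.precision
    omega = prec.omega_for(model.n_factors)
    qs_t = _beliefs_list(beliefs)
    nf = model.n_factors
    grad = np.zeros(nf)
    events = np.zeros(nf)
    T = len(qs_t)
    for f in range(nf):
        w = omega[f]
        if np.isinf(w):
            continue
        base = model.B.values[f]
        for tau in range(1, T):
            a = 0
            if action_sequence is not None:
                a = int(action_sequence[tau - 1]) % base.shape[2]
            Bfa = base[:, :, a]
            lnB = safe_log(Bfa)
            logits = w * lnB
            logits = logits - logits.max(axis=0, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=0, keepdims=True)
            eterm = (p * lnB).sum(axis=0)  # per previous state
            q_prev = qs_t[tau - 1][f]
            q_next = qs_t[tau][f]
            grad[f] += float(q_next @ lnB @ q_prev - eterm @ q_prev)
            events[f] += 1.0
    avg = np.divide(grad, events, out=np.zeros_like(grad), where=events > 0)
    if prior is not None:
        with np.errstate(divide="ignore"):
            avg = avg + np.where(
                events > 0,
                prior.prior_rate * (np.log(prior.prior_mean) - np.log(omega)) / omega,
                0.0,
            )
    return PrecisionError(omega_error=avg, omega_events=events)


def ascend_precision(
    belief: PrecisionBelief,
    error,
    n_steps: int = 64,
    tol: float = 1e-5,
    max_estimate: float = 1e3,
) -> PrecisionBelief:
    """Gradient ascent on a single precision parameter.

    ``error`` is either a fixed signed gradient (in precision units) or a
    callable ``error(estimate) -> gradient`` re-evaluated at every step.
    Updates are performed in the log domain (``ln x += step * x * error``),
    which preserves positivity; the prior's pull toward ``prior_mean`` is
    added automatically. Ascent halts early once ``|error| < tol`` and raises
    if the estimate diverges beyond ``max_estimate``.
    """
    if belief.step <= 0:
        raise ValueError("ascent step must be positive")
    x = belief.estimate
    trace = list(belief.trace)
    for _ in range(n_steps):
        g = error(x) if callable(error) else float(error)
        log_grad = x * g + belief.prior_log_gradient(x)
        if abs(g) < tol and abs(log_grad) < tol:
            break
        x = float(np.exp(np.log(x) + belief.step * log_grad))
        trace.append(x)
        if abs(x) > max_estimate:
            raise RuntimeError(
                f"precision ascent diverged (estimate {x:.3g} exceeds {max_estimate:g})"
            )
    return replace(belief, estimate=x, trace=trace)


# ---------------------------------------------------------------------------
# recovery from simulated traces
# ---------------------------------------------------------------------------


def _trace_observations(rec) -> tuple[np.ndarray, np.ndarray]:
    """Observation matrix (T+1 x modalities) and action sequence from a trial."""
    rows = []
    if rec.initial_outcomes is not None:
        rows.append(list(rec.initial_outcomes))
    rows.extend(list(o) for o in rec.outcomes)
    return np.asarray(rows, dtype=int), np.asarray(rec.actions, dtype=int)


@dataclass
class _ZetaStats:
    """Per-level sufficient statistics for the ζ stationarity condition."""

    sdata: np.ndarray  # sum of q * ln A[o] per level
    wconf: np.ndarray  # accumulated config weights (flattened)
    events: np.ndarray


def _collect_zeta_stats(model, beliefs_per_trace, obs_per_trace) -> _ZetaStats:
    prec = model.precision
    sizes = model.factor_sizes
    lev = _level_index(sizes, prec.zeta_factor)
    n_levels = sizes[prec.zeta_factor]
    modalities = prec.zeta_modalities or tuple(range(model.n_modalities))
    sdata = np.zeros(n_levels)
    events = np.zeros(n_levels)
    wconf = np.zeros(int(np.prod(sizes)))
    lnflats = {m: safe_log(model.A.values[m].reshape(model.A.values[m].shape[0], -1)) for m in modalities}
    for qs_t, obs in zip(beliefs_per_trace, obs_per_trace):
        for tau in range(min(obs.shape[0], len(qs_t))):
            w = _joint_weights(qs_t[tau])
            wconf += w
            for m in modalities:
                np.add.at(sdata, lev, w * lnflats[m][obs[tau, m]])
                np.add.at(events, lev, w)
    return _ZetaStats(sdata=sdata, wconf=wconf, events=events)


def _zeta_stat_gradient(
    stats: _ZetaStats, model, zeta: np.ndarray, level: int
) -> tuple[float, float]:
    """Total free-energy gradient and Fisher curvature for one ζ level."""
    prec = model.precision
    sizes = model.factor_sizes
    lev = _level_index(sizes, prec.zeta_factor)
    modalities = prec.zeta_modalities or tuple(range(model.n_modalities))
    mask = lev == level
    if stats.events[level] <= 1e-12:
        return 0.0, 0.0
    total = stats.sdata[level]
    curv = 0.0
    for m in modalities:
        lnflat = safe_log(model.A.values[m].reshape(model.A.values[m].shape[0], -1))
        cols = lnflat[:, mask]
        z = np.full(mask.sum(), zeta[level])
        logits = z[None, :] * cols
        logits = logits - logits.max(axis=0, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=0, keepdims=True)
        eterm = (p * cols).sum(axis=0)
        var = (p * cols**2).sum(axis=0) - eterm**2
        total -= float(stats.wconf[mask] @ eterm)
        curv += float(stats.wconf[mask] @ var)
    return total, curv


def _collect_omega_stats(model, beliefs_per_trace, pairs_per_trace=None):
    """Accumulate consecutive-state pair tables per factor.

    Uses exact pairwise posteriors when provided; otherwise the mean-field
    product of consecutive marginals.
    """
    from .inference import factor_pair_marginal

    nf = model.n_factors
    sizes = model.factor_sizes
    pair = [np.zeros((n, n)) for n in sizes]
    events = np.zeros(nf)
    for i, qs_t in enumerate(beliefs_per_trace):
        xis = pairs_per_trace[i] if pairs_per_trace is not None else None
        for tau in range(1, len(qs_t)):
            for f in range(nf):
                if xis is not None:
                    pair[f] += factor_pair_marginal(xis[tau - 1], sizes, f)
                else:
                    pair[f] += np.outer(qs_t[tau][f], qs_t[tau - 1][f])
            events += 1.0
    return pair, events


def _omega_stat_gradient(
    pair: np.ndarray, n_events: float, base: np.ndarray, omega: float
) -> tuple[float, float]:
    """Total free-energy gradient and Fisher curvature for one factor's ω."""
    if n_events <= 0:
        return 0.0, 0.0
    lnB = safe_log(base[:, :, 0])
    logits = omega * lnB
    logits = logits - logits.max(axis=0, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=0, keepdims=True)
    eterm = (p * lnB).sum(axis=0)
    var = (p * lnB**2).sum(axis=0) - eterm**2
    w_prev = pair.sum(axis=0)
    grad = float((pair * lnB).sum() - eterm @ w_prev)
    return grad, float(var @ w_prev)


def recover_from_trace(
    traces,
    which: str,
    prior_mean: float = 1.0,
    prior_rate: float = 1.0,
    outer_iters: int = 8,
    ascent_steps: int = 64,
    ascent_step_size: float = 0.7,
    infer_iters: int = 16,
    infer_step: float = 0.5,
) -> dict[str, PrecisionBelief]:
    """Estimate ζ (per stimulus location) or ω (per stimulus) from trials.

    Alternates between (i) re-inferring smoothed state beliefs for every
    trace under the current precision estimates, with the recorded actions
    and outcomes held fixed, and (ii) gradient ascent of each precision
    parameter to the stationary point of its accumulated free-energy
    gradient. The generative model is taken from the traces' scene
    configuration, known up to the target precisions. Returns one
    ``PrecisionBelief`` per estimated parameter, keyed ``"zeta_loc_{j}"`` or
    ``"omega_stim_{f}"``, each carrying its full ascent trace.
    """
    if which not in ("zeta", "omega"):
        raise ValueError("which must be 'zeta' or 'omega'")
    if not traces:
        raise ValueError("at least one trace is required")
    from .scene import build_scene_model  # deferred: scene imports inference

    config = traces[0].config
    ns = config.n_stimuli
    obs_acts = [_trace_observations(rec) for rec in traces]

    # the generative process is known up to the target precision: non-target
    # parameters take their true values when the scene records them
    zeta_est = np.asarray(
        config.true_zeta_by_location or config.zeta_by_location, dtype=float
    )
    omega_est = np.asarray(
        config.true_omega_by_stimulus or config.omega_by_stimulus, dtype=float
    )
    if which == "zeta":
        zeta_est = zeta_est.copy()
        zeta_est[1:] = prior_mean
        names = [f"zeta_loc_{j}" for j in range(1, ns + 1)]
    else:
        omega_est = np.full(ns, float(prior_mean))
        names = [f"omega_stim_{f}" for f in range(ns)]
    beliefs_out = {
        name: PrecisionBelief(prior_mean, prior_mean, prior_rate, step=ascent_step_size)
        for name in names
    }

    from .inference import forward_backward_posterior

    identifiable = True
    for outer in range(outer_iters):
        model = build_scene_model(config, zeta=list(zeta_est), omega=list(omega_est))
        beliefs_per_trace = []
        pairs_per_trace: list | None = []
        for (obs, acts), rec in zip(obs_acts, traces):
            try:
                marg, xis, _ = forward_backward_posterior(model, obs, acts if len(acts) else [0])
                beliefs_per_trace.append(marg)
                if pairs_per_trace is not None:
                    pairs_per_trace.append(xis)
            except ValueError:  # joint space too large: fall back to mean field
                b, _, _ = update_state_beliefs(
                    model, obs, acts if len(acts) else [0],
                    iters=infer_iters, step=infer_step, n_steps=obs.shape[0],
                )
                beliefs_per_trace.append(b.s)
                pairs_per_trace = None

        def newton_error(grad_curv, x):
            """Damped-Newton ascent direction expressed as a precision-domain
            error: ``ascend_precision`` turns it into the log-domain step
            ``(x * total_grad + prior_grad) / (curvature + prior_rate)``."""
            g, curv = grad_curv
            prior_g = prior_rate * (np.log(prior_mean) - np.log(x))
            denom = x * x * curv + prior_rate + 1e-12
            return (x * g + prior_g) / (x * denom)

        if which == "zeta":
            stats = _collect_zeta_stats(model, beliefs_per_trace, [o for o, _ in obs_acts])
            if stats.events[1:].sum() <= 1e-9:
                identifiable = False
                break
            for j in range(1, ns + 1):
                name = f"zeta_loc_{j}"

                def err(x, j=j):
                    z = zeta_est.copy()
                    z[j] = x
                    return newton_error(_zeta_stat_gradient(stats, model, z, j), x)

                work = PrecisionBelief(
                    float(zeta_est[j]), prior_mean, prior_rate=0.0, step=ascent_step_size
                )
                work.trace = beliefs_out[name].trace
                work = ascend_precision(work, err, n_steps=ascent_steps)
                beliefs_out[name] = replace(work, prior_rate=prior_rate)
                zeta_est[j] = work.estimate
        else:
            pair, events = _collect_omega_stats(model, beliefs_per_trace, pairs_per_trace)
            if events[:ns].sum() <= 0:
                identifiable = False
                break
            for f in range(ns):
                name = f"omega_stim_{f}"
                base = model.B.values[f]

                def err(x, f=f, base=base):
                    return newton_error(_omega_stat_gradient(pair[f], events[f], base, x), x)

                work = PrecisionBelief(
                    float(omega_est[f]), prior_mean, prior_rate=0.0, step=ascent_step_size
                )
                work.trace = beliefs_out[name].trace
                work = ascend_precision(work, err, n_steps=ascent_steps)
                beliefs_out[name] = replace(work, prior_rate=prior_rate)
                omega_est[f] = work.estimate

    if not identifiable:
        warnings.warn(
            "recover_from_trace: configuration is unidentifiable (no evidence); "
            "returning the prior",
            RuntimeWarning,
        )
    return beliefs_out


def recovery_report(
    beliefs: dict[str, PrecisionBelief],
    truth: dict[str, float] | None = None,
    n_trials: int | None = None,
    seed: int | None = None,
) -> str:
    """JSON recovery report: truth (if known), estimates, ascent traces."""
    payload = {
        "n_trials": n_trials,
        "seed": seed,
        "parameters": {
            name: {
                "estimate": pb.estimate,
                "prior_mean": pb.prior_mean,
                "prior_rate": pb.prior_rate,
                "truth": None if truth is None else truth.get(name),
                "trace": [float(x) for x in pb.trace],
            }
            for name, pb in beliefs.items()
        },
    }
    return json.dumps(payload, indent=1)
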