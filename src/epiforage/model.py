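"""Categorical generative models with explicit precision (inverse-temperature) beliefs.

A discrete-state generative model for active inference consists of

* a likelihood array ``A`` per outcome modality, mapping hidden-state
  configurations to outcome probabilities,
* a transition array ``B`` per hidden-state factor, mapping the previous state
  and an action to a distribution over next states,
* log prior preferences ``C`` per modality,
* an initial-state prior ``D`` per factor,
* a policy space (ordered action sequences), and
* a set of precision parameters: a sensory precision ``zeta`` attached to the
  levels of one designated factor (e.g. one precision per fixation location),
  and a transition precision (inverse volatility) ``omega`` per factor.

Precisions act as inverse temperatures of Gibbs measures: the effective
likelihood column for a state configuration with precision z is
``softmax(z * ln A[:, s])`` and similarly for transitions with ``omega``.
At precision 1 the base tables are recovered; at precision 0 columns become
uniform; as precision grows without bound a column concentrates on its argmax
(for transitions, an identity matrix in the limit of zero volatility).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LOG_FLOOR",
    "CategoricalTable",
    "TransitionTable",
    "PreferenceVector",
    "InitialBelief",
    "PrecisionSet",
    "PolicySpace",
    "GenerativeModel",
    "ValidationReport",
    "safe_log",
    "apply_sensory_precision",
    "apply_transition_precision",
    "precision_softmax",
    "validate_model",
]

#: Default floor applied before every logarithm of a probability table.
LOG_FLOOR = float(np.exp(-16.0))

_NORM_TOL = 1e-10


def safe_log(x: np.ndarray | float, floor: float = LOG_FLOOR) -> np.ndarray:
    """Elementwise ``ln(max(x, floor))`` for nonnegative probability tables.

    Exact for entries >= ``floor``; monotone everywhere. Raises ``ValueError``
    on negative input (probabilities cannot be negative).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("safe_log: negative entries are outside the probability domain")
    return np.log(np.maximum(arr, floor))


def _softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def precision_softmax(column: np.ndarray, precision: float, floor: float = LOG_FLOOR) -> np.ndarray:
    """Gibbs re-weighting of a single probability column.

    Returns ``softmax(precision * ln column)`` with the log floored at
    ``floor``. ``precision`` may be ``np.inf``, in which case the result is
    one-hot at the argmax (uniform over the argmax set on ties).
    """
    if precision < 0 or not (precision > 0 or precision == 0):
        raise ValueError(f"precision must be nonnegative, got {precision}")
    col = np.asarray(column, dtype=float)
    if np.isinf(precision):
        top = col == col.max()
        return top / top.sum()
    return _softmax(precision * safe_log(col, floor))


# ---------------------------------------------------------------------------
# model components
# ---------------------------------------------------------------------------


@dataclass
class CategoricalTable:
    """Likelihood arrays, one per outcome modality.

    ``values[m]`` has shape ``(n_outcomes_m, *factor_sizes)``: the leading axis
    indexes outcome levels and the remaining axes index the hidden-state
    configuration. Every column (fixed state configuration) is a probability
    distribution.
    """

    values: list[np.ndarray]
    modality_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if not self.modality_names:
            self.modality_names = [f"modality_{m}" for m in range(len(self.values))]

    @property
    def n_modalities(self) -> int:
        return len(self.values)

    @property
    def factor_sizes(self) -> tuple[int, ...]:
        return tuple(self.values[0].shape[1:])

    def copy(self) -> "CategoricalTable":
        return CategoricalTable([v.copy() for v in self.values], list(self.modality_names))

    def violations(self) -> list[str]:
        out: list[str] = []
        for m, v in enumerate(self.values):
            name = self.modality_names[m]
            if np.any(np.isnan(v)):
                out.append(f"A[{name}]: NaN entries")
                continue
            if np.any(v < 0):
                out.append(f"A[{name}]: negative entries")
            sums = v.sum(axis=0)
            bad = np.argwhere(np.abs(sums - 1.0) > _NORM_TOL)
            if bad.size:
                j = tuple(bad[0])
                out.append(
                    f"A[{name}]: column {j} sums to {sums[j]:.6g} (expected 1)"
                )
        return out


@dataclass
class TransitionTable:
    """Transition arrays, one per hidden-state factor.

    ``values[f]`` has shape ``(n_states_f, n_states_f, n_actions)``:
    next state x previous state x action. Each column (previous state, action)
    is a probability distribution over next states.
    """

    values: list[np.ndarray]
    action_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = []
        for v in self.values:
            v = np.asarray(v, dtype=float)
            if v.ndim == 2:  # action-independent factor
                v = v[:, :, None]
            vals.append(v)
        self.values = vals

    @property
    def n_factors(self) -> int:
        return len(self.values)

    def for_action(self, factor: int, action: int) -> np.ndarray:
        v = self.values[factor]
        return v[:, :, action % v.shape[2]]

    def copy(self) -> "TransitionTable":
        return TransitionTable([v.copy() for v in self.values], list(self.action_labels))

    def violations(self) -> list[str]:
        out: list[str] = []
        for f, v in enumerate(self.values):
            if np.any(np.isnan(v)):
                out.append(f"B[factor {f}]: NaN entries")
                continue
            if np.any(v < 0):
                out.append(f"B[factor {f}]: negative entries")
            sums = v.sum(axis=0)
            bad = np.argwhere(np.abs(sums - 1.0) > _NORM_TOL)
            if bad.size:
                j = tuple(bad[0])
                out.append(f"B[factor {f}]: column {j} sums to {sums[j]:.6g} (expected 1)")
        return out


@dataclass
class PreferenceVector:
    """Log prior preferences over outcome levels, one vector per modality.

    ``exp(values[m])`` must normalize to 1: preferences are stored as the log
    of a proper prior over outcomes.
    """

    values: list[np.ndarray]

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]

    @classmethod
    def uniform(cls, n_outcomes: Sequence[int]) -> "PreferenceVector":
        return cls([np.full(n, -np.log(n)) for n in n_outcomes])

    def violations(self) -> list[str]:
        out = []
        for m, v in enumerate(self.values):
            s = np.exp(v).sum()
            if abs(s - 1.0) > _NORM_TOL:
                out.append(f"C[modality {m}]: exp-sum {s:.6g} (expected 1)")
        return out


@dataclass
class InitialBelief:
    """Prior over the initial state of each factor."""

    values: list[np.ndarray]

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]

    @classmethod
    def uniform(cls, sizes: Sequence[int]) -> "InitialBelief":
        return cls([np.full(n, 1.0 / n) for n in sizes])

    def violations(self) -> list[str]:
        out = []
        for f, v in enumerate(self.values):
            if np.any(v < 0):
                out.append(f"D[factor {f}]: negative entries")
            if abs(v.sum() - 1.0) > _NORM_TOL:
                out.append(f"D[factor {f}]: sums to {v.sum():.6g} (expected 1)")
        return out


@dataclass
class PrecisionSet:
    """Sensory precision ``zeta`` and transition precision ``omega``.

    ``zeta`` holds one positive precision per level of ``zeta_factor`` (e.g.
    one per fixation location); it modulates the likelihood of the modalities
    in ``zeta_modalities`` (``None`` means all modalities). ``omega`` holds one
    positive precision per hidden-state factor. The value ``np.inf`` is a
    symbolic zero-volatility / noiseless flag handled by argmax one-hot
    construction, never by floating-point overflow. Unspecified entries
    default to 1 (precision-neutral).
    """

    zeta: np.ndarray | None = None
    zeta_factor: int | None = None
    zeta_modalities: tuple[int, ...] | None = None
    omega: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.zeta is not None:
            self.zeta = np.asarray(self.zeta, dtype=float)
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float)

    @classmethod
    def neutral(cls) -> "PrecisionSet":
        return cls()

    def zeta_for(self, n_levels: int) -> np.ndarray:
        if self.zeta is None:
            return np.ones(n_levels)
        return self.zeta

    def omega_for(self, n_factors: int) -> np.ndarray:
        if self.omega is None:
            return np.ones(n_factors)
        return self.omega

    def violations(self) -> list[str]:
        out = []
        for name, arr in (("zeta", self.zeta), ("omega", self.omega)):
            if arr is None:
                continue
            if np.any(np.isnan(arr)) or np.any(arr <= 0):
                out.append(f"{name}: entries must be strictly positive (inf allowed)")
        if self.zeta is not None and self.zeta_factor is None:
            out.append("zeta given without zeta_factor")
        return out


@dataclass
class PolicySpace:
    """Ordered list of action sequences over the policy horizon."""

    policies: np.ndarray  # (n_policies, horizon) int
    horizon: int = 0

    def __post_init__(self) -> None:
        self.policies = np.asarray(self.policies, dtype=int)
        if self.policies.ndim == 1:
            self.policies = self.policies[:, None]
        if self.horizon == 0:
            self.horizon = self.policies.shape[1]

    @classmethod
    def single_step(cls, n_actions: int) -> "PolicySpace":
        """All one-saccade policies (horizon 1)."""
        return cls(np.arange(n_actions)[:, None], horizon=1)

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]

    def violations(self, n_actions: int) -> list[str]:
        out = []
        if self.horizon < 1:
            out.append("policy horizon must be >= 1")
        if self.policies.shape[1] != self.horizon:
            out.append("policy sequence length differs from horizon")
        if self.policies.size and (self.policies.min() < 0 or self.policies.max() >= n_actions):
            out.append("policy contains invalid action indices")
        return out


@dataclass
class GenerativeModel:
    """A complete discrete-state generative model for active inference."""

    A: CategoricalTable
    B: TransitionTable
    C: PreferenceVector
    D: InitialBelief
    precision: PrecisionSet = field(default_factory=PrecisionSet.neutral)
    policies: PolicySpace | None = None
    gamma_prior: float = 16.0

    def __post_init__(self) -> None:
        if self.policies is None:
            self.policies = PolicySpace.single_step(self.n_actions)

    @property
    def factor_sizes(self) -> tuple[int, ...]:
        return self.A.factor_sizes

    @property
    def n_factors(self) -> int:
        return len(self.B.values)

    @property
    def n_modalities(self) -> int:
        return self.A.n_modalities

    @property
    def n_outcomes(self) -> tuple[int, ...]:
        return tuple(v.shape[0] for v in self.A.values)

    @property
    def n_actions(self) -> int:
        return max(v.shape[2] for v in self.B.values)

    def modulated(self) -> "GenerativeModel":
        """Return a copy with ζ applied to A and ω applied to B (precision-neutral copy)."""
        return replace(
            self,
            A=apply_sensory_precision(self.A, self.precision),
            B=apply_transition_precision(self.B, self.precision),
            precision=PrecisionSet.neutral(),
        )


# ---------------------------------------------------------------------------
# precision operators
# ---------------------------------------------------------------------------


def _check_precisions(arr: np.ndarray, name: str) -> None:
    if np.any(np.isnan(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} precisions must be strictly positive, got {arr}")


def _gibbs_columns(table: np.ndarray, precision: np.ndarray, floor: float) -> np.ndarray:
    """Apply columnwise Gibbs re-weighting along axis 0.

    ``precision`` broadcasts against the column axes of ``table``. Columns with
    infinite precision are replaced by one-hot vectors at their argmax
    (uniform over ties).
    """
    logp = safe_log(table, floor)
    finite = np.where(np.isinf(precision), 1.0, precision)
    out = _softmax(finite * logp, axis=0)
    if np.any(np.isinf(precision)):
        hard = table == table.max(axis=0, keepdims=True)
        hard = hard / hard.sum(axis=0, keepdims=True)
        mask = np.broadcast_to(np.isinf(precision), table.shape)
        out = np.where(mask, hard, out)
    return out


def apply_sensory_precision(
    A: CategoricalTable, zeta: PrecisionSet, floor: float = LOG_FLOOR
) -> CategoricalTable:
    """Gibbs-modulate likelihood columns by the sensory precision ζ.

    Each state-configuration column ``A[:, s]`` of a modulated modality is
    replaced by ``softmax(z(s) * ln A[:, s])`` where ``z(s)`` is the precision
    attached to the configuration's level of the designated ζ-bearing factor.
    ζ = 1 is the identity map; ζ → 0 gives uniform columns; ζ = inf gives a
    one-hot at the column argmax. The input table is left unmodified.
    """
    out = A.copy()
    if zeta.zeta is None:
        return out
    _check_precisions(zeta.zeta, "zeta")
    factor = zeta.zeta_factor
    if factor is None:
        raise ValueError("PrecisionSet.zeta_factor must be set when zeta is given")
    modalities = zeta.zeta_modalities
    if modalities is None:
        modalities = tuple(range(A.n_modalities))
    for m in modalities:
        table = A.values[m]
        n_levels = table.shape[1 + factor]
        if zeta.zeta.shape[0] != n_levels:
            raise ValueError(
                f"zeta has {zeta.zeta.shape[0]} entries but factor {factor} has {n_levels} levels"
            )
        # broadcast zeta over (outcomes, *factor_sizes) aligned with zeta_factor
        shape = [1] * table.ndim
        shape[1 + factor] = n_levels
        z = zeta.zeta.reshape(shape)
        new = _gibbs_columns(table, z, floor)
        # precision 1 is an exact identity, bypassing the log floor
        unit = np.broadcast_to(z == 1.0, table.shape)
        out.values[m] = np.where(unit, table, new)
        if np.any(out.values[m].sum(axis=0) == 0):
            raise ValueError("degenerate model: likelihood column of exact zeros")
    return out


def apply_transition_precision(
    B: TransitionTable, omega: PrecisionSet, floor: float = LOG_FLOOR
) -> TransitionTable:
    """Gibbs-modulate transition columns by the precision ω (inverse volatility).

    Per factor, every (previous state, action) column is replaced by
    ``softmax(omega_f * ln B[:, s, a])``. ω = 1 returns the base table
    unchanged (no flooring applied); ω = inf yields a one-hot at the column
    argmax, so a diagonally dominant base becomes the identity transition
    matrix in the zero-volatility limit. Factors subject to modulation
    (ω != 1) must have strictly positive base columns.
    """
    out = B.copy()
    if omega.omega is None:
        return out
    _check_precisions(omega.omega, "omega")
    if omega.omega.shape[0] != B.n_factors:
        raise ValueError(
            f"omega has {omega.omega.shape[0]} entries but model has {B.n_factors} factors"
        )
    for f, w in enumerate(omega.omega):
        if w == 1.0:
            continue  # identity map, valid even for deterministic base tables
        base = B.values[f]
        if np.any(base <= 0) and not np.isinf(w):
            raise ValueError(
                f"degenerate model: factor {f} has zero entries in an omega-modulated base column"
            )
        out.values[f] = _gibbs_columns(base, np.asarray(w), floor)
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str]

    def __bool__(self) -> bool:
        return self.ok


def validate_model(m: GenerativeModel) -> ValidationReport:
    """Report-only structural validation of a generative model."""
    v: list[str] = []
    v += m.A.violations()
    v += m.B.violations()
    v += m.C.violations()
    v += m.D.violations()
    v += m.precision.violations()
    if m.policies is not None:
        v += m.policies.violations(m.n_actions)

    sizes = m.factor_sizes
    if len(m.B.values) != len(sizes):
        v.append(
            f"factor count mismatch: A implies {len(sizes)} factors, B has {len(m.B.values)}"
        )
    else:
        for f, (b, n) in enumerate(zip(m.B.values, sizes)):
            if b.shape[0] != n or b.shape[1] != n:
                v.append(f"B[factor {f}] shape {b.shape[:2]} != ({n}, {n})")
    if len(m.C.values) != m.n_modalities:
        v.append("C modality count differs from A")
    else:
        for mm, (c, n) in enumerate(zip(m.C.values, m.n_outcomes)):
            if c.shape[0] != n:
                v.append(f"C[modality {mm}] length {c.shape[0]} != {n}")
    if len(m.D.values) != len(sizes):
        v.append("D factor count differs from A")
    else:
        for f, (d, n) in enumerate(zip(m.D.values, sizes)):
            if d.shape[0] != n:
                v.append(f"D[factor {f}] length {d.shape[0]} != {n}")

    omega = m.precision.omega
    if omega is not None and len(omega) == len(m.B.values):
        for f, w in enumerate(omega):
            if w != 1.0 and np.any(m.B.values[f] <= 0) and not np.isinf(w):
                v.append(f"B[factor {f}]: zero entries but flagged for omega modulation")
    if m.gamma_prior <= 0:
        v.append("gamma_prior must be positive")
    return ValidationReport(ok=not v, violations=v)
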