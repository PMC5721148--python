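"""Reading and writing generative-model definition files (YAML or JSON).

A model file records factor and modality sizes, the A/B/C/D tables (either
as explicit nested lists or as named constructors such as ``"identity"`` or
``"diagonally_dominant(0.8)"`` for transition factors), the precision set
(ζ vector, its factor and modalities, ω vector with ``"inf"`` accepted as
the symbolic zero-volatility flag), the policy space and the γ prior.
Round-trips are lossless to double precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import yaml

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

__all__ = [
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
    "beliefs_to_frame",
]


def beliefs_to_frame(per_policy_beliefs, F_traces=None):
    """Belief trajectories in long format for diagnostics and rasters.

    ``per_policy_beliefs`` maps policy index -> BeliefState (or nested
    time x factor lists). Returns a DataFrame with columns
    (policy, time, factor, level, value) plus, when ``F_traces`` is given,
    appended rows (policy, iteration, factor="F", level=-1, value).
    """
    import pandas as pd

    rows = []
    for p, beliefs in enumerate(per_policy_beliefs):
        s = beliefs.s if hasattr(beliefs, "s") else beliefs
        for tau, row in enumerate(s):
            for f, q in enumerate(row):
                for level, value in enumerate(np.asarray(q)):
                    rows.append(
                        {"policy": p, "time": tau, "factor": str(f),
                         "level": level, "value": float(value)}
                    )
    if F_traces is not None:
        for p, trace in enumerate(F_traces):
            for it, value in enumerate(np.asarray(trace)):
                rows.append(
                    {"policy": p, "time": it, "factor": "F", "level": -1,
                     "value": float(value)}
                )
    return pd.DataFrame(rows)

_CONSTRUCTOR_RE = re.compile(r"^diagonally_dominant\(\s*([0-9.eE+-]+)\s*\)$")


def _b_factor_from_spec(spec, n: int, n_actions: int) -> np.ndarray:
    if isinstance(spec, str):
        if spec == "identity":
            mat = np.eye(n)
        else:
            m = _CONSTRUCTOR_RE.match(spec)
            if not m:
                raise ValueError(f"unknown transition constructor: {spec!r}")
            from .scene import diagonally_dominant

            mat = diagonally_dominant(n, float(m.group(1)))
        return np.repeat(mat[:, :, None], 1, axis=2)
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def model_to_dict(model: GenerativeModel) -> dict:
    prec = model.precision

    def enc(x):
        return np.where(np.isinf(x), None, x).tolist() if x is not None else None

    def enc_inf(arr):
        if arr is None:
            return None
        return ["inf" if np.isinf(v) else float(v) for v in arr]

    return {
        "factor_sizes": list(model.factor_sizes),
        "n_outcomes": list(model.n_outcomes),
        "A": [a.tolist() for a in model.A.values],
        "modality_names": list(model.A.modality_names),
        "B": [b.tolist() for b in model.B.values],
        "C": [c.tolist() for c in model.C.values],
        "D": [d.tolist() for d in model.D.values],
        "precision": {
            "zeta": enc_inf(prec.zeta),
            "zeta_factor": prec.zeta_factor,
            "zeta_modalities": list(prec.zeta_modalities) if prec.zeta_modalities else None,
            "omega": enc_inf(prec.omega),
        },
        "policies": model.policies.policies.tolist(),
        "policy_horizon": model.policies.horizon,
        "gamma_prior": float(model.gamma_prior),
    }


def _dec_inf(values):
    if values is None:
        return None
    return np.array([np.inf if v in ("inf", None) else float(v) for v in values])


def model_from_dict(data: dict) -> GenerativeModel:
    sizes = data["factor_sizes"]
    n_actions = int(np.max(data["policies"]) + 1) if len(data["policies"]) else 1
    B = [
        _b_factor_from_spec(spec, n, n_actions)
        for spec, n in zip(data["B"], sizes)
    ]
    prec = data.get("precision") or {}
    model = GenerativeModel(
        A=CategoricalTable(
            [np.asarray(a, dtype=float) for a in data["A"]],
            list(data.get("modality_names") or []),
        ),
        B=TransitionTable(B),
        C=PreferenceVector([np.asarray(c, dtype=float) for c in data["C"]]),
        D=InitialBelief([np.asarray(d, dtype=float) for d in data["D"]]),
        precision=PrecisionSet(
            zeta=_dec_inf(prec.get("zeta")),
            zeta_factor=prec.get("zeta_factor"),
            zeta_modalities=tuple(prec["zeta_modalities"]) if prec.get("zeta_modalities") else None,
            omega=_dec_inf(prec.get("omega")),
        ),
        policies=PolicySpace(np.asarray(data["policies"], dtype=int), int(data["policy_horizon"])),
        gamma_prior=float(data["gamma_prior"]),
    )
    report = validate_model(model)
    if not report.ok:
        raise ValueError(f"model file failed validation: {report.violations}")
    return model


def save_model(model: GenerativeModel, path: str | Path) -> None:
    path = Path(path)
    data = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(data))
    else:
        path.write_text(yaml.safe_dump(data, default_flow_style=None))


def load_model(path: str | Path) -> GenerativeModel:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(data)
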