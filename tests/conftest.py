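import numpy as np
import pytest

from epiforage import (
    CategoricalTable,
    GenerativeModel,
    InitialBelief,
    PolicySpace,
    PrecisionSet,
    PreferenceVector,
    TransitionTable,
)


@pytest.fixture
def two_state_model():
    """Single factor, two states, deterministic-ish likelihood; identity dynamics."""
    A = CategoricalTable([np.array([[0.9, 0.2], [0.1, 0.8]])])
    B = TransitionTable([np.eye(2)[:, :, None]])
    return GenerativeModel(
        A=A,
        B=B,
        C=PreferenceVector.uniform([2]),
        D=InitialBelief([np.array([0.5, 0.5])]),
        precision=PrecisionSet.neutral(),
        policies=PolicySpace.single_step(1),
        gamma_prior=1.0,
    )


def kl(p, q):
    p = np.asarray(p, dtype=float)
    q = np.maximum(np.asarray(q, dtype=float), 1e-300)
    return float(np.sum(np.where(p > 0, p * np.log(p / q), 0.0)))


@pytest.fixture
def kl_div():
    return kl
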