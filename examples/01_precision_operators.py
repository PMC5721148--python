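"""Gibbs precision operators on likelihood and transition tables.

Builds a small likelihood column and a diagonally dominant transition matrix
and shows how the sensory precision zeta and the transition precision omega
(inverse volatility) re-weight them: precision 1 leaves a table unchanged,
precision 0 flattens it, and infinite precision concentrates it on the
argmax (an identity transition matrix, in the case of zero volatility).
"""

import numpy as np

from epiforage import PrecisionSet, TransitionTable, apply_transition_precision, precision_softmax
from epiforage.scene import diagonally_dominant

col = np.array([0.9, 0.1])
print("likelihood column", col)
for zeta in (0.0, 0.5, 1.0, 2.0, np.inf):
    print(f"  zeta={zeta:>4}: {np.round(precision_softmax(col, zeta), 4)}")
print("(zeta=1 reproduces the base column; zeta=2 sharpens it to ~[0.988, 0.012];")
print(" zeta=0 is maximal sensory uncertainty: the outcome carries no information)\n")

base = diagonally_dominant(3, 0.8)
print("base transition matrix (stay probability 0.8):")
print(base)
for omega in (0.25, 1.0, 4.0, np.inf):
    mod = apply_transition_precision(
        TransitionTable([base[:, :, None]]), PrecisionSet(omega=np.array([omega]))
    ).values[0][:, :, 0]
    print(f"\nomega={omega} (volatility {1/omega if omega else np.inf:.3g}):")
    print(np.round(mod, 4))
print("\n(omega -> inf yields the identity matrix: states never change;")
print(" small omega means a volatile world whose states decay toward uniform)")
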