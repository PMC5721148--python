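# epiforage

Discrete-state active inference with explicit beliefs about uncertainty:
a simulator and analysis library for **epistemic visual foraging** under
**sensory precision** (ζ) and **volatility** (ω⁻¹) beliefs, with
Bayes-optimal recovery of the precision parameters from simulated
behaviour.

It is written for computational-neuroscience and behavioural-modelling
work: building categorical (POMDP-style) generative models, simulating
salience-driven saccades, quantifying the *streetlight effect* and
*inhibition of return*, and fitting precision parameters to behavioural
traces.

## The model in brief

An agent entertains a generative model with likelihood **A**
(`P(o|s)`), transitions **B** (`P(s'|s,a)`), outcome preferences **C**
and initial prior **D**. Perception minimizes variational free energy
`F` over a mean-field posterior; action selects policies by the softmax
`π = σ(−F − γG)` of their expected free energy

```
G(π, τ) = −E[ln C(o)] − I(s_τ ; o_τ | π)
```

whose second term — the mutual information between predicted states and
outcomes — is the *epistemic value* or salience of a policy. Two
inverse-temperature parameters encode the agent's beliefs about its own
uncertainty, each as a Gibbs re-weighting of a base table:

```
P(o|s)  ∝ exp( ζ(s) · ln A[o, s] )      sensory precision
P(s'|s) ∝ exp( ω_f  · ln B[s', s] )     transition precision (1/volatility)
```

ζ = 1 and ω = 1 recover the base model; ζ → 0 makes a sensory channel
useless; ω → ∞ makes a state permanent (identity transitions). In the
visual scene (four stimuli of three possible identities plus a fixation
cross; *what* and *where* outcome modalities; uniform preferences) these
parameters shape foraging: imprecise locations lose salience and are
rarely fixated, and volatile stimuli regain salience quickly, shortening
their inhibition of return. Both precisions can themselves be estimated
from behaviour by gradient updates to their free-energy stationary
points.

## Worked example

```python
import numpy as np
from epiforage import SceneConfig, Environment, build_scene_model, run_trial, fixation_frequency

cfg = SceneConfig(zeta_by_location=[1.0, 0.5, 2.0, 2.0, 2.0])  # location 1 imprecise
model = build_scene_model(cfg)

shares = []
for ss in np.random.SeedSequence(42).spawn(40):
    env = Environment.from_config(cfg, np.random.default_rng(ss))
    rec = run_trial(model, env, 19, int(ss.generate_state(1)[0] % 2**31), config=cfg)
    shares.append(fixation_frequency(rec, cfg.n_locations))
print(np.stack(shares).mean(axis=0).round(3))
```

prints

```
[0.    0.    0.347 0.338 0.314]
```

— the fixation cross (entry 0) and the low-precision location (entry 1)
attract essentially no fixations, while the three equal-precision
locations split the trial at roughly a third each: looking where the
light is good is Bayes-optimal when behaviour is driven by information
gain. The same scene with one volatile stimulus yields the
inhibition-of-return curve (`volatility_sweep`): median saccades between
returns rise from ≈ 1.1 at ω = 0.5 to ≈ 4.5 at ω = 8.

The `examples/` directory holds one short narrative script per
capability (precision operators, belief updating against an exact
oracle, foraging, inhibition of return, precision recovery); each prints
its numbers with a line on what they mean. A thin CLI wraps the same
library calls:

```bash
epiforage run --which fig4a --seed 1 --out runs     # streetlight experiment
epiforage sweep --kind volatility --seed 1          # IoR vs omega table
epiforage recover --seed 1                          # precision recovery reports
```

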