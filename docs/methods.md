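# Methods

## The model

`epiforage` simulates active inference in a discrete-state (partially
observed Markov decision process) generative model. Hidden states are
factorized; factor `f` at time τ is a categorical variable `s_τ^f`. The
model's components are

* **A** — one likelihood array per outcome modality,
  `A_m[o, s¹, …, s^F] = P(o_τ = o | s_τ)`;
* **B** — one transition array per factor,
  `B_f[s', s, a] = P(s_{τ+1}^f = s' | s_τ^f = s, a)`;
* **C** — log prior preferences over outcomes per modality (uniform in all
  foraging scenes: behaviour is purely epistemic);
* **D** — the initial-state prior per factor;
* a policy space of action sequences, scored by expected free energy `G`
  and combined with accumulated variational free energy `F` in the policy
  posterior `π = σ(−F − γG)`, with policy precision `γ` (dimensionless
  inverse temperature, prior mean 16 in the scenes).

### Precision parameters

Two further inverse temperatures parameterize the agent's beliefs about its
own uncertainty, each acting as a Gibbs re-weighting of a base table:

* **sensory precision ζ** (one value per level of a designated factor — in
  the scenes, per fixation location) maps a likelihood column `A[:, s]` to
  `softmax(ζ(s) · ln A[:, s])`. ζ = 1 recovers the base table, ζ → 0 makes
  outcomes uninformative, ζ → ∞ makes the mapping deterministic at the
  column argmax.
* **transition precision ω** (inverse volatility, one per factor) applies
  the same construction to transition columns. ω → ∞ turns a diagonally
  dominant base into the identity matrix (a world that never changes);
  small ω is a volatile world whose state beliefs relax toward uniform
  between observations at the closed-form rate
  `λ(ω) = q(ω) − (1 − q(ω))/(n − 1)`, where `q(ω)` is the modulated stay
  probability.

Because the Gibbs construction takes logarithms of the base table,
ω-modulated base transitions must be strictly positive; the identity matrix
arises only as the symbolic ω = ∞ limit, which is handled by argmax one-hot
construction (ties uniform over the argmax set), never by floating
overflow. Every logarithm of a probability table is floored at
`ε = e⁻¹⁶` (`safe_log`); the floor is configurable and documented, and
precision 1 bypasses it so that the identity map is exact.

## Inference

Perception minimizes variational free energy under a mean-field posterior
over policies, time points and factors. Each marginal receives three
messages, all under the precision-modulated tables: the expected
log-transition from the past (or `ln D`), the expected log-transition from
the future, and the mean-field expectation of the log-likelihood of
observed outcomes. Updates are damped in log space (step 0.25, 16 sweeps,
convergence at |ΔF| < 1e-6 by default) and pass through a softmax; the
log-belief auxiliary variables and per-sweep prediction errors are exposed
as a `Depolarization` trace. Sweeps update one (time, factor) marginal at a
time with fresh messages, which makes the recorded free energy provably
non-increasing for any step size in (0, 1].

A `window=1` mode performs pure Bayesian filtering: each slice's prior is
the ω-modulated transition applied to the frozen previous posterior. In
this mode an uninformative likelihood leaves beliefs exactly on the
transition-propagated prior — which is also what produces the exact
geometric decay visible in the firing-rate rasters. The trial loop uses
this filtering mode: with one-saccade policies re-evaluated at every step,
expected free energy depends only on current-time beliefs, so action
selection is unchanged while long sweeps stay fast. Full-trajectory
re-smoothing remains the `update_state_beliefs` default.

Expected free energy of a policy accumulates, per future time and modality,
`G = −pragmatic − epistemic`, with the pragmatic term the expected log
preference of predicted outcomes and the epistemic term (salience) the
mutual information between predicted states and outcomes, computed as
predicted-outcome entropy minus expected likelihood-column entropy
(ambiguity). With uniform preferences the pragmatic term is constant and
behaviour is purely information-seeking: a resolved state has zero
salience (the origin of inhibition of return), an uninformative channel
has zero salience at any belief (the origin of the streetlight effect).

γ is updated by damped iteration of `β ← β₀ + (π − π₀)·G` with `γ = 1/β`
and `π₀ = σ(−γG)`; the foraging reproductions hold γ at its prior mean so
that ζ and ω effects are isolated.

### Exact references

Two independent exact routes validate the variational scheme on small
models: exhaustive enumeration of state trajectories
(`exact_posterior_oracle`, refusing state spaces beyond 10⁵ trajectories)
and forward–backward smoothing on the joint configuration chain
(`forward_backward_posterior`), which also yields exact pairwise
posteriors and the exact log evidence. A brute-force expected-free-energy
evaluation (`enumerate_efe`) recomputes the epistemic term as a double sum
over joint states and outcomes.

Mean-field posteriors cannot represent strong posterior correlations: on
generic random tables the exact smoothing posterior can be multimodal and
the mean-field marginals commit to one mode (KL of order 1). The oracle
comparison fixtures (`make_fixture`) are therefore drawn from an
identifiable regime — one modality per factor with dominant observation
probability uniform on (0.85, 0.95), transition columns and priors mixed
60 % with uniform — where the exact posterior is close to factorized;
measured worst-case KL over 1000 fixtures is 2.8e-3. Conclusions about
agreement with exact inference are claims about this regime, not about
arbitrarily correlated models.

## The foraging scene

The default scene has four stimuli, each with three possible identities,
and five fixation locations (the four stimuli plus a central cross).
Hidden factors: four identity factors and the eye position. Modalities:
*what* (three identities plus a null level seen at the cross; the foveated
stimulus's identity is reported with base accuracy `p_correct`, further
sharpened or flattened by the fixated location's ζ) and *where* (an exact
identity mapping of eye position — proprioception). Eye movements are
deterministic under the commanded saccade; stimulus identities evolve under
a diagonally dominant base transition modulated by each stimulus's ω. The
agent's believed (ζ, ω) and the environment's true (ζ, ω) are
independently configurable and equal by default. Actions are sampled from
the policy posterior in the scene experiments (`softmax(−γG)` with γ = 16);
under argmax selection, symmetric configurations would collapse onto
index-ordered round-robins through the documented tie-break.

Numeric study conditions (chosen once; all values live in `SceneConfig`
and the experiment manifests):

* **Streetlight runs**: ζ = 0.5 at the manipulated location, 2.0 at the
  others, base accuracy 0.9, stay probability 0.6, believed = true ω = 1
  for all stimuli, 19 saccades. Finite volatility is essential here: if
  stimuli were believed unchanging, the precise locations would saturate
  after one glance and never regain salience, leaving the imprecise
  location the only source of residual information — the opposite of the
  intended effect. With ω = 1 the precise locations re-inflate within a
  saccade or two and dominate indefinitely (measured low-ζ share ≈ 0.00
  against ≈ 0.33 per precise location over 200 seeds).
* **Volatility / inhibition-of-return sweeps**: one stimulus's believed =
  true ω swept over {0.5, 1, 2, 4, 8}; the other stimuli believed stable
  (ω⁻¹ = 0); ζ = 1 everywhere with base accuracy 0.8 and stay probability
  0.75; 50 saccades per trial. The noisier what-channel matters: with
  near-noiseless observations a single fixation fully resolves a stimulus
  and any perceptible decay restores full salience in one step, pinning
  return intervals at ~1 for all volatile settings. With partial
  resolution, salience recovers over several saccades at the ω-dependent
  rate and the median return interval rises monotonically across the grid
  (measured 1.12 → 4.53 over 100 seeds).
* **Recovery scenes**: one stimulus, two locations. For ζ recovery the
  stimulus identity is truly constant (ω⁻¹ = 0) and the true ζ differs
  from the agent's neutral belief; for ω recovery the what-channel is
  sharp (ζ = 2) with base stay probability 0.8 and the true ω differs.
  The acting agent believes ω = 1, which keeps the stimulus salient and
  the trace rich in observations.

## Precision learning

The Gibbs parameterization gives the free-energy derivative with respect to
a precision an exponential-family form: the posterior-expected base
log-probability of what was observed (ζ) or inferred to have happened (ω),
minus its expectation under the current modulated table (the
partition-function derivative). Gradients vanish at the generating values,
are exactly zero for flat columns (unidentifiable) and for unvisited
locations or single-step traces (no evidence).

`recover_from_trace` alternates (i) exact forward–backward smoothing of
every trace under the current estimates — actions and outcomes held fixed —
with (ii) per-parameter updates in the log-precision domain to the
stationary point of the accumulated gradient, regularized by a Gaussian
prior on the log precision (mean 1, rate 1 by default, entering once per
dataset). Two deliberate departures from a naive scheme:

* The inner update is a damped Newton step (damping 0.7) using the Fisher
  curvature available from the same sufficient statistics, rather than a
  small fixed-step ascent: a fixed step on a per-event-normalized gradient
  either crawls or lets the prior — whose weight is then comparable to the
  whole dataset — pin the estimate near its mean. The public
  `ascend_precision` keeps the plain log-domain ascent contract.
* The E-step uses the exact smoother rather than the mean-field engine:
  mean-field smoothing overcounts evidence through strong temporal ties
  (each slice receives its neighbours' posteriors, which already contain
  the shared evidence), which measurably biases ζ estimates low (about
  −40 % at ζ_true = 0.5). The exact smoother removes the bias (measured
  recovery at 500 trials: ζ 0.5 → 0.52, 2.0 → 2.02; ω 0.5 → 0.49,
  4.0 → 3.61); its pairwise posteriors likewise replace the mean-field
  product in the ω statistics. For models whose joint configuration space
  exceeds the smoother's limit the mean-field engine is the documented
  fallback.

## What the synthetic data does and does not show

All data in this package are generated by the package itself: the
environment samples from the same parametric family the agent believes in
(up to deliberately mismatched precision values). Passing tests therefore
show internal consistency — the scheme infers what the generative process
encodes, the behavioural phenomena follow from the stated information
dynamics, and precision parameters are recoverable when the rest of the
model is known. They do not show that human eye movements are generated
this way: real scenes have continuous kinematics, structured stimuli,
preferences, and model mismatch, none of which are emulated. The
inhibition-of-return and streetlight results are directional
reproductions; their numeric values depend on the documented condition
choices above.

## Numerical choices

* log floor `e⁻¹⁶` before every logarithm; precision 1 bypasses it.
* variational schedule: 16 sweeps, step 0.25, tolerance 1e-6 (scene
  filtering uses step 0.5; both are within the provable-descent range).
* enumeration oracle limit 1e5 trajectories; forward–backward limit 512
  joint configurations; fixture generator limit 46 configurations.
* MAP action ties break toward the lowest policy index; sampled actions
  draw from the marginal over next actions with the run's seeded generator.
* γ iteration damping 0.5, β clipped at 1e-6 with a warning.
* all run-level randomness fans out from a single seed through
  `numpy.random.SeedSequence.spawn`; sweep cells offset the base seed by a
  fixed prime stride so cells never share streams.
* problem sizes in the shipped tests and the acceptance script (trial
  counts of 100–500, sweeps of 100 seeds × 50 saccades, 100 oracle
  fixtures) were chosen to estimate each quantity with comfortable margin
  at desk scale; all are arguments, not constants.

## Known limitations

* Mean-field smoothing is biased on strongly correlated posteriors (see
  above); the exact smoothers are the reference on small models, but they
  do not scale past a few hundred joint configurations.
* Policies are one-saccade by default; deeper policy trees are supported
  by `PolicySpace` but grow combinatorially and are not exercised by the
  foraging experiments.
* ω is scalar per factor; a per-level ω (one per state value, mirroring
  ζ) would be a straightforward extension of the same Gibbs construction
  but is not implemented.
* Learning touches only the precisions; the base A and B tables are fixed
  and assumed known during recovery.
* No hierarchical (deep temporal) models and no continuous-state
  formulation.
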