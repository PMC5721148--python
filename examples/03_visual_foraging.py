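"""The streetlight effect in simulated visual foraging.

One fixation location is believed to have low sensory precision (zeta 0.5
versus 2.0 elsewhere). Because all outcome preferences are uniform, saccades
are driven purely by expected information gain — and an imprecise location
resolves little uncertainty, so the agent rarely looks there.
"""

import numpy as np

from epiforage import Environment, SceneConfig, build_scene_model, fixation_frequency, run_trial

cfg = SceneConfig(zeta_by_location=[1.0, 0.5, 2.0, 2.0, 2.0])
model = build_scene_model(cfg)

env = Environment.from_config(cfg, np.random.default_rng(0))
rec = run_trial(model, env, 19, seed=0, config=cfg)
print("one trial, 19 saccades (location 0 = fixation cross, 1 = low-precision):")
print("  trace:", rec.eye_positions)

shares = []
for ss in np.random.SeedSequence(42).spawn(40):
    env = Environment.from_config(cfg, np.random.default_rng(ss))
    r = run_trial(model, env, 19, int(ss.generate_state(1)[0] % 2**31), config=cfg)
    shares.append(fixation_frequency(r, cfg.n_locations))
mean = np.stack(shares).mean(axis=0)
print("\nmean fixation share over 40 seeded trials:")
for loc, (s, z) in enumerate(zip(mean, cfg.zeta_by_location)):
    tag = "cross" if loc == 0 else f"zeta={z}"
    print(f"  location {loc} ({tag:>9}): {s:.3f}")
print("\n(the low-precision location attracts far fewer fixations than its")
print(" equal-precision neighbours at ~1/3 each: the streetlight effect)")
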