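"""Inhibition of return and its dependence on believed volatility.

A recently inspected stimulus carries no residual information, so the agent
avoids it — until its believed volatility has had time to re-inflate the
uncertainty. Sweeping the believed transition precision omega of one
stimulus shows the return interval (saccades between successive fixations)
growing with omega: stable stimuli stay "inhibited" longer.
"""

from epiforage import volatility_sweep

table = volatility_sweep([0.5, 2.0, 8.0], n_seeds=15, trial_length=50, base_seed=1)
print(table.to_string(index=False))
print(
    "\n(higher omega = lower believed volatility -> longer inhibition of return;"
    "\n a volatile stimulus is revisited after only a saccade or two)"
)
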