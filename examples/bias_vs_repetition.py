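"""Contraction geometry, not response repetition, drives the bias.

In a no-reference design (both tones drawn around a roving base
frequency) trials can be labeled two ways: Bias+/Bias- by whether
pulling the remembered first tone toward the running stimulus mean
enlarges or shrinks the perceived difference, and Repeat/Alternate by
whether the correct response repeats the previous trial's.  A
contraction observer shows a large Bias gap and almost no Repeat gap.
"""

import intervalbias as ib

weights = ib.default_weights()
observer = ib.ObserverParams(ib.ModelTag.MEMORY_TRACE, weights=weights, sigma=0.04)
cfg = ib.SimulationConfig(
    ib.ProtocolSpec(ib.Protocol.NO_REFERENCE), observer,
    n_participants=150, master_seed=3,
)
blocks, _ = ib.simulate_experiment(cfg)

bias = ib.percent_correct_by_bias(blocks)
repeat = ib.percent_correct_by_repeat(blocks)
print(f"Bias+  {bias.pc_group1:.1f}%   Bias-  {bias.pc_group2:.1f}%   "
      f"gap {bias.gap:+.1f} points")
print(f"Repeat {repeat.pc_group1:.1f}%   Alternate {repeat.pc_group2:.1f}%   "
      f"gap {repeat.gap:+.1f} points")
print(
    "\nThe two labelings are nearly independent here, so the large Bias\n"
    "gap next to the flat Repeat gap shows the performance asymmetry\n"
    "follows the stimulus statistics, not a tendency to repeat responses."
)
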