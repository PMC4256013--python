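"""Per-block maximum-likelihood fits and BIC model comparison.

Simulates a small reference-protocol dataset with the contraction observer,
fits three models to every 80-trial block — the one-parameter memory-
trace model (fixed contraction weights, free noise sigma), the
one-parameter history-free model, and the two-parameter response-bias
model — and compares them per block (log-likelihood at equal parameter
count, BIC otherwise).
"""

import numpy as np

import intervalbias as ib

weights = ib.default_weights()
observer = ib.ObserverParams(ib.ModelTag.MEMORY_TRACE, weights=weights, sigma=0.03)
cfg = ib.SimulationConfig(
    ib.ProtocolSpec(ib.Protocol.REFERENCE), observer,
    n_participants=40, master_seed=11,
)
blocks, _ = ib.simulate_experiment(cfg)

rng = np.random.default_rng(0)
fits_mt = [
    ib.fit_block(ib.ModelTag.MEMORY_TRACE, b, weights=weights, n_starts=25, rng=rng)
    for b in blocks
]
fits_naive = [ib.fit_block(ib.ModelTag.NAIVE, b, n_starts=25, rng=rng) for b in blocks]
fits_rb = [
    ib.fit_block(ib.ModelTag.RESPONSE_BIAS, b, n_starts=25, rng=rng) for b in blocks
]

sigmas = [f.sigma for f in fits_mt]
print(f"fitted memory-trace sigma: median {np.median(sigmas):.4f} "
      f"(generating value 0.0300)")

# per-block interval-bias magnitude, for the bias-vs-BIC correlation
mags = [
    abs(ib.percent_correct_by_reference([b]).gap) for b in blocks
]
vs_naive = ib.compare_models_across_blocks(fits_mt, fits_naive)
vs_rb = ib.compare_models_across_blocks(fits_mt, fits_rb, bias_magnitudes=mags)

print(f"memory trace beats history-free model in "
      f"{100 * vs_naive.win_fraction_a:.0f}% of blocks ({vs_naive.compared_on})")
print(f"memory trace beats response-bias model in "
      f"{100 * vs_rb.win_fraction_a:.0f}% of blocks ({vs_rb.compared_on}; "
      f"2-parameter model pays ln(80) = {np.log(80):.2f} nats)")
if not vs_rb.correlation_degenerate:
    print(f"BIC difference vs bias magnitude: Pearson r = {vs_rb.pearson_r:.2f}, "
          f"Spearman rho = {vs_rb.spearman_rho:.2f}")
print(
    "\nA win rate above 50% for the memory-trace model says the\n"
    "contraction weights capture real trial-to-trial structure that a\n"
    "fixed response bias cannot."
)
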