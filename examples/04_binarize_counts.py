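"""Binarize binned ChIP counts under the Poisson background model.

Simulates one mark track at count level (background mean 2, enrichment
mean 20 per 200-bp bin) with a matched input control, binarizes it, and
scores the calls against the known presence pattern.
"""

import numpy as np

from statewitch import SimulationConfig, binarize_track, simulate_counts

cfg = SimulationConfig(n_bins=50_000, seed=9, background_rate=2.0,
                       enrichment_rate=20.0, switch_plan=[], n_genes=10)
sim = simulate_counts(cfg)

for name, control in (("global background", None),
                      ("matched control", sim.control)):
    calls = binarize_track(sim.counts, control, p_cut=1e-4)
    sens = calls[sim.presence == 1].mean()
    fpr = calls[sim.presence == 0].mean()
    print(f"{name:>18s}: sensitivity {sens:.3f}, "
          f"false-positive rate {fpr:.2e}")

print("\nA bin is called iff P(X >= count | Poisson(lambda)) <= 1e-4; "
      "with a control, lambda is the smoothed, library-scaled local rate "
      "floored at the global mean.")
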