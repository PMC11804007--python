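"""Simulate a small paired cohort, train the chromatin-state HMM on the
control condition, label its states, and segment one sample.

The printed accuracy compares decoded states with the simulator's hidden
truth; the genome fractions show the chromatin-state composition, with
the quiescent state covering roughly half the genome.
"""

import numpy as np

from statewitch import (
    SimulationConfig,
    align_states,
    baum_welch,
    label_states,
    segment,
    simulate_cohort,
    state_genome_fractions,
)

cfg = SimulationConfig(n_bins=4000, n_patients=4, seed=42)
cohort = simulate_cohort(cfg)

model = baum_welch(cohort.condition_tracks("iNSC"), K=8, seed=1,
                   n_restarts=2, max_iter=150, trained_on="iNSC")
model = align_states(model, cfg.true_model())  # truth known: one state space
labels = label_states(model)

seg = segment(cohort.tracks[(0, "GIC")], model)
truth = cohort.truth.states[(0, "GIC")]
print(f"decoded-vs-truth bin agreement: {(seg.states == truth).mean():.3f}")

print("\nfitted emission probabilities (rows = states):")
for k in range(8):
    row = " ".join(f"{e:.2f}" for e in model.E[k])
    print(f"  {labels.labels[k]:<24s} {row}")

print("\ngenome fraction per state (pooled over the cohort, %):")
segs = [segment(t, model) for t in cohort.condition_tracks("GIC")]
for lab, pct in state_genome_fractions(segs, K=8, label_map=labels).items():
    print(f"  {lab:<24s} {pct:5.1f}")
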