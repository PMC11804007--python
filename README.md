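# statewitch

Chromatin-state segmentation and state-switch analysis for paired
tumour / control epigenomes.

Glioblastoma stem cells (GIC) and induced neural stem cells (iNSC)
derived from the same patients differ less in their genomes than in
their chromatin: promoters, enhancers and polycomb domains are
redistributed during transformation.  `statewitch` provides the full
computational chain for quantifying that redistribution from
histone-mark ChIP-seq across a patient cohort:

- **Binarization** of binned mark counts under a Poisson background
  (`binarize_track`), and single-mark peak analysis: QC (< 5,000 peaks
  excluded), consensus peaks, condition-specific gene sets,
  Fisher-tested annotation distributions, paired differential binding,
  and boolean mark combinations (`H3K27ac AND NOT H3K4me3` for
  candidate enhancers).
- **Chromatin-state segmentation** with a K-state multivariate
  Bernoulli-emission hidden Markov model: state *k* emits mark *m* with
  probability `E[k, m]`; training by Baum–Welch with seeded restarts,
  posterior decoding, BIC-tabulated model-size selection (K = 8 by
  convention for the canonical state set), rule-based functional
  labelling, and cross-condition generalization scoring.
- **Switch detection**: per patient, both conditions are segmented on a
  shared bin grid and a region is a *switch* when at least two patients
  show the identical ordered (iNSC state → GIC state) transition —
  classified activating, repressing or neutral via the state labels.
- **Expression integration**: DE calls at fold change > 2 and p < 0.01,
  concordance percentages per mark gain/loss or switch class, proximal
  enhancer → nearest-gene linking within 50 kb, and a druggable-target
  triage table.
- **A synthetic-data module** (`simulate_cohort`) generating paired
  multi-patient cohorts from a known hidden-state process — planted
  switch regions, patient support sets, and an expression table with
  configurable concordance — so the whole pipeline is testable against
  ground truth with no download.

The model and all analysis conventions are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Detect recurrent switches on a synthetic 10-patient cohort
(`examples/02_recurrent_switches.py`):

```python
from statewitch import (SimulationConfig, simulate_cohort, segment,
                        bin_transitions, recurrent_switches,
                        label_states, transition_matrix)

cfg = SimulationConfig(seed=7)          # 10 patients, 2 x 4 mark tracks
cohort = simulate_cohort(cfg)
model = cfg.true_model()
labels = label_states(model)

per_patient = {
    p: bin_transitions(segment(cohort.tracks[(p, "iNSC")], model),
                       segment(cohort.tracks[(p, "GIC")], model))
    for p in cohort.patient_ids()
}
events = recurrent_switches(per_patient, cohort.grid, K=8,
                            min_patients=2, label_map=labels,
                            genes=cohort.genes)
tmat, shares = transition_matrix(events, K=8, label_map=labels)
```

Output:

```
planted recurrent regions: 30, recovered: 30 (100%), events outside any planted region: 1
switch shares: activating 45.2%, repressing 54.8%, neutral 0.0%

most frequent cross-class switches (iNSC -> GIC, n regions):
  active_tss               -> poised_gene_body         5
  enhancers                -> poised_gene_body         4
  ...
```

All 30 planted ≥2-patient switch regions are recovered through the
noisy segmentations (the one extra event is a single-bin coincidence of
segmentation noise in two patients), and the activating/repressing
shares land near the planted 43/57 split.  The other examples cover
training and labelling a model from scratch (decoded-vs-truth agreement
0.990), expression concordance (≈ 85% / 88% of DE genes move in the
expected direction at the default cohort size), and count-level
binarization (sensitivity 0.95 at a false-positive rate below 1e-4).

A thin CLI wraps the same stages:

```sh
statewitch demo --out out/ --seed 7        # simulate -> train -> switches -> summary
statewitch simulate --out cohort/ --seed 3
statewitch binarize --counts counts.tsv --out binary.tsv
statewitch train --tracks binary.tsv --states 8 --seed 1 --out model.yaml
```

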