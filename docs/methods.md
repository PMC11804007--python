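# Methods

`statewitch` analyses paired tumour / control epigenomes — concretely,
glioblastoma stem cells (GIC) and induced neural stem cells (iNSC) derived
from the same patients — by segmenting four histone-mark tracks into
chromatin states, detecting patient-recurrent state switches between the
two conditions, and scoring their concordance with differential
expression.  This note describes the model, the synthetic study
conditions, the numerical choices, and what the tests do and do not show.

## The chromatin-state model

Each genomic bin (200 bp by default) carries a binary vector over M
histone marks (H3K4me3, H3K27ac, H3K36me3, H3K27me3 by default).  A
hidden Markov model with K states generates these vectors: state *k*
emits mark *m* with probability `E[k, m]`, independently across marks
(a multivariate Bernoulli emission), and states evolve along the genome
with transition matrix `A`.  Chromosomes are independent chains; the
initial distribution `π` is re-applied at every chromosome start.

Inference is standard:

- **forward–backward** with per-step scaling gives the total
  log-likelihood and per-bin posterior state probabilities; the
  recursions are numba-compiled (pure-python fallback) since they are the
  only sequential part of the computation.
- **Baum–Welch** (EM) trains `π`, `A`, `E` across a cohort of track
  sets.  The log-likelihood trace is non-decreasing by construction and
  is stored on the model.  Restart 0 uses a deterministic
  pattern-frequency initialisation: emission rows are seeded from the
  most frequent observed mark combinations plus one half-intensity copy
  of the commonest single-mark pattern.  The half-intensity row matters:
  states that differ only in emission *intensity* (strong vs weak
  polycomb) form an EM basin that random restarts reach only
  occasionally, while the informed start reaches it reliably.  Remaining
  restarts are random, seeded as `seed + restart`, best final
  log-likelihood wins.
- **Segmentation** assigns each bin its max-posterior state (ties break
  to the lowest index); Viterbi decoding is available as an option but
  the per-bin max-posterior call is the default, matching common
  practice for chromatin-state maps.
- **Model size.** `select_model` trains over a grid of K (default 4–16
  in steps of 2) and reports log-likelihood and BIC per K with the
  fitted emissions.  The default choice is K = 8 when it is in the grid
  — chromatin-state counts are conventionally chosen for emission
  interpretability, with the table as supporting evidence — otherwise
  the BIC minimiser.

Emission probabilities are clipped to `[1e-6, 1 − 1e-6]` to avoid
`log(0)` and absorbing emissions.

### State labels

For K = 8 the emissions are labelled by thresholded rules (τ = 0.5):
active TSS (H3K4me3 & H3K27ac high), enhancers (H3K27ac high, H3K4me3
low), active transcription (H3K36me3 high plus another active mark),
transcription (H3K36me3 only), poised gene body (H3K36me3 & H3K27me3),
repressed polycomb (H3K27me3 only), weak repressed polycomb (H3K27me3 in
[τ/2, τ), others low) and quiescent (all low).  When a rule matches
several states the state closest to the label's emission prototype keeps
it and the others are reassigned to their nearest unused prototype and
flagged — labelling from a heatmap is ultimately a judgement call, and
the flag marks where the rules were ambiguous.  The activity partition
used downstream is: active = {active TSS, enhancers, transcription,
active transcription}; everything else inactive.

### Cross-model comparison

`match_states` matches two models' states greedily by Pearson
correlation of emission rows.  Correlation is scale-free, so a near-flat
row (quiescent) would correlate arbitrarily with anything; pairs
involving a row with standard deviation < 0.02 fall back to negative
mean absolute difference, which ranks them below all genuine
correlations and keeps the matching deterministic.
`generalization_overlap` segments the same tracks with both models and
reports the percentage of bins assigned matched states — by definition
100 when a model is compared with itself.

## Binarization

`binarize_track` converts binned read counts to presence calls under a
Poisson background: a bin is called iff `P(X ≥ count | Poisson(λ)) ≤
p_cut` (default 1e-4; bin size default 200 bp — the conventions of the
standard binarization tool, reported in output metadata).  Without a
control, λ is the global mean count.  With a control, λ is the control
smoothed over ±2 bins, scaled by the library-size ratio, floored at the
global treatment mean (the floor avoids zero rates in empty control
bins).  Calls are monotone in the count.  One caveat: because the
Poisson tail threshold grows sublinearly in λ, jointly rescaling
treatment and control can in principle flip calls whose counts sit
exactly at the decision boundary; away from the boundary calls are
scale-stable, which is what the test asserts.

## Peak-level layer

- **QC**: samples with fewer than 5,000 peaks are excluded as technical
  failures; correlation outliers (mean same-mark correlation below the
  group mean − 2 sd) are flagged, encoding as a rule the visual
  exclusion of a track that clusters apart.
- **Consensus peaks**: bases covered by ≥ `min_support` input sets,
  merged; computed by an exact sweep over interval endpoints.
- **Differential binding** is a defined, reproducible test rather than a
  wrapped external package: counts-per-million, log2(x+1), paired
  t-test across patients, Benjamini–Hochberg FDR.  A site is
  GIC-specific when FDR < 0.05 and log2FC > 1 (iNSC-specific mirrored).
  Total-count normalisation carries composition bias when one condition
  has many strongly bound sites; the |log2FC| > 1 requirement keeps such
  shifts (~0.4 log2 units at the simulated 5% spike fraction) out of
  the called classes.
- **Mark combinations** (`combine_marks`) evaluate boolean rules such as
  `H3K27ac AND NOT H3K4me3` (candidate enhancers) at base resolution.
- **Fisher's exact test** goes through `scipy.stats.fisher_exact`; the
  test suite verifies it against full hypergeometric enumeration for
  every 2×2 table with total ≤ 40.

## Switch detection

Both conditions of a patient are segmented on the same bin grid, and the
per-bin ordered pair (iNSC state → GIC state) is recorded.  A bin
supports a switch when ≥ `min_patients` patients (default 2) show the
identical ordered pair there; adjacent qualifying bins with the same
pair merge into regions.  Region support is conservative: the supporting
set is the intersection of per-bin supporters, and a run is split rather
than allowed to fall below the threshold — this prevents chaining weakly
supported bins into one inflated region.  The bin grid is the switch
unit because peak calls differ across patients, and "the same region in
two patients" is only well-defined on a shared coordinate system; a
peak-restricted mode intersects switch regions with a supplied consensus
peak BED for a more literal peak-based reading.  Switches are
activating (inactive → active state), repressing (active → inactive) or
neutral, and each region is annotated and linked to the nearest gene
within 50 kb (TSS-to-edge distance; ties to the smaller gene id).

## Expression integration

Differential expression is an input table (gene, log2FC, p); genes are
called up/down at |log2FC| > 1 (fold change > 2) and p < 0.01.
Concordance for a gene stratum (a mark gain/loss, a state, or a switch
class) is the percentage of its differentially expressed members moving
in the expected direction — gains of H3K4me3/H3K27ac/H3K36me3 and
activating switches predict up; H3K27me3 gains and repressing switches
predict down.  Non-DE genes are excluded from the percentage
denominator (total member counts are reported alongside).  Proximal
enhancers — enhancer-state regions annotated intronic or distal
intergenic — link to the nearest TSS within 50 kb; enhancer/DE
association is tested by Fisher's exact test.  Target triage joins
switch-linked DE genes with a user-supplied flags table (no external
databases are queried) and reports flag-combination counts.

## Synthetic study conditions

The generator emulates the deposited cohort's structure: 10 patients ×
2 conditions × 4 marks, binary tracks on a two-chromosome grid (6,000 ×
200 bp bins by default), one hidden chain per patient shared between
conditions except inside planted switch regions, and an expression
table wired to the planted switches.

Fixed defaults (chosen once as the study conditions):

- **Emissions**: the 8-state template above with highs ≥ 0.85, lows ≤
  0.02 and weak polycomb at 0.48 — a well-separated idealisation of a
  real emission heatmap.
- **Transitions**: sticky (self-probability 0.96; 0.98 for quiescent and
  weak polycomb), with half of each state's off-diagonal mass decaying
  into quiescent, making quiescent ≈ 48% of the genome at stationarity.
  True-model segmentation accuracy under these conditions is ≥ 0.99.
- **Switch plan**: 13 activating and 17 repressing recurrent regions
  (43% / 57%, the shares reported for the real cohort) of 10 bins
  (2 kb), patient support cycling {2, 3, 5}, plus six single-patient
  decoys the recurrence filter must reject.  All pairs are anchored on
  the poised/bivalent state: its two strong marks make a 2-kb island
  identifiable against any background.  Absence-defined states
  (quiescent, weak polycomb) and the singly-marked polycomb state are
  not planted, because a short island of such a state adjacent to a
  confusable background run gets absorbed by the sticky prior — the
  transition cost exceeds the emission evidence available in 2 kb.
  This is a genuine identifiability limit of sticky-HMM segmentation at
  short scales, not an implementation artefact.
- **Expression**: each planted region's realised nearest gene (within
  50 kb) is differentially expressed in the concordant direction with
  probability 0.90 (activating) / 0.80 (repressing) — the concordance
  levels reported for the real cohort — else in the opposite direction;
  DE magnitudes are |N(2.5, 0.5)| with p-values ≤ 1e-3.  Background
  genes get log2FC ~ N(0, 0.25) and uniform p-values.
- **Counts** (for the binarization layer): Poisson with background mean
  2 and enrichment mean 20 per bin.

Everything is reproducible byte-for-byte from the config seed.

### What the synthetic data does not capture

Real ChIP-seq adds mappability artefacts, copy-number distortion,
antibody efficiency differences between patients, correlated mark
emissions, peak-width structure below the bin scale, and shared
inter-patient variation (the generator draws independent chains from one
parameter set).  Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not performance on real libraries.

## Numerical choices and problem sizes

- Scaled (normalised) forward–backward; emission likelihoods computed in
  log space and shifted per bin before exponentiation.
- EM stops at Δloglik < 1e-3 (default) or 200 iterations; ties in
  max-posterior decoding go to the lowest state index; greedy state
  matching breaks ties by index.
- The test suite runs its heavier checks at reduced but still decisive
  sizes: parameter recovery at 5×10⁴ bins, binarization null rate at
  10⁶ bins, switch recovery on the full 10-patient default cohort,
  concordance recovery at 500 linked genes over a 2.2×10⁷ bp grid.
  The stationarity check runs under a generic sticky chain
  (self-probability 0.9): genome-fraction deviation from the stationary
  law is pure finite-chain noise with standard deviation
  ≈ √(p(1−p)·L/n) for run length L, so the very sticky default chain
  would need far longer genomes for the same precision; a separate
  check verifies decoded fractions track the truth fractions under the
  default chain.
- Switch-recovery exactness is asserted on transitions derived from the
  true hidden states, which isolates the detection and recurrence
  logic; under decoded segmentations the same conditions give 100%
  recall with occasionally one or two single-bin false events — the
  false-positive level predicted by ~1% per-bin segmentation noise.

## Known limitations

- The weak-polycomb state is intrinsically hard: defined by an
  intermediate emission rate on one mark, it is only identifiable over
  long runs, biases decoded genome fractions when runs are short, and
  required the informed EM initialisation to be found at all.
- Nearest-gene assignment uses TSS distance only; no expression-aware or
  contact-based enhancer–gene mapping.
- The differential-binding test uses CPM + paired t, a deliberately
  simple defined test; it does not reproduce shrinkage-based tools'
  point estimates.
- No read-level simulation, copy-number or mappability modelling; peak
  calling and alignment are upstream of this package.
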