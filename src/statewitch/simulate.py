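"""Synthetic paired-cohort epigenome generator with known ground truth.

Emulates the structure of a paired tumour / syngeneic-control ChIP-seq
cohort: 10 patients, two conditions (GIC tumour stem cells vs iNSC
controls), four histone marks binarized on a common bin grid, hidden
chromatin states drawn from a sticky Markov chain shared between a
patient's two conditions except inside planted switch regions, plus a
differential-expression table whose up/down calls are concordant with the
planted switch classes at configured rates.

Every quantity the downstream pipeline estimates (states, switches, switch
recurrence, concordance) is recorded in :class:`TruthTables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from ._kernels import sample_markov_chain
from .binarize import BinarizedTrackSet
from .genome import BinGrid, GeneModel, GenomicInterval, write_gene_table
from .hmm import DEFAULT_MARKS, STATE_LABELS, ACTIVE_LABELS, HMMModel

CONDITIONS = ("iNSC", "GIC")

#: default emission template, rows in canonical label order
#: (marks: H3K4me3, H3K27ac, H3K36me3, H3K27me3).  Qualitatively mirrors
#: the published emission heatmap: a TSS state high in H3K4me3+H3K27ac, an
#: enhancer state high in H3K27ac only, transcription states high in
#: H3K36me3, polycomb states high in H3K27me3, a near-zero quiescent state.
DEFAULT_EMISSIONS = np.array(
    [
        [0.98, 0.95, 0.05, 0.02],  # active_tss
        [0.02, 0.95, 0.05, 0.02],  # enhancers
        [0.05, 0.85, 0.95, 0.02],  # active_transcription
        [0.02, 0.05, 0.95, 0.02],  # transcription
        [0.02, 0.02, 0.80, 0.85],  # poised_gene_body
        [0.02, 0.02, 0.02, 0.95],  # repressed_polycomb
        [0.02, 0.02, 0.02, 0.48],  # weak_repressed_polycomb
        [0.01, 0.01, 0.01, 0.01],  # quiescent
    ]
)

#: canonical state indices by label for the default template
STATE_INDEX = {
    "active_tss": 0,
    "enhancers": 1,
    "active_transcription": 2,
    "transcription": 3,
    "poised_gene_body": 4,
    "repressed_polycomb": 5,
    "weak_repressed_polycomb": 6,
    "quiescent": 7,
}
QUIESCENT = STATE_INDEX["quiescent"]


def default_transition_matrix(K: int = 8) -> np.ndarray:
    """Sticky chain with a dominant quiescent state.

    Non-quiescent states decay preferentially into quiescent (half their
    off-diagonal mass), making quiescent ~48% of the genome at
    stationarity; the weak-polycomb state is entered more rarely and held
    longer, reflecting broad shallow domains.
    """
    A = np.zeros((K, K))
    if K == 8:
        W = STATE_INDEX["weak_repressed_polycomb"]
        for i in range(K):
            self_p = 0.98 if i in (QUIESCENT, W) else 0.96
            A[i, i] = self_p
            off = 1 - self_p
            others = [j for j in range(K) if j != i]
            if i != QUIESCENT:
                A[i, QUIESCENT] = off / 2
                rest = [j for j in others if j != QUIESCENT]
                w = np.array([0.4 if j == W else 1.0 for j in rest])
                A[i, rest] = off / 2 * w / w.sum()
            else:
                w = np.array([0.4 if j == W else 1.0 for j in others])
                A[i, others] = off * w / w.sum()
    else:
        A[:] = 0.05 / max(K - 1, 1)
        np.fill_diagonal(A, 0.95)
    return A


@dataclass(frozen=True)
class SwitchPlanEntry:
    """A planted state switch: inside ``region`` the listed patients carry
    ``state_insc`` in iNSC and ``state_gic`` in GIC."""

    region: GenomicInterval
    state_insc: int
    state_gic: int
    patients: tuple[int, ...]

    def direction(self) -> str:
        a = STATE_LABELS[self.state_insc] in ACTIVE_LABELS
        b = STATE_LABELS[self.state_gic] in ACTIVE_LABELS
        if not a and b:
            return "activating"
        if a and not b:
            return "repressing"
        return "neutral"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    n_bins: int = 6000
    bin_size: int = 200
    n_states: int = 8
    n_marks: int = 4
    mark_names: list[str] = field(default_factory=lambda: list(DEFAULT_MARKS))
    n_patients: int = 10
    transition_matrix: np.ndarray | None = None
    emission_matrix: np.ndarray | None = None
    switch_plan: list[SwitchPlanEntry] | None = None
    n_genes: int = 300
    concordance_rates: dict[str, float] = field(
        default_factory=lambda: {"activating": 0.90, "repressing": 0.80}
    )
    de_lfc_mean: float = 2.5
    de_lfc_sd: float = 0.5
    background_rate: float = 2.0
    enrichment_rate: float = 20.0
    seed: int = 0
    chrom_split: float = 0.6  # fraction of bins on the first chromosome

    def resolve(self) -> "SimulationConfig":
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.n_states)
        if self.emission_matrix is None:
            if (self.n_states, self.n_marks) != DEFAULT_EMISSIONS.shape:
                raise ValueError(
                    "no default emission template for this K/M; supply one"
                )
            self.emission_matrix = DEFAULT_EMISSIONS.copy()
        A = np.asarray(self.transition_matrix, dtype=float)
        E = np.asarray(self.emission_matrix, dtype=float)
        if A.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape mismatch")
        if np.max(np.abs(A.sum(axis=1) - 1)) > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")
        if E.shape != (self.n_states, self.n_marks):
            raise ValueError("emission matrix shape mismatch")
        if E.min() < 0 or E.max() > 1:
            raise ValueError("emission probabilities must lie in [0, 1]")
        for r in self.concordance_rates.values():
            if not 0 <= r <= 1:
                raise ValueError("concordance rates must lie in [0, 1]")
        if self.switch_plan is None:
            self.switch_plan = default_switch_plan(self.grid(),
                                                   self.n_patients)
        grid = self.grid()
        for e in self.switch_plan:
            if e.region.chrom not in grid.chrom_sizes:
                raise ValueError(f"switch region off-grid: {e.region}")
            if e.region.end > grid.chrom_sizes[e.region.chrom]:
                raise ValueError(f"switch region off-grid: {e.region}")
            if e.state_insc == e.state_gic:
                raise ValueError("switch states must differ")
            if max(e.state_insc, e.state_gic) >= self.n_states:
                raise ValueError("switch state index out of range")
        return self

    def grid(self) -> BinGrid:
        n1 = max(int(round(self.n_bins * self.chrom_split)), 1)
        n2 = self.n_bins - n1
        sizes = {"chr1": n1 * self.bin_size}
        if n2 > 0:
            sizes["chr2"] = n2 * self.bin_size
        return BinGrid(sizes, self.bin_size)

    def true_model(self) -> HMMModel:
        self.resolve()
        A = np.asarray(self.transition_matrix, dtype=float)
        m = HMMModel(
            pi=np.full(self.n_states, 1 / self.n_states),
            A=A,
            E=np.asarray(self.emission_matrix, dtype=float),
            mark_names=list(self.mark_names),
            trained_on="truth",
        )
        # start chains at stationarity
        m.pi = m.stationary_distribution()
        return m

    def to_yaml(self, path: str | Path) -> None:
        self.resolve()
        d = {
            k: v for k, v in asdict(self).items()
            if k not in ("transition_matrix", "emission_matrix",
                         "switch_plan")
        }
        d["transition_matrix"] = np.asarray(self.transition_matrix).tolist()
        d["emission_matrix"] = np.asarray(self.emission_matrix).tolist()
        d["switch_plan"] = [
            {
                "chrom": e.region.chrom,
                "start": e.region.start,
                "end": e.region.end,
                "state_insc": e.state_insc,
                "state_gic": e.state_gic,
                "patients": list(e.patients),
            }
            for e in self.switch_plan
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# planted (iNSC -> GIC) pairs: activating resolve the poised/bivalent
# state into active states, repressing do the reverse.  The poised state's
# two strong positive marks (H3K36me3 + H3K27me3) make a 2-kb planted
# island identifiable against any background; absence-defined states
# (quiescent, weak polycomb) and the singly-marked polycomb state can be
# absorbed by an adjacent confusable run under a sticky chain and are not
# planted.
_ACTIVATING_PAIRS = [
    (STATE_INDEX["poised_gene_body"], STATE_INDEX["active_tss"]),
    (STATE_INDEX["poised_gene_body"], STATE_INDEX["enhancers"]),
    (STATE_INDEX["poised_gene_body"], STATE_INDEX["active_transcription"]),
    (STATE_INDEX["poised_gene_body"], STATE_INDEX["transcription"]),
]
_REPRESSING_PAIRS = [(b, a) for a, b in _ACTIVATING_PAIRS]
_POISED = STATE_INDEX["poised_gene_body"]


def default_switch_plan(
    grid: BinGrid,
    n_patients: int = 10,
    n_activating: int = 13,
    n_repressing: int = 17,
    n_decoys: int = 6,
    region_bins: int = 10,
) -> list[SwitchPlanEntry]:
    """Deterministic planted switch plan.

    13 activating and 17 repressing recurrent regions (43% / 57%, the
    shares reported for the real cohort) with patient support cycling
    through {2, 3, 5}, plus single-patient decoys that the recurrence
    filter must reject.  Regions are 2 kb (10 bins) and evenly spaced
    along the grid.
    """
    n_regions = n_activating + n_repressing + n_decoys
    spacing = grid.n_bins // (n_regions + 1)
    if spacing < region_bins + 4:
        raise ValueError("grid too small for the default switch plan")
    classes = (["activating"] * n_activating + ["repressing"] * n_repressing
               + ["decoy"] * n_decoys)
    plan: list[SwitchPlanEntry] = []
    ia = ir = 0
    support_cycle = [2, 3, 5]
    for i, cls in enumerate(classes):
        g0 = (i + 1) * spacing
        # translate global bin range to a chromosome-local interval
        for chrom, sl in grid.chrom_slices():
            if sl.start <= g0 < sl.stop:
                local = g0 - sl.start
                if local + region_bins > sl.stop - sl.start:
                    local = sl.stop - sl.start - region_bins
                region = GenomicInterval(
                    chrom,
                    local * grid.bin_size,
                    (local + region_bins) * grid.bin_size,
                )
                break
        if cls == "activating":
            pair = _ACTIVATING_PAIRS[ia % len(_ACTIVATING_PAIRS)]
            ia += 1
            support = support_cycle[(ia - 1) % len(support_cycle)]
        elif cls == "repressing":
            pair = _REPRESSING_PAIRS[ir % len(_REPRESSING_PAIRS)]
            ir += 1
            support = support_cycle[(ir - 1) % len(support_cycle)]
        else:
            pair = (_ACTIVATING_PAIRS + _REPRESSING_PAIRS)[
                i % (len(_ACTIVATING_PAIRS) * 2)
            ]
            support = 1
        support = min(support, n_patients)
        patients = tuple((i + j) % n_patients for j in range(support))
        plan.append(SwitchPlanEntry(region, pair[0], pair[1], patients))
    return plan


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic cohort."""

    states: dict[tuple[int, str], np.ndarray]  # (patient, condition) -> bins
    planted: list[SwitchPlanEntry]
    gene_truth: pd.DataFrame

    def recurrent_planted(self, min_patients: int = 2) -> list[SwitchPlanEntry]:
        return [e for e in self.planted if len(e.patients) >= min_patients]


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    grid: BinGrid
    tracks: dict[tuple[int, str], BinarizedTrackSet]
    genes: list[GeneModel]
    expression: pd.DataFrame
    truth: TruthTables

    def condition_tracks(self, condition: str) -> list[BinarizedTrackSet]:
        return [
            t for (p, c), t in sorted(self.tracks.items(),
                                      key=lambda kv: kv[0])
            if c == condition
        ]

    def patient_ids(self) -> list[int]:
        return sorted({p for p, _ in self.tracks})

    def to_directory(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (p, c), t in sorted(self.tracks.items()):
            df = pd.DataFrame(t.calls, columns=t.marks)
            df.to_csv(outdir / f"tracks_P{p:02d}_{c}.tsv", sep="\t",
                      index=False)
        self.expression.to_csv(outdir / "expression.tsv", sep="\t",
                               index=False)
        write_gene_table(self.genes, outdir / "genes.bed")
        self.truth.gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t",
                                     index=False)
        self.config.to_yaml(outdir / "config.yaml")
        rows = []
        for i, e in enumerate(self.truth.planted):
            rows.append(
                {
                    "region_id": i,
                    "chrom": e.region.chrom,
                    "start": e.region.start,
                    "end": e.region.end,
                    "state_insc": e.state_insc,
                    "state_gic": e.state_gic,
                    "n_patients": len(e.patients),
                    "patients": ",".join(map(str, e.patients)),
                    "class": e.direction(),
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "planted_switches.tsv", sep="\t",
                                  index=False)


def _sample_chain(
    model: HMMModel, grid: BinGrid, rng: np.random.Generator
) -> np.ndarray:
    states = np.empty(grid.n_bins, dtype=np.int64)
    pi_cum = np.cumsum(model.pi)
    A_cum = np.cumsum(model.A, axis=1)
    for _, sl in grid.chrom_slices():
        u = rng.random(sl.stop - sl.start)
        states[sl] = sample_markov_chain(pi_cum, A_cum, u)
    return states


def _place_gene(
    rng: np.random.Generator,
    grid: BinGrid,
    chrom: str,
    tss: int,
    gene_id: str,
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    length = int(rng.integers(2000, 8001))
    size = grid.chrom_sizes[chrom]
    tss = int(np.clip(tss, 1, size - 2))
    if strand == "+":
        start, end = tss, min(tss + length, size)
    else:
        start, end = max(tss - length, 0), tss + 1
    tx = GenomicInterval(chrom, start, end, strand)
    # 1-3 exon blocks inside the transcript
    n_ex = int(rng.integers(1, 4))
    cuts = np.sort(rng.integers(start, end, size=2 * n_ex))
    exons = []
    for a, b in zip(cuts[::2], cuts[1::2]):
        if b > a:
            exons.append(GenomicInterval(chrom, int(a), int(b), strand))
    if not exons:
        exons = [GenomicInterval(chrom, start, end, strand)]
    return GeneModel(gene_id, gene_id, tx, exons)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full paired cohort with truth tables.

    Per patient one hidden chain is drawn and shared by both conditions;
    inside each planted switch region the planned states are forced for
    the listed patients.  Marks are emitted independently per condition as
    Bernoulli(E[state, mark]).  Genes are placed near switch regions (one
    each) plus uniformly at random; each region's realised nearest gene
    within 50 kb receives a differential-expression call concordant with
    the region's switch class at the configured rate.  Byte-reproducible
    from ``config.seed``.
    """
    config.resolve()
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    model = config.true_model()
    E = np.asarray(config.emission_matrix, dtype=float)
    plan = list(config.switch_plan)

    states: dict[tuple[int, str], np.ndarray] = {}
    tracks: dict[tuple[int, str], BinarizedTrackSet] = {}
    for p in range(config.n_patients):
        base = _sample_chain(model, grid, rng)
        per_cond = {"iNSC": base.copy(), "GIC": base.copy()}
        for e in plan:
            if p in e.patients:
                lo, hi = grid.bin_range(e.region)
                per_cond["iNSC"][lo:hi] = e.state_insc
                per_cond["GIC"][lo:hi] = e.state_gic
        for cond in CONDITIONS:
            s = per_cond[cond]
            calls = (rng.random((grid.n_bins, config.n_marks))
                     < E[s]).astype(np.uint8)
            states[(p, cond)] = s
            tracks[(p, cond)] = BinarizedTrackSet(
                grid, list(config.mark_names), calls,
                sample_id=f"P{p:02d}", condition=cond,
            )

    # --- genes -----------------------------------------------------------
    genes: list[GeneModel] = []
    for i, e in enumerate(plan):
        offset = int(rng.integers(2000, 20001)) * (1 if rng.random() < 0.5
                                                   else -1)
        tss = int(e.region.midpoint) + offset
        genes.append(_place_gene(rng, grid, e.region.chrom, tss,
                                 f"SWG{i:04d}"))
    n_background = max(config.n_genes - len(plan), 0)
    for i in range(n_background):
        chrom = rng.choice(grid.chroms)
        tss = int(rng.integers(0, grid.chrom_sizes[chrom]))
        genes.append(_place_gene(rng, grid, chrom, tss, f"BGG{i:04d}"))

    # realised region -> nearest gene within 50 kb (edge-to-TSS distance)
    def region_nearest_gene(region: GenomicInterval) -> str | None:
        best, bestd = None, 50_000 + 1
        for g in genes:
            if g.tx_interval.chrom != region.chrom:
                continue
            t = g.tss
            d = 0 if region.start <= t < region.end else min(
                abs(t - region.start), abs(t - (region.end - 1))
            )
            if d < bestd or (d == bestd and best is not None
                             and g.gene_id < best):
                best, bestd = g.gene_id, d
        return best

    # --- expression ------------------------------------------------------
    lfc = {g.gene_id: float(rng.normal(0, 0.25)) for g in genes}
    pval = {g.gene_id: float(rng.uniform()) for g in genes}
    truth_rows = []
    for i, e in enumerate(plan):
        gid = region_nearest_gene(e.region)
        cls = e.direction()
        if gid is None:
            continue
        rate = config.concordance_rates.get(cls)
        if rate is None or len(e.patients) < 1:
            continue
        concordant = bool(rng.random() < rate)
        expected = {"activating": 1.0, "repressing": -1.0}.get(cls, 1.0)
        sign = expected if concordant else -expected
        mag = abs(rng.normal(config.de_lfc_mean, config.de_lfc_sd))
        lfc[gid] = float(sign * mag)
        pval[gid] = float(10 ** -rng.uniform(3, 8))
        truth_rows.append(
            {
                "gene_id": gid,
                "region_id": i,
                "class": cls,
                "n_patients": len(e.patients),
                "expected_direction": "up" if expected > 0 else "down",
                "concordant": concordant,
                "log2fc": lfc[gid],
                "p": pval[gid],
            }
        )
    expression = pd.DataFrame(
        {
            "gene": [g.gene_id for g in genes],
            "log2fc": [lfc[g.gene_id] for g in genes],
            "p": [pval[g.gene_id] for g in genes],
        }
    )
    truth = TruthTables(states, plan, pd.DataFrame(truth_rows))
    return SimulatedCohort(config, grid, tracks, genes, expression, truth)


@dataclass
class CountSimulation:
    counts: np.ndarray
    control: np.ndarray
    presence: np.ndarray
    states: np.ndarray


def simulate_counts(
    config: SimulationConfig, mark_index: int = 0
) -> CountSimulation:
    """Count-level output for one mark track plus a matched input control.

    Treatment bins are Poisson(enrichment_rate) where the mark is present
    and Poisson(background_rate) otherwise; the control is
    Poisson(background_rate) everywhere.
    """
    config.resolve()
    if not config.enrichment_rate > config.background_rate > 0:
        raise ValueError("need enrichment_rate > background_rate > 0")
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    model = config.true_model()
    states = _sample_chain(model, grid, rng)
    E = np.asarray(config.emission_matrix, dtype=float)
    presence = (rng.random(grid.n_bins) < E[states, mark_index]).astype(
        np.uint8
    )
    lam = np.where(presence == 1, config.enrichment_rate,
                   config.background_rate)
    counts = rng.poisson(lam)
    control = rng.poisson(config.background_rate, size=grid.n_bins)
    return CountSimulation(counts, control, presence, states)
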