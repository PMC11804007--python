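"""Single-histone-mark peak layer: QC, consensus peaks, condition-specific
sets, annotation-distribution comparison, differential binding and
mark-combination functional regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import (
    AnnotationCall,
    GeneModel,
    GenomicInterval,
    annotate_regions,
    merge_intervals,
)

#: functional annotation categories in which a mark's peaks are linked to
#: genes (promoters for H3K4me3; gene bodies for H3K36me3; both for
#: H3K27ac and H3K27me3)
MARK_CATEGORIES = {
    "H3K4me3": {"promoter"},
    "H3K36me3": {"exon", "intron"},
    "H3K27ac": {"promoter", "exon", "intron"},
    "H3K27me3": {"promoter", "exon", "intron"},
}


@dataclass
class PeakSet:
    """Merged, sorted peak calls for one (sample, mark)."""

    sample_id: str
    condition: str
    mark: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.peaks:
            self.peaks = merge_intervals(self.peaks)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass
class DiffBoundSite:
    site: GenomicInterval
    mark: str
    log2fc: float  # GIC over iNSC
    p: float
    fdr: float
    klass: str  # gic_only / insc_only / shared

    @staticmethod
    def classify(log2fc: float, fdr: float, alpha: float = 0.05,
                 lfc: float = 1.0) -> str:
        if fdr < alpha and log2fc > lfc:
            return "gic_only"
        if fdr < alpha and log2fc < -lfc:
            return "insc_only"
        return "shared"


def qc_filter(
    peaksets: Sequence[PeakSet], min_peaks: int = 5000
) -> tuple[list[PeakSet], list[PeakSet], pd.DataFrame]:
    """Exclude technical failures: peak sets with fewer than ``min_peaks``
    peaks.  Returns (kept, excluded, decision log)."""
    kept, excluded, log = [], [], []
    for ps in peaksets:
        ok = ps.n_peaks >= min_peaks
        (kept if ok else excluded).append(ps)
        log.append(
            {
                "sample_id": ps.sample_id,
                "condition": ps.condition,
                "mark": ps.mark,
                "n_peaks": ps.n_peaks,
                "decision": "kept" if ok else "excluded",
            }
        )
    return kept, excluded, pd.DataFrame(log)


def track_correlation(
    tracks: Sequence[np.ndarray],
    marks: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Pairwise Pearson matrix over binned score vectors plus outliers.

    A track is an outlier when its mean correlation with the other tracks
    of the same mark falls below that group's mean - 2 sd.  Zero-variance
    tracks have undefined correlations (NaN) and are flagged directly.
    """
    n = len(tracks)
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError("tracks must share length")
    X = np.asarray(tracks, dtype=float)
    sd = X.std(axis=1)
    corr = np.full((n, n), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(X[ok])
        idx = np.flatnonzero(ok)
        corr[np.ix_(idx, idx)] = sub
    np.fill_diagonal(corr, 1.0)
    outliers = [int(i) for i in np.flatnonzero(~ok)]
    marks = list(marks) if marks is not None else ["" for _ in range(n)]
    for mark in sorted(set(marks)):
        members = [i for i in range(n) if marks[i] == mark and ok[i]]
        if len(members) < 3:
            continue
        means = []
        for i in members:
            others = [j for j in members if j != i]
            means.append(np.nanmean(corr[i, others]))
        means = np.array(means)
        cut = means.mean() - 2 * means.std()
        for i, m in zip(members, means):
            if m < cut:
                outliers.append(i)
    return corr, sorted(set(outliers))


def _coverage_regions(
    peaksets: Sequence[Sequence[GenomicInterval]], min_support: int
) -> list[GenomicInterval]:
    """Maximal regions whose every base is covered by >= min_support sets."""
    events: dict[str, list[tuple[int, int]]] = {}
    for ps in peaksets:
        for iv in merge_intervals(ps):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        start = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth >= min_support and start is None:
                start = pos
            elif depth < min_support and start is not None:
                if pos > start:
                    out.append(GenomicInterval(chrom, start, pos))
                start = None
    return out


def consensus_peaks(
    peaksets: Sequence[PeakSet], min_support: int
) -> PeakSet:
    """Bases covered by >= ``min_support`` input sets, merged."""
    marks = {ps.mark for ps in peaksets}
    if len(marks) > 1:
        raise ValueError(f"mixed marks in consensus: {sorted(marks)}")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    regions = _coverage_regions([ps.peaks for ps in peaksets], min_support)
    return PeakSet("consensus", "", marks.pop() if marks else "",
                   regions)


def peak_genes(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    mark: str,
    promoter_window: int = 3000,
) -> set[str]:
    """Genes associated with a mark's peaks, restricted to the mark's
    functional annotation categories."""
    if mark not in MARK_CATEGORIES:
        raise ValueError(f"unknown mark {mark!r}")
    cats = MARK_CATEGORIES[mark]
    calls = annotate_regions(list(peaks), genes, promoter_window)
    return {c.nearest_gene for c in calls if c.category in cats}


def specific_and_common(
    peaks_gic: PeakSet,
    peaks_insc: PeakSet,
    genes: Sequence[GeneModel],
    promoter_window: int = 3000,
) -> dict:
    """Gene-level three-way partition for one mark.

    Returns gene sets common to both conditions and specific to each, with
    percentages of the union (sum to 100).
    """
    if peaks_gic.mark != peaks_insc.mark:
        raise ValueError("peak sets must share the mark")
    g_gic = peak_genes(peaks_gic.peaks, genes, peaks_gic.mark,
                       promoter_window)
    g_insc = peak_genes(peaks_insc.peaks, genes, peaks_insc.mark,
                        promoter_window)
    common = g_gic & g_insc
    only_gic = g_gic - g_insc
    only_insc = g_insc - g_gic
    total = len(common) + len(only_gic) + len(only_insc)
    pct = (lambda s: 100.0 * len(s) / total) if total else (lambda s: 0.0)
    return {
        "common": common,
        "gic_specific": only_gic,
        "insc_specific": only_insc,
        "pct_common": pct(common),
        "pct_gic_specific": pct(only_gic),
        "pct_insc_specific": pct(only_insc),
    }


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds ratio ad/bc with 0/inf handling, two-sided p computed as
    the total probability of tables, at fixed margins, no more likely than
    the observed one).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    odds, p = stats.fisher_exact(t.astype(np.int64), alternative="two-sided")
    return float(odds), float(p)


def compare_annotation_distributions(
    calls_gic: Sequence[AnnotationCall],
    calls_insc: Sequence[AnnotationCall],
) -> pd.DataFrame:
    """Per-category fold change and Fisher p between the two conditions.

    For category c the table is [[gic_c, gic_rest], [insc_c, insc_rest]];
    fold change is fraction_gic / fraction_insc.
    """
    if not calls_gic or not calls_insc:
        raise ValueError("both call lists must be non-empty")
    n_g, n_i = len(calls_gic), len(calls_insc)
    cats = sorted(
        {c.category for c in calls_gic} | {c.category for c in calls_insc}
    )
    rows = []
    for cat in cats:
        g = sum(c.category == cat for c in calls_gic)
        i = sum(c.category == cat for c in calls_insc)
        odds, p = fisher_exact_2x2([[g, n_g - g], [i, n_i - i]])
        fg, fi = g / n_g, i / n_i
        rows.append(
            {
                "category": cat,
                "n_gic": g,
                "n_insc": i,
                "fold_change": np.inf if fi == 0 else fg / fi,
                "odds_ratio": odds,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def differential_binding(
    count_matrix: np.ndarray | pd.DataFrame,
    conditions: Sequence[str],
    patients: Sequence[str | int],
    sites: Sequence[GenomicInterval] | None = None,
    mark: str = "",
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Paired differential binding across a site x sample count matrix.

    Counts-per-million normalisation, log2(x+1), a paired t-test across
    patients (GIC vs iNSC), Benjamini-Hochberg FDR, and classification of
    each site as gic_only / insc_only / shared by (FDR < alpha,
    |log2FC| > lfc_threshold).
    """
    X = np.asarray(count_matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    conditions = list(conditions)
    patients = list(patients)
    if len(conditions) != X.shape[1] or len(patients) != X.shape[1]:
        raise ValueError("design length must match sample count")
    pair_g, pair_i = {}, {}
    for j, (c, p) in enumerate(zip(conditions, patients)):
        if c == "GIC":
            pair_g[p] = j
        elif c == "iNSC":
            pair_i[p] = j
        else:
            raise ValueError(f"unknown condition {c!r}")
    paired = sorted(set(pair_g) & set(pair_i))
    if len(paired) < 2:
        raise ValueError("need >= 2 complete GIC/iNSC pairs")
    cpm = X / X.sum(axis=0, keepdims=True) * 1e6
    logc = np.log2(cpm + 1)
    G = logc[:, [pair_g[p] for p in paired]]
    I = logc[:, [pair_i[p] for p in paired]]
    diffs = G - I
    log2fc = diffs.mean(axis=1)
    tres = stats.ttest_rel(G, I, axis=1)
    pvals = np.asarray(tres.pvalue)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    rows = []
    for s in range(X.shape[0]):
        rows.append(
            {
                "site": s if sites is None else f"{sites[s].chrom}:"
                f"{sites[s].start}-{sites[s].end}",
                "mark": mark,
                "log2fc": log2fc[s],
                "p": pvals[s],
                "fdr": fdr[s],
                "class": DiffBoundSite.classify(log2fc[s], fdr[s], alpha,
                                                lfc_threshold),
            }
        )
    return pd.DataFrame(rows)


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class _RuleParser:
    """Tiny recursive-descent parser for mark-combination rules:
    expr := term (OR term)* ; term := factor (AND factor)* ;
    factor := NOT factor | '(' expr ')' | MARK."""

    def __init__(self, rule: str, marks: set[str]):
        self.tokens = _TOKEN.findall(rule)
        self.pos = 0
        self.marks = marks

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def eat(self) -> str:
        t = self.peek()
        if t is None:
            raise ValueError("unexpected end of rule")
        self.pos += 1
        return t

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise ValueError(f"trailing token {self.peek()!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() and self.peek().upper() == "OR":
            self.eat()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() and self.peek().upper() == "AND":
            self.eat()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        t = self.eat()
        if t.upper() == "NOT":
            return ("not", self.factor())
        if t == "(":
            node = self.expr()
            if self.eat() != ")":
                raise ValueError("unbalanced parentheses")
            return node
        if t in self.marks:
            return ("mark", t)
        raise ValueError(f"unknown mark in rule: {t!r}")


def combine_marks(
    sets: dict[str, PeakSet], rule: str
) -> PeakSet:
    """Base-level boolean combination of per-mark coverage.

    ``rule`` is an expression over mark names with AND / OR / NOT and
    parentheses, e.g. ``"H3K27ac AND NOT H3K4me3"`` for candidate
    enhancers.
    """
    ast = _RuleParser(rule, set(sets)).parse()
    chroms = sorted(
        {iv.chrom for ps in sets.values() for iv in ps.peaks}
    )
    out: list[GenomicInterval] = []
    for chrom in chroms:
        points = set()
        cov: dict[str, list[tuple[int, int]]] = {}
        for mark, ps in sets.items():
            ivs = [(iv.start, iv.end) for iv in ps.peaks
                   if iv.chrom == chrom]
            cov[mark] = ivs
            for s, e in ivs:
                points.update((s, e))
        bps = sorted(points)
        if not bps:
            continue

        def covered(mark: str, pos: int) -> bool:
            return any(s <= pos < e for s, e in cov[mark])

        def ev(node, pos: int) -> bool:
            op = node[0]
            if op == "mark":
                return covered(node[1], pos)
            if op == "not":
                return not ev(node[1], pos)
            if op == "and":
                return ev(node[1], pos) and ev(node[2], pos)
            return ev(node[1], pos) or ev(node[2], pos)

        run_start = None
        for a, b in zip(bps[:-1], bps[1:]):
            val = ev(ast, a)
            if val and run_start is None:
                run_start = a
            elif not val and run_start is not None:
                out.append(GenomicInterval(chrom, run_start, a))
                run_start = None
        if run_start is not None:
            out.append(GenomicInterval(chrom, run_start, bps[-1]))
    return PeakSet("combined", "", rule, out)
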