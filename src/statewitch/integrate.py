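"""Integration of epigenetic calls with differential expression.

Joins histone-mark gains/losses, chromatin states and state switches to a
per-gene differential-expression table: concordance percentages
(up vs down among differentially expressed member genes), proximal
enhancer -> gene linking within 50 kb, enrichment tests and the
druggable-target triage table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval
from .peaks import fisher_exact_2x2
from .switches import SwitchEvent

#: marks whose gain is expected to increase expression
ACTIVATING_MARKS = {"H3K4me3", "H3K27ac", "H3K36me3"}
REPRESSIVE_MARKS = {"H3K27me3"}


@dataclass(frozen=True)
class DEGene:
    """One row of the differential-expression table (GIC over iNSC)."""

    gene_id: str
    log2fc: float
    p: float

    @property
    def status(self) -> str:
        if self.p < 0.01 and self.log2fc > 1:
            return "up"
        if self.p < 0.01 and self.log2fc < -1:
            return "down"
        return "ns"


def call_de(
    expression: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Call up/down/ns per gene: |log2FC| > 1 (fold change > 2) and
    p < 0.01."""
    required = {"gene", "log2fc", "p"}
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    df = expression.copy()
    df["status"] = "ns"
    sig = df["p"] < p_threshold
    df.loc[sig & (df["log2fc"] > lfc_threshold), "status"] = "up"
    df.loc[sig & (df["log2fc"] < -lfc_threshold), "status"] = "down"
    return df


def gene_sets_from_marks(
    specific_genes: dict[str, dict[str, set[str]]],
) -> dict[str, tuple[set[str], str]]:
    """Strata with expected DE direction from condition-specific gene sets.

    ``specific_genes`` maps mark -> {"gic_specific": set, "insc_specific":
    set}.  A GIC-specific (gained-in-GIC) activating mark predicts
    upregulation; a gained repressive mark predicts downregulation; losses
    (iNSC-specific) mirror.
    """
    strata: dict[str, tuple[set[str], str]] = {}
    for mark, sets in specific_genes.items():
        if mark in ACTIVATING_MARKS:
            gain_dir, loss_dir = "up", "down"
        elif mark in REPRESSIVE_MARKS:
            gain_dir, loss_dir = "down", "up"
        else:
            raise ValueError(f"unknown mark {mark!r}")
        if "gic_specific" in sets:
            strata[f"{mark}_gain"] = (set(sets["gic_specific"]), gain_dir)
        if "insc_specific" in sets:
            strata[f"{mark}_loss"] = (set(sets["insc_specific"]), loss_dir)
    return strata


def concordance(
    gene_sets: dict[str, tuple[set[str], str]],
    de: pd.DataFrame,
) -> pd.DataFrame:
    """Per-stratum up/down percentages and concordance with expectation.

    Non-DE (ns) member genes are excluded from the percentage denominators
    (the published convention); total member counts are reported alongside
    for transparency.  Strata with no DE member genes report NA.
    """
    if "status" not in de.columns:
        de = call_de(de)
    status = dict(zip(de["gene"], de["status"]))
    rows = []
    for stratum, (members, expected) in sorted(gene_sets.items()):
        st = [status.get(g, "ns") for g in set(members)]
        n_up = sum(s == "up" for s in st)
        n_down = sum(s == "down" for s in st)
        n_de = n_up + n_down
        if n_de == 0:
            pct_up = pct_down = conc = np.nan
        else:
            pct_up = 100.0 * n_up / n_de
            pct_down = 100.0 * n_down / n_de
            conc = pct_up if expected == "up" else pct_down
        rows.append(
            {
                "stratum": stratum,
                "expected_direction": expected,
                "n_members": len(set(members)),
                "n_up": n_up,
                "n_down": n_down,
                "pct_up": pct_up,
                "pct_down": pct_down,
                "concordance_pct": conc,
            }
        )
    return pd.DataFrame(rows)


def link_enhancers(
    enhancer_regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int = 50_000,
) -> pd.DataFrame:
    """Link each enhancer region to its nearest gene TSS within 50 kb.

    Distance is measured from the TSS to the nearest edge of the region
    (zero when the TSS falls inside it); regions beyond ``max_distance``
    from every TSS stay unlinked.  Regions should be pre-filtered to
    intronic / distal intergenic annotation.
    """
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.tx_interval.chrom, []).append(g)
    for r in enhancer_regions:
        best, bestd = None, np.inf
        for g in by_chrom.get(r.chrom, []):
            t = g.tss
            d = 0 if r.start <= t < r.end else min(
                abs(t - r.start), abs(t - (r.end - 1))
            )
            if d < bestd or (d == bestd and best is not None
                             and g.gene_id < best.gene_id):
                best, bestd = g, d
        linked = best is not None and bestd <= max_distance
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "gene": best.gene_id if linked else "",
                "distance": int(bestd) if linked else -1,
                "linked": linked,
            }
        )
    return pd.DataFrame(rows)


def enhancer_de_enrichment(
    links_gic: pd.DataFrame,
    links_insc: pd.DataFrame,
    de: pd.DataFrame,
) -> dict:
    """Fisher test of enhancer condition-specificity against DE direction.

    Builds the 2x2 table [[gic_up, gic_down], [insc_up, insc_down]] over
    genes linked to GIC-only and iNSC-only enhancers.
    """
    if "status" not in de.columns:
        de = call_de(de)
    status = dict(zip(de["gene"], de["status"]))

    def counts(links: pd.DataFrame) -> tuple[int, int]:
        genes = {g for g in links.loc[links["linked"], "gene"]}
        up = sum(status.get(g) == "up" for g in genes)
        down = sum(status.get(g) == "down" for g in genes)
        return up, down

    gu, gd = counts(links_gic)
    iu, idn = counts(links_insc)
    table = [[gu, gd], [iu, idn]]
    if min(gu + gd, iu + idn) == 0:
        warnings.warn("degenerate enhancer/DE table; p set to 1")
        return {"table": table, "odds_ratio": np.nan, "p": 1.0}
    odds, p = fisher_exact_2x2(table)
    return {"table": table, "odds_ratio": odds, "p": p}


def triage_targets(
    switch_events: Sequence[SwitchEvent],
    de: pd.DataFrame,
    flags_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Candidate target genes from switches joined with DE and user flags.

    Activated candidates: genes linked to activating switches and
    upregulated; repressed candidates mirror.  ``flags_table`` (gene +
    boolean columns, externally curated) partitions candidates into
    subgroups; counts per flag combination are returned.
    """
    if "status" not in de.columns:
        de = call_de(de)
    status = dict(zip(de["gene"], de["status"]))
    rows = []
    for e in switch_events:
        if not e.linked_gene or e.direction == "neutral":
            continue
        st = status.get(e.linked_gene, "ns")
        if e.direction == "activating" and st == "up":
            rows.append((e.linked_gene, "activated"))
        elif e.direction == "repressing" and st == "down":
            rows.append((e.linked_gene, "repressed"))
    cand = pd.DataFrame(sorted(set(rows)), columns=["gene", "candidate_class"])
    flag_cols: list[str] = []
    if flags_table is not None and len(flags_table):
        if "gene" not in flags_table.columns:
            raise ValueError("flags table must have a 'gene' column")
        flag_cols = [c for c in flags_table.columns if c != "gene"]
        known = set(flags_table["gene"])
        for g in cand["gene"]:
            if g not in known:
                warnings.warn(f"gene {g} missing from flags table; kept")
        cand = cand.merge(flags_table, on="gene", how="left")
        cand[flag_cols] = cand[flag_cols].fillna(False)
    subgroups: dict = {}
    if flag_cols:
        for _, row in cand.iterrows():
            key = frozenset(c for c in flag_cols if bool(row[c]))
            subgroups[key] = subgroups.get(key, 0) + 1
    else:
        subgroups = {"unannotated": len(cand)}
    return cand, subgroups
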