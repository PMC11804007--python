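"""Paired chromatin-state switch detection with patient recurrence.

A switch is a bin (merged into regions) where the same ordered
(iNSC state -> GIC state) transition is observed in at least
``min_patients`` patients of the cohort.  Switches are classified as
activating (inactive -> active state), repressing (active -> inactive)
or neutral using the functional state labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    AnnotationCall,
    GeneModel,
    GenomicInterval,
    annotate_region,
    _GeneIndex,
)
from .hmm import Segmentation, StateLabelMap


@dataclass
class SwitchEvent:
    """A recurrent (iNSC -> GIC) state switch region."""

    region: GenomicInterval
    from_state: int
    to_state: int
    supporting_patients: frozenset
    direction: str = "neutral"
    from_label: str = ""
    to_label: str = ""
    annotation: AnnotationCall | None = None
    linked_gene: str | None = None

    @property
    def n_support(self) -> int:
        return len(self.supporting_patients)


@dataclass
class TransitionMatrix:
    """K x K counts of switching regions (row = iNSC, col = GIC state)."""

    counts: np.ndarray
    labels: dict[int, str] | None = None

    @property
    def total_switching(self) -> int:
        off = self.counts.copy()
        np.fill_diagonal(off, 0)
        return int(off.sum())


def bin_transitions(
    seg_insc: Segmentation, seg_gic: Segmentation
) -> np.ndarray:
    """Per-bin (from, to) state pairs as an (n_bins, 2) array."""
    if seg_insc.grid != seg_gic.grid:
        raise ValueError("segmentations must share the grid")
    return np.stack([seg_insc.states, seg_gic.states], axis=1)


def recurrent_switches(
    per_patient: dict | Sequence[np.ndarray],
    grid,
    K: int,
    min_patients: int = 2,
    label_map: StateLabelMap | None = None,
    genes: Sequence[GeneModel] | None = None,
    max_gene_distance: int = 50_000,
    peaks: Sequence[GenomicInterval] | None = None,
) -> list[SwitchEvent]:
    """Recurrence-filtered switch regions from per-patient transitions.

    ``per_patient`` maps patient id -> (n_bins, 2) transition pairs (or is
    a sequence, in which case positional ids are used).  A bin qualifies
    for an ordered pair when >= ``min_patients`` patients show exactly
    that pair there; adjacent qualifying bins with the same pair merge
    into one region whose support is the minimum per-bin support
    (supporting patients: those showing the pair in every bin).  With
    ``peaks`` given, events are restricted to regions overlapping the
    supplied (e.g. consensus-peak) intervals.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    if not isinstance(per_patient, dict):
        per_patient = {i: t for i, t in enumerate(per_patient)}
    pids = sorted(per_patient)
    P = len(pids)
    if P == 0:
        return []
    fr = np.stack([per_patient[p][:, 0] for p in pids])  # (P, B)
    to = np.stack([per_patient[p][:, 1] for p in pids])
    n_bins = fr.shape[1]
    code = np.where(fr != to, fr * K + to, -1)  # -1 = non-switching

    gene_index = _GeneIndex(genes) if genes else None

    events: list[SwitchEvent] = []
    for chrom, sl in grid.chrom_slices():
        codes_c = code[:, sl]
        nb = codes_c.shape[1]
        # per bin, the set of qualifying pair codes
        open_runs: dict[int, tuple[int, frozenset]] = {}  # code -> (start, patients)
        for b in range(nb + 1):
            if b < nb:
                col = codes_c[:, b]
                vals, cnts = np.unique(col[col >= 0], return_counts=True)
                here = {
                    int(v): frozenset(pids[i] for i in np.flatnonzero(col == v))
                    for v, c in zip(vals, cnts)
                    if c >= min_patients
                }
            else:
                here = {}
            for c in list(open_runs):
                if c not in here:
                    start, pats = open_runs.pop(c)
                    events.append(
                        _make_event(grid, chrom, start, b, c, K, pats,
                                    label_map, gene_index,
                                    max_gene_distance)
                    )
            for c, pats in here.items():
                if c in open_runs:
                    start, acc = open_runs[c]
                    merged = acc & pats
                    if len(merged) >= min_patients:
                        open_runs[c] = (start, merged)
                    else:
                        # the patient intersection would fall below the
                        # recurrence threshold: close and restart the run
                        events.append(
                            _make_event(grid, chrom, start, b, c, K, acc,
                                        label_map, gene_index,
                                        max_gene_distance)
                        )
                        open_runs[c] = (b, pats)
                else:
                    open_runs[c] = (b, pats)
    if peaks is not None:
        events = [
            e for e in events
            if any(e.region.overlaps(p) for p in peaks)
        ]
    events.sort(key=lambda e: (e.region.chrom, e.region.start,
                               e.from_state, e.to_state))
    return events


def nearest_gene_by_edge(gene_index: _GeneIndex, region: GenomicInterval):
    """Nearest gene by TSS-to-region-edge distance (0 when the TSS lies
    inside the region); ties break to the smaller gene id."""
    best, bestd = None, np.inf
    seen = set()
    for pos in (region.start, region.midpoint, region.end - 1):
        g, d = gene_index.nearest(region.chrom, pos)
        if not np.isfinite(d) or g.gene_id in seen:
            continue
        seen.add(g.gene_id)
        t = g.tss
        ed = 0 if region.start <= t < region.end else min(
            abs(t - region.start), abs(t - (region.end - 1))
        )
        if ed < bestd or (ed == bestd and best is not None
                          and g.gene_id < best.gene_id):
            best, bestd = g, ed
    return best, bestd


def _make_event(
    grid, chrom, b0, b1, code, K, patients, label_map, gene_index,
    max_gene_distance,
) -> SwitchEvent:
    bs = grid.bin_size
    region = GenomicInterval(
        chrom, b0 * bs, min(b1 * bs, grid.chrom_sizes[chrom])
    )
    from_state, to_state = code // K, code % K
    direction, fl, tl = "neutral", "", ""
    if label_map is not None:
        fl, tl = label_map.labels[from_state], label_map.labels[to_state]
        a_from = label_map.activity(from_state)
        a_to = label_map.activity(to_state)
        if a_from == "inactive" and a_to == "active":
            direction = "activating"
        elif a_from == "active" and a_to == "inactive":
            direction = "repressing"
    annotation = linked = None
    if gene_index is not None:
        annotation = annotate_region(region, gene_index)
        g, edge_d = nearest_gene_by_edge(gene_index, region)
        if g is not None and edge_d <= max_gene_distance:
            linked = g.gene_id
    return SwitchEvent(
        region, int(from_state), int(to_state), frozenset(patients),
        direction, fl, tl, annotation, linked,
    )


def transition_matrix(
    events: Sequence[SwitchEvent],
    K: int,
    label_map: StateLabelMap | None = None,
) -> tuple[TransitionMatrix, dict[str, float]]:
    """Counts of switching regions per ordered state pair plus the
    percentage shares of activating / repressing / neutral switches."""
    counts = np.zeros((K, K), dtype=np.int64)
    shares = {"activating": 0, "repressing": 0, "neutral": 0}
    for e in events:
        counts[e.from_state, e.to_state] += 1
        d = e.direction
        if label_map is not None and not e.from_label:
            a = label_map.activity(e.from_state)
            b = label_map.activity(e.to_state)
            d = ("activating" if (a, b) == ("inactive", "active")
                 else "repressing" if (a, b) == ("active", "inactive")
                 else "neutral")
        shares[d] += 1
    total = sum(shares.values())
    pct = {
        k: (100.0 * v / total if total else 0.0) for k, v in shares.items()
    }
    labels = label_map.labels if label_map else None
    return TransitionMatrix(counts, labels), pct


def top_switches(
    matrix: TransitionMatrix,
    k: int = 6,
    label_map: StateLabelMap | None = None,
    cross_class_only: bool = True,
) -> list[tuple[int, int, int]]:
    """Top-k (from, to, count) cells by switching-region count.

    With ``cross_class_only`` (the default) only activating or repressing
    cells are eligible.  Ties break deterministically by (from, to) index.
    """
    K = matrix.counts.shape[0]
    cells = []
    for i in range(K):
        for j in range(K):
            if i == j or matrix.counts[i, j] == 0:
                continue
            if cross_class_only:
                if label_map is None:
                    raise ValueError(
                        "cross_class_only requires a label map"
                    )
                a, b = label_map.activity(i), label_map.activity(j)
                if a == b:
                    continue
            cells.append((int(matrix.counts[i, j]), i, j))
    cells.sort(key=lambda c: (-c[0], c[1], c[2]))
    return [(i, j, n) for n, i, j in cells[:k]]


def switches_table(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "chrom": e.region.chrom,
                "start": e.region.start,
                "end": e.region.end,
                "from_state": e.from_state,
                "to_state": e.to_state,
                "from_label": e.from_label,
                "to_label": e.to_label,
                "direction": e.direction,
                "n_support": e.n_support,
                "patients": ",".join(map(str,
                                         sorted(e.supporting_patients))),
                "category": e.annotation.category if e.annotation else "",
                "linked_gene": e.linked_gene or "",
            }
        )
    return pd.DataFrame(rows)
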