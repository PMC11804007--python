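"""Poisson-background binarization of binned ChIP signal.

Converts per-bin read counts (optionally with a matched input control) into
binary mark-presence calls, one track per (sample, mark), the input
representation the chromatin-state HMM expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .genome import BinGrid, GenomicInterval


@dataclass
class BinarizedTrackSet:
    """Binary presence calls for M marks over one sample's bin grid."""

    grid: BinGrid
    marks: list[str]
    calls: np.ndarray  # (n_bins, M) uint8
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (bins x marks)")
        if self.calls.shape != (self.grid.n_bins, len(self.marks)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({self.grid.n_bins}, {len(self.marks)})"
            )

    def mark_vector(self, mark: str) -> np.ndarray:
        return self.calls[:, self.marks.index(mark)]

    def ones_as_intervals(self, mark: str) -> list[GenomicInterval]:
        """Runs of 1-bins for one mark as merged genomic intervals."""
        out: list[GenomicInterval] = []
        v = self.mark_vector(mark)
        for chrom, sl in self.grid.chrom_slices():
            vv = v[sl]
            edges = np.flatnonzero(np.diff(np.r_[0, vv, 0]))
            for s, e in zip(edges[::2], edges[1::2]):
                out.append(
                    GenomicInterval(
                        chrom,
                        int(s) * self.grid.bin_size,
                        min(int(e) * self.grid.bin_size,
                            self.grid.chrom_sizes[chrom]),
                    )
                )
        return out


def poisson_threshold(lam: float, p_cut: float) -> int:
    """Smallest integer c with P(X >= c) <= p_cut for X ~ Poisson(lam)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must lie in (0, 1)")
    c = max(int(poisson.ppf(1 - p_cut, lam)) - 2, 0)
    while poisson.sf(c - 1, lam) > p_cut:
        c += 1
    return c


def binarize_track(
    counts: np.ndarray,
    control: np.ndarray | None = None,
    p_cut: float = 1e-4,
    smooth_window: int = 2,
) -> np.ndarray:
    """Binary calls from per-bin counts under a Poisson background.

    Without a control the background rate is the global mean count.  With a
    control, the per-bin rate is the control smoothed over +/-
    ``smooth_window`` bins, scaled by the treatment/control library-size
    ratio and floored at the global treatment mean (avoids zero rates).
    Bin call = 1 iff P(X >= count | Poisson(rate)) <= ``p_cut``.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must lie in (0, 1)")
    gmean = float(counts.mean())
    if gmean == 0:
        return np.zeros(counts.shape, dtype=np.uint8)
    if control is None:
        lam = np.full(counts.shape, gmean)
    else:
        control = np.asarray(control)
        if control.shape != counts.shape:
            raise ValueError("control length must match counts")
        if np.any(control < 0):
            raise ValueError("negative control counts")
        w = 2 * smooth_window + 1
        kernel = np.ones(w) / w
        smoothed = np.convolve(control.astype(float), kernel, mode="same")
        # edge bins: renormalise for the truncated window
        norm = np.convolve(np.ones_like(control, dtype=float), kernel,
                           mode="same")
        smoothed = smoothed / norm
        ctot = float(control.sum())
        scale = counts.sum() / ctot if ctot > 0 else 1.0
        lam = np.maximum(smoothed * scale, gmean)
    # count >= poisson_threshold(lam, p_cut)  <=>  sf(count - 1, lam) <= p_cut
    return (poisson.sf(counts - 1, lam) <= p_cut).astype(np.uint8)


def binarize_sample(
    grid: BinGrid,
    marks: list[str],
    count_matrix: np.ndarray,
    control_matrix: np.ndarray | None = None,
    p_cut: float = 1e-4,
    sample_id: str = "",
    condition: str = "",
) -> BinarizedTrackSet:
    """Binarize an (n_bins, M) count matrix into a track set."""
    count_matrix = np.asarray(count_matrix)
    calls = np.empty(count_matrix.shape, dtype=np.uint8)
    for m in range(count_matrix.shape[1]):
        ctrl = None if control_matrix is None else control_matrix[:, m]
        calls[:, m] = binarize_track(count_matrix[:, m], ctrl, p_cut)
    return BinarizedTrackSet(grid, marks, calls, sample_id, condition)
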