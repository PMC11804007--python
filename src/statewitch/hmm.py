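"""Multivariate Bernoulli-emission hidden Markov model for chromatin states.

Each genomic bin carries an M-vector of binary histone-mark calls; a hidden
state k emits mark m with probability E[k, m] independently across marks
(the ChromHMM emission model).  Chromosomes are independent chains: the
initial distribution is re-applied at every chromosome start.

Provides Baum-Welch training with restarts, posterior decoding,
model-size selection, cross-model state matching and generalization
overlap, rule-based functional state labelling, and genome-fraction
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._kernels import backward_scaled, forward_scaled
from .binarize import BinarizedTrackSet
from .genome import BinGrid, GenomicInterval

EPS = 1e-6  # emission clipping; prevents log(0) and absorbing emissions

DEFAULT_MARKS = ["H3K4me3", "H3K27ac", "H3K36me3", "H3K27me3"]

STATE_LABELS = (
    "active_tss",
    "enhancers",
    "active_transcription",
    "transcription",
    "poised_gene_body",
    "repressed_polycomb",
    "weak_repressed_polycomb",
    "quiescent",
)
ACTIVE_LABELS = frozenset(
    {"transcription", "active_transcription", "enhancers", "active_tss"}
)
INACTIVE_LABELS = frozenset(STATE_LABELS) - ACTIVE_LABELS

# emission prototypes (H3K4me3, H3K27ac, H3K36me3, H3K27me3) used to
# resolve rule collisions and to label rule-ambiguous states
_PROTOTYPES = {
    "active_tss": np.array([0.9, 0.9, 0.1, 0.05]),
    "enhancers": np.array([0.05, 0.9, 0.1, 0.05]),
    "active_transcription": np.array([0.1, 0.6, 0.9, 0.05]),
    "transcription": np.array([0.05, 0.05, 0.9, 0.05]),
    "poised_gene_body": np.array([0.05, 0.05, 0.6, 0.7]),
    "repressed_polycomb": np.array([0.05, 0.05, 0.05, 0.9]),
    "weak_repressed_polycomb": np.array([0.02, 0.02, 0.02, 0.35]),
    "quiescent": np.array([0.02, 0.02, 0.02, 0.02]),
}


@dataclass
class HMMModel:
    """Parameters of a K-state, M-mark Bernoulli HMM."""

    pi: np.ndarray  # (K,)
    A: np.ndarray  # (K, K) row-stochastic
    E: np.ndarray  # (K, M) Bernoulli emission probabilities
    mark_names: list[str] = field(default_factory=lambda: list(DEFAULT_MARKS))
    trained_on: str = ""
    log_likelihood_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.E = np.clip(np.asarray(self.E, dtype=float), EPS, 1 - EPS)
        K, M = self.E.shape
        if self.pi.shape != (K,) or self.A.shape != (K, K):
            raise ValueError("inconsistent parameter shapes")
        if len(self.mark_names) != M:
            raise ValueError("mark_names length must equal M")
        if abs(self.pi.sum() - 1) > 1e-9:
            raise ValueError("pi must sum to 1")
        if np.max(np.abs(self.A.sum(axis=1) - 1)) > 1e-9:
            raise ValueError("A rows must sum to 1")

    @property
    def K(self) -> int:
        return self.E.shape[0]

    @property
    def M(self) -> int:
        return self.E.shape[1]

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of A for eigenvalue 1, normalised to sum 1."""
        w, v = np.linalg.eig(self.A.T)
        i = int(np.argmin(np.abs(w - 1)))
        p = np.real(v[:, i])
        return p / p.sum()

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "states": self.K,
            "marks": list(self.mark_names),
            "trained_on": self.trained_on,
            "pi": [float(x) for x in self.pi],
            "A": [[float(x) for x in row] for row in self.A],
            "E": [[float(x) for x in row] for row in self.E],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HMMModel":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            pi=np.array(d["pi"]),
            A=np.array(d["A"]),
            E=np.array(d["E"]),
            mark_names=list(d["marks"]),
            trained_on=d.get("trained_on", ""),
        )


@dataclass
class Segmentation:
    """Hard per-bin state assignments for one sample."""

    grid: BinGrid
    states: np.ndarray  # (n_bins,) int
    posteriors: np.ndarray | None = None  # (n_bins, K)
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (self.grid.n_bins,):
            raise ValueError("states length must equal grid.n_bins")

    def to_intervals(
        self, label_map: "StateLabelMap | None" = None
    ) -> list[GenomicInterval]:
        """Merge same-state runs into BED4-style intervals."""
        out: list[GenomicInterval] = []
        bs = self.grid.bin_size
        for chrom, sl in self.grid.chrom_slices():
            s = self.states[sl]
            edges = np.flatnonzero(np.diff(s)) + 1
            bounds = np.r_[0, edges, len(s)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                st = int(s[a])
                name = label_map.labels[st] if label_map else f"state_{st}"
                out.append(
                    GenomicInterval(
                        chrom,
                        int(a) * bs,
                        min(int(b) * bs, self.grid.chrom_sizes[chrom]),
                        name=name,
                    )
                )
        return out


@dataclass
class StateLabelMap:
    """Functional labels for HMM states and their activity classes."""

    labels: dict[int, str]
    flagged: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        used = [l for l in self.labels.values()]
        if len(used) != len(set(used)):
            raise ValueError("duplicate state labels")
        for l in used:
            if l not in STATE_LABELS:
                raise ValueError(f"unknown label {l!r}")

    def activity(self, state: int) -> str:
        return "active" if self.labels[state] in ACTIVE_LABELS else "inactive"

    def index_of(self, label: str) -> int:
        for k, l in self.labels.items():
            if l == label:
                return k
        raise KeyError(label)


def emission_loglik(obs: np.ndarray, state: int, model: HMMModel) -> float:
    """Log-likelihood of one M-vector under state ``state``'s Bernoullis."""
    obs = np.asarray(obs)
    if obs.shape != (model.M,):
        raise ValueError(f"obs length {obs.shape} != M={model.M}")
    e = model.E[state]
    return float(np.sum(obs * np.log(e) + (1 - obs) * np.log(1 - e)))


def _log_emission_matrix(X: np.ndarray, E: np.ndarray) -> np.ndarray:
    """(T, K) log-likelihoods for all bins and states, vectorised."""
    X = X.astype(float)
    return X @ np.log(E).T + (1 - X) @ np.log(1 - E).T


def _sequences(tracks: BinarizedTrackSet) -> list[np.ndarray]:
    """Per-chromosome observation matrices (chromosomes are independent)."""
    return [tracks.calls[sl] for _, sl in tracks.grid.chrom_slices()]


def forward_backward(
    tracks: BinarizedTrackSet, model: HMMModel
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-bin posterior state probabilities.

    Scaled (normalised) recursions; each chromosome is an independent
    sequence restarted from the initial distribution.
    """
    if tracks.calls.shape[1] != model.M:
        raise ValueError("track mark count does not match model M")
    gammas = []
    loglik = 0.0
    for X in _sequences(tracks):
        logB = _log_emission_matrix(X, model.E)
        B = np.exp(logB - logB.max(axis=1, keepdims=True))
        alpha, c = forward_scaled(B, model.A, model.pi)
        beta = backward_scaled(B, model.A, c)
        loglik += float(np.log(c).sum() + logB.max(axis=1).sum())
        g = alpha * beta
        g /= g.sum(axis=1, keepdims=True)
        gammas.append(g)
    return loglik, np.vstack(gammas)


def _em_step(
    seqs: list[np.ndarray],
    pi: np.ndarray,
    A: np.ndarray,
    E: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """One Baum-Welch E+M step over all sequences; returns the loglik of
    the *input* parameters and the updated (pi, A, E)."""
    K, M = E.shape
    pi_acc = np.zeros(K)
    xi_acc = np.zeros((K, K))
    gX_acc = np.zeros((K, M))
    g_acc = np.zeros(K)
    loglik = 0.0
    n_seq = 0
    for X in seqs:
        logB = _log_emission_matrix(X, E)
        shift = logB.max(axis=1)
        B = np.exp(logB - shift[:, None])
        alpha, c = forward_scaled(B, A, pi)
        beta = backward_scaled(B, A, c)
        loglik += float(np.log(c).sum() + shift.sum())
        g = alpha * beta
        g /= g.sum(axis=1, keepdims=True)
        pi_acc += g[0]
        if len(X) > 1:
            xi_acc += A * (
                alpha[:-1].T @ (B[1:] * beta[1:] / c[1:, None])
            )
        gX_acc += g.T @ X
        g_acc += g.sum(axis=0)
        n_seq += 1
    pi_new = pi_acc / n_seq
    rows = xi_acc.sum(axis=1, keepdims=True)
    A_new = np.where(rows > 0, xi_acc / np.where(rows > 0, rows, 1), A)
    E_new = np.clip(gX_acc / g_acc[:, None], EPS, 1 - EPS)
    return loglik, pi_new, A_new, E_new


def _informed_init(
    seqs: list[np.ndarray], K: int, M: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic initialisation from observed mark-combination
    frequencies.

    Emission rows are seeded with the most frequent binary mark patterns,
    plus one half-intensity copy of the commonest single-mark pattern:
    states that differ only in emission intensity (e.g. strong vs weak
    polycomb) are otherwise a hard-to-reach EM basin from random starts.
    """
    X = np.vstack(seqs)
    codes = X.astype(np.int64) @ (1 << np.arange(M, dtype=np.int64))
    cnt = np.bincount(codes, minlength=2 ** M)
    order = np.argsort(cnt)[::-1]
    singles = [int(c) for c in order
               if bin(int(c)).count("1") == 1 and cnt[c] > 0]
    rows: list[list[float]] = []
    n_top = min(K - 1 if singles else K, 2 ** M)
    for c in order[:n_top]:
        rows.append([0.88 if (int(c) >> m) & 1 else 0.06
                     for m in range(M)])
    if singles and len(rows) < K:
        c = singles[0]
        rows.append([0.45 if (c >> m) & 1 else 0.04 for m in range(M)])
    while len(rows) < K:  # more states than patterns: neutral filler rows
        rows.append([0.3 + 0.4 * ((len(rows) + m) % 2) for m in range(M)])
    E = np.array(rows[:K])
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    return np.full(K, 1 / K), A, E


def baum_welch(
    cohort: Sequence[BinarizedTrackSet],
    K: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-3,
    trained_on: str = "",
) -> HMMModel:
    """Train a K-state model on a cohort of binarized track sets.

    Restart 0 uses the deterministic pattern-frequency initialisation;
    the remaining restarts are random, seeded as ``seed + restart``.  The
    model with the best final log-likelihood wins.  The per-iteration
    log-likelihood trace is stored on the returned model and is
    non-decreasing (EM guarantee).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not cohort:
        raise ValueError("empty cohort")
    marks = cohort[0].marks
    grid = cohort[0].grid
    for t in cohort[1:]:
        if t.marks != marks or t.grid != grid:
            raise ValueError("cohort tracks must share grid and mark order")
    M = len(marks)
    seqs = [X for t in cohort for X in _sequences(t)]

    best: tuple[float, HMMModel] | None = None
    for r in range(n_restarts):
        if r == 0:
            pi, A, E = _informed_init(seqs, K, M)
        else:
            rng = np.random.default_rng(seed + r)
            pi = np.full(K, 1 / K)
            A = np.full((K, K), 0.2 / max(K - 1, 1))
            np.fill_diagonal(A, 0.8)
            A = A * (0.8 + 0.4 * rng.random((K, K)))
            A /= A.sum(axis=1, keepdims=True)
            E = rng.uniform(0.1, 0.9, size=(K, M))
        trace: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            loglik, pi, A, E = _em_step(seqs, pi, A, E)
            trace.append(loglik)
            if loglik - prev < tol and np.isfinite(prev):
                break
            prev = loglik
        model = HMMModel(pi, A, E, list(marks), trained_on, trace)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], model)
    assert best is not None
    return best[1]


def n_parameters(K: int, M: int) -> int:
    return (K - 1) + K * (K - 1) + K * M


def select_model(
    cohort: Sequence[BinarizedTrackSet],
    K_grid: Sequence[int] = (4, 6, 8, 10, 12, 14, 16),
    seed: int = 0,
    default_K: int = 8,
    **bw_kwargs,
) -> tuple[list[dict], int, dict[int, HMMModel]]:
    """Train across a grid of state counts and report loglik/BIC per K.

    The chosen K is ``default_K`` whenever it is in the grid (model size is
    picked for emission interpretability, with the table as evidence);
    otherwise the BIC minimiser.
    """
    if not K_grid:
        raise ValueError("K_grid must be non-empty")
    n_obs = sum(t.grid.n_bins for t in cohort)
    table: list[dict] = []
    models: dict[int, HMMModel] = {}
    for K in K_grid:
        m = baum_welch(cohort, K, seed=seed, **bw_kwargs)
        ll = m.log_likelihood_trace[-1]
        bic = -2 * ll + n_parameters(K, m.M) * np.log(n_obs)
        table.append({"K": K, "loglik": ll, "BIC": bic,
                      "emissions": m.E.copy()})
        models[K] = m
    if default_K in K_grid:
        chosen = default_K
    else:
        chosen = int(min(table, key=lambda r: r["BIC"])["K"])
    return table, chosen, models


def segment(
    tracks: BinarizedTrackSet,
    model: HMMModel,
    keep_posteriors: bool = False,
) -> Segmentation:
    """Max-posterior per-bin state assignment (ties -> lowest state index)."""
    if tracks.calls.shape[1] != model.M:
        raise ValueError("track mark count does not match model M")
    _, gamma = forward_backward(tracks, model)
    states = np.argmax(gamma, axis=1)  # argmax takes the first maximum
    return Segmentation(
        tracks.grid,
        states,
        gamma if keep_posteriors else None,
        tracks.sample_id,
        tracks.condition,
    )


def viterbi(tracks: BinarizedTrackSet, model: HMMModel) -> Segmentation:
    """Most-probable joint path (optional alternative to max-posterior)."""
    states = np.empty(tracks.grid.n_bins, dtype=np.int64)
    logA = np.log(model.A)
    pos = 0
    for X in _sequences(tracks):
        logB = _log_emission_matrix(X, model.E)
        T = len(X)
        delta = np.log(model.pi) + logB[0]
        back = np.zeros((T, model.K), dtype=np.int64)
        for t in range(1, T):
            cand = delta[:, None] + logA
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(model.K)] + logB[t]
        path = np.empty(T, dtype=np.int64)
        path[-1] = int(np.argmax(delta))
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        states[pos:pos + T] = path
        pos += T
    return Segmentation(tracks.grid, states, None,
                        tracks.sample_id, tracks.condition)


_FLAT_SD = 0.02  # rows varying by less than ~2 points are effectively flat


def _emission_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two emission rows.

    Correlation is scale-free, so a near-flat row (e.g. a quiescent state
    whose entries differ only by estimation noise) would correlate
    arbitrarily with anything; pairs involving such a row fall back to
    negative mean absolute difference, which ranks them below all genuine
    correlations while keeping the ordering deterministic.
    """
    if a.std() < _FLAT_SD or b.std() < _FLAT_SD:
        return -float(np.abs(a - b).mean())  # in (-1, 0]
    return float(np.corrcoef(a, b)[0, 1])


def match_states(
    model_a: HMMModel, model_b: HMMModel
) -> tuple[dict[int, int], dict[int, float]]:
    """Greedy maximum-similarity bijection from model_a states to model_b
    states using Pearson correlation of emission rows; ties break toward
    lower indices."""
    if model_a.K != model_b.K or model_a.M != model_b.M:
        raise ValueError("models must share K and M")
    K = model_a.K
    sim = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            sim[i, j] = _emission_similarity(model_a.E[i], model_b.E[j])
    mapping: dict[int, int] = {}
    sims: dict[int, float] = {}
    free_a, free_b = set(range(K)), set(range(K))
    while free_a:
        best = None
        for i in sorted(free_a):
            for j in sorted(free_b):
                if best is None or sim[i, j] > best[0] + 1e-15:
                    best = (sim[i, j], i, j)
        _, i, j = best
        mapping[i] = j
        sims[i] = float(sim[i, j])
        free_a.discard(i)
        free_b.discard(j)
    return mapping, sims


def permute_states(model: HMMModel, perm: Sequence[int]) -> HMMModel:
    """Reorder states so that new state i is old state ``perm[i]``."""
    perm = list(perm)
    if sorted(perm) != list(range(model.K)):
        raise ValueError("perm must be a permutation of the states")
    return HMMModel(
        model.pi[perm],
        model.A[np.ix_(perm, perm)],
        model.E[perm],
        list(model.mark_names),
        model.trained_on,
        list(model.log_likelihood_trace),
    )


def align_states(model: HMMModel, reference: HMMModel) -> HMMModel:
    """Permute ``model``'s states to best match ``reference``'s emission
    rows (greedy Pearson matching)."""
    mapping, _ = match_states(reference, model)
    return permute_states(model, [mapping[k] for k in range(model.K)])


def generalization_overlap(
    cohort: Sequence[BinarizedTrackSet],
    model_a: HMMModel,
    model_b: HMMModel,
) -> float:
    """Percent of bins on which the two models agree after state matching.

    Both models segment the same tracks; model_b's assignments are mapped
    through the match_states bijection before comparison.
    """
    mapping, _ = match_states(model_a, model_b)
    inv = np.empty(model_b.K, dtype=np.int64)
    for i, j in mapping.items():
        inv[j] = i
    agree = 0
    total = 0
    for t in cohort:
        sa = segment(t, model_a).states
        sb = inv[segment(t, model_b).states]
        agree += int((sa == sb).sum())
        total += len(sa)
    return 100.0 * agree / total


def _rule_label(e: np.ndarray, marks: list[str], tau: float) -> str | None:
    """Thresholded emission rules for the eight canonical chromatin states."""
    idx = {m: marks.index(m) for m in DEFAULT_MARKS}
    k4 = e[idx["H3K4me3"]] >= tau
    k27ac = e[idx["H3K27ac"]] >= tau
    k36 = e[idx["H3K36me3"]] >= tau
    k27me3 = e[idx["H3K27me3"]] >= tau
    low = e < tau / 2
    if k36 and k27me3:
        return "poised_gene_body"
    if k4 and k27ac:
        return "active_tss"
    if k36 and (k4 or k27ac):
        return "active_transcription"
    if k36:
        return "transcription"
    if k27ac and not k4:
        return "enhancers"
    if k27me3 and low[idx["H3K4me3"]] and low[idx["H3K27ac"]] \
            and low[idx["H3K36me3"]]:
        return "repressed_polycomb"
    if tau / 2 <= e[idx["H3K27me3"]] < tau and low[idx["H3K4me3"]] \
            and low[idx["H3K27ac"]] and low[idx["H3K36me3"]]:
        return "weak_repressed_polycomb"
    if bool(low.all()):
        return "quiescent"
    return None


def label_states(model: HMMModel, tau: float = 0.5) -> StateLabelMap:
    """Assign the eight canonical functional labels to an 8-state model.

    Rule-based on emissions thresholded at ``tau``; when a rule matches
    several states, the state nearest the label's emission prototype keeps
    it and the others are re-assigned to their nearest unused prototype and
    flagged.  Requires K = 8 (supply a custom StateLabelMap otherwise).
    """
    if model.K != 8:
        raise ValueError(
            "rule-based labelling is defined for K=8; supply a StateLabelMap"
        )
    marks = list(model.mark_names)
    proto_order = [marks.index(m) for m in DEFAULT_MARKS]

    def proto(label: str) -> np.ndarray:
        p = np.empty(model.M)
        p[proto_order] = _PROTOTYPES[label][:]  # reorder to model mark order
        return p

    provisional: dict[int, str | None] = {
        k: _rule_label(model.E[k], marks, tau) for k in range(model.K)
    }
    labels: dict[int, str] = {}
    flagged: set[int] = set()
    # resolve collisions: closest state to the prototype keeps the label
    for lab in STATE_LABELS:
        claimants = [k for k, l in provisional.items() if l == lab]
        if not claimants:
            continue
        claimants.sort(key=lambda k: (np.abs(model.E[k] - proto(lab)).sum(), k))
        labels[claimants[0]] = lab
        for k in claimants[1:]:
            flagged.add(k)
    # unresolved states: nearest unused prototype by L1 emission distance
    unused = [l for l in STATE_LABELS if l not in labels.values()]
    leftover = sorted(k for k in range(model.K) if k not in labels)
    for k in leftover:
        if k not in flagged:
            flagged.add(k)
        best = min(unused, key=lambda l: np.abs(model.E[k] - proto(l)).sum())
        labels[k] = best
        unused.remove(best)
    return StateLabelMap(labels, flagged)


def state_genome_fractions(
    segmentations: Sequence[Segmentation],
    K: int,
    label_map: StateLabelMap | None = None,
) -> dict[str, float]:
    """Percent of bins per state, pooled across segmentations (sums to 100)."""
    if not segmentations:
        raise ValueError("no segmentations given")
    grid = segmentations[0].grid
    counts = np.zeros(K)
    for s in segmentations:
        if s.grid != grid:
            raise ValueError("segmentations must share the grid")
        counts += np.bincount(s.states, minlength=K)
    pct = 100.0 * counts / counts.sum()
    if label_map is None:
        return {f"state_{k}": float(pct[k]) for k in range(K)}
    return {label_map.labels[k]: float(pct[k]) for k in range(K)}
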