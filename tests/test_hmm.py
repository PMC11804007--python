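"""HMM inference against exhaustive path enumeration and simulation truth."""

import itertools

import numpy as np
import pytest

from statewitch import (
    BinarizedTrackSet,
    BinGrid,
    HMMModel,
    SimulationConfig,
    baum_welch,
    emission_loglik,
    forward_backward,
    generalization_overlap,
    label_states,
    match_states,
    segment,
    select_model,
    simulate_cohort,
    state_genome_fractions,
    viterbi,
)
from statewitch.hmm import EPS, Segmentation, StateLabelMap


def random_model(K, M, rng):
    A = rng.random((K, K)) + 0.1
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.random(K) + 0.1
    pi /= pi.sum()
    E = rng.uniform(0.05, 0.95, size=(K, M))
    return HMMModel(pi, A, E, [f"m{i}" for i in range(M)])


def tracks_from(X, marks=None):
    T, M = X.shape
    grid = BinGrid({"chr1": T * 200}, 200)
    return BinarizedTrackSet(
        grid, marks or [f"m{i}" for i in range(M)], X.astype(np.uint8)
    )


def enumerate_loglik_and_posteriors(X, model):
    """Independent oracle: sum over all K^T hidden paths directly."""
    T, M = X.shape
    K = model.K
    total = 0.0
    post = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = model.pi[path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]]
        for t in range(T):
            e = model.E[path[t]]
            p *= np.prod(np.where(X[t] == 1, e, 1 - e))
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return np.log(total), post / total


class TestEmissionLoglik:
    def test_half_probabilities_symmetric(self):
        m = HMMModel(
            np.array([1.0]), np.array([[1.0]]),
            np.full((1, 3), 0.5), ["a", "b", "c"],
        )
        for obs in ([0, 0, 0], [1, 0, 1], [1, 1, 1]):
            assert emission_loglik(np.array(obs), 0, m) == pytest.approx(
                -3 * np.log(2)
            )

    def test_saturated_emissions_near_zero(self):
        m = HMMModel(np.array([1.0]), np.array([[1.0]]),
                     np.ones((1, 4)), list("wxyz"))
        ll = emission_loglik(np.ones(4), 0, m)
        assert ll == pytest.approx(4 * np.log(1 - EPS))

    def test_matches_termwise_product(self):
        rng = np.random.default_rng(0)
        m = random_model(3, 4, rng)
        obs = rng.integers(0, 2, size=4)
        k = 2
        expected = sum(
            np.log(m.E[k, j]) if obs[j] else np.log(1 - m.E[k, j])
            for j in range(4)
        )
        assert emission_loglik(obs, k, m) == pytest.approx(expected)

    def test_wrong_length_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            emission_loglik(np.zeros(3), 0, random_model(2, 4, rng))


class TestForwardBackward:
    @pytest.mark.parametrize("T", [2, 4, 6])
    def test_matches_path_enumeration(self, T):
        rng = np.random.default_rng(42)
        model = random_model(3, 2, rng)
        X = rng.integers(0, 2, size=(T, 2))
        ll, gamma = forward_backward(tracks_from(X), model)
        oll, opost = enumerate_loglik_and_posteriors(X, model)
        assert ll == pytest.approx(oll, abs=1e-8)
        assert np.max(np.abs(gamma - opost)) < 1e-8

    def test_single_state_posterior_trivial(self):
        m = HMMModel(np.array([1.0]), np.array([[1.0]]),
                     np.array([[0.3, 0.7]]), ["a", "b"])
        X = np.array([[1, 0], [0, 1], [1, 1]])
        ll, gamma = forward_backward(tracks_from(X), m)
        assert np.allclose(gamma, 1.0)
        expected = sum(emission_loglik(x, 0, m) for x in X)
        assert ll == pytest.approx(expected)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        model = random_model(4, 3, rng)
        X = rng.integers(0, 2, size=(50, 3))
        _, gamma = forward_backward(tracks_from(X), model)
        assert np.allclose(gamma.sum(axis=1), 1, atol=1e-12)

    def test_palindrome_symmetry(self):
        """Symmetric A and uniform pi make the chain reversible: a
        reversed observation sequence has identical likelihood."""
        rng = np.random.default_rng(2)
        K = 3
        # symmetric row-stochastic A + uniform pi => reversible chain
        r = rng.uniform(0.2, 0.8)
        A = r * np.eye(K) + (1 - r) / K * np.ones((K, K))
        m = HMMModel(np.full(K, 1 / K), A,
                     rng.uniform(0.1, 0.9, (K, 2)), ["a", "b"])
        X = rng.integers(0, 2, size=(9, 2))
        ll_f, _ = forward_backward(tracks_from(X), m)
        ll_r, _ = forward_backward(tracks_from(X[::-1].copy()), m)
        assert ll_f == pytest.approx(ll_r, abs=1e-9)

    def test_chromosomes_are_independent_sequences(self):
        rng = np.random.default_rng(3)
        m = random_model(2, 2, rng)
        X = rng.integers(0, 2, size=(8, 2))
        two = BinarizedTrackSet(
            BinGrid({"c1": 800, "c2": 800}, 200), ["a", "b"],
            np.vstack([X[:4], X[4:]]).astype(np.uint8),
        )
        ll_two, _ = forward_backward(two, m)
        ll_a, _ = forward_backward(tracks_from(X[:4]), m)
        ll_b, _ = forward_backward(tracks_from(X[4:]), m)
        assert ll_two == pytest.approx(ll_a + ll_b, abs=1e-9)


class TestBaumWelch:
    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, size=(200, 3))
        m = baum_welch([tracks_from(X)], K=3, seed=0, n_restarts=2,
                       max_iter=30)
        t = np.array(m.log_likelihood_trace)
        assert np.all(np.diff(t) >= -1e-6)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(150, 2))
        m1 = baum_welch([tracks_from(X)], K=2, seed=5, n_restarts=2,
                        max_iter=20)
        m2 = baum_welch([tracks_from(X)], K=2, seed=5, n_restarts=2,
                        max_iter=20)
        assert np.array_equal(m1.E, m2.E) and np.array_equal(m1.A, m2.A)

    def test_guards(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 2, size=(10, 2))
        with pytest.raises(ValueError):
            baum_welch([tracks_from(X)], K=1)
        with pytest.raises(ValueError):
            baum_welch([], K=3)

    def test_small_parameter_recovery(self):
        """Two well-separated states are recovered from their own data."""
        E = np.array([[0.9, 0.9], [0.1, 0.1]])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        cfg = SimulationConfig(
            n_bins=8_000, n_patients=1, n_states=2, n_marks=2,
            mark_names=["a", "b"], transition_matrix=A, emission_matrix=E,
            switch_plan=[], n_genes=5, seed=13,
        )
        co = simulate_cohort(cfg)
        m = baum_welch(list(co.tracks.values()), K=2, seed=0, n_restarts=3,
                       max_iter=100)
        truth = HMMModel(np.array([0.5, 0.5]), A, E, ["a", "b"])
        mapping, _ = match_states(truth, m)
        Eh = m.E[[mapping[0], mapping[1]]]
        assert np.max(np.abs(Eh - E)) < 0.05


class TestSegment:
    def test_well_separated_two_state_accuracy(self):
        E = np.array([[0.95, 0.95], [0.05, 0.05]])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        cfg = SimulationConfig(
            n_bins=5_000, n_patients=1, n_states=2, n_marks=2,
            mark_names=["a", "b"], transition_matrix=A, emission_matrix=E,
            switch_plan=[], n_genes=5, seed=19,
        )
        co = simulate_cohort(cfg)
        m = cfg.true_model()
        seg = segment(co.tracks[(0, "iNSC")], m)
        acc = (seg.states == co.truth.states[(0, "iNSC")]).mean()
        assert acc >= 0.99

    def test_posterior_tie_takes_lowest_index(self):
        K = 3
        m = HMMModel(
            np.full(K, 1 / K), np.full((K, K), 1 / K),
            np.full((K, 2), 0.5), ["a", "b"],
        )
        X = np.array([[0, 1], [1, 0], [1, 1]])
        seg = segment(tracks_from(X), m)
        assert np.all(seg.states == 0)

    def test_viterbi_agrees_on_well_separated_data(self):
        cfg = SimulationConfig(n_bins=2_000, n_patients=1, seed=23,
                               switch_plan=[], n_genes=5)
        co = simulate_cohort(cfg)
        m = cfg.true_model()
        t = co.tracks[(0, "GIC")]
        assert (segment(t, m).states == viterbi(t, m).states).mean() > 0.98

    def test_segmentation_bed_round_trip(self, tmp_path):
        from statewitch import read_intervals, write_bed

        cfg = SimulationConfig(n_bins=500, n_patients=1, seed=3,
                               switch_plan=[], n_genes=5)
        co = simulate_cohort(cfg)
        seg = segment(co.tracks[(0, "iNSC")], cfg.true_model())
        ivs = seg.to_intervals()
        p = tmp_path / "seg.bed"
        write_bed(ivs, p)
        back = read_intervals(p)
        assert [(i.chrom, i.start, i.end, i.name) for i in back] == [
            (i.chrom, i.start, i.end, i.name) for i in ivs
        ]
        # intervals tile the genome
        assert sum(i.length for i in ivs) == sum(
            co.grid.chrom_sizes.values()
        )


class TestMatchStates:
    def test_identity_on_self(self):
        rng = np.random.default_rng(31)
        m = random_model(5, 4, rng)
        mapping, sims = match_states(m, m)
        assert mapping == {k: k for k in range(5)}
        assert all(s > 0.999 for s in sims.values())

    def test_recovers_constructed_permutation(self):
        rng = np.random.default_rng(32)
        m = random_model(6, 4, rng)
        perm = np.array([3, 0, 5, 1, 4, 2])
        m2 = HMMModel(m.pi[perm], m.A[perm][:, perm], m.E[perm],
                      m.mark_names)
        mapping, _ = match_states(m, m2)
        # state k of m sits at position perm^-1(k) in m2
        inv = {int(p): i for i, p in enumerate(perm)}
        assert mapping == inv

    def test_random_models_give_bijection(self):
        rng = np.random.default_rng(33)
        a, b = random_model(4, 3, rng), random_model(4, 3, rng)
        mapping, _ = match_states(a, b)
        assert sorted(mapping.keys()) == [0, 1, 2, 3]
        assert sorted(mapping.values()) == [0, 1, 2, 3]

    def test_unequal_K_rejected(self):
        rng = np.random.default_rng(34)
        with pytest.raises(ValueError):
            match_states(random_model(3, 2, rng), random_model(4, 2, rng))


class TestGeneralization:
    def test_self_overlap_is_exactly_100(self, small_cohort):
        cfg = small_cohort.config
        m = cfg.true_model()
        tracks = small_cohort.condition_tracks("iNSC")[:2]
        assert generalization_overlap(tracks, m, m) == 100.0

    def test_mild_perturbation_keeps_high_overlap(self, small_cohort):
        cfg = small_cohort.config
        m = cfg.true_model()
        E2 = np.clip(np.asarray(cfg.emission_matrix) + 0.03, 0.01, 0.99)
        m2 = HMMModel(m.pi, m.A, E2, m.mark_names)
        tracks = small_cohort.condition_tracks("iNSC")[:2]
        assert generalization_overlap(tracks, m, m2) >= 90.0


class TestLabelStates:
    def test_canonical_rows(self):
        rows = {
            (0.9, 0.9, 0.1, 0.05): "active_tss",
            (0.02, 0.02, 0.02, 0.02): "quiescent",
            (0.05, 0.9, 0.05, 0.02): "enhancers",
            (0.02, 0.02, 0.9, 0.02): "transcription",
            (0.05, 0.6, 0.9, 0.02): "active_transcription",
            (0.02, 0.02, 0.7, 0.8): "poised_gene_body",
            (0.02, 0.02, 0.02, 0.9): "repressed_polycomb",
            (0.02, 0.02, 0.02, 0.35): "weak_repressed_polycomb",
        }
        E = np.array(list(rows.keys()))
        m = HMMModel(np.full(8, 1 / 8), np.full((8, 8), 1 / 8), E)
        lm = label_states(m)
        for k, expected in enumerate(rows.values()):
            assert lm.labels[k] == expected
        assert not lm.flagged

    def test_default_template_labels_bijective(self):
        cfg = SimulationConfig()
        m = cfg.true_model()
        lm = label_states(m)
        assert sorted(lm.labels.values()) == sorted(
            [
                "active_tss", "enhancers", "active_transcription",
                "transcription", "poised_gene_body", "repressed_polycomb",
                "weak_repressed_polycomb", "quiescent",
            ]
        )
        assert not lm.flagged
        assert lm.activity(lm.index_of("enhancers")) == "active"
        assert lm.activity(lm.index_of("poised_gene_body")) == "inactive"

    def test_colliding_rules_flag_surplus_state(self):
        E = np.array(
            [
                [0.9, 0.9, 0.05, 0.02],
                [0.85, 0.95, 0.05, 0.02],  # second TSS-like row
                [0.05, 0.9, 0.05, 0.02],
                [0.02, 0.02, 0.9, 0.02],
                [0.02, 0.6, 0.9, 0.02],
                [0.02, 0.02, 0.7, 0.8],
                [0.02, 0.02, 0.02, 0.9],
                [0.02, 0.02, 0.02, 0.02],
            ]
        )
        m = HMMModel(np.full(8, 1 / 8), np.full((8, 8), 1 / 8), E)
        lm = label_states(m)
        assert len(set(lm.labels.values())) == 8
        assert lm.flagged  # surplus TSS-like state was reassigned

    def test_non_eight_state_model_needs_user_map(self):
        rng = np.random.default_rng(35)
        with pytest.raises(ValueError):
            label_states(random_model(4, 4, rng))

    def test_duplicate_labels_rejected_in_map(self):
        with pytest.raises(ValueError):
            StateLabelMap({0: "quiescent", 1: "quiescent"})


class TestGenomeFractions:
    def test_constant_segmentation(self, grid):
        seg = Segmentation(grid, np.zeros(grid.n_bins, dtype=int))
        f = state_genome_fractions([seg], K=3)
        assert f["state_0"] == 100.0

    def test_fractions_sum_to_100(self, small_cohort):
        m = small_cohort.config.true_model()
        segs = [
            segment(t, m)
            for t in small_cohort.condition_tracks("iNSC")[:2]
        ]
        f = state_genome_fractions(segs, K=8)
        assert sum(f.values()) == pytest.approx(100.0, abs=1e-6)

    def test_pooling_is_weighted_average(self, grid):
        s1 = Segmentation(grid, np.zeros(grid.n_bins, dtype=int))
        s2 = Segmentation(grid, np.ones(grid.n_bins, dtype=int))
        f = state_genome_fractions([s1, s2], K=2)
        assert f["state_0"] == pytest.approx(50.0)


class TestSelectModel:
    def test_singleton_grid_chooses_that_K(self):
        rng = np.random.default_rng(41)
        X = rng.integers(0, 2, size=(300, 3))
        table, chosen, _ = select_model(
            [tracks_from(X)], K_grid=[3], n_restarts=1, max_iter=10,
        )
        assert chosen == 3 and len(table) == 1

    def test_default_K_preferred_when_in_grid(self):
        rng = np.random.default_rng(42)
        X = rng.integers(0, 2, size=(300, 4))
        table, chosen, _ = select_model(
            [tracks_from(X)], K_grid=[4, 8], n_restarts=1, max_iter=10,
        )
        assert chosen == 8 and [r["K"] for r in table] == [4, 8]

    def test_bic_minimised_near_true_K(self):
        E = np.array([[0.95, 0.05, 0.05], [0.05, 0.95, 0.05],
                      [0.05, 0.05, 0.95], [0.9, 0.9, 0.9]])
        A = np.full((4, 4), 0.05)
        np.fill_diagonal(A, 0.85)
        cfg = SimulationConfig(
            n_bins=8_000, n_patients=1, n_states=4, n_marks=3,
            mark_names=list("abc"), transition_matrix=A, emission_matrix=E,
            switch_plan=[], n_genes=5, seed=43,
        )
        co = simulate_cohort(cfg)
        table, _, _ = select_model(
            list(co.tracks.values()), K_grid=[2, 3, 4, 5, 6],
            default_K=0, n_restarts=2, max_iter=60,
        )
        best = min(table, key=lambda r: r["BIC"])["K"]
        assert best in (3, 4, 5)
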