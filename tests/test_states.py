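"""Compendium, posture groups, coarsening, HMM training/selection, decoding,
and the dwelling-model comparison."""

import itertools

import numpy as np
import pytest

from wormstates.states import (
    PostureCompendium,
    PostureHMM,
    TransitionMatrix,
    assign_postures,
    block_ratio,
    build_compendium,
    build_transition_matrix,
    cluster_posture_groups,
    coarsen_intervals,
    compare_models,
    empirical_duration_dists,
    model_error,
    pairwise_recurrence_metric,
    select_model_bic,
    simulate_dwelling_models,
    similarity_transition_matrix,
    train_hmm,
    ventral_align,
    viterbi_decode,
)
from wormstates.synthetic import (
    default_generator_model,
    generate_posture_dataset,
    generate_state_sequence,
)


class TestVentralAlign:
    def test_right_side_traveler_unchanged(self):
        from tests.test_record import make_record

        rec = make_record(ventral="right")
        out = ventral_align([rec])[0]
        np.testing.assert_array_equal(out.posture, rec.posture)

    def test_left_side_negated_and_involution(self):
        from tests.test_record import make_record

        rec = make_record(ventral="left")
        once = ventral_align([rec])[0]
        np.testing.assert_array_equal(once.posture, -rec.posture)
        twice = ventral_align([once])[0]
        np.testing.assert_array_equal(twice.posture, rec.posture)

    def test_unknown_side_excluded_with_warning(self):
        from tests.test_record import make_record

        with pytest.warns(UserWarning, match="unknown ventral"):
            out = ventral_align([make_record(ventral="unknown")])
        assert out == []


class TestCompendium:
    def test_exact_prototypes_fully_explained(self):
        X, labels, protos = generate_posture_dataset(10, 100, noise_sd=0.0, seed=0)
        comp = build_compendium(X, max_K=20, seed=0)
        assert comp.size <= 10
        # ten distinct repeated prototypes: ten clusters explain everything
        assert comp.selection_curve[9] == pytest.approx(1.0, abs=1e-9)
        assert comp.variance_explained >= 0.75

    def test_fixture_selects_near_100_prototypes(self):
        X, _, _ = generate_posture_dataset(100, 1000, seed=7)
        comp = build_compendium(X, max_K=200, seed=0)
        assert 95 <= comp.size <= 105
        assert comp.variance_explained >= 0.75

    def test_selection_curve_non_decreasing(self):
        X, _, _ = generate_posture_dataset(20, 100, seed=1)
        comp = build_compendium(X, max_K=50, seed=0)
        assert (np.diff(comp.selection_curve) >= -1e-12).all()

    def test_prototypes_mean_centered(self):
        from wormstates import _splines

        X, _, _ = generate_posture_dataset(20, 100, seed=1)
        comp = build_compendium(X, max_K=50, seed=0)
        B = _splines.design_matrix(14, 1000)
        np.testing.assert_allclose(
            (comp.prototypes @ B.T).mean(axis=1), 0.0, atol=1e-9
        )

    def test_too_few_postures_rejected(self):
        with pytest.raises(ValueError, match="max_K"):
            build_compendium(np.zeros((10, 14)), max_K=20)


class TestAssignPostures:
    def test_prototype_maps_to_itself(self):
        _, _, protos = generate_posture_dataset(20, 5, seed=0)
        comp = PostureCompendium(protos, 1.0, np.ones(1))
        ids = assign_postures(protos, comp)
        np.testing.assert_array_equal(ids, np.arange(20))

    def test_equidistant_tie_takes_lowest_index(self):
        protos = np.zeros((2, 14))
        protos[0, 0], protos[1, 0] = 1.0, -1.0
        comp = PostureCompendium(protos, 1.0, np.ones(1))
        assert assign_postures(np.zeros((1, 14)), comp)[0] == 0

    def test_fixture_accuracy(self):
        X, labels, protos = generate_posture_dataset(100, 50, noise_sd=0.05, seed=3)
        comp = PostureCompendium(protos, 1.0, np.ones(1))
        assert (assign_postures(X, comp) == labels).mean() > 0.99

    def test_invalid_frames_missing(self):
        _, _, protos = generate_posture_dataset(5, 2, seed=0)
        comp = PostureCompendium(protos, 1.0, np.ones(1))
        ids = assign_postures(protos, comp, valid=np.array([True] * 4 + [False]))
        assert ids[-1] == -1


class TestTransitionMatrix:
    def test_run_collapses_to_single_transition(self):
        T = build_transition_matrix(np.array([1, 1, 1, 2]), n_postures=3)
        assert T.probs[1, 2] == 1.0
        assert T.counts.sum() == 1

    def test_alternating_sequence(self):
        T = build_transition_matrix(np.array([1, 2] * 10), n_postures=3)
        assert T.probs[1, 2] == 1.0 and T.probs[2, 1] == 1.0

    def test_fixture_matrix_within_3se(self):
        rng = np.random.default_rng(0)
        P = np.array([[0.0, 0.7, 0.3], [0.2, 0.0, 0.8], [0.5, 0.5, 0.0]])
        seq = [0]
        for _ in range(20000):
            seq.append(rng.choice(3, p=P[seq[-1]]))
        T = build_transition_matrix(np.asarray(seq), n_postures=3)
        for i in range(3):
            n = T.counts[i].sum()
            se = np.sqrt(P[i] * (1 - P[i]) / n)
            assert (np.abs(T.probs[i] - P[i]) <= 3 * se + 1e-9).all()

    def test_unvisited_rows_flagged(self):
        T = build_transition_matrix(np.array([0, 1, 0, 1]), n_postures=3)
        assert not T.defined_rows[2]
        assert T.probs[2].sum() == 0


def block_matrix(n_groups=3, per_group=6, p_intra=0.12, p_inter=0.01):
    K = n_groups * per_group
    labels = np.repeat(np.arange(n_groups), per_group)
    T = np.where(labels[:, None] == labels[None, :], p_intra, p_inter)
    np.fill_diagonal(T, 0.0)
    T = T / T.sum(axis=1, keepdims=True)
    return T, labels


class TestPostureGroups:
    def test_exact_block_matrix_recovers_k_and_ratio(self):
        T, labels = block_matrix(n_groups=3)
        tm = TransitionMatrix(T, T, np.ones(T.shape[0], bool))
        groups, k = cluster_posture_groups(tm, n_restarts=20, seed=0)
        assert k == 3
        # recovered partition matches the construction
        for g in range(3):
            sel = labels == g
            assert np.unique(groups.assignment[sel]).size == 1
        # closed form: ratio of the normalized intra to inter probabilities
        expected = block_ratio(T, labels)
        assert groups.intra_inter_ratio == pytest.approx(expected, rel=1e-6)

    def test_generator_fixture_selects_eight_groups(self, hour_record, model):
        rec, truth = hour_record
        T = build_transition_matrix(truth.postures, n_postures=100)
        groups, k = cluster_posture_groups(T, n_restarts=50, seed=0)
        assert k == 8

    def test_criterion_invariant_to_permutation(self):
        rng = np.random.default_rng(5)
        T, labels = block_matrix(n_groups=4, per_group=5)
        perm = rng.permutation(T.shape[0])
        assert block_ratio(T, labels) == pytest.approx(
            block_ratio(T[np.ix_(perm, perm)], labels[perm])
        )


class TestCoarsening:
    def test_composition_arithmetic(self):
        ids = np.concatenate([np.full(40, 2), np.full(20, 4)])
        ids = np.tile(ids, 30)  # 30 bins of 60 frames
        seq, k = coarsen_intervals(ids, frame_rate=20.0, k_range=range(2, 3), seed=0)
        np.testing.assert_allclose(seq.fractions[0, 2], 2 / 3, atol=1e-9)
        np.testing.assert_allclose(seq.fractions[0, 4], 1 / 3, atol=1e-9)

    def test_mostly_missing_bin_gets_missing_symbol(self):
        ids = np.full(60 * 10, 3)
        ids[:40] = -1  # first bin >50% missing
        seq, _ = coarsen_intervals(ids, frame_rate=20.0, k_range=range(2, 4), seed=0)
        assert seq.symbols[0] == -1
        assert (seq.symbols[1:] >= 0).all()

    def test_group_pure_bins_select_eight_clusters(self, hour_record, model):
        rec, truth = hour_record
        gid = model.group_of_posture[truth.postures]
        seq, k = coarsen_intervals(gid, rec.frame_rate, seed=0)
        assert k == 8
        # mapping is identity up to relabeling: symbols equal dominant group
        fpb = 60
        nb = seq.n_bins
        dom = np.array([
            np.bincount(gid[b * fpb : (b + 1) * fpb], minlength=8).argmax()
            for b in range(nb)
        ])
        assert (seq.symbols == dom).mean() > 0.95


class TestTrainHMM:
    def test_one_state_model_matches_symbol_frequencies(self):
        rng = np.random.default_rng(0)
        symbols = rng.choice(4, p=[0.5, 0.3, 0.15, 0.05], size=5000)
        m = train_hmm([symbols], n_states=1, n_restarts=2, seed=0, n_symbols=4)
        freq = np.bincount(symbols, minlength=4) / symbols.size
        se = np.sqrt(freq * (1 - freq) / symbols.size)
        assert (np.abs(m.emission[0] - freq) < 3 * se + 1e-9).all()

    def test_two_state_disjoint_emissions_recovered(self):
        rng = np.random.default_rng(1)
        trans = np.array([[0.95, 0.05], [0.1, 0.9]])
        emit = np.array([[0.9, 0.1, 0.0, 0.0], [0.0, 0.0, 0.4, 0.6]])
        states = [0]
        for _ in range(8000):
            states.append(rng.choice(2, p=trans[states[-1]]))
        states = np.asarray(states)
        symbols = np.array([rng.choice(4, p=emit[s]) for s in states])
        m = train_hmm([symbols], n_states=2, n_restarts=3, seed=0, n_symbols=4)
        # match states by emission similarity
        order = [0, 1] if m.emission[0, 0] > m.emission[1, 0] else [1, 0]
        assert np.abs(m.emission[order] - emit).max() < 0.05
        assert np.abs(m.transition[np.ix_(order, order)] - trans).max() < 0.05

    def test_same_seed_same_model(self):
        rng = np.random.default_rng(2)
        symbols = rng.integers(0, 8, 2000)
        a = train_hmm([symbols], 3, n_restarts=2, seed=9)
        b = train_hmm([symbols], 3, n_restarts=2, seed=9)
        np.testing.assert_array_equal(a.transition, b.transition)
        np.testing.assert_array_equal(a.emission, b.emission)

    def test_matches_hmmlearn_from_shared_init(self):
        """Independent oracle: identical EM trajectory as hmmlearn."""
        import warnings

        from hmmlearn.hmm import CategoricalHMM

        from wormstates import _hmm_core

        rng = np.random.default_rng(3)
        obs = rng.integers(0, 4, 500)
        t0 = rng.dirichlet(np.ones(3), 3)
        e0 = rng.dirichlet(np.ones(4), 3)
        tr, em, logl, _ = _hmm_core.baum_welch(
            obs, [500], 3, 4, t0.copy(), e0.copy(), tol=0, max_iter=10
        )
        ref = CategoricalHMM(
            n_components=3, n_features=4, init_params="", params="te",
            tol=-1, n_iter=10,
        )
        ref.startprob_ = np.full(3, 1 / 3)
        ref.transmat_ = t0.copy()
        ref.emissionprob_ = e0.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref.fit(obs[:, None], [500])
            ref_logl = ref.score(obs[:, None], [500])
        assert logl == pytest.approx(ref_logl, abs=1e-8)
        np.testing.assert_allclose(tr, ref.transmat_, atol=1e-10)
        np.testing.assert_allclose(em, ref.emissionprob_, atol=1e-10)

    def test_missing_symbols_split_sequences(self):
        symbols = np.array([0, 1, 0, 1, -1, -1, 2, 3, 2, 3])
        m = train_hmm([symbols], 2, n_restarts=1, seed=0, n_symbols=4)
        assert m.n_obs == 8  # missing bins contribute no observations


class TestModelSelection:
    def test_equal_likelihood_prefers_smallest_model(self):
        symbols = np.zeros(500, dtype=int)  # single symbol: size-independent fit
        best, curve, _ = select_model_bic(
            [symbols], state_range=range(1, 4), n_restarts=1, seed=0, n_symbols=2
        )
        assert best == 1
        assert curve[1] < curve[2] < curve[3]

    def test_three_state_generator_recovered(self):
        protos = np.zeros((6, 14))
        m3 = default_generator_model()
        trans = np.array(
            [[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]]
        )
        emit = np.array(
            [[0.8, 0.1, 0.1, 0.0], [0.1, 0.8, 0.0, 0.1], [0.0, 0.1, 0.1, 0.8]]
        )
        from wormstates.synthetic import GeneratorModel

        gen = GeneratorModel(
            transition=trans, emission=emit,
            prototypes=protos, group_of_posture=np.arange(6) % 4,
        )
        seqs = [generate_state_sequence(gen, 4000, seed=i)[1] for i in range(2)]
        best, _, _ = select_model_bic(
            seqs, state_range=range(2, 6), n_restarts=3, seed=1, n_symbols=4
        )
        assert best == 3


class TestCompareModels:
    def _model(self, emission):
        n = emission.shape[0]
        return PostureHMM(np.full((n, n), 1 / n), emission, 0.0, 0.0, 1)

    def test_self_distance_zero(self):
        rng = np.random.default_rng(0)
        e = rng.dirichlet(np.ones(8), 4)
        d = compare_models([self._model(e), self._model(e)])
        assert d[0, 1] == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        e = rng.dirichlet(np.ones(8), 4)
        perm = rng.permutation(4)
        d = compare_models([self._model(e), self._model(e[perm])])
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_fits_converge_to_same_model(self):
        gen = default_generator_model()
        seqs = [generate_state_sequence(gen, 7200, seed=50 + i)[1] for i in range(2)]
        m1 = train_hmm(seqs, 9, n_restarts=1, seed=0)
        m2 = train_hmm(seqs, 9, n_restarts=1, seed=123)
        d = compare_models([m1, m2])
        assert d[0, 1] < 0.1

    def test_unequal_sizes_error(self):
        a = self._model(np.full((2, 8), 1 / 8))
        b = self._model(np.full((3, 8), 1 / 8))
        with pytest.raises(ValueError, match="same number"):
            compare_models([a, b])


class TestViterbi:
    def test_deterministic_chain_decoded_exactly(self):
        trans = np.array([[0.99, 0.01], [0.01, 0.99]])
        emit = np.array([[1.0, 0.0], [0.0, 1.0]])
        m = PostureHMM(trans, emit, 0.0, 0.0, 1)
        symbols = np.array([0, 0, 1, 1, 1, 0])
        path = viterbi_decode(m, symbols)
        np.testing.assert_array_equal(path.states, symbols)

    def test_matches_exhaustive_enumeration(self):
        """Brute-force oracle over all state paths on 10-bin instances."""
        rng = np.random.default_rng(4)
        for trial in range(5):
            n_states, n_symbols, T = 3, 4, 10
            trans = rng.dirichlet(np.ones(n_states), n_states)
            emit = rng.dirichlet(np.ones(n_symbols), n_states)
            m = PostureHMM(trans, emit, 0.0, 0.0, 1)
            symbols = rng.integers(0, n_symbols, T)
            decoded = viterbi_decode(m, symbols).states

            # enumeration with the same floor-smoothed emissions
            e = emit + 1e-8
            e = e / e.sum(axis=1, keepdims=True)
            lt = np.log(trans + 1e-8)
            le = np.log(e)
            best, best_lp = None, -np.inf
            for path in itertools.product(range(n_states), repeat=T):
                lp = -np.log(n_states) + le[path[0], symbols[0]]
                for t in range(1, T):
                    lp += lt[path[t - 1], path[t]] + le[path[t], symbols[t]]
                if lp > best_lp:
                    best, best_lp = path, lp
            np.testing.assert_array_equal(decoded, np.asarray(best))

    def test_roaming_label_goes_to_fastest_state(self):
        trans = np.array([[0.9, 0.1], [0.1, 0.9]])
        emit = np.array([[0.9, 0.1], [0.1, 0.9]])
        m = PostureHMM(trans, emit, 0.0, 0.0, 1)
        symbols = np.array([0] * 10 + [1] * 10)
        velocity = np.array([0.01] * 10 + [0.3] * 10)
        path = viterbi_decode(m, symbols, velocity_per_bin=velocity)
        assert path.labels[path.states[15]] == "roam"
        assert path.labels[path.states[0]].startswith("dwell")

    def test_missing_symbols_left_undecoded(self):
        m = PostureHMM(np.eye(2) * 0.9 + 0.05, np.eye(2), 0.0, 0.0, 1)
        symbols = np.array([0, -1, 1])
        path = viterbi_decode(m, symbols)
        assert path.states[1] == -1


class TestDwellingModels:
    def test_deterministic_cycle_reproduced(self):
        K = 4
        P = np.roll(np.eye(K), 1, axis=1)  # 0->1->2->3->0
        dists = [np.array([0.05])] * K  # one frame per posture at 20 Hz
        ids = simulate_dwelling_models(
            "empirical-transition", 40, 20.0, P, dists, seed=0
        )
        start = ids[0]
        expected = (start + np.arange(40)) % K
        np.testing.assert_array_equal(ids, expected)

    def test_marginal_durations_match_empirical(self):
        rng = np.random.default_rng(0)
        K = 5
        P = np.ones((K, K)) - np.eye(K)
        P /= P.sum(axis=1, keepdims=True)
        dists = [rng.choice([0.05, 0.1, 0.2, 0.5], size=200,
                            p=[0.4, 0.3, 0.2, 0.1]) for _ in range(K)]
        ids = simulate_dwelling_models(
            "empirical-transition", 200_000, 20.0, P, dists, seed=1
        )
        sampled = np.concatenate(empirical_duration_dists(ids, 20.0, K))
        from scipy.stats import ks_2samp

        stat, _ = ks_2samp(sampled, np.concatenate(dists))
        assert stat < 0.05

    def test_similarity_kernel_prefers_near_prototypes(self):
        protos = np.zeros((3, 14))
        protos[1, 0] = 0.1  # near prototype 0
        protos[2, 0] = 5.0  # far
        P = similarity_transition_matrix(protos)
        assert P[0, 1] > P[0, 2]
        np.testing.assert_allclose(P.sum(axis=1), 1.0)
        assert np.diag(P).max() == 0.0

    def test_hmm_model_beats_similarity_model_on_group_structured_data(
        self, hour_record, model
    ):
        rec, truth = hour_record
        fr = rec.frame_rate
        # dwelling frames only, sub-modes lumped
        state = np.repeat(truth.state_path, 60)[: rec.n_frames]
        dwell = state != model.roaming_state
        real_ids = truth.postures[dwell]
        K = model.prototypes.shape[0]
        T_emp = build_transition_matrix(real_ids, n_postures=K).probs
        dists = empirical_duration_dists(real_ids, fr, K)
        real_mat = pairwise_recurrence_metric(real_ids, fr, n_postures=K)

        hmm = PostureHMM(model.transition, model.emission, 0.0, 0.0, 1)
        n = real_ids.size
        ids_hmm = simulate_dwelling_models(
            "posture-hmm", n, fr, T_emp, dists, seed=2,
            hmm=hmm, group_of_posture=model.group_of_posture,
            roaming_state=model.roaming_state,
        )
        ids_sim = simulate_dwelling_models(
            "similarity-transition", n, fr, T_emp, dists, seed=3,
            prototypes=model.prototypes,
        )
        err_hmm = model_error(
            pairwise_recurrence_metric(ids_hmm, fr, n_postures=K), real_mat
        )
        err_sim = model_error(
            pairwise_recurrence_metric(ids_sim, fr, n_postures=K), real_mat
        )
        assert err_hmm < err_sim


class TestRecurrenceMetric:
    def test_hand_computed_first_passage(self):
        mat = pairwise_recurrence_metric(np.array([1, 2, 1, 3]), 1.0, n_postures=4)
        assert mat[1, 2] == pytest.approx(1.0)
        assert mat[1, 3] == pytest.approx(2.0)  # mean of (3-0, 3-2)
        assert mat[1, 1] == pytest.approx(2.0)  # recurrence of posture 1

    def test_never_followed_pair_missing(self):
        mat = pairwise_recurrence_metric(np.array([3, 1]), 1.0, n_postures=4)
        assert np.isnan(mat[1, 3])

    def test_unobserved_posture_missing_row_and_column(self):
        mat = pairwise_recurrence_metric(np.array([0, 1, 0]), 1.0, n_postures=3)
        assert np.isnan(mat[2]).all() and np.isnan(mat[:, 2]).all()


class TestModelError:
    def test_identical_matrices_zero(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert model_error(m, m) == 0.0

    def test_three_unit_differences_sum_to_three(self):
        a = np.zeros((2, 2))
        b = a.copy()
        b[0, 0] = b[0, 1] = b[1, 0] = 1.0
        assert model_error(a, b) == 3.0

    def test_nan_entries_excluded_pairwise(self):
        a = np.array([[1.0, np.nan], [2.0, 2.0]])
        b = np.array([[2.0, 5.0], [np.nan, 2.0]])
        assert model_error(a, b) == 1.0

    def test_no_overlap_errors(self):
        a = np.full((2, 2), np.nan)
        with pytest.raises(ValueError, match="overlap"):
            model_error(a, a)
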