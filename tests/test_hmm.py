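"""Discrete HMM core against exhaustive-enumeration oracles and hmmlearn."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecghmm.hmm import (AnnotatedSequence, ExpertTrainConfig, HmmModel,
                        baum_welch_iterate, expert_assisted_train,
                        forward_loglik, left_right_mask,
                        reject_discrepant_annotation, sample_model,
                        supervised_estimate, viterbi)


def random_model(k, v, rng, mask=None):
    m = np.ones((k, k), dtype=bool) if mask is None else mask
    a = rng.uniform(0.1, 1.0, (k, k)) * m
    a /= a.sum(axis=1, keepdims=True)
    b = rng.uniform(0.1, 1.0, (k, v))
    b /= b.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.1, 1.0, k)
    pi /= pi.sum()
    return HmmModel([f"s{i}" for i in range(k)], [f"o{i}" for i in range(v)],
                    a, b, pi, m)


def brute_force_paths(model, obs):
    """Enumerate all K^T paths; return (total probability, best prob, best path)."""
    total, best_p, best_path = 0.0, -1.0, None
    for path in itertools.product(range(model.n_states), repeat=len(obs)):
        p = model.pi[path[0]] * model.B[path[0], obs[0]]
        for s0, s1, o in zip(path, path[1:], obs[1:]):
            p *= model.A[s0, s1] * model.B[s1, o]
        total += p
        if p > best_p:
            best_p, best_path = p, path
    return total, best_p, best_path


class TestForward:
    def test_single_state_model_is_emission_product(self, rng):
        model = HmmModel(["s"], ["a", "b"], [[1.0]], [[0.3, 0.7]], [1.0])
        obs = rng.integers(0, 2, 20)
        expected = np.log(model.B[0, obs]).sum()
        assert forward_loglik(model, obs) == pytest.approx(expected)

    def test_matches_exhaustive_path_sum(self, rng):
        for _ in range(60):
            k = int(rng.integers(1, 4))
            t = int(rng.integers(1, 8))
            model = random_model(k, int(rng.integers(2, 4)), rng)
            obs = rng.integers(0, model.n_symbols, t)
            total, _, _ = brute_force_paths(model, obs)
            assert forward_loglik(model, obs) == pytest.approx(np.log(total), abs=1e-9)

    def test_impossible_symbol_gives_minus_inf(self):
        model = HmmModel(["x", "y"], ["a", "b"], [[0.5, 0.5], [0.5, 0.5]],
                         [[1.0, 0.0], [1.0, 0.0]], [0.5, 0.5])
        assert forward_loglik(model, [0, 1, 0]) == -np.inf

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            forward_loglik(random_model(2, 2, rng), [])

    def test_agrees_with_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        for _ in range(5):
            model = random_model(3, 4, rng)
            obs = rng.integers(0, 4, 60)
            ref = hmmlearn.CategoricalHMM(n_components=3)
            ref.startprob_, ref.transmat_, ref.emissionprob_ = model.pi, model.A, model.B
            assert forward_loglik(model, obs) == pytest.approx(
                ref.score(obs.reshape(-1, 1)), abs=1e-8)
            assert np.array_equal(viterbi(model, obs)[0], ref.predict(obs.reshape(-1, 1)))


class TestViterbi:
    def test_permutation_emissions_decode_symbols(self, rng):
        b = np.eye(3)[[2, 0, 1]]  # state i emits symbol perm(i) only
        model = HmmModel(list("xyz"), list("abc"),
                         np.full((3, 3), 1 / 3), b, np.full(3, 1 / 3))
        obs = rng.integers(0, 3, 30)
        path, _ = viterbi(model, obs)
        sym_to_state = {2: 0, 0: 1, 1: 2}
        assert [sym_to_state[o] for o in obs] == list(path)

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(100):
            model = random_model(2, int(rng.integers(2, 4)), rng)
            obs = rng.integers(0, model.n_symbols, int(rng.integers(1, 7)))
            _, best_p, best_path = brute_force_paths(model, obs)
            path, logp = viterbi(model, obs)
            assert np.exp(logp) == pytest.approx(best_p, rel=1e-9)
            # the returned path must attain the maximum probability (paths
            # may differ from the enumeration order only on numerical ties)
            p_ours = model.pi[path[0]] * model.B[path[0], obs[0]]
            for s0, s1, o in zip(path, path[1:], obs[1:]):
                p_ours *= model.A[s0, s1] * model.B[s1, o]
            assert p_ours == pytest.approx(best_p, rel=1e-9)

    def test_uniform_model_tie_breaks_to_lowest_state(self):
        model = HmmModel(list("xyz"), list("ab"), np.full((3, 3), 1 / 3),
                         np.full((3, 2), 0.5), np.full(3, 1 / 3))
        path, _ = viterbi(model, [0, 1, 0, 1])
        assert np.all(path == 0)

    def test_impossible_path_names_first_dead_position(self):
        model = HmmModel(["x", "y"], ["a", "b"], [[1.0, 0.0], [0.0, 1.0]],
                         [[1.0, 0.0], [1.0, 0.0]], [1.0, 0.0],
                         structure_mask=np.array([[True, False], [False, True]]))
        with pytest.raises(ValueError, match="position 2"):
            viterbi(model, [0, 0, 1])


class TestSupervised:
    def test_transition_count_ratio(self):
        ann = AnnotatedSequence([0, 0, 1], [0, 0, 1])
        with pytest.warns(UserWarning):  # state S2 has no outgoing transition
            model = supervised_estimate([ann], ["S1", "S2"], ["a", "b"], pseudocount=0.0)
        assert model.A[0, 0] == pytest.approx(0.5)
        assert model.A[0, 1] == pytest.approx(0.5)

    def test_initial_distribution_from_first_labels(self):
        ann = AnnotatedSequence([0, 1, 0], [0, 1, 0])
        model = supervised_estimate([ann], ["S1", "S2"], ["a", "b"], pseudocount=0.0)
        assert model.pi[0] == pytest.approx(1.0)

    def test_unobserved_state_warns_uniform(self):
        ann = AnnotatedSequence([0, 0], [0, 0])
        with pytest.warns(UserWarning, match="never"):
            model = supervised_estimate([ann], ["S1", "S2"], ["a"], pseudocount=0.0)
        assert model.A[1] == pytest.approx([0.5, 0.5])

    def test_maximizes_complete_data_likelihood(self, rng):
        # oracle: perturbing the MLE in any direction lowers the labeled
        # joint likelihood
        true = random_model(3, 3, rng)
        states, obs = sample_model(true, 400, rng)
        ann = AnnotatedSequence(obs, states)
        mle = supervised_estimate([ann], true.states, true.alphabet, pseudocount=0.0)

        def complete_ll(m):
            ll = np.log(m.pi[states[0]]) + np.log(m.B[states[0], obs[0]])
            ll += np.log(m.A[states[:-1], states[1:]]).sum()
            ll += np.log(m.B[states[1:], obs[1:]]).sum()
            return ll

        base = complete_ll(mle)
        for _ in range(20):
            a = mle.A + rng.normal(0, 0.02, mle.A.shape)
            a = np.clip(a, 1e-6, None)
            a /= a.sum(axis=1, keepdims=True)
            pert = HmmModel(mle.states, mle.alphabet, a, mle.B, mle.pi)
            assert complete_ll(pert) <= base + 1e-12

    def test_mask_zeros_stay_zero(self):
        mask = left_right_mask(3, cyclic=False)
        ann = AnnotatedSequence([0, 1, 0, 1], [0, 0, 1, 2])
        model = supervised_estimate([ann], ["a", "b", "c"], ["x", "y"],
                                    structure_mask=mask)
        assert np.all(model.A[~mask] == 0.0)


class TestBaumWelch:
    def test_stationary_point_unchanged(self):
        model = HmmModel(["s"], ["a", "b"], [[1.0]], [[0.25, 0.75]], [1.0])
        obs = np.array([1, 1, 0, 1])
        fit, _ = baum_welch_iterate(model, obs, 3)
        assert fit.B[0] == pytest.approx([0.25, 0.75])

    def test_loglik_trace_monotone(self, rng):
        for _ in range(5):
            model = random_model(3, 3, rng)
            obs = rng.integers(0, 3, 200)
            _, trace = baum_welch_iterate(model, obs, 15)
            assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_two_state_parameter_recovery(self):
        # oracle: generation-parameter recovery from a favorable seeded start
        true = HmmModel(["a", "b"], ["x", "y", "z"],
                        [[0.9, 0.1], [0.2, 0.8]],
                        [[0.7, 0.2, 0.1], [0.05, 0.15, 0.8]], [0.5, 0.5])
        _, obs = sample_model(true, 2000, np.random.default_rng(1))
        start = random_model(2, 3, np.random.default_rng(0))
        fit, trace = baum_welch_iterate(start, obs, 50)
        err = min(np.abs(fit.A[np.ix_(p, p)] - true.A).max()
                  for p in ((0, 1), (1, 0)))
        assert err < 0.05
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_mask_zeros_absorbing(self, rng):
        mask = left_right_mask(4)
        model = random_model(4, 3, rng, mask)
        _, obs = sample_model(model, 300, rng)
        fit, _ = baum_welch_iterate(model, obs, 10)
        assert np.all(fit.A[~mask] == 0.0)

    def test_rows_remain_stochastic(self, rng):
        model = random_model(3, 4, rng)
        obs = rng.integers(0, 4, 150)
        fit, _ = baum_welch_iterate(model, obs, 5)
        fit.validate()


class TestRejectRule:
    def test_identical_models_kept(self, rng):
        m = random_model(3, 3, rng)
        assert reject_discrepant_annotation(m, m) is False

    def test_disjoint_emissions_rejected(self):
        a = np.full((2, 2), 0.5)
        m1 = HmmModel(["x", "y"], ["a", "b"], a, [[1.0, 0.0], [0.0, 1.0]], [0.5, 0.5])
        m2 = HmmModel(["x", "y"], ["a", "b"], a, [[0.0, 1.0], [1.0, 0.0]], [0.5, 0.5])
        assert reject_discrepant_annotation(m1, m2, threshold=0.49) is True

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            reject_discrepant_annotation(random_model(2, 2, rng),
                                         random_model(3, 2, rng))

    def test_rejection_monotone_in_perturbation(self, rng):
        ref = random_model(4, 4, rng)
        rolled = HmmModel(ref.states, ref.alphabet, ref.A,
                          np.roll(ref.B, 1, axis=0), ref.pi)
        decisions = []
        for eps in (0.0, 0.25, 0.5, 0.75, 1.0):
            b = (1 - eps) * ref.B + eps * rolled.B
            cand = HmmModel(ref.states, ref.alphabet, ref.A, b, ref.pi)
            decisions.append(reject_discrepant_annotation(cand, ref, threshold=0.15))
        assert decisions == sorted(decisions)  # False..False True..True


def _expert_fixture():
    rng = np.random.default_rng(4)
    mask = left_right_mask(4)
    a = np.zeros((4, 4))
    for i in range(4):
        a[i, i], a[i, (i + 1) % 4] = 0.6, 0.4
    b = np.array([[0.9, 0.04, 0.03, 0.03],
                  [0.04, 0.9, 0.03, 0.03],
                  [0.03, 0.04, 0.9, 0.03],
                  [0.03, 0.03, 0.04, 0.9]])
    true = HmmModel(list("wxyz"), list("abcd"), a, b, [1, 0, 0, 0], mask)
    states, obs = sample_model(true, 1500, rng)
    return true, states, obs, mask


class TestExpertAssistedTraining:
    def test_single_expert_equals_supervised_plus_one_iteration(self):
        true, states, obs, mask = _expert_fixture()
        ann = AnnotatedSequence(obs[:150], states[:150], "e1")
        result = expert_assisted_train([ann], obs, true.states, true.alphabet, mask)
        ref = supervised_estimate([ann], true.states, true.alphabet,
                                  structure_mask=mask)
        ref, _ = baum_welch_iterate(ref, obs, 1)
        assert np.allclose(result.model.A, ref.A)
        assert np.allclose(result.model.B, ref.B)

    def test_identical_annotations_blend_to_single_expert_result(self):
        true, states, obs, mask = _expert_fixture()
        ann = AnnotatedSequence(obs[:150], states[:150], "e1")
        twin = AnnotatedSequence(obs[:150], states[:150], "e2")
        single = expert_assisted_train([ann], obs, true.states, true.alphabet, mask)
        double = expert_assisted_train([ann, twin], obs, true.states,
                                       true.alphabet, mask)
        assert np.allclose(double.model.A, single.model.A, atol=1e-12)
        assert np.allclose(double.model.B, single.model.B, atol=1e-12)

    def test_permuted_annotation_rejected(self):
        # oracle: the scrambled labels produce a candidate whose mean TV
        # distance from the running model exceeds the gate
        true, states, obs, mask = _expert_fixture()
        ann1 = AnnotatedSequence(obs[:150], states[:150], "e1")
        ann2 = AnnotatedSequence(obs[150:300], states[150:300], "e2")
        scrambled = AnnotatedSequence(
            obs[300:450],
            np.random.default_rng(8).permutation(states[300:450]), "e3")
        three = expert_assisted_train([ann1, ann2, scrambled], obs,
                                      true.states, true.alphabet, mask)
        two = expert_assisted_train([ann1, ann2], obs, true.states,
                                    true.alphabet, mask)
        assert three.rejected == ["e3"]
        assert np.allclose(three.model.A, two.model.A)
        assert np.allclose(three.model.B, two.model.B)

    def test_annotation_longer_than_stream_rejected(self):
        true, states, obs, mask = _expert_fixture()
        ann = AnnotatedSequence(obs, states, "e1")
        with pytest.raises(ValueError, match="longer"):
            expert_assisted_train([ann], obs[:100], true.states, true.alphabet, mask)

    def test_no_annotations_rejected(self):
        true, _, obs, mask = _expert_fixture()
        with pytest.raises(ValueError, match="at least one"):
            expert_assisted_train([], obs, true.states, true.alphabet, mask)


@given(st.integers(0, 2**31 - 1))
def test_forward_viterbi_bounds_property(seed):
    """log P(best path) <= log P(O): the Viterbi path is one summand."""
    rng = np.random.default_rng(seed)
    model = random_model(int(rng.integers(1, 4)), int(rng.integers(2, 4)), rng)
    obs = rng.integers(0, model.n_symbols, int(rng.integers(1, 12)))
    _, logp = viterbi(model, obs)
    assert logp <= forward_loglik(model, obs) + 1e-9
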