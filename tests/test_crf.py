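"""Linear-chain CRF: scoring, partition function, gradients, Viterbi."""

import itertools

import numpy as np
import pytest

from cnerkit import crf
from cnerkit.tagging import TagSchema, decode_tags


def _augmented(L):
    return L + 2


def _enumerate_scores(P, W):
    n, L = P.shape
    seqs = list(itertools.product(range(L), repeat=n))
    return seqs, np.array([crf.sequence_score(P, W, y) for y in seqs])


def _best_by_tie_rule(seqs, scores):
    """Exhaustive argmax; ties prefer the lowest label at the latest
    differing position (reverse-lexicographic minimum)."""
    m = scores.max()
    tied = [y for y, s in zip(seqs, scores) if np.isclose(s, m, atol=1e-12)]
    return min(tied, key=lambda y: tuple(reversed(y)))


class TestSequenceScore:
    def test_single_position(self):
        P = np.array([[2.0, 5.0]])
        W = np.zeros((4, 4))
        assert crf.sequence_score(P, W, [1]) == 5.0

    def test_all_zero_scores(self):
        P = np.zeros((4, 3))
        W = np.zeros((5, 5))
        for y in itertools.product(range(3), repeat=4):
            assert crf.sequence_score(P, W, list(y)) == 0.0

    def test_term_by_term_hand_sum(self, rng):
        n, L = 3, 3
        P = rng.normal(size=(n, L))
        W = rng.normal(size=(_augmented(L),) * 2)
        y = [2, 0, 1]
        S, E = crf.start_index(L), crf.stop_index(L)
        expected = (
            P[0, 2] + P[1, 0] + P[2, 1]
            + W[S, 2] + W[2, 0] + W[0, 1] + W[1, E]
        )
        assert crf.sequence_score(P, W, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            crf.sequence_score(np.zeros((3, 2)), np.zeros((4, 4)), [0, 1])


class TestLogPartition:
    def test_uniform_single_position(self):
        P = np.zeros((1, 2))
        W = np.zeros((4, 4))
        assert crf.log_partition(P, W) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            n, L = 3, 3
            P = rng.normal(size=(n, L))
            W = rng.normal(size=(_augmented(L),) * 2)
            _, scores = _enumerate_scores(P, W)
            m = scores.max()
            expected = m + np.log(np.exp(scores - m).sum())
            assert crf.log_partition(P, W) == pytest.approx(expected, abs=1e-8)

    def test_emission_shift_identity(self, rng):
        """Adding c to every emission raises log Z by n * c."""
        n, L, c = 4, 3, 0.7
        P = rng.normal(size=(n, L))
        W = rng.normal(size=(_augmented(L),) * 2)
        assert crf.log_partition(P + c, W) == pytest.approx(
            crf.log_partition(P, W) + n * c, abs=1e-9
        )


class TestNegLogLikelihood:
    def test_certainty_limit(self):
        n, L = 3, 4
        P = np.full((n, L), -1e4)
        y = [1, 2, 0]
        for i, lab in enumerate(y):
            P[i, lab] = 0.0
        W = np.zeros((_augmented(L),) * 2)
        assert crf.neg_log_likelihood(P, W, y) == pytest.approx(0.0, abs=1e-8)

    def test_uniform_scores(self):
        P = np.zeros((2, 3))
        W = np.zeros((5, 5))
        assert crf.neg_log_likelihood(P, W, [0, 0]) == pytest.approx(
            np.log(9.0), abs=1e-12
        )

    def test_probabilities_normalize_by_enumeration(self, rng):
        n, L = 3, 3
        P = rng.normal(size=(n, L))
        W = rng.normal(size=(_augmented(L),) * 2)
        seqs, _ = _enumerate_scores(P, W)
        total = sum(np.exp(-crf.neg_log_likelihood(P, W, y)) for y in seqs)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_nonnegative_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 5))
            L = int(rng.integers(2, 5))
            P = rng.normal(size=(n, L))
            W = rng.normal(size=(_augmented(L),) * 2)
            y = rng.integers(0, L, size=n)
            assert crf.neg_log_likelihood(P, W, y) >= -1e-12


class TestGradients:
    def test_analytic_matches_central_differences(self, rng):
        for _ in range(5):
            n, L = 4, 3
            P = rng.normal(size=(n, L))
            W = rng.normal(size=(_augmented(L),) * 2)
            y = rng.integers(0, L, size=n)
            dP, dW = crf.nll_gradients(P, W, y)
            eps = 1e-6
            for idx in np.ndindex(P.shape):
                Pp, Pm = P.copy(), P.copy()
                Pp[idx] += eps
                Pm[idx] -= eps
                num = (
                    crf.neg_log_likelihood(Pp, W, y)
                    - crf.neg_log_likelihood(Pm, W, y)
                ) / (2 * eps)
                assert abs(dP[idx] - num) < 1e-4
            for idx in np.ndindex(W.shape):
                Wp, Wm = W.copy(), W.copy()
                Wp[idx] += eps
                Wm[idx] -= eps
                num = (
                    crf.neg_log_likelihood(P, Wp, y)
                    - crf.neg_log_likelihood(P, Wm, y)
                ) / (2 * eps)
                assert abs(dW[idx] - num) < 1e-4

    def test_marginals_sum_to_one(self, rng):
        P = rng.normal(size=(5, 4))
        W = rng.normal(size=(6, 6))
        unary, pairwise, _, _, _ = crf.crf_marginals(P, W)
        np.testing.assert_allclose(unary.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(pairwise.sum(axis=(1, 2)), 1.0, atol=1e-10)


class TestViterbi:
    def test_zero_transitions_factorize(self, rng):
        n, L = 6, 4
        P = rng.normal(size=(n, L))
        W = np.zeros((_augmented(L),) * 2)
        path, score = crf.viterbi_decode(P, W)
        assert path == list(P.argmax(axis=1))
        assert score == pytest.approx(P.max(axis=1).sum(), abs=1e-12)

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(10):
            n, L = 4, 4
            P = rng.normal(size=(n, L))
            W = rng.normal(size=(_augmented(L),) * 2)
            seqs, scores = _enumerate_scores(P, W)
            path, score = crf.viterbi_decode(P, W)
            assert score == pytest.approx(scores.max(), abs=1e-10)
            assert tuple(path) == _best_by_tie_rule(seqs, scores)

    def test_all_zero_scores_tie_to_label_zero(self):
        P = np.zeros((5, 3))
        W = np.zeros((5, 5))
        path, score = crf.viterbi_decode(P, W)
        assert path == [0] * 5 and score == 0.0

    def test_returned_score_is_sequence_score(self, rng):
        P = rng.normal(size=(5, 3))
        W = rng.normal(size=(5, 5))
        path, score = crf.viterbi_decode(P, W)
        assert score == pytest.approx(crf.sequence_score(P, W, path), abs=1e-10)

    def test_viterbi_score_below_log_partition(self, rng):
        for _ in range(10):
            P = rng.normal(size=(4, 3))
            W = rng.normal(size=(5, 5))
            _, score = crf.viterbi_decode(P, W)
            assert score < crf.log_partition(P, W) + 1e-12


class TestConstrainedDecoding:
    def test_constrained_viterbi_is_always_strictly_decodable(self, rng):
        schema = TagSchema()
        pen = crf.constraint_penalties(schema)
        L = schema.n_tags
        for _ in range(50):
            n = int(rng.integers(1, 12))
            P = rng.normal(scale=5.0, size=(n, L))
            W = rng.normal(size=(L + 2, L + 2))
            path, _ = crf.viterbi_decode(P, W + pen)
            decode_tags(schema.decode(path), schema, policy="strict")  # no raise

    def test_unconstrained_can_produce_illegal_runs(self):
        schema = TagSchema()
        L = schema.n_tags
        P = np.zeros((2, L))
        P[1, schema.tag_to_id("I-DIS")] = 5.0  # bare I-DIS is attractive
        W = np.zeros((L + 2, L + 2))
        path, _ = crf.viterbi_decode(P, W)
        tags = schema.decode(path)
        with pytest.raises(Exception):
            decode_tags(tags, schema, policy="strict")


class TestBatchedCrf:
    def test_batched_nll_averages_per_sentence(self, rng):
        layer = crf.LinearChainCrf(3, rng)
        W = layer.params["W"]
        P = rng.normal(size=(2, 5, 3))
        y = rng.integers(0, 3, size=(2, 5))
        mask = np.array([[1, 1, 1, 1, 1], [1, 1, 1, 0, 0]], dtype=float)
        expected = (
            crf.neg_log_likelihood(P[0], W, y[0])
            + crf.neg_log_likelihood(P[1, :3], W, y[1, :3])
        ) / 2
        assert layer.nll(P, y, mask) == pytest.approx(expected, abs=1e-10)

    def test_batched_gradient_matches_single(self, rng):
        layer = crf.LinearChainCrf(3, rng)
        W = layer.params["W"]
        P = rng.normal(size=(1, 4, 3))
        y = rng.integers(0, 3, size=(1, 4))
        mask = np.ones((1, 4))
        layer.nll(P, y, mask)
        dP = layer.backward()
        dP1, dW1 = crf.nll_gradients(P[0], W, y[0])
        np.testing.assert_allclose(dP[0], dP1, atol=1e-12)
        np.testing.assert_allclose(layer.grads["W"], dW1, atol=1e-12)
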