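"""The assembled tagger: determinism, shapes, gradients, training contracts."""

import numpy as np
import pytest

from cnerkit.model import NerTagger, _pad_batch
from cnerkit.synthetic import GeneratorSpec, generate_corpus
from cnerkit.tagging import DEFAULT_SCHEMA
from cnerkit.embeddings import Vocabulary


@pytest.fixture(scope="module")
def tiny_sentences():
    return generate_corpus(GeneratorSpec(seed=21), 6)


def _fresh_network(sentences, **kw):
    defaults = dict(d_model=8, filters=8, heads=2, dropout=0.0, seed=4)
    defaults.update(kw)
    est = NerTagger(**defaults)
    vocab = Vocabulary.from_corpus(sentences)
    net = est.build_network(len(vocab), DEFAULT_SCHEMA)
    ids = [vocab.encode(s.chars) for s in sentences]
    tags = [np.array(DEFAULT_SCHEMA.encode(s.tags)) for s in sentences]
    return net, ids, tags


class TestBuild:
    def test_same_seed_identical_parameters(self, tiny_sentences):
        net1, _, _ = _fresh_network(tiny_sentences)
        net2, _, _ = _fresh_network(tiny_sentences)
        for (n1, p1), (n2, p2) in zip(net1.parameters(), net2.parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1, p2)

    def test_emission_shape_contract(self, tiny_sentences):
        net, ids, tags = _fresh_network(tiny_sentences)
        cids, _, mask = _pad_batch(ids[:3], tags[:3])
        P = net.emissions(cids, mask)
        assert P.shape == (3, cids.shape[1], DEFAULT_SCHEMA.n_tags)

    def test_eval_forward_is_deterministic_despite_dropout(self, tiny_sentences):
        net, ids, tags = _fresh_network(tiny_sentences, dropout=0.5)
        cids, _, mask = _pad_batch(ids[:2], tags[:2])
        P1 = net.emissions(cids, mask, train=False)
        P2 = net.emissions(cids, mask, train=False)
        np.testing.assert_array_equal(P1, P2)

    def test_incompatible_dims_rejected(self):
        est = NerTagger(d_model=8, filters=8, heads=3)
        with pytest.raises(ValueError, match="divisible"):
            est.build_network(10, DEFAULT_SCHEMA)
        est = NerTagger(dropout=1.0)
        with pytest.raises(ValueError, match="dropout"):
            est.build_network(10, DEFAULT_SCHEMA)

    def test_sklearn_params_round_trip(self):
        est = NerTagger(heads=8, learning_rate=0.01)
        params = est.get_params()
        assert params["heads"] == 8
        clone = NerTagger(**params)
        assert clone.get_params() == params


class TestGradients:
    def test_end_to_end_gradient_check_two_sentence_batch(self, tiny_sentences):
        """Analytic gradient of the batch loss vs central differences."""
        net, ids, tags = _fresh_network(tiny_sentences)
        cids, tg, mask = _pad_batch(ids[:2], tags[:2])
        net.loss(cids, tg, mask)
        net.backward()
        analytic = net.get_flat_grads()
        flat = net.get_flat_params()
        rng = np.random.default_rng(0)
        idx = rng.choice(flat.size, size=250, replace=False)
        eps = 1e-6  # below the distance to the nearest ReLU breakpoint
        for i in idx:
            fp = flat.copy()
            fp[i] += eps
            net.set_flat_params(fp)
            lp = net.loss(cids, tg, mask)
            fp[i] -= 2 * eps
            net.set_flat_params(fp)
            lm = net.loss(cids, tg, mask)
            assert abs((lp - lm) / (2 * eps) - analytic[i]) < 1e-3
        net.set_flat_params(flat)

    def test_gradient_flows_without_mha(self, tiny_sentences):
        net, ids, tags = _fresh_network(tiny_sentences, use_mha=False)
        cids, tg, mask = _pad_batch(ids[:2], tags[:2])
        net.loss(cids, tg, mask)
        net.backward()
        assert np.abs(net.get_flat_grads()).max() > 0


class TestTraining:
    def test_memorization_drives_nll_down_and_f1_to_100(self):
        """Ten memorizable sentences: the NLL collapses and the model
        reproduces every gold mention on its own training set."""
        sents = generate_corpus(GeneratorSpec(seed=5), 10)
        est = NerTagger(
            d_model=32, filters=16, heads=4, dropout=0.0, epochs=800,
            batch_size=10, learning_rate=3e-3, seed=0,
        )
        est.fit(sents)
        assert est.report_.losses[-1] < 0.1
        assert est.score(sents) == 100.0

    def test_lr_zero_leaves_parameters_unchanged(self, tiny_sentences):
        est = NerTagger(
            d_model=8, filters=8, heads=2, dropout=0.0, epochs=1,
            learning_rate=0.0, seed=1,
        )
        est.fit(tiny_sentences)
        before = est.network_.get_flat_params()
        est2 = NerTagger(**est.get_params())
        est2.fit(tiny_sentences)
        np.testing.assert_array_equal(before, est2.network_.get_flat_params())
        # and equals a freshly initialized, untrained network
        fresh = est.build_network(len(est.vocab_), est.schema_)
        np.testing.assert_array_equal(before, fresh.get_flat_params())

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            NerTagger().fit([])

    def test_overlong_sentence_directs_to_split(self, tiny_sentences):
        est = NerTagger(max_len=10)
        with pytest.raises(ValueError, match="split_document"):
            est.fit(tiny_sentences)

    def test_training_is_reproducible(self):
        sents = generate_corpus(GeneratorSpec(seed=2), 12)
        runs = []
        for _ in range(2):
            est = NerTagger(
                d_model=8, filters=8, heads=2, epochs=2, seed=7, dropout=0.3
            )
            est.fit(sents)
            runs.append(est.network_.get_flat_params())
        np.testing.assert_array_equal(runs[0], runs[1])


class TestPredict:
    def test_empty_input_gives_empty_output(self, tiny_sentences):
        est = NerTagger(d_model=8, filters=8, heads=2, epochs=1, seed=0)
        est.fit(tiny_sentences)
        assert est.predict([]) == []

    def test_untrained_zeroed_head_predicts_all_o(self, tiny_sentences):
        est = NerTagger(d_model=8, filters=8, heads=2, epochs=1,
                        learning_rate=0.0, seed=0, constrained_decode=False)
        est.fit(tiny_sentences)
        est.network_.emission.params["W"][:] = 0.0
        est.network_.emission.params["b"][:] = 0.0
        est.network_.crf.params["W"][:] = 0.0
        for tags in est.predict([s.chars for s in tiny_sentences[:3]]):
            assert set(tags) == {"O"}

    def test_prediction_invariant_to_batch_size(self, tiny_sentences):
        est = NerTagger(d_model=8, filters=8, heads=2, epochs=2, seed=0)
        est.fit(tiny_sentences)
        X = [s.chars for s in tiny_sentences]
        est.batch_size = 1
        one = est.predict(X)
        est.batch_size = 20
        twenty = est.predict(X)
        assert one == twenty

    def test_predictions_are_well_formed_spans(self, tiny_sentences):
        est = NerTagger(d_model=8, filters=8, heads=2, epochs=2, seed=0)
        est.fit(tiny_sentences)
        for mentions, sent in zip(
            est.predict_mentions([s.chars for s in tiny_sentences]), tiny_sentences
        ):
            for m in mentions:
                assert 0 <= m.start < m.end <= len(sent.chars)

    def test_overlong_prediction_input_rejected(self, tiny_sentences):
        est = NerTagger(d_model=8, filters=8, heads=2, epochs=1, seed=0)
        est.fit(tiny_sentences)
        with pytest.raises(ValueError, match="split_document"):
            est.predict(["x" * 300])


class TestAblationScaffold:
    def test_mha_switch_changes_only_the_encoder(self, tiny_sentences):
        with_mha = NerTagger(d_model=8, filters=8, heads=2, epochs=1, seed=0)
        without = NerTagger(
            d_model=8, filters=8, heads=2, epochs=1, seed=0, use_mha=False
        )
        with_mha.fit(tiny_sentences)
        without.fit(tiny_sentences)
        X = [s.chars for s in tiny_sentences]
        assert len(with_mha.predict(X)) == len(without.predict(X))
        names_with = {n.split(".")[0] for n, _ in with_mha.network_.parameters()}
        names_without = {n.split(".")[0] for n, _ in without.network_.parameters()}
        assert any("MultiHead" in n for n in names_with)
        assert not any("MultiHead" in n for n in names_without)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, tiny_sentences):
        est = NerTagger(d_model=8, filters=8, heads=2, epochs=2, seed=0)
        est.fit(tiny_sentences)
        est.save(tmp_path / "ckpt")
        loaded = NerTagger.load(tmp_path / "ckpt")
        X = [s.chars for s in tiny_sentences]
        assert est.predict(X) == loaded.predict(X)
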