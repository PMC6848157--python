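import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import promlm as P
from promlm.embedding import EmbeddingModel, load_model, save_model, whole_word_token
from promlm.tokenizer import NGramLevel, Sentence


def brute_force_ngrams(word, minn, maxn):
    """Independent oracle: exhaustive substrings of the wrapped word."""
    wrapped = "<" + word + ">"
    out = {wrapped}
    for size in range(minn, maxn + 1):
        for i in range(len(wrapped) - size + 1):
            out.add(wrapped[i:i + size])
    return out


class TestCharNgrams:
    def test_worked_example(self):
        assert P.char_ngrams("ATGAC", 3, 3) == {
            "<AT", "ATG", "TGA", "GAC", "AC>", "<ATGAC>"}

    def test_word_shorter_than_minn(self):
        assert P.char_ngrams("A", 3, 3) == {"<A>"}

    def test_whole_word_differs_from_interior_gram(self):
        grams = P.char_ngrams("ATGAC", 3, 3)
        assert "TGA" in grams and "<TGA>" not in grams
        assert whole_word_token("TGA") == "<TGA>"

    def test_minn_exceeding_maxn_rejected(self):
        with pytest.raises(ValueError):
            P.char_ngrams("ACGT", 4, 3)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(word=st.text(alphabet="ACGT", min_size=1, max_size=10),
           minn=st.integers(1, 6), maxn=st.integers(1, 6))
    def test_matches_bruteforce_enumeration(self, word, minn, maxn):
        if minn > maxn:
            return
        assert P.char_ngrams(word, minn, maxn) == brute_force_ngrams(word, minn, maxn)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(word=st.text(alphabet="ACGT", min_size=1, max_size=10))
    def test_exactly_one_whole_word_token(self, word):
        grams = P.char_ngrams(word, 3, 6)
        assert sum(g == whole_word_token(word) for g in grams) == 1


def toy_model(dim=2, minn=2, maxn=3):
    """Hand-set model over words {TG, GA} with basis-vector grams."""
    cfg = P.EmbeddingConfig(dim=dim, minn=minn, maxn=maxn, epoch=1)
    grams = sorted(P.char_ngrams("TG", minn, maxn) | P.char_ngrams("GA", minn, maxn))
    gram_ids = {g: i for i, g in enumerate(grams)}
    Z = np.zeros((len(grams), dim))
    context_ids = {"0": 0, "1": 1}
    V = np.zeros((2, dim))
    return EmbeddingModel(NGramLevel(2), cfg, gram_ids, Z, context_ids, V)


class TestScore:
    def test_zero_vectors_score_zero(self):
        m = toy_model()
        assert P.score("TG", "1", m) == 0.0

    def test_identity_dot_product(self):
        m = toy_model()
        m.Z[:] = 0.0
        g = sorted(P.char_ngrams("TG", 2, 3))[0]
        m.Z[m.gram_ids[g], 0] = 1.0
        m.V[m.context_ids["1"], 0] = 1.0
        assert P.score("TG", "1", m) == 1.0

    def test_matches_loop_oracle(self, rng):
        m = toy_model(dim=4)
        m.Z[:] = rng.normal(size=m.Z.shape)
        m.V[:] = rng.normal(size=m.V.shape)
        expected = 0.0
        for g in P.char_ngrams("GA", 2, 3):
            if g in m.gram_ids:
                for d in range(4):
                    expected += m.Z[m.gram_ids[g], d] * m.V[m.context_ids["0"], d]
        assert np.isclose(P.score("GA", "0", m), expected)

    def test_unknown_word_scores_zero(self):
        m = toy_model()
        m.Z[:] = 1.0
        m.V[:] = 1.0
        assert P.score("CCCCCCCC", "1", m) == 0.0


class TestSequenceVector:
    def test_single_word_constant_grams(self):
        m = toy_model(dim=3)
        v = np.array([1.0, -2.0, 0.5])
        for g in P.char_ngrams("TG", 2, 3):
            m.Z[m.gram_ids[g]] = v
        s = Sentence(("TG",), "x", NGramLevel(2))
        assert np.allclose(P.sequence_vector(s, m), v)

    def test_two_words_average(self, rng):
        m = toy_model(dim=3)
        m.Z[:] = rng.normal(size=m.Z.shape)
        u = m.word_vector("TG")
        w = m.word_vector("GA")
        s = Sentence(("TG", "GA"), "x", NGramLevel(2))
        assert np.allclose(P.sequence_vector(s, m), (u + w) / 2)

    def test_matches_double_loop_oracle(self):
        rec = P.SequenceRecord("x", "ACGTACGTACGTACGTACGT")
        sent = P.tokenize(rec, 3)
        m = P.train_embedding([sent], None,
                              P.EmbeddingConfig(dim=5, epoch=1, seed=0,
                                                objective="skipgram", loss="ns"))
        got = P.sequence_vector(sent, m)
        reps = []
        for w in sent.words:
            idx = [m.gram_ids[g] for g in P.char_ngrams(w, 3, 6) if g in m.gram_ids]
            reps.append(np.mean([m.Z[i] for i in idx], axis=0))
        assert np.allclose(got, np.mean(reps, axis=0))

    def test_order_invariance(self, rng):
        m = toy_model(dim=3)
        m.Z[:] = rng.normal(size=m.Z.shape)
        a = P.sequence_vector(Sentence(("TG", "GA", "TG"), "x", NGramLevel(2)), m)
        b = P.sequence_vector(Sentence(("GA", "TG", "TG"), "x", NGramLevel(2)), m)
        assert np.allclose(a, b)

    def test_unknown_sentence_warns_and_zeroes(self):
        m = toy_model(dim=3)
        s = Sentence(("CCCCCCCCCC",), "x", NGramLevel(2))
        with pytest.warns(UserWarning, match="no model-known"):
            v = P.sequence_vector(s, m)
        assert np.array_equal(v, np.zeros(3))


class TestTrainEmbedding:
    def corpus(self, n=20, level=3, rate=0.0, seed=2):
        l1, _ = P.generate(P.SyntheticSpec(n_pos=n, n_neg=n,
                                           per_position_mutation_rate=rate,
                                           strength_mutation_gap=0.0, seed=seed))
        return [P.tokenize(r, level) for r in l1.records], l1.labels()

    def test_vocabulary_covers_corpus(self):
        sents = [P.tokenize(P.SequenceRecord("a", "ATGAC"), 3),
                 P.tokenize(P.SequenceRecord("b", "TTTTT"), 3)]
        m = P.train_embedding(sents, np.array([0, 1]),
                              P.EmbeddingConfig(dim=4, epoch=1, seed=0))
        corpus_grams = set()
        for s in sents:
            for w in s.words:
                corpus_grams |= P.char_ngrams(w, 3, 6)
        assert corpus_grams <= set(m.gram_ids)

    def test_supervised_deterministic(self):
        sents, y = self.corpus(n=10)
        cfg = P.EmbeddingConfig(dim=8, epoch=3, seed=42)
        m1 = P.train_embedding(sents, y, cfg)
        m2 = P.train_embedding(sents, y, cfg)
        assert np.array_equal(m1.Z, m2.Z) and np.array_equal(m1.V, m2.V)

    @pytest.mark.parametrize("objective,loss", [("skipgram", "ns"),
                                                ("skipgram", "softmax"),
                                                ("cbow", "ns")])
    def test_unsupervised_deterministic_and_covering(self, objective, loss):
        sents, _ = self.corpus(n=4)
        cfg = P.EmbeddingConfig(dim=6, epoch=1, seed=7, objective=objective,
                                loss=loss, ws=3)
        m1 = P.train_embedding(sents, None, cfg)
        m2 = P.train_embedding(sents, None, cfg)
        assert np.array_equal(m1.Z, m2.Z)
        assert set(m1.context_ids) == {w for s in sents for w in s.words}

    def test_loss_converges_with_small_jitter(self):
        sents, y = self.corpus(n=30)
        m = P.train_embedding(sents, y, P.EmbeddingConfig(dim=16, epoch=40, seed=5))
        h = np.array(m.loss_history)
        assert h[-1] < 0.1 * h[0]           # converged
        assert np.all(np.diff(h) <= 0.02)   # only small transient jitter

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            P.train_embedding([], None, P.EmbeddingConfig())

    def test_supervised_requires_two_classes(self):
        sents, y = self.corpus(n=4)
        with pytest.raises(ValueError, match="both classes"):
            P.train_embedding(sents, np.zeros(len(sents)), P.EmbeddingConfig())

    def test_hs_loss_unsupported(self):
        sents, y = self.corpus(n=4)
        with pytest.raises(ValueError, match="hs"):
            P.train_embedding(sents, y, P.EmbeddingConfig(loss="hs"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            P.EmbeddingConfig(minn=4, maxn=3)
        with pytest.raises(ValueError):
            P.EmbeddingConfig(lr=0.0)
        with pytest.raises(ValueError):
            P.EmbeddingConfig(loss="bogus")


def test_model_persistence_roundtrip(tmp_path):
    l1, _ = P.generate(P.SyntheticSpec(n_pos=5, n_neg=5, seed=1))
    sents = [P.tokenize(r, 3) for r in l1.records]
    m = P.train_embedding(sents, l1.labels(), P.EmbeddingConfig(dim=6, epoch=2, seed=3))
    path = tmp_path / "model.txt"
    save_model(m, path)
    m2 = load_model(path)
    assert m2.gram_ids == m.gram_ids
    assert np.array_equal(m2.Z, m.Z) and np.array_equal(m2.V, m.V)
    s = sents[0]
    assert np.allclose(P.sequence_vector(s, m), P.sequence_vector(s, m2))
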