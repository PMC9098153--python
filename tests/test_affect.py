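"""Text sentiment (NB + boosting), prosody emotion scoring, word error rate."""

import itertools
import math

import numpy as np
import pytest

import smht
from smht.affect import BoostRound, NBModel, _doc_term_matrix
from smht.containers import LabeledCorpus, ValidationError


class TestPreprocess:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("I feel FINE.", ["i", "feel", "fine"]),
            ("", []),
            ("so-so, so so", ["so", "so", "so", "so"]),
            ("don't worry!", ["don't", "worry"]),
        ],
    )
    def test_tokenization_rules(self, raw, expected):
        assert smht.preprocess_text(raw) == expected


def _brute_force_posterior(corpus, tokens, smoothing=1.0):
    """Exhaustive Bayes-rule enumeration over a tiny vocabulary."""
    classes = sorted(set(corpus.labels), key=smht.SENTIMENT_CLASSES.index)
    vocab = corpus.vocabulary
    post = {}
    for c in classes:
        docs = [d for d, l in zip(corpus.documents, corpus.labels) if l == c]
        prior = len(docs) / len(corpus.documents)
        counts = {t: sum(d.count(t) for d in docs) for t in vocab}
        total = sum(counts.values())
        p = prior
        for tok in tokens:
            if tok in vocab:
                p *= (counts[tok] + smoothing) / (total + smoothing * len(vocab))
        post[c] = p
    z = sum(post.values())
    return {c: p / z for c, p in post.items()}


class TestNaiveBayes:
    def test_single_class_posterior_is_one(self):
        corpus = LabeledCorpus([["good", "day"], ["calm", "sea"]], ["positive"] * 2)
        model = smht.train_naive_bayes(corpus)
        post = smht.nb_posterior(model, ["good", "sea"])
        assert post["positive"] == pytest.approx(1.0)

    def test_symmetric_corpus_balanced_document(self):
        corpus = LabeledCorpus(
            [["up", "up"], ["down", "down"]], ["positive", "negative"]
        )
        model = smht.train_naive_bayes(corpus)
        post = smht.nb_posterior(model, ["up", "down"])
        assert post["positive"] == pytest.approx(0.5, abs=1e-12)
        assert post["negative"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        corpus = LabeledCorpus(
            [["a", "a", "b"], ["b", "b"], ["a", "c"], ["c", "c", "b"]],
            ["negative", "negative", "positive", "objective"],
        )
        model = smht.train_naive_bayes(corpus)
        for tokens in itertools.chain.from_iterable(
            itertools.product("abc", repeat=r) for r in range(0, 4)
        ):
            ours = smht.nb_posterior(model, list(tokens))
            oracle = _brute_force_posterior(corpus, list(tokens))
            for c in oracle:
                assert ours[c] == pytest.approx(oracle[c], abs=1e-12)

    def test_empty_and_oov_documents_return_priors(self, sentiment_corpus):
        model = smht.train_naive_bayes(sentiment_corpus)
        priors = np.exp(model.log_priors)
        for doc in ([], ["zzz", "qqq"]):
            post = smht.nb_posterior(model, doc)
            assert np.allclose(list(post.values()), priors, atol=1e-12)

    def test_matches_sklearn_reference(self, sentiment_corpus):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        model = smht.train_naive_bayes(sentiment_corpus)
        counts = _doc_term_matrix(sentiment_corpus.documents, model.vocabulary)
        y = [model.classes.index(c) for c in sentiment_corpus.labels]
        ref = sklearn_nb.MultinomialNB(alpha=1.0).fit(counts, y)
        ours = counts @ model.log_likelihood.T + model.log_priors
        theirs = ref.predict_log_proba(counts)
        ours_norm = ours - np.logaddexp.reduce(ours, axis=1, keepdims=True)
        assert np.allclose(ours_norm, theirs, atol=1e-8)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            smht.train_naive_bayes(LabeledCorpus([], []))


class TestAdaBoost:
    def test_random_guess_boundary_alpha_zero(self):
        assert smht.samme_alpha(2 / 3, 3) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_scalar_arithmetic(self):
        assert smht.samme_alpha(0.3, 3) == pytest.approx(
            math.log(0.7 / 0.3) + math.log(2), abs=1e-9
        )

    def test_separable_corpus_reaches_perfect_training_accuracy(self):
        uni = {
            "negative": {"n1": 0.5, "n2": 0.5},
            "objective": {"o1": 0.5, "o2": 0.5},
            "positive": {"p1": 0.5, "p2": 0.5},
        }
        corpus = smht.simulate_corpus(uni, 40, 8, seed=1)
        ensemble = smht.train_adaboost(corpus, T=10, seed=1)
        pred = ensemble.predict(corpus.documents)
        assert pred == corpus.labels
        assert ensemble.n_rounds <= 10

    def test_single_class_rejected(self):
        corpus = LabeledCorpus([["a"], ["b"]], ["positive", "positive"])
        with pytest.raises(ValidationError):
            smht.train_adaboost(corpus)

    def test_binary_training_error_bound(self):
        # overlapping 2-class corpus; ensemble error <= prod 2 sqrt(eps(1-eps))
        uni = {
            "negative": {"w1": 0.6, "w2": 0.4},
            "positive": {"w1": 0.4, "w2": 0.6},
        }
        corpus = smht.simulate_corpus(uni, 150, 10, seed=3)
        ensemble = smht.train_adaboost(corpus, T=15, seed=3)
        pred = ensemble.predict(corpus.documents)
        err = np.mean([p != t for p, t in zip(pred, corpus.labels)])
        bound = np.prod(
            [2 * math.sqrt(r.error * (1 - r.error)) for r in ensemble.rounds]
        )
        assert err <= bound + 1e-12

    def test_every_round_better_than_chance(self, sentiment_corpus):
        ensemble = smht.train_adaboost(sentiment_corpus, T=8, seed=2)
        k = len(ensemble.classes)
        for rnd in ensemble.rounds:
            assert rnd.error < (k - 1) / k
            assert rnd.alpha > 0


def _constant_model(vocabulary, classes, winner):
    """NB model whose prediction is always ``winner`` (via the prior)."""
    K = len(classes)
    priors = np.full(K, -1e3)
    priors[classes.index(winner)] = 0.0
    return NBModel(
        classes=classes,
        vocabulary=vocabulary,
        log_priors=priors,
        log_likelihood=np.zeros((K, len(vocabulary))),
        smoothing=1.0,
    )


class TestSSEScore:
    classes = ("negative", "objective", "positive")

    def _ensemble(self, alphas_by_class):
        rounds = [
            BoostRound(_constant_model((), self.classes, c), alpha, 0.1)
            for c, alpha in alphas_by_class.items()
            if alpha > 0
        ]
        return smht.SentimentEnsemble(rounds, self.classes, ())

    def test_unanimous_positive_is_one(self):
        assert smht.sse_score(self._ensemble({"positive": 2.0}), []) == 1.0

    def test_uniform_votes_are_neutral(self):
        ens = self._ensemble({"negative": 1.0, "objective": 1.0, "positive": 1.0})
        assert smht.sse_score(ens, []) == pytest.approx(0.5)

    def test_vote_expectation(self):
        ens = self._ensemble({"negative": 0.6, "objective": 0.2, "positive": 0.2})
        assert smht.sse_score(ens, []) == pytest.approx(0.3)

    def test_invariant_to_split_weak_learners(self):
        whole = self._ensemble({"negative": 1.0, "positive": 3.0})
        split = smht.SentimentEnsemble(
            [
                BoostRound(_constant_model((), self.classes, "negative"), 0.5, 0.1),
                BoostRound(_constant_model((), self.classes, "negative"), 0.5, 0.1),
                BoostRound(_constant_model((), self.classes, "positive"), 3.0, 0.1),
            ],
            self.classes,
            (),
        )
        assert smht.sse_score(split, []) == pytest.approx(
            smht.sse_score(whole, []), abs=1e-12
        )


class TestEmotionScorer:
    def _fit(self, effect, seed=0, per_class=100):
        labels = np.repeat(np.arange(len(smht.EMOTIONS)), per_class)
        feats = smht.simulate_prosody(labels, effect, seed)
        return smht.EmotionScorer.fit(feats, labels), labels

    def test_class_mean_is_confidently_classified(self):
        scorer, _ = self._fit(effect=4.0, seed=1)
        for c in range(len(smht.EMOTIONS)):
            dist, _ = smht.see_score(4.0 * smht.simulate.PROSODY_PROTOTYPES[c], scorer)
            assert dist[smht.EMOTIONS[c]] > 0.99

    def test_indistinguishable_classes_give_uniform_posterior(self):
        scorer, _ = self._fit(effect=0.0, seed=2)
        scorer.means[:] = 0.0
        scorer.variances[:] = 1.0
        dist, scalar = smht.see_score(np.zeros(6), scorer)
        assert np.allclose(list(dist.values()), 1 / 6, atol=1e-12)
        assert scalar == pytest.approx(np.mean(list(smht.EMOTION_VALENCE.values())))

    def test_held_out_accuracy_at_two_sd(self):
        scorer, _ = self._fit(effect=2.0, seed=3)
        labels = np.repeat(np.arange(6), 100)
        held_out = smht.simulate_prosody(labels, 2.0, seed=4)
        pred = scorer.posterior(held_out).argmax(axis=1)
        assert (pred == labels).mean() > 0.8

    def test_dimension_mismatch_rejected(self):
        scorer, _ = self._fit(effect=1.0)
        with pytest.raises(ValidationError):
            smht.see_score(np.zeros(4), scorer)


class TestWordErrorRate:
    def test_identical_sequences(self):
        assert smht.word_error_rate(["a", "b"], ["a", "b"]) == 0.0

    def test_single_substitution(self):
        assert smht.word_error_rate(["a", "b", "c"], ["a", "x", "c"]) == pytest.approx(1 / 3)

    def test_empty_hypothesis_all_deletions(self):
        assert smht.word_error_rate(["a", "b", "c"], []) == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            smht.word_error_rate([], ["a"])

    def test_matches_edlib_reference(self):
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(0)
        alphabet = "abcde"
        for _ in range(100):
            ref = rng.choice(list(alphabet), size=rng.integers(1, 12))
            hyp = rng.choice(list(alphabet), size=rng.integers(0, 12))
            expected = edlib.align("".join(hyp), "".join(ref))["editDistance"]
            assert smht.word_error_rate(ref, hyp) == pytest.approx(
                expected / len(ref), abs=1e-12
            )
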