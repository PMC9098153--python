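"""Subjective-channel affect scoring.

Text channel (semantic summary extraction, SSE): a from-scratch multinomial
Naive Bayes sentiment classifier over {negative, objective, positive},
strengthened by multi-class AdaBoost (SAMME) over weight-resampled NB weak
learners, whose weighted vote is mapped to a scalar valence in [0, 1].

Speech channel (speech emotion extraction, SEE): a pluggable scorer over
numeric prosody features.  The reference implementation is a diagonal-Gaussian
class-conditional model over six emotions; any object with the same
``posterior`` interface (e.g. a trained neural model) can be swapped in.

Also houses the word-error-rate metric used to characterize an upstream
speech-to-text stage.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .containers import EMOTIONS, SENTIMENT_CLASSES, LabeledCorpus, ValidationError

#: Scalar valence of the three sentiment classes.
SENTIMENT_VALENCE: dict[str, float] = {"negative": 0.0, "objective": 0.5, "positive": 1.0}

#: Scalar valence of the six emotion classes (total order fixed):
#: sad < fearful < angry < neutral < surprised < happy.
EMOTION_VALENCE: dict[str, float] = {
    "sad": 0.0,
    "fearful": 0.1,
    "angry": 0.2,
    "neutral": 0.5,
    "surprised": 0.7,
    "happy": 1.0,
}

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def preprocess_text(raw: str) -> list[str]:
    """Lowercase, strip punctuation, split on non-word boundaries.

    Hyphens and commas act as separators ("so-so, so so" -> so so so so);
    apostrophes are kept inside words.  Empty input yields an empty sequence.
    """
    return _TOKEN_RE.findall(raw.lower())


# --------------------------------------------------------------------------
# Multinomial Naive Bayes
# --------------------------------------------------------------------------

@dataclass
class NBModel:
    """Multinomial Naive Bayes with additive smoothing.

    ``log_likelihood[c, t]`` is the smoothed log probability of token ``t``
    given class ``c``; rows exponentiate to 1 over the vocabulary.
    """

    classes: tuple[str, ...]
    vocabulary: tuple[str, ...]
    log_priors: np.ndarray      # (K,)
    log_likelihood: np.ndarray  # (K, V)
    smoothing: float

    def __post_init__(self) -> None:
        self._vocab_index = {t: i for i, t in enumerate(self.vocabulary)}

    def count_vector(self, tokens) -> np.ndarray:
        """Token counts over the model vocabulary; OOV tokens are dropped."""
        counts = np.zeros(len(self.vocabulary))
        for tok in tokens:
            idx = self._vocab_index.get(tok)
            if idx is not None:
                counts[idx] += 1
        return counts


def _doc_term_matrix(
    documents: list[list[str]], vocabulary: tuple[str, ...]
) -> np.ndarray:
    index = {t: i for i, t in enumerate(vocabulary)}
    mat = np.zeros((len(documents), len(vocabulary)))
    for i, doc in enumerate(documents):
        for tok in doc:
            j = index.get(tok)
            if j is not None:
                mat[i, j] += 1
    return mat


def train_naive_bayes(
    corpus: LabeledCorpus,
    smoothing: float = 1.0,
    sample_indices: np.ndarray | None = None,
) -> NBModel:
    """Fit multinomial NB with additive smoothing over the corpus vocabulary.

    ``sample_indices`` restricts training to a (possibly repeated) subset of
    documents while keeping the full-corpus vocabulary and class set; the
    AdaBoost weak learners use this for weight-proportional resampling.
    """
    if len(corpus) == 0:
        raise ValidationError("cannot train on an empty corpus")
    if smoothing < 0:
        raise ValidationError("smoothing must be non-negative")
    classes = tuple(c for c in SENTIMENT_CLASSES if c in set(corpus.labels))
    vocabulary = corpus.vocabulary
    counts = _doc_term_matrix(corpus.documents, vocabulary)
    labels = np.array([classes.index(lb) for lb in corpus.labels])
    if sample_indices is not None:
        counts = counts[sample_indices]
        labels = labels[sample_indices]
    K, V = len(classes), len(vocabulary)
    class_counts = np.zeros(K)
    token_counts = np.zeros((K, V))
    for c in range(K):
        mask = labels == c
        class_counts[c] = mask.sum()
        token_counts[c] = counts[mask].sum(axis=0)
    if np.any(class_counts == 0):
        # resample may drop a class; keep its prior at the smoothing floor
        class_counts = np.maximum(class_counts, 1e-10)
    log_priors = np.log(class_counts) - np.log(class_counts.sum())
    smoothed = token_counts + smoothing
    log_lik = np.log(smoothed) - np.log(smoothed.sum(axis=1, keepdims=True))
    return NBModel(
        classes=classes,
        vocabulary=vocabulary,
        log_priors=log_priors,
        log_likelihood=log_lik,
        smoothing=smoothing,
    )


def nb_posterior(model: NBModel, tokens) -> dict[str, float]:
    """Normalized class posterior for a token sequence.

    Out-of-vocabulary tokens carry no evidence (dropped), so an all-OOV or
    empty document returns the class priors.
    """
    counts = model.count_vector(tokens)
    log_post = model.log_priors + model.log_likelihood @ counts
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    return dict(zip(model.classes, (float(v) for v in post)))


def _nb_predict_matrix(model: NBModel, counts: np.ndarray) -> np.ndarray:
    """Class index predictions for a document-term count matrix."""
    scores = counts @ model.log_likelihood.T + model.log_priors
    return scores.argmax(axis=1)


# --------------------------------------------------------------------------
# AdaBoost (SAMME) over NB weak learners
# --------------------------------------------------------------------------

@dataclass
class BoostRound:
    model: NBModel
    alpha: float
    error: float


@dataclass
class SentimentEnsemble:
    """SAMME ensemble of NB weak learners with weighted majority voting."""

    rounds: list[BoostRound]
    classes: tuple[str, ...]
    vocabulary: tuple[str, ...]

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def vote_distribution(self, tokens) -> dict[str, float]:
        """Alpha-weighted vote mass per class, normalized to 1."""
        votes = np.zeros(len(self.classes))
        for rnd in self.rounds:
            counts = rnd.model.count_vector(tokens)
            pred = int(
                np.argmax(rnd.model.log_priors + rnd.model.log_likelihood @ counts)
            )
            votes[pred] += rnd.alpha
        if votes.sum() == 0:
            votes[:] = 1.0
        votes /= votes.sum()
        return dict(zip(self.classes, (float(v) for v in votes)))

    def predict(self, documents: list[list[str]]) -> list[str]:
        counts = _doc_term_matrix(documents, self.vocabulary)
        votes = np.zeros((len(documents), len(self.classes)))
        for rnd in self.rounds:
            preds = _nb_predict_matrix(rnd.model, counts)
            votes[np.arange(len(documents)), preds] += rnd.alpha
        return [self.classes[i] for i in votes.argmax(axis=1)]


def samme_alpha(error: float, n_classes: int) -> float:
    """SAMME round weight ``ln((1 - eps)/eps) + ln(K - 1)``."""
    if n_classes < 2:
        raise ValidationError("boosting needs at least 2 classes")
    eps = min(max(error, 1e-10), 1 - 1e-10)
    return math.log((1 - eps) / eps) + math.log(n_classes - 1)


def train_adaboost(
    corpus: LabeledCorpus,
    T: int = 50,
    smoothing: float = 1.0,
    seed: int = 0,
) -> SentimentEnsemble:
    """SAMME boosting of NB weak learners on weight-proportional resamples.

    Each round trains NB on an n-document resample drawn with probability
    proportional to the current sample weights, measures the weighted training
    error ``eps_t`` of that learner on the full corpus, and re-weights
    misclassified documents by ``exp(alpha_t)``.  Boosting halts early when a
    learner is no better than random guessing (``eps_t >= (K-1)/K``) or
    perfect (``eps_t = 0``, kept with a clamped error so alpha stays finite).
    """
    present = sorted(set(corpus.labels))
    if len(present) < 2:
        raise ValidationError("boosting needs at least 2 classes present")
    if T < 1:
        raise ValidationError("T must be positive")
    rng = np.random.default_rng(seed)
    classes = tuple(c for c in SENTIMENT_CLASSES if c in set(corpus.labels))
    K = len(classes)
    n = len(corpus)
    counts = _doc_term_matrix(corpus.documents, corpus.vocabulary)
    labels = np.array([classes.index(lb) for lb in corpus.labels])
    weights = np.full(n, 1.0 / n)
    rounds: list[BoostRound] = []
    for _ in range(T):
        idx = rng.choice(n, size=n, replace=True, p=weights)
        weak = train_naive_bayes(corpus, smoothing=smoothing, sample_indices=idx)
        pred = _nb_predict_matrix(weak, counts)
        miss = pred != labels
        eps = float(weights[miss].sum())
        if eps >= (K - 1) / K:
            break
        alpha = samme_alpha(eps, K)
        rounds.append(BoostRound(model=weak, alpha=alpha, error=eps))
        if eps <= 0.0:
            break
        weights = weights * np.exp(alpha * miss)
        weights /= weights.sum()
    if not rounds:
        # fall back to a single unweighted learner so the ensemble is usable
        weak = train_naive_bayes(corpus, smoothing=smoothing)
        pred = _nb_predict_matrix(weak, counts)
        eps = float(weights[pred != labels].sum())
        rounds.append(BoostRound(model=weak, alpha=max(samme_alpha(eps, K), 1e-10), error=eps))
    return SentimentEnsemble(rounds=rounds, classes=classes, vocabulary=corpus.vocabulary)


def sse_score(ensemble: SentimentEnsemble, tokens) -> float:
    """Scalar text-valence score: expectation of the class valence map
    under the ensemble's weighted-vote distribution (negative 0, objective
    0.5, positive 1)."""
    votes = ensemble.vote_distribution(tokens)
    return float(sum(SENTIMENT_VALENCE[c] * v for c, v in votes.items()))


# --------------------------------------------------------------------------
# Speech emotion scorer (pluggable surrogate)
# --------------------------------------------------------------------------

@dataclass
class EmotionScorer:
    """Diagonal-Gaussian class-conditional scorer over prosody features.

    A stand-in observation model exposing the same ``posterior`` interface a
    trained sequence model would; parameters can be fit from labeled feature
    vectors with :meth:`fit`.
    """

    classes: tuple[str, ...]
    means: np.ndarray       # (K, d)
    variances: np.ndarray   # (K, d)
    log_priors: np.ndarray  # (K,)
    valence: dict[str, float]

    @classmethod
    def fit(
        cls,
        features: np.ndarray,
        labels: np.ndarray,
        classes: tuple[str, ...] = EMOTIONS,
        valence: dict[str, float] | None = None,
        var_floor: float = 1e-6,
    ) -> "EmotionScorer":
        """Gaussian MLE per class from labeled prosody features.

        ``labels`` are class indices into ``classes``.
        """
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels)
        K, d = len(classes), features.shape[1]
        means = np.zeros((K, d))
        variances = np.ones((K, d))
        priors = np.zeros(K)
        for c in range(K):
            rows = features[labels == c]
            if len(rows) == 0:
                raise ValidationError(f"no training examples for class {classes[c]}")
            means[c] = rows.mean(axis=0)
            variances[c] = np.maximum(rows.var(axis=0), var_floor)
            priors[c] = len(rows)
        return cls(
            classes=classes,
            means=means,
            variances=variances,
            log_priors=np.log(priors / priors.sum()),
            valence=dict(valence or EMOTION_VALENCE),
        )

    def posterior(self, features: np.ndarray) -> np.ndarray:
        """Class posteriors for one feature vector or a batch (rows)."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.means.shape[1]:
            raise ValidationError(
                f"feature dimension {x.shape[1]} != scorer dimension "
                f"{self.means.shape[1]}"
            )
        diff = x[:, None, :] - self.means[None, :, :]
        log_lik = -0.5 * (
            (diff**2 / self.variances).sum(axis=2)
            + np.log(2 * np.pi * self.variances).sum(axis=1)
        )
        log_post = log_lik + self.log_priors
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


def see_score(
    features: np.ndarray, scorer: EmotionScorer
) -> tuple[dict[str, float], float]:
    """Emotion posterior and scalar valence for one prosody feature vector."""
    post = scorer.posterior(features)[0]
    dist = dict(zip(scorer.classes, (float(v) for v in post)))
    scalar = float(sum(scorer.valence[c] * p for c, p in dist.items()))
    return dist, scalar


# --------------------------------------------------------------------------
# Word error rate
# --------------------------------------------------------------------------

def word_error_rate(reference, hypothesis) -> float:
    """(substitutions + insertions + deletions) / |reference|, minimal edits."""
    ref = list(reference)
    hyp = list(hypothesis)
    if not ref:
        raise ValidationError("reference must be non-empty")
    prev = np.arange(len(hyp) + 1)
    for i, r in enumerate(ref, start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        for j, h in enumerate(hyp, start=1):
            cur[j] = min(
                prev[j] + 1,             # deletion
                cur[j - 1] + 1,          # insertion
                prev[j - 1] + (r != h),  # substitution / match
            )
        prev = cur
    return float(prev[-1]) / len(ref)
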