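"""Synthetic-data generators with planted statistical structure.

Every downstream stage of the pipeline (fuzzy factor analysis, psychometric
validation, text sentiment, prosody emotion scoring, score fusion) is exercised
on data from these generators, so each generator plants a known ground truth:

* Likert responses come from a latent common-factor model
  ``z = Lambda f + sqrt(psi) eps`` thresholded at fixed cutpoints, optionally
  contaminated by a fraction of mean-shifted outlier respondents.
* Retest administrations hit a requested test-retest correlation.
* Criterion scores hit a requested concurrent-validity correlation.
* Text documents are drawn from class-conditional unigram models.
* Prosody features are class-conditional Gaussians around emotion prototypes.
* Cohorts tie all three channels to one binary health state.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .containers import (
    EMOTIONS,
    SENTIMENT_CLASSES,
    AssessmentCohort,
    LabeledCorpus,
    ResponseMatrix,
    ValidationError,
)

#: Global latent-to-Likert cutpoints; a standard-normal latent maps to
#: categories 1..5 with probabilities (.067, .242, .383, .242, .067).
DEFAULT_CUTPOINTS: tuple[float, float, float, float] = (-1.5, -0.5, 0.5, 1.5)


class ConfigError(ValidationError):
    """Raised for invalid generator configuration."""


# --------------------------------------------------------------------------
# Likert questionnaire channel
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the latent-factor Likert generator.

    ``loading_pattern`` is items x factors with row-wise sum of squares <= 1;
    ``uniqueness`` is the per-item unique variance added on top (scalar or
    per-item).  ``outlier_fraction`` of respondents get their latent rows
    shifted by ``outlier_magnitude`` latent standard deviations before
    thresholding.
    """

    n_respondents: int
    n_items: int
    n_factors: int
    loading_pattern: np.ndarray
    uniqueness: np.ndarray | float = 1.0
    likert_cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1 or self.n_items < 1 or self.n_factors < 1:
            raise ConfigError("n_respondents, n_items, n_factors must be positive")
        lam = np.asarray(self.loading_pattern, dtype=float)
        if not np.all(np.isfinite(lam)):
            raise ConfigError("loading_pattern must be finite")
        if lam.shape != (self.n_items, self.n_factors):
            raise ConfigError(
                f"loading_pattern shape {lam.shape} != (n_items, n_factors)"
            )
        if np.any(np.sum(lam**2, axis=1) > 1.0 + 1e-9):
            raise ConfigError("row-wise sum of squared loadings must be <= 1")
        object.__setattr__(self, "loading_pattern", lam)
        psi = np.broadcast_to(np.asarray(self.uniqueness, dtype=float), (self.n_items,))
        if np.any(psi < 0):
            raise ConfigError("uniqueness must be non-negative")
        object.__setattr__(self, "uniqueness", np.array(psi))
        cuts = tuple(float(c) for c in self.likert_cutpoints)
        if len(cuts) != 4 or np.any(np.diff(cuts) <= 0):
            raise ConfigError("likert_cutpoints must be 4 strictly ascending reals")
        object.__setattr__(self, "likert_cutpoints", cuts)
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ConfigError("outlier_fraction must be in [0, 0.5)")
        if self.outlier_magnitude <= 0:
            raise ConfigError("outlier_magnitude must be positive")


@dataclass
class SimulatedResponses:
    """Responses plus generator-side bookkeeping for verification."""

    responses: ResponseMatrix
    latent: np.ndarray          # pre-threshold latent scores (n x p)
    outlier_indices: np.ndarray  # indices of contaminated respondents
    config: SimulationConfig


def _threshold(latent: np.ndarray, cutpoints: tuple[float, ...]) -> np.ndarray:
    return 1 + np.searchsorted(np.asarray(cutpoints), latent).astype(np.int64)


def simulate_responses(config: SimulationConfig) -> SimulatedResponses:
    """Draw a Likert response matrix from the latent common-factor model.

    Exactly ``floor(outlier_fraction * n)`` respondents are contaminated by a
    positive latent mean shift of ``outlier_magnitude``; their indices are
    returned for downstream verification.
    """
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_respondents, config.n_items, config.n_factors
    factors = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, p))
    latent = factors @ config.loading_pattern.T + np.sqrt(config.uniqueness) * noise
    n_out = int(math.floor(config.outlier_fraction * n))
    outliers = np.sort(rng.choice(n, size=n_out, replace=False))
    latent[outliers] += config.outlier_magnitude
    values = _threshold(latent, config.likert_cutpoints)
    return SimulatedResponses(
        responses=ResponseMatrix(values),
        latent=latent,
        outlier_indices=outliers,
        config=config,
    )


# --------------------------------------------------------------------------
# Retest channel: hit a requested test-retest correlation
# --------------------------------------------------------------------------

def _retest_category_moments(
    rho: float, cutpoints: tuple[float, ...], n_nodes: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional retest-category moments per base category.

    For a base entry in category ``b`` the latent score is truncated standard
    normal on that bin; the retest entry is the ``cutpoints`` discretization
    of ``rho * y + sqrt(1 - rho^2) * eps``.  Returns per-category mean and
    variance of the retest entry (5-vectors), by quadrature over the bin.
    """
    edges = np.concatenate(([-np.inf], cutpoints, [np.inf]))
    values = np.arange(1, 6, dtype=float)
    cdf_edges = stats.norm.cdf(edges)
    u = (np.arange(n_nodes) + 0.5) / n_nodes
    s = math.sqrt(max(0.0, 1.0 - rho**2))
    means = np.empty(5)
    variances = np.empty(5)
    for b in range(5):
        lo, hi = cdf_edges[b], cdf_edges[b + 1]
        y = stats.norm.ppf(np.clip(lo + u * (hi - lo), 1e-14, 1 - 1e-14))
        if s == 0.0:
            cat = 1 + np.searchsorted(np.asarray(cutpoints), rho * y)
            means[b] = cat.mean()
            variances[b] = cat.var()
            continue
        upper = stats.norm.cdf((edges[1:, None] - rho * y[None, :]) / s)
        lower = stats.norm.cdf((edges[:-1, None] - rho * y[None, :]) / s)
        probs = (upper - lower).mean(axis=1)
        m1 = float(values @ probs)
        m2 = float((values**2) @ probs)
        means[b] = m1
        variances[b] = m2 - m1**2
    return means, variances


def _expected_total_corr(rho: float, base_values: np.ndarray,
                         cutpoints: tuple[float, ...]) -> float:
    """Expected total-score correlation of base vs retest at latent mixing rho.

    Conditional on the base matrix the retest entries are independent, so the
    retest total decomposes into a deterministic part (sum of conditional
    category means) plus independent noise; the correlation follows in closed
    form from the per-category moment tables.
    """
    m, v = _retest_category_moments(rho, cutpoints)
    bins = base_values - 1
    t1 = base_values.sum(axis=1).astype(float)
    expected_t2 = m[bins].sum(axis=1)
    within_var = float(v[bins].sum(axis=1).mean())
    cov = float(np.mean(t1 * expected_t2) - t1.mean() * expected_t2.mean())
    var_t1 = float(t1.var())
    var_t2 = float(expected_t2.var()) + within_var
    if cov <= 0 or var_t1 == 0 or var_t2 == 0:
        return 0.0
    return cov / math.sqrt(var_t1 * var_t2)


def simulate_retest(
    base: ResponseMatrix,
    reliability: float,
    seed: int,
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS,
) -> ResponseMatrix:
    """Second administration targeting a given test-retest correlation.

    The latent score behind each observed category is reconstructed by a
    truncated-normal posterior draw, mixed with fresh noise
    (``y2 = rho y1 + sqrt(1-rho^2) eps``) and re-thresholded.  The mixing
    ``rho`` is calibrated against the observed base matrix so that the
    *expected total-score* Pearson correlation equals ``reliability``,
    whatever the base's inter-item correlation structure; the calibration uses
    the closed-form conditional decomposition of the retest total.
    ``reliability=1`` returns an exact copy of the base administration.
    """
    if not 0.0 <= reliability <= 1.0:
        raise ConfigError("reliability must be in [0, 1]")
    if reliability == 1.0:
        return ResponseMatrix(base.values.copy(), list(base.item_names))
    rng = np.random.default_rng(seed)
    edges = np.concatenate(([-np.inf], cutpoints, [np.inf]))
    lo = stats.norm.cdf(edges[base.values - 1])
    hi = stats.norm.cdf(edges[base.values])
    u = rng.uniform(lo, hi)
    y1 = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    if reliability == 0.0:
        rho = 0.0
    else:
        f = lambda r: _expected_total_corr(r, base.values, cutpoints) - reliability
        hi_rho = 1.0 - 1e-9
        if f(hi_rho) <= 0:  # target above what mixing can reach; copy-like limit
            rho = hi_rho
        else:
            rho = float(optimize.brentq(f, 0.0, hi_rho, xtol=1e-6))
    y2 = rho * y1 + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(y1.shape)
    return ResponseMatrix(_threshold(y2, cutpoints), list(base.item_names))


# --------------------------------------------------------------------------
# Criterion channel: hit a requested concurrent-validity correlation
# --------------------------------------------------------------------------

def simulate_criterion(
    base: ResponseMatrix, validity: float, seed: int
) -> np.ndarray:
    """Criterion-scale totals correlating ``validity`` with the base totals.

    The criterion is continuous (an established-instrument total such as an
    SCL-90 global score), so no discretization attenuation applies and the
    sample correlation converges to ``validity`` exactly.
    """
    if not -1.0 <= validity <= 1.0:
        raise ConfigError("validity must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    totals = base.total_scores().astype(float)
    sd = totals.std()
    if sd == 0:
        raise ConfigError("base totals are constant; validity target undefined")
    z = (totals - totals.mean()) / sd
    mix = validity * z + math.sqrt(1 - validity**2) * rng.standard_normal(len(z))
    # arbitrary affine placement on an SCL-90-like global-severity scale
    return 160.0 + 40.0 * mix


# --------------------------------------------------------------------------
# Text channel
# --------------------------------------------------------------------------

_NEGATIVE_WORDS = (
    "sad", "tired", "hopeless", "afraid", "lonely",
    "stressed", "angry", "worthless", "anxious", "exhausted",
)
_POSITIVE_WORDS = (
    "happy", "calm", "confident", "rested", "hopeful",
    "content", "cheerful", "relaxed", "energetic", "satisfied",
)
_NEUTRAL_WORDS = (
    "ship", "watch", "cargo", "deck", "voyage", "port", "crew", "engine",
    "weather", "schedule", "work", "day", "time", "food", "cabin", "sea",
    "route", "duty", "contract", "family",
)


def default_class_unigrams() -> dict[str, dict[str, float]]:
    """Built-in three-class unigram models over a small maritime lexicon.

    The negative and positive classes put 60% of their mass on a disjoint
    sentiment vocabulary and 40% on shared neutral words; the objective class
    is uniform over the neutral words.  Mirror-symmetric by construction.
    """
    def dist(weighted: dict[tuple[str, ...], float]) -> dict[str, float]:
        out: dict[str, float] = {}
        for words, mass in weighted.items():
            for w in words:
                out[w] = mass / len(words)
        total = sum(out.values())
        return {w: p / total for w, p in out.items()}

    return {
        "negative": dist({_NEGATIVE_WORDS: 0.6, _NEUTRAL_WORDS: 0.4}),
        "objective": dist({_NEUTRAL_WORDS: 1.0}),
        "positive": dist({_POSITIVE_WORDS: 0.6, _NEUTRAL_WORDS: 0.4}),
    }


def _dist_vector(
    dist: dict[str, float], vocabulary: tuple[str, ...]
) -> np.ndarray:
    vec = np.array([dist.get(tok, 0.0) for tok in vocabulary], dtype=float)
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ConfigError(
            f"class distribution sums to {vec.sum():.12f}, not 1 (tolerance 1e-9)"
        )
    if np.any(vec < 0):
        raise ConfigError("class distribution has negative probabilities")
    return vec


def simulate_corpus(
    class_unigrams: dict[str, dict[str, float]],
    docs_per_class: int,
    doc_length: int,
    seed: int,
) -> LabeledCorpus:
    """Balanced corpus of i.i.d. unigram documents, one model per class."""
    if docs_per_class < 1 or doc_length < 1:
        raise ConfigError("docs_per_class and doc_length must be positive")
    vocabulary = tuple(sorted({t for d in class_unigrams.values() for t in d}))
    rng = np.random.default_rng(seed)
    vocab_arr = np.array(vocabulary)
    documents: list[list[str]] = []
    labels: list[str] = []
    for label in SENTIMENT_CLASSES:
        if label not in class_unigrams:
            continue
        vec = _dist_vector(class_unigrams[label], vocabulary)
        draws = rng.choice(len(vocab_arr), size=(docs_per_class, doc_length), p=vec)
        documents.extend([list(vocab_arr[row]) for row in draws])
        labels.extend([label] * docs_per_class)
    if not documents:
        raise ConfigError("class_unigrams contained no recognized class")
    return LabeledCorpus(documents=documents, labels=labels, vocabulary=vocabulary)


# --------------------------------------------------------------------------
# Prosody channel
# --------------------------------------------------------------------------

#: Emotion prototype directions in a 6-D prosody feature space (intonation,
#: pitch level, pitch variability, energy, speech rate, voice quality).  Rows
#: are mutually 2 noise-SD apart per unit effect size.
PROSODY_PROTOTYPES: np.ndarray = math.sqrt(2.0) * np.eye(len(EMOTIONS))

#: Emotion-occupancy distributions over EMOTIONS =
#: (neutral, happy, sad, angry, fearful, surprised).
HEALTHY_EMOTION_PROBS = np.array([0.35, 0.30, 0.08, 0.07, 0.05, 0.15])
AT_RISK_EMOTION_PROBS = np.array([0.35, 0.08, 0.30, 0.07, 0.15, 0.05])


def simulate_prosody(
    emotions: np.ndarray, effect_size: float, seed: int
) -> np.ndarray:
    """Gaussian prosody features around per-emotion prototypes.

    ``emotions`` are indices into :data:`smht.containers.EMOTIONS`; class mean
    separation is ``2 * effect_size`` noise standard deviations.
    """
    rng = np.random.default_rng(seed)
    emotions = np.asarray(emotions)
    means = effect_size * PROSODY_PROTOTYPES[emotions]
    return means + rng.standard_normal(means.shape)


# --------------------------------------------------------------------------
# Full cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic assessment cohort.

    Effect sizes are channel informativeness knobs in latent/noise SD units:
    ``scale_effect`` splits the groups' latent response means symmetrically,
    ``text_effect`` in [0, 1] moves document mixtures toward the positive
    (healthy) or negative (at-risk) unigram model, ``prosody_effect`` scales
    the emotion-prototype separation.  ``interview_noise`` is the probability
    that the interview label contradicts the true state.
    """

    n_subjects: int = 1000
    n_items: int = 20
    n_factors: int = 4
    loading: float = 0.6
    scale_effect: float = 0.8
    text_effect: float = 0.6
    prosody_effect: float = 1.0
    interview_noise: float = 0.05
    doc_length: int = 40
    at_risk_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("a cohort needs at least 2 subjects")
        for name in ("text_effect", "interview_noise", "at_risk_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.interview_noise > 0.5:
            raise ConfigError("interview_noise must be <= 0.5")
        if self.scale_effect < 0 or self.prosody_effect < 0:
            raise ConfigError("effect sizes must be non-negative")


def simple_structure_loadings(p: int, k: int, value: float) -> np.ndarray:
    """Simple-structure loading pattern: contiguous item blocks per factor."""
    lam = np.zeros((p, k))
    for f, block in enumerate(np.array_split(np.arange(p), k)):
        lam[block, f] = value
    return lam


def simulate_cohort(config: CohortConfig, seed: int) -> AssessmentCohort:
    """Cohort whose three channels all carry the planted binary health state."""
    base = int(seed) % (2**31 - 16)
    rng_state = np.random.default_rng(base)
    true_state = (rng_state.random(config.n_subjects) < config.at_risk_rate).astype(int)

    # objective channel: symmetric latent mean split of +-scale_effect/2
    lam = simple_structure_loadings(config.n_items, config.n_factors, config.loading)
    psi = 1.0 - config.loading**2
    rng_scale = np.random.default_rng(base + 1)
    factors = rng_scale.standard_normal((config.n_subjects, config.n_factors))
    noise = rng_scale.standard_normal((config.n_subjects, config.n_items))
    latent = factors @ lam.T + math.sqrt(psi) * noise
    latent += ((true_state - 0.5) * config.scale_effect)[:, None]
    responses = ResponseMatrix(_threshold(latent, DEFAULT_CUTPOINTS))

    # text channel: mixture of the objective model with the signed pole
    rng_text = np.random.default_rng(base + 2)
    unigrams = default_class_unigrams()
    vocabulary = tuple(sorted({t for d in unigrams.values() for t in d}))
    vocab_arr = np.array(vocabulary)
    w = 0.5 * config.text_effect
    d_obj = _dist_vector(unigrams["objective"], vocabulary)
    d_neg = _dist_vector(unigrams["negative"], vocabulary)
    d_pos = _dist_vector(unigrams["positive"], vocabulary)
    mix_healthy = (1 - w) * d_obj + w * d_pos
    mix_risk = (1 - w) * d_obj + w * d_neg
    documents: list[list[str]] = []
    for s in range(config.n_subjects):
        vec = mix_risk if true_state[s] else mix_healthy
        idx = rng_text.choice(len(vocab_arr), size=config.doc_length, p=vec)
        documents.append(list(vocab_arr[idx]))

    # speech channel: emotion occupancy differs by state, features by effect
    rng_emo = np.random.default_rng(base + 3)
    emotions = np.where(
        true_state[:, None],
        rng_emo.multinomial(1, AT_RISK_EMOTION_PROBS, size=config.n_subjects),
        rng_emo.multinomial(1, HEALTHY_EMOTION_PROBS, size=config.n_subjects),
    ).argmax(axis=1)
    prosody = simulate_prosody(emotions, config.prosody_effect, base + 4)

    # interview channel: flips true_state with probability interview_noise
    rng_int = np.random.default_rng(base + 5)
    flips = rng_int.random(config.n_subjects) < config.interview_noise
    interview = np.where(flips, 1 - true_state, true_state)

    return AssessmentCohort(
        true_state=true_state,
        responses=responses,
        documents=documents,
        prosody=prosody,
        true_emotions=emotions,
        interview_label=interview,
        seed=int(seed),
    )
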