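"""Scale-validation suite: reliability, validity, item analysis, readability.

Conventions (declared once, used throughout):

* variances are unbiased (``ddof=1``); the Pearson correlation is
  convention-free because numerator and scale terms use the same ``N``;
* test-retest reliability and criterion validity share one Pearson kernel;
* item discrimination uses the critical-ratio method: respondents are ranked
  by total score, the top and bottom 27% compared per item with a Welch
  (unequal-variance) t statistic, and items whose groups do not differ at the
  declared alpha level are marked for deletion;
* normality screening flags items with |skewness| > 2 or |excess kurtosis| > 7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ResponseMatrix, ValidationError


def _as_values(X) -> np.ndarray:
    if isinstance(X, ResponseMatrix):
        return X.values.astype(float)
    return np.asarray(X, dtype=float)


# --------------------------------------------------------------------------
# Reliability
# --------------------------------------------------------------------------

def cronbach_alpha(X) -> float:
    """Cronbach's alpha ``K/(K-1) (1 - sum var(Y_i) / var(X))``.

    ``Y_i`` are item scores, ``X`` the per-respondent total; variances use the
    unbiased (n-1) convention.
    """
    values = _as_values(X)
    n, k = values.shape
    if k < 2:
        raise ValidationError("Cronbach's alpha needs at least 2 items")
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total score has zero variance")
    item_var = values.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def pearson_r(x, y) -> float:
    """Pearson correlation, the shared kernel of retest and validity checks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length vectors")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).mean())
    sy = np.sqrt((yc**2).mean())
    if sx == 0 or sy == 0:
        raise ValidationError("correlation undefined for a constant input")
    return float((xc * yc).mean() / (sx * sy))


def retest_reliability(X1, X2) -> float:
    """Pearson correlation of total scores across two administrations."""
    t1 = _as_values(X1).sum(axis=1)
    t2 = _as_values(X2).sum(axis=1)
    return pearson_r(t1, t2)


def criterion_validity(scale_scores, criterion) -> float:
    """Pearson correlation of scale scores with an established criterion."""
    return pearson_r(scale_scores, criterion)


# --------------------------------------------------------------------------
# Item analysis
# --------------------------------------------------------------------------

def item_discrimination(
    X,
    high_low_fraction: float = 0.27,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Critical-ratio item analysis against high/low total-score groups.

    For each item, respondents are ranked by the *rest score* (scale total
    excluding that item, so an uninformative item faces an exact null), the
    top and bottom fractions are compared with a Welch t critical ratio, and
    the verdict is delete iff ``p > alpha_level``.  Groups are formed by
    quantile thresholds with all boundary ties included, so verdicts are
    invariant to respondent order.  An item with no variation and no mean
    difference across groups has CR 0 and is deleted without numerical
    failure; zero within-group variance with distinct means is maximally
    discriminating.
    """
    if not 0 < high_low_fraction <= 0.5:
        raise ValidationError("high_low_fraction must be in (0, 0.5]")
    values = _as_values(X)
    names = (
        list(X.item_names)
        if isinstance(X, ResponseMatrix)
        else [f"item_{j + 1}" for j in range(values.shape[1])]
    )
    n = values.shape[0]
    if int(round(high_low_fraction * n)) < 2:
        raise ValidationError("sample too small for the requested group fraction")
    totals = values.sum(axis=1)

    rows = []
    for j, name in enumerate(names):
        rest = totals - values[:, j]
        q_lo, q_hi = np.quantile(rest, [high_low_fraction, 1 - high_low_fraction])
        lo = values[rest <= q_lo, j]
        hi = values[rest >= q_hi, j]
        if hi.std(ddof=1) == 0 and lo.std(ddof=1) == 0:
            if hi.mean() == lo.mean():
                cr, p = 0.0, 1.0
            else:
                cr, p = np.inf if hi.mean() > lo.mean() else -np.inf, 0.0
        else:
            cr, p = stats.ttest_ind(hi, lo, equal_var=False)
        rows.append(
            {
                "item": name,
                "critical_ratio": float(cr),
                "p_value": float(p),
                "verdict": "delete" if p > alpha_level else "keep",
            }
        )
    return pd.DataFrame(rows).set_index("item")


def normality_screen(
    X,
    skew_threshold: float = 2.0,
    kurtosis_threshold: float = 7.0,
) -> pd.DataFrame:
    """Flag items whose score distribution departs grossly from normality.

    An item is flagged when |skewness| or |excess kurtosis| exceeds the
    declared thresholds; a constant item is flagged outright.
    """
    values = _as_values(X)
    names = (
        list(X.item_names)
        if isinstance(X, ResponseMatrix)
        else [f"item_{j + 1}" for j in range(values.shape[1])]
    )
    rows = []
    for j, name in enumerate(names):
        col = values[:, j]
        if col.std() == 0:
            rows.append(
                {"item": name, "skewness": np.nan, "kurtosis": np.nan, "flagged": True}
            )
            continue
        sk = float(stats.skew(col))
        ku = float(stats.kurtosis(col))  # excess kurtosis
        rows.append(
            {
                "item": name,
                "skewness": sk,
                "kurtosis": ku,
                "flagged": abs(sk) > skew_threshold or abs(ku) > kurtosis_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("item")


# --------------------------------------------------------------------------
# Readability
# --------------------------------------------------------------------------

def readability(word_count: float, sentence_count: float, syllable_count: float) -> float:
    """Flesch reading-ease score of the scale text.

    ``206.835 - 1.015 (words/sentences) - 84.6 (syllables/words)``; higher
    means easier text (roughly 0-100 for ordinary prose).
    """
    if word_count <= 0 or sentence_count <= 0 or syllable_count < 0:
        raise ValidationError("counts must be positive")
    return float(
        206.835
        - 1.015 * (word_count / sentence_count)
        - 84.6 * (syllable_count / word_count)
    )


def count_syllables(word: str) -> int:
    """Crude vowel-group syllable count (helper; the main interface takes counts)."""
    groups = 0
    prev_vowel = False
    for ch in word.lower():
        is_vowel = ch in "aeiouy"
        if is_vowel and not prev_vowel:
            groups += 1
        prev_vowel = is_vowel
    return max(groups, 1)


# --------------------------------------------------------------------------
# Dimension vote weighting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionVotes:
    """Five-point vote tallies for one candidate scale dimension."""

    dimension_name: str
    votes_by_grade: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.votes_by_grade) != 5 or any(c < 0 for c in self.votes_by_grade):
            raise ValidationError("votes_by_grade must be 5 non-negative counts")

    @property
    def total_votes(self) -> int:
        return int(sum(self.votes_by_grade))

    @property
    def grade_mass(self) -> int:
        """Weighted vote mass ``sum g * count_g``."""
        return int(sum(g * c for g, c in zip(range(1, 6), self.votes_by_grade)))


def dimension_vote_weighting(
    votes: list[DimensionVotes],
    min_total: int = 142,
    min_grade_mass: int = 80,
) -> pd.DataFrame:
    """Rank candidate dimensions by normalized five-point vote weight.

    ``weight = sum g * count_g / (5 * total_votes)``.  Dimensions with fewer
    than ``min_total`` total votes or weighted mass below ``min_grade_mass``
    are excluded from the ranking (rank NA, exclusion reason recorded).
    Included dimensions are ranked by descending weight, ties broken by name.
    """
    if not votes:
        raise ValidationError("empty vote vector")
    rows = []
    for v in votes:
        if v.total_votes == 0:
            weight = 0.0
        else:
            weight = v.grade_mass / (5.0 * v.total_votes)
        reasons = []
        if v.total_votes < min_total:
            reasons.append(f"n < {min_total}")
        if v.grade_mass < min_grade_mass:
            reasons.append(f"m < {min_grade_mass}")
        rows.append(
            {
                "dimension": v.dimension_name,
                "total_votes": v.total_votes,
                "grade_mass": v.grade_mass,
                "weight": weight,
                "included": not reasons,
                "exclusion_reason": "; ".join(reasons),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["included", "weight", "dimension"], ascending=[False, False, True]
    ).reset_index(drop=True)
    ranks = np.full(len(df), np.nan)
    ranks[: int(df["included"].sum())] = np.arange(1, int(df["included"].sum()) + 1)
    df["rank"] = ranks
    return df.set_index("dimension")
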