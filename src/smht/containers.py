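"""Shared data containers for the assessment pipeline.

The three observation channels of the dual subjective-objective design are a
Likert questionnaire (objective channel), free-text answers (semantic channel)
and prosody feature vectors (speech-emotion channel).  Every container here is
a thin, validated wrapper over numpy/pandas structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentiment classes of the text channel, in canonical order.
SENTIMENT_CLASSES: tuple[str, ...] = ("negative", "objective", "positive")

#: Emotion classes of the speech channel, in canonical order.
EMOTIONS: tuple[str, ...] = ("neutral", "happy", "sad", "angry", "fearful", "surprised")

LIKERT_MIN = 1
LIKERT_MAX = 5


class ValidationError(ValueError):
    """Raised when an input container violates its declared invariants."""


@dataclass
class ResponseMatrix:
    """Respondents x items Likert response table (integers 1..5).

    Parameters
    ----------
    values
        Integer array of shape ``(n_respondents, n_items)`` with entries in 1..5.
    item_names
        Item labels; defaults to ``item_1 .. item_p``.
    """

    values: np.ndarray
    item_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("response matrix must be a non-empty 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded, atol=0):
                raise ValidationError("response matrix entries must be integers")
            self.values = rounded.astype(np.int64)
        if self.values.min() < LIKERT_MIN or self.values.max() > LIKERT_MAX:
            bad = np.argwhere((self.values < LIKERT_MIN) | (self.values > LIKERT_MAX))[0]
            raise ValidationError(
                f"entry {self.values[tuple(bad)]} at row {bad[0] + 1}, "
                f"column {bad[1] + 1} outside the 1..5 Likert range"
            )
        if not self.item_names:
            self.item_names = [f"item_{j + 1}" for j in range((self.values.shape[1]))]
        if len(self.item_names) != self.values.shape[1]:
            raise ValidationError("item_names length must match the item count")

    @property
    def n_respondents(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.values.shape[1])

    def total_scores(self) -> np.ndarray:
        """Per-respondent scale totals (sum over items)."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.item_names)


@dataclass
class LabeledCorpus:
    """Token documents with three-class sentiment labels.

    ``documents[i]`` is a token sequence, ``labels[i]`` its class in
    {negative, objective, positive}.
    """

    documents: list[list[str]]
    labels: list[str]
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.documents) != len(self.labels):
            raise ValidationError("documents and labels must have equal length")
        bad = set(self.labels) - set(SENTIMENT_CLASSES)
        if bad:
            raise ValidationError(f"labels {sorted(bad)} outside {SENTIMENT_CLASSES}")
        if not self.vocabulary:
            seen: dict[str, None] = {}
            for doc in self.documents:
                for tok in doc:
                    seen.setdefault(tok, None)
            self.vocabulary = tuple(sorted(seen))

    def __len__(self) -> int:
        return len(self.documents)


@dataclass
class AssessmentCohort:
    """Multi-channel cohort with binary ground-truth mental-health state.

    Each subject contributes a questionnaire row, a free-text document, a
    prosody feature vector, and a (noisy) interview label standing in for a
    face-to-face expert assessment.
    """

    true_state: np.ndarray          # (n,) 0 = healthy, 1 = at-risk
    responses: ResponseMatrix       # objective channel
    documents: list[list[str]]      # text channel, one document per subject
    prosody: np.ndarray             # (n, d) speech-channel features
    true_emotions: np.ndarray       # (n,) index into EMOTIONS
    interview_label: np.ndarray     # (n,) noisy copy of true_state
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.true_state)
        if n < 2:
            raise ValidationError("a cohort needs at least 2 subjects")
        channels = {
            "responses": self.responses.n_respondents,
            "documents": len(self.documents),
            "prosody": self.prosody.shape[0],
            "true_emotions": len(self.true_emotions),
            "interview_label": len(self.interview_label),
        }
        off = {k: v for k, v in channels.items() if v != n}
        if off:
            raise ValidationError(f"channel subject counts differ from {n}: {off}")

    @property
    def n_subjects(self) -> int:
        return int(len(self.true_state))
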