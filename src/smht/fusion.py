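"""Weighted fusion of objective and subjective assessment components.

The objective scale score and the two subjective channel scores (text, speech)
are combined as a convex combination with default weight ratio 6 : 1.5 : 3.5
(objective : text : speech), normalized internally by the weight sum.  All
components are oriented as *distress* in [0, 1] before fusion; the binary
decision is "at-risk iff fused score >= threshold" with default threshold 0.5.

Calibration against interview ground truth is reported as the relative
accuracy improvement of the fused decision over the scale-only decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ValidationError

DEFAULT_WEIGHTS: tuple[float, float, float] = (6.0, 1.5, 3.5)
DEFAULT_THRESHOLD: float = 0.5


def normalize_objective(
    raw_total: float, item_count: int, likert_min: int = 1, likert_max: int = 5
) -> float:
    """Map a raw scale total onto [0, 1] by its attainable range."""
    lo, hi = item_count * likert_min, item_count * likert_max
    raw = np.asarray(raw_total, dtype=float)
    if np.any(raw < lo) or np.any(raw > hi):
        raise ValidationError(f"total outside attainable range [{lo}, {hi}]")
    out = (raw - lo) / (hi - lo)
    return float(out) if out.ndim == 0 else out


@dataclass
class FusedAssessment:
    """Per-subject fused score with its components and weights."""

    objective: float
    sse: float
    see: float
    weights: tuple[float, float, float]
    fused: float

    @property
    def normalized_weights(self) -> tuple[float, ...]:
        total = sum(self.weights)
        return tuple(w / total for w in self.weights)


def fuse(
    objective: float,
    sse: float,
    see: float,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> FusedAssessment:
    """Convex combination ``sum(w_i c_i) / sum(w_i)`` of the three components."""
    comps = (objective, sse, see)
    for name, c in zip(("objective", "sse", "see"), comps):
        if not 0.0 <= c <= 1.0:
            raise ValidationError(f"component {name}={c} outside [0, 1]")
    if any(w < 0 for w in weights) or sum(weights) <= 0:
        raise ValidationError("weights must be non-negative and not all zero")
    fused = float(np.dot(weights, comps) / sum(weights))
    return FusedAssessment(
        objective=objective, sse=sse, see=see, weights=tuple(weights), fused=fused
    )


def fuse_scores(
    components: np.ndarray, weights: tuple[float, float, float] = DEFAULT_WEIGHTS
) -> np.ndarray:
    """Vectorized fusion of an (n, 3) component array."""
    comps = np.asarray(components, dtype=float)
    if comps.ndim != 2 or comps.shape[1] != 3:
        raise ValidationError("components must be an (n, 3) array")
    if np.any(comps < 0) or np.any(comps > 1):
        raise ValidationError("components must lie in [0, 1]")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be non-negative and not all zero")
    return comps @ w / w.sum()


def classify(score, threshold: float = DEFAULT_THRESHOLD):
    """Binary decision: at-risk (1) iff ``score >= threshold`` (>= tie rule)."""
    score = np.asarray(score, dtype=float)
    if np.any(score < 0) or np.any(score > 1):
        raise ValidationError("score must lie in [0, 1]")
    out = (score >= threshold).astype(int)
    return int(out) if out.ndim == 0 else out


@dataclass
class CalibrationResult:
    """Accuracy of fused vs scale-only decisions against ground truth.

    ``calibration_rate`` is the percent relative accuracy improvement
    ``100 (acc_fused - acc_scale) / acc_scale``; ``self_test_error`` is the
    mean absolute difference between fused and self-reported scores when
    self-reports are supplied.
    """

    acc_fused: float
    acc_scale_only: float
    calibration_rate: float | None
    self_test_error: float | None = None


def calibration_rate(
    fused_decisions,
    scale_decisions,
    ground_truth,
    fused_scores=None,
    self_reports=None,
) -> CalibrationResult:
    """Compare fused and scale-only decision accuracy against ground truth.

    A zero scale-only accuracy leaves the relative rate undefined (None).
    """
    fused_decisions = np.asarray(fused_decisions)
    scale_decisions = np.asarray(scale_decisions)
    truth = np.asarray(ground_truth)
    if not len(truth) or len(fused_decisions) != len(truth) or len(
        scale_decisions
    ) != len(truth):
        raise ValidationError("decision vectors must have equal positive length")
    acc_fused = float((fused_decisions == truth).mean())
    acc_scale = float((scale_decisions == truth).mean())
    rate = None if acc_scale == 0 else 100.0 * (acc_fused - acc_scale) / acc_scale
    self_err = None
    if self_reports is not None:
        if fused_scores is None:
            raise ValidationError("self_reports supplied without fused_scores")
        self_err = float(
            np.mean(np.abs(np.asarray(fused_scores) - np.asarray(self_reports)))
        )
    return CalibrationResult(
        acc_fused=acc_fused,
        acc_scale_only=acc_scale,
        calibration_rate=rate,
        self_test_error=self_err,
    )
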