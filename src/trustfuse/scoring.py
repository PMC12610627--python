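"""Questionnaire and behavioral trust scoring, with reliability statistics.

The 12-item questionnaire mixes distrust-phrased items (1-3, reverse-keyed as
``11 - value``) with trust-phrased items (4-12); the session score is the mean
of the keyed items, staying on the 1-10 Likert scale shared with the EEG
scores. Behavioral codings are collapsed to a 0-10 score from five normalized
sub-scores (adherence, latency, reliance, interventions, verifications).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateInputError,
    FieldValidationError,
    InvalidArgumentError,
    UndefinedStatisticError,
)
from .types import (
    REVERSE_KEYED_ITEMS,
    BehaviorCoding,
    EventTimeline,
    QuestionnaireResponse,
    TrustCurve,
    TrustCurvePoint,
)


def key_items(items: np.ndarray) -> np.ndarray:
    """Apply reverse keying: distrust-phrased items become ``11 - value``.

    Involution: applying twice returns the original responses.
    """
    items = np.asarray(items, dtype=float)
    keyed = items.copy()
    idx = np.asarray(REVERSE_KEYED_ITEMS) - 1
    keyed[..., idx] = 11.0 - keyed[..., idx]
    return keyed


def score_questionnaire(response: QuestionnaireResponse) -> float:
    """Mean of the 12 keyed items; stays in [1, 10]."""
    for i, v in enumerate(response.items, start=1):
        if not (1 <= v <= 10):
            raise FieldValidationError(f"item {i} out of range [1, 10]: {v}")
    return float(np.mean(key_items(np.asarray(response.items))))


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha: ``(k/(k-1)) * (1 - sum(item variances)/var(total score))``.

    Variances are sample variances (n-1 denominator); ``item_matrix`` is
    respondents x keyed items.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InvalidArgumentError("need >= 2 respondents and >= 2 items")
    k = m.shape[1]
    item_vars = np.var(m, axis=0, ddof=1)
    total_var = np.var(m.sum(axis=1), ddof=1)
    if total_var == 0.0:
        raise DegenerateInputError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def align_to_events(
    scored: list[tuple[str, float]] | dict[str, float],
    events: EventTimeline,
    modality: str = "questionnaire",
) -> TrustCurve:
    """Place per-event scores on the session timeline, sorted by time.

    ``scored`` maps event_id -> score (or is a list of pairs). Every score
    must reference a timeline event, and at most once.
    """
    pairs = list(scored.items()) if isinstance(scored, dict) else list(scored)
    by_id = events.by_id()
    orphans = [eid for eid, _ in pairs if eid not in by_id]
    if orphans:
        raise AlignmentError(f"event_id(s) not in timeline: {orphans}")
    seen: set[str] = set()
    for eid, _ in pairs:
        if eid in seen:
            raise AlignmentError(f"duplicate score for event {eid}")
        seen.add(eid)
    points = [
        TrustCurvePoint(event_id=eid, t_s=by_id[eid].t_start_s, score=float(s))
        for eid, s in pairs
    ]
    return TrustCurve(modality=modality, points=points)


@dataclass(frozen=True)
class BehaviorNorms:
    """Scaling constants for the behavioral sub-scores.

    tau_s: decision-latency scale (s) for ``exp(-latency/tau)``.
    count_scale: half-saturation count c for ``1 / (1 + count/c)``.
    """

    tau_s: float = 5.0
    count_scale: float = 3.0


def score_behavior(coding: BehaviorCoding, norms: BehaviorNorms = BehaviorNorms()) -> float:
    """0-10 behavioral trust score: 10 x mean of five normalized sub-scores.

    Sub-scores: adherence_pct/100; exp(-latency/tau); and 1/(1 + count/c)
    for reliance, interventions and verifications. Monotone: raising any
    count or the latency never increases the score.
    """
    for name in ("reliance", "interventions", "verifications"):
        if getattr(coding, name) < 0:
            raise FieldValidationError(f"{name} must be >= 0")
    sub = np.array(
        [
            coding.adherence_pct / 100.0,
            np.exp(-coding.latency_s / norms.tau_s),
            1.0 / (1.0 + coding.reliance / norms.count_scale),
            1.0 / (1.0 + coding.interventions / norms.count_scale),
            1.0 / (1.0 + coding.verifications / norms.count_scale),
        ]
    )
    return float(np.clip(10.0 * sub.mean(), 0.0, 10.0))


def confusion_counts(labels_a, labels_b, categories) -> np.ndarray:
    cats = list(categories)
    idx = {c: i for i, c in enumerate(cats)}
    m = np.zeros((len(cats), len(cats)), dtype=int)
    for a, b in zip(labels_a, labels_b, strict=True):
        m[idx[a], idx[b]] += 1
    return m


def kappa_from_confusion(matrix: np.ndarray) -> float:
    """Unweighted Cohen's kappa from a square contingency table."""
    m = np.asarray(matrix, dtype=float)
    n = m.sum()
    if n < 2:
        raise InvalidArgumentError("need >= 2 observations")
    po = np.trace(m) / n
    pe = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
    if pe == 1.0:
        raise UndefinedStatisticError("expected agreement p_e = 1; kappa undefined")
    return float((po - pe) / (1.0 - pe))


def interrater_kappa(coder_a, coder_b) -> float:
    """Unweighted Cohen's kappa ``(p_o - p_e) / (1 - p_e)`` between two raters."""
    a = list(coder_a)
    b = list(coder_b)
    if len(a) != len(b):
        raise InvalidArgumentError("label sequences differ in length")
    if len(a) < 2:
        raise InvalidArgumentError("need >= 2 observations")
    cats = sorted(set(a) | set(b), key=str)
    return kappa_from_confusion(confusion_counts(a, b, cats))
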