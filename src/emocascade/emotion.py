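"""Dominant-emotion assignment and emotion summary tables.

Posts carry a 7-way probability vector over the basic-emotion labels
(anger, disgust, fear, joy, sadness, surprise) plus neutral, produced by
an upstream classifier and summing to one. A post's *dominant emotion* is
the label with the highest probability; exact ties (measure zero on real
scores, but possible on constructed input) are broken by a fixed label
order so the assignment is deterministic.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

#: Canonical label order; doubles as the documented tie-break order.
EMOTIONS: tuple[str, ...] = (
    "anger",
    "disgust",
    "fear",
    "joy",
    "neutral",
    "sadness",
    "surprise",
)

#: Emotion labels excluding the neutral baseline (regression dummy set).
NON_NEUTRAL: tuple[str, ...] = tuple(e for e in EMOTIONS if e != "neutral")

#: Column names used for score vectors in event tables.
SCORE_COLUMNS: tuple[str, ...] = tuple(f"score_{e}" for e in EMOTIONS)

SCORE_SUM_TOL = 1e-6


def dominant_emotion(
    scores: Mapping[str, float] | Sequence[float],
    tie_break_order: Sequence[str] = EMOTIONS,
) -> str:
    """Return the label with the highest probability score.

    Parameters
    ----------
    scores
        Mapping from label to probability, or a sequence ordered as
        :data:`EMOTIONS`.
    tie_break_order
        Label order used to resolve exact ties; earlier wins.

    Raises
    ------
    ValueError
        If the vector is all zero, has negative entries, or contains an
        unknown label.
    """
    if isinstance(scores, Mapping):
        unknown = set(scores) - set(EMOTIONS)
        if unknown:
            raise ValueError(f"unknown emotion labels: {sorted(unknown)}")
        vec = {e: float(scores.get(e, 0.0)) for e in EMOTIONS}
    else:
        arr = list(scores)
        if len(arr) != len(EMOTIONS):
            raise ValueError(f"expected {len(EMOTIONS)} scores, got {len(arr)}")
        vec = {e: float(v) for e, v in zip(EMOTIONS, arr)}
    if any(v < 0 for v in vec.values()):
        raise ValueError("emotion scores must be non-negative")
    top = max(vec.values())
    if top <= 0.0:
        raise ValueError("all-zero emotion score vector")
    for label in tie_break_order:
        if vec.get(label, -1.0) == top:
            return label
    raise ValueError("tie_break_order does not cover the maximal label")


def emotion_frequency_table(
    features: pd.DataFrame, group_by: str = "event_label"
) -> pd.DataFrame:
    """Percentage of cascades labelled with each dominant emotion.

    Returns a table with one row per emotion and one column per group plus
    a pooled ``ALL`` column; each column sums to 100 (before rounding).
    """
    if features.empty:
        raise ValueError("features table is empty")
    out: dict[str, pd.Series] = {}
    for group, sub in features.groupby(group_by, sort=True):
        counts = sub["dominant_emotion"].value_counts()
        out[str(group)] = counts.reindex(EMOTIONS, fill_value=0) / len(sub) * 100.0
    pooled = features["dominant_emotion"].value_counts()
    out["ALL"] = pooled.reindex(EMOTIONS, fill_value=0) / len(features) * 100.0
    table = pd.DataFrame(out)
    table.index.name = "emotion"
    return table


def emotion_intensity(
    events: pd.DataFrame, group_by: str = "event_label"
) -> pd.DataFrame:
    """Mean probability score of each emotion per group of posts.

    Computed over all records (originals and reshares alike) by default;
    pass a cascade-level frame to average over cascades instead. Row means
    per group sum to one because each score vector lies on the simplex.
    """
    if events.empty:
        raise ValueError("event table is empty")
    cols = list(SCORE_COLUMNS)
    grouped = events.groupby(group_by, sort=True)[cols].mean()
    grouped.loc["ALL"] = events[cols].mean()
    grouped.columns = list(EMOTIONS)
    return grouped.T.rename_axis("emotion")


def weighted_prf(
    pred_labels: Iterable[str], true_labels: Iterable[str]
) -> tuple[float, float, float]:
    """Support-weighted precision, recall and F1 of a label prediction.

    Per-class scores are weighted by the class's support in the true
    labels, so classes absent from the truth contribute zero weight.
    """
    pred = list(pred_labels)
    true = list(true_labels)
    if len(pred) != len(true):
        raise ValueError(
            f"length mismatch: {len(pred)} predictions vs {len(true)} truths"
        )
    if not true:
        raise ValueError("empty label lists")
    p, r, f, _ = precision_recall_fscore_support(
        true, pred, average="weighted", zero_division=0
    )
    return float(p), float(r), float(f)
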