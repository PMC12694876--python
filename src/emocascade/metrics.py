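"""Per-cascade propagation metrics and the feature table fed to regression.

Five measures characterize how a cascade propagates:

* **size** — number of reshares plus one (the root counts).
* **lifetime** — seconds between the root and the last reshare.
* **median delay** — median gap between consecutive events of the
  cascade's chronological sequence (a cadence / speed measure).
* **time to Nth reshare** — seconds until the Nth reshare (N=5 by
  default); defined only for cascades with at least N reshares.
* **burstiness (CV)** — coefficient of variation sigma/mu of the
  inter-event gaps. CV > 1 means events are more clustered than a
  memoryless (Poisson) process; CV < 1 means more regular spacing.

Undefined metrics are returned as NaN and excluded listwise by the
regression layer. All internal units are seconds; summary tables convert
lifetime to minutes for presentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emotion import EMOTIONS, dominant_emotion
from .ingest import Cascade

#: Feature-table metric columns.
METRIC_COLUMNS = ("size", "lifetime_s", "median_delay_s", "time5rt_s", "cv")

LOG_COVARIATES = {
    "log_followers": "followers",
    "log_friends": "friends",
    "log_statuses": "statuses",
    "log_likes": "likes",
}


def cascade_size(c: Cascade) -> int:
    """Number of reshares plus one."""
    return c.size


def lifetime(c: Cascade) -> float:
    """Seconds between the root post and the last reshare."""
    return float(c.retweet_times[-1] - c.root_time)


def inter_event_delays(c: Cascade, include_root: bool = True) -> np.ndarray:
    """Gaps (seconds) between consecutive events of the cascade sequence.

    With ``include_root`` the root is event zero of the sequence, so the
    gaps telescope to the lifetime. Without it, only reshare-to-reshare
    gaps are returned (empty for a single reshare).
    """
    times = c.retweet_times
    if include_root:
        times = np.concatenate(([c.root_time], times))
    return np.diff(times)


def median_delay(c: Cascade, include_root: bool = True) -> float:
    """Median of the inter-event gaps (NaN when no gaps exist)."""
    gaps = inter_event_delays(c, include_root=include_root)
    if gaps.size == 0:
        return float("nan")
    return float(np.median(gaps))


def time_to_nth_retweet(c: Cascade, n: int = 5) -> float:
    """Seconds from the root to the nth reshare; NaN if fewer exist."""
    if n < 1:
        raise ValueError("n must be >= 1")
    times = c.retweet_times
    if times.size < n:
        return float("nan")
    return float(times[n - 1] - c.root_time)


def burstiness_cv(c: Cascade, include_root: bool = True) -> float:
    """Coefficient of variation sigma/mu of the inter-event gaps.

    Uses the sample standard deviation (denominator length-1). Undefined
    (NaN) when fewer than two gaps exist or the mean gap is zero.
    """
    gaps = inter_event_delays(c, include_root=include_root)
    if gaps.size < 2:
        return float("nan")
    mu = float(np.mean(gaps))
    if mu <= 0.0:
        return float("nan")
    return float(np.std(gaps, ddof=1) / mu)


def cv_of_gaps(gaps: np.ndarray) -> float:
    """CV estimator on a raw gap series (same conventions as above)."""
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size < 2:
        return float("nan")
    mu = float(np.mean(gaps))
    if mu <= 0.0:
        return float("nan")
    return float(np.std(gaps, ddof=1) / mu)


def summarize_features(
    cascades: list[Cascade],
    authors: pd.DataFrame,
    include_root_gaps: bool = True,
    nth: int = 5,
) -> pd.DataFrame:
    """One row per cascade: metrics, dominant emotion, author covariates.

    Count covariates are log(1+x)-transformed (their minima are zero).
    The cascade's emotion is the root post's dominant emotion; reshares
    carry the root's scores by construction.

    Raises ``KeyError`` naming the ids when a root author is missing from
    the author table.
    """
    missing = sorted(
        {c.root["author_id"] for c in cascades} - set(authors.index.astype(str))
    )
    if missing:
        raise KeyError(f"authors missing from covariate table: {missing[:10]}")
    rows = []
    for c in cascades:
        root = c.root
        author = authors.loc[str(root["author_id"])]
        scores = {e: root[f"score_{e}"] for e in EMOTIONS}
        rows.append({
            "cascade_id": root["event_id"],
            "author_id": str(root["author_id"]),
            "event_label": c.event_label,
            "size": cascade_size(c),
            "lifetime_s": lifetime(c),
            "median_delay_s": median_delay(c, include_root=include_root_gaps),
            "time5rt_s": time_to_nth_retweet(c, n=nth),
            "cv": burstiness_cv(c, include_root=include_root_gaps),
            "dominant_emotion": dominant_emotion(scores),
            **{
                name: float(np.log1p(author[src]))
                for name, src in LOG_COVARIATES.items()
            },
            "verified": bool(author["verified"]),
            "word_count": int(root["word_count"]),
            "has_hashtag": bool(root["has_hashtag"]),
        })
    return pd.DataFrame(rows)


def cohort_summary(
    features: pd.DataFrame, group_by: str = "event_label"
) -> pd.DataFrame:
    """Mean and SD of each propagation metric per group and pooled.

    Lifetime is reported in minutes; delays stay in seconds. Groups with
    a single cascade get SD 0 and ``degenerate=True``.
    """
    if features.empty:
        raise ValueError("features table is empty")
    work = features.assign(lifetime_min=features["lifetime_s"] / 60.0)
    metrics = ["size", "lifetime_min", "median_delay_s", "time5rt_s", "cv"]

    def agg(sub: pd.DataFrame) -> dict:
        row: dict = {"n": len(sub), "degenerate": len(sub) == 1}
        for m in metrics:
            row[f"{m}_mean"] = float(sub[m].mean())
            sd = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
            row[f"{m}_sd"] = 0.0 if np.isnan(sd) else sd
        return row

    rows = {str(g): agg(sub) for g, sub in work.groupby(group_by, sort=True)}
    rows["ALL"] = agg(work)
    out = pd.DataFrame(rows).T
    out.index.name = group_by
    return out
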