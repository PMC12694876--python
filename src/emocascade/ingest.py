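"""Reading, validating and assembling reshare event streams.

An event stream is a flat table with one record per original post or
reshare. Records whose ``root_id`` is empty are originals (cascade roots);
every other record reshares the original named by its ``root_id``. A
*cascade* is a root plus the time-ordered series of its reshares inside a
fixed observation window after the triggering event (default 21 days).
Only roots with at least one reshare form a cascade (size >= 2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .emotion import SCORE_COLUMNS, SCORE_SUM_TOL

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400.0

#: Required event-table columns (besides the 7 score columns).
EVENT_COLUMNS: tuple[str, ...] = (
    "event_id",
    "root_id",
    "author_id",
    "time_s",
    "word_count",
    "has_hashtag",
    "event_label",
)

AUTHOR_COLUMNS: tuple[str, ...] = (
    "author_id",
    "followers",
    "friends",
    "statuses",
    "likes",
    "verified",
)

_TRUTHY = {"true", "t", "1", "yes", "y"}
_FALSY = {"false", "f", "0", "no", "n", ""}


class SchemaError(ValueError):
    """The input table does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a value-level invariant (with row numbers)."""


def _parse_bool(series: pd.Series, name: str) -> pd.Series:
    """Accept true/false/0/1 dialects for a boolean column."""
    if series.dtype == bool:
        return series
    def conv(v: object) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, float, np.integer, np.floating)):
            return bool(int(v))
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise ValidationError(f"column {name!r}: cannot parse boolean {v!r}")
    return series.map(conv)


def validate_events(
    events: pd.DataFrame, score_policy: str = "strict"
) -> pd.DataFrame:
    """Validate (and under ``renormalize`` repair) an event table.

    ``score_policy``:

    * ``strict`` — reject rows whose emotion scores do not sum to one
      within tolerance (rows reported by position).
    * ``renormalize`` — rescale each score vector to sum to exactly one.
    """
    if score_policy not in ("strict", "renormalize"):
        raise ValueError(f"unknown score policy {score_policy!r}")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"missing event columns: {missing}")
    unknown_scores = [
        c for c in events.columns
        if c.startswith("score_") and c not in SCORE_COLUMNS
    ]
    if unknown_scores:
        raise SchemaError(f"unknown emotion score columns: {unknown_scores}")
    missing_scores = [c for c in SCORE_COLUMNS if c not in events.columns]
    if missing_scores:
        raise SchemaError(f"missing emotion score columns: {missing_scores}")

    df = events.copy()
    df["event_id"] = df["event_id"].astype(str)
    df["root_id"] = df["root_id"].fillna("").astype(str)
    df["author_id"] = df["author_id"].astype(str)
    df["event_label"] = df["event_label"].astype(str)
    df["time_s"] = pd.to_numeric(df["time_s"])
    df["word_count"] = pd.to_numeric(df["word_count"]).astype(int)
    df["has_hashtag"] = _parse_bool(df["has_hashtag"], "has_hashtag")
    for c in SCORE_COLUMNS:
        df[c] = pd.to_numeric(df[c])

    if not np.isfinite(df["time_s"].to_numpy()).all():
        bad = np.flatnonzero(~np.isfinite(df["time_s"].to_numpy()))
        raise ValidationError(f"non-finite time_s at rows {bad[:10].tolist()}")
    scores = df[list(SCORE_COLUMNS)].to_numpy(dtype=float)
    if (scores < 0).any():
        bad = np.flatnonzero((scores < 0).any(axis=1))
        raise ValidationError(f"negative emotion scores at rows {bad[:10].tolist()}")
    sums = scores.sum(axis=1)
    off = np.abs(sums - 1.0) > SCORE_SUM_TOL
    if off.any():
        if score_policy == "strict":
            bad = np.flatnonzero(off)
            raise ValidationError(
                f"emotion scores do not sum to 1 at rows {bad[:10].tolist()} "
                f"(sums e.g. {sums[bad[:3]].tolist()}); "
                "use score_policy='renormalize' to rescale"
            )
        zero = sums <= 0
        if zero.any():
            raise ValidationError(
                f"all-zero emotion scores at rows {np.flatnonzero(zero)[:10].tolist()}"
            )
        df.loc[:, list(SCORE_COLUMNS)] = scores / sums[:, None]
    dup = df["event_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate event_id values: {df.loc[dup, 'event_id'].head().tolist()}"
        )
    return df


def read_events(
    path: str | Path, format: str | None = None, score_policy: str = "strict"
) -> pd.DataFrame:
    """Read an event stream from JSONL or CSV and validate it.

    ``format`` is inferred from the file suffix when omitted. Malformed
    JSONL lines are reported with their 1-based line numbers.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        rows, errors = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    errors.append((lineno, str(exc)))
        if errors:
            raise ValidationError(f"malformed JSONL lines: {errors[:10]}")
        df = pd.DataFrame(rows)
    elif fmt == "csv":
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if df.empty:
        raise SchemaError(f"{path}: no records")
    return validate_events(df, score_policy=score_policy)


def write_events(events: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write an event table as JSONL (default) or CSV."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    cols = list(EVENT_COLUMNS) + list(SCORE_COLUMNS)
    df = events[cols]
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                rec["has_hashtag"] = bool(rec["has_hashtag"])
                fh.write(json.dumps(rec) + "\n")
    elif fmt == "csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_authors(path: str | Path) -> pd.DataFrame:
    """Read the author covariate table (CSV), indexed by ``author_id``."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    if df.empty:
        logger.warning("author table %s is empty", path)
        return pd.DataFrame(columns=AUTHOR_COLUMNS[1:]).rename_axis("author_id")
    missing = [c for c in AUTHOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing author columns: {missing}")
    df["author_id"] = df["author_id"].astype(str)
    if df["author_id"].duplicated().any():
        dups = df.loc[df["author_id"].duplicated(), "author_id"].head().tolist()
        raise ValidationError(f"duplicate author_id values: {dups}")
    for c in ("followers", "friends", "statuses", "likes"):
        df[c] = pd.to_numeric(df[c]).astype(np.int64)
        if (df[c] < 0).any():
            raise ValidationError(f"negative values in author column {c!r}")
    if (df["statuses"] < 1).any():
        raise ValidationError("author statuses must be >= 1")
    df["verified"] = _parse_bool(df["verified"], "verified")
    return df.set_index("author_id")


def write_authors(authors: pd.DataFrame, path: str | Path) -> None:
    authors.reset_index().to_csv(path, index=False)


@dataclass
class Cascade:
    """A root post plus its time-ordered reshares.

    ``retweets`` is sorted by ``(time_s, event_id)``; ties in time are
    legal (zero gaps occur in real streams) and broken by id so ordering
    is deterministic.
    """

    root: dict
    retweets: pd.DataFrame
    event_label: str
    _times: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.retweets) + 1

    @property
    def root_time(self) -> float:
        return float(self.root["time_s"])

    @property
    def retweet_times(self) -> np.ndarray:
        if self._times is None:
            self._times = self.retweets["time_s"].to_numpy(dtype=float)
        return self._times


def build_cascades(
    events: pd.DataFrame,
    event_start_s: float | Mapping[str, float],
    window_days: float = 21,
) -> list[Cascade]:
    """Group validated events into cascades under the window rule.

    Events outside ``[start, start + window_days*86400]`` (per event
    label) are dropped, as are reshares whose root is absent from the
    retained records (orphans); both counts are logged. Roots without any
    retained reshare are excluded, so every cascade has size >= 2.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    if isinstance(event_start_s, Mapping):
        starts = events["event_label"].map(event_start_s)
        if starts.isna().any():
            missing = sorted(set(events.loc[starts.isna(), "event_label"]))
            raise ValueError(f"no event_start_s for labels: {missing}")
        starts = starts.to_numpy(dtype=float)
    else:
        starts = np.full(len(events), float(event_start_s))
    t = events["time_s"].to_numpy(dtype=float)
    in_window = (t >= starts) & (t <= starts + window_days * SECONDS_PER_DAY)
    n_dropped_window = int((~in_window).sum())
    if n_dropped_window:
        logger.info("dropped %d events outside the observation window", n_dropped_window)
    df = events.loc[in_window]

    is_root = df["root_id"] == ""
    roots = df.loc[is_root]
    retweets = df.loc[~is_root]
    root_ids = set(roots["event_id"])
    orphan = ~retweets["root_id"].isin(root_ids)
    if orphan.any():
        logger.info("dropped %d orphan reshares (root absent or out of window)",
                    int(orphan.sum()))
    retweets = retweets.loc[~orphan].sort_values(
        ["time_s", "event_id"], kind="mergesort"
    )

    cascades: list[Cascade] = []
    groups = dict(tuple(retweets.groupby("root_id", sort=False)))
    for root in roots.sort_values("event_id").to_dict(orient="records"):
        group = groups.get(root["event_id"])
        if group is None or group.empty:
            continue
        early = group["time_s"].to_numpy(dtype=float) < root["time_s"]
        if early.any():
            logger.info(
                "dropped %d reshares earlier than their root %s",
                int(early.sum()), root["event_id"],
            )
            group = group.loc[~early]
            if group.empty:
                continue
        cascades.append(
            Cascade(root=root, retweets=group.reset_index(drop=True),
                    event_label=str(root["event_label"]))
        )
    return cascades


def filter_by_size(cascades: list[Cascade], min_size: int) -> list[Cascade]:
    """Keep cascades of at least ``min_size`` posts, preserving order.

    ``min_size=6`` is the "at least five retweets" regime used for the
    speed and burstiness analyses.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2 (every cascade has a reshare)")
    return [c for c in cascades if c.size >= min_size]


def flatten_cascades(cascades: list[Cascade]) -> pd.DataFrame:
    """Flatten cascades back to an event table (roots first per cascade)."""
    frames = []
    for c in cascades:
        frames.append(pd.DataFrame([c.root]))
        frames.append(c.retweets)
    if not frames:
        return pd.DataFrame(columns=list(EVENT_COLUMNS) + list(SCORE_COLUMNS))
    return pd.concat(frames, ignore_index=True)[
        list(EVENT_COLUMNS) + list(SCORE_COLUMNS)
    ]
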