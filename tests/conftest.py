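"""Shared fixtures: hand-built cascades and a small synthetic scenario."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import emocascade as ec
from emocascade.emotion import EMOTIONS

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_cascade(
    offsets,
    root_time: float = 0.0,
    dominant: str = "neutral",
    event_label: str = "DC",
    author_id: str = "a0",
    root_id: str = "root",
) -> ec.Cascade:
    """Build a Cascade directly from reshare offsets (seconds from root)."""
    offsets = np.asarray(offsets, dtype=float)
    scores = {f"score_{e}": (0.94 if e == dominant else 0.01) for e in EMOTIONS}
    root = {
        "event_id": root_id, "root_id": "", "author_id": author_id,
        "time_s": root_time, "word_count": 10, "has_hashtag": False,
        "event_label": event_label, **scores,
    }
    retweets = pd.DataFrame({
        "event_id": [f"{root_id}r{j:05d}" for j in range(len(offsets))],
        "root_id": root_id,
        "author_id": author_id,
        "time_s": root_time + offsets,
        "word_count": 10,
        "has_hashtag": False,
        "event_label": event_label,
        **{k: v for k, v in scores.items()},
    })
    return ec.Cascade(root=root, retweets=retweets, event_label=event_label)


@pytest.fixture(scope="session")
def small_scenario():
    """A 1,500-cascade balanced synthetic scenario, fully assembled."""
    config = ec.ScenarioConfig.recovery(n_cascades=1500, seed=42)
    events, authors, truth = ec.gen_event_stream(config)
    cascades = ec.build_cascades(events, 0.0, config.window_days)
    features = ec.summarize_features(cascades, authors)
    return {
        "config": config, "events": events, "authors": authors,
        "truth": truth, "cascades": cascades, "features": features,
    }
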