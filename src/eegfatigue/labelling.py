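"""Threshold derivation from subjective scores and the labelled modelling table.

Labels are binary and come only from scores: a row is fatigued (1) iff its
score is greater than or equal to the applicable threshold.  The physical
threshold is the mean of all subjects' physical-event (s2) scores in the
highest-intensity session; the mental threshold is the mean of all
subjects' mental-event (s3) scores across all sessions.  Baseline (s1)
rows are compared against the minimum of the two thresholds (a
configurable convention; with realistic baselines it yields label 0).

Only the task events s1, s2, s3 contribute modelling rows, one per
(subject, session, task event): 12 subjects x 3 sessions -> 108 rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from eegfatigue.constants import (
    CHANNELS,
    FEATURE_NAMES,
    TASK_CONTEXT,
    TASK_EVENTS,
    canonical_channels,
)
from eegfatigue.errors import ThresholdError

logger = logging.getLogger(__name__)

#: Thresholds reported for the reference dataset; usable via
#: ``LabelPolicy.pinned()`` instead of re-deriving from scores.
REFERENCE_PHYSICAL_THRESHOLD = 45.0
REFERENCE_MENTAL_THRESHOLD = 36.0


@dataclass(frozen=True)
class LabelPolicy:
    """Fatigue thresholds; the rule is inclusive (score >= threshold -> 1)."""

    physical_threshold: float
    mental_threshold: float
    #: How baseline (s1) rows are labelled: "min" compares the baseline
    #: score against min(physical, mental) threshold.
    baseline_rule: str = "min"

    def __post_init__(self) -> None:
        for name in ("physical_threshold", "mental_threshold"):
            v = getattr(self, name)
            if not pd.notna(v) or v != v or abs(v) == float("inf"):
                raise ThresholdError(f"{name} must be finite, got {v}")
        if self.baseline_rule != "min":
            raise ThresholdError(f"unknown baseline rule {self.baseline_rule!r}")

    @property
    def baseline_threshold(self) -> float:
        return min(self.physical_threshold, self.mental_threshold)

    @classmethod
    def pinned(cls) -> "LabelPolicy":
        return cls(REFERENCE_PHYSICAL_THRESHOLD, REFERENCE_MENTAL_THRESHOLD)

    def to_metadata(self) -> dict:
        return {
            "physical_threshold": self.physical_threshold,
            "mental_threshold": self.mental_threshold,
            "baseline_rule": self.baseline_rule,
            "rule": "label 1 iff score >= threshold",
        }


def derive_threshold(scores: pd.DataFrame, event: str, sessions=None) -> float:
    """Arithmetic mean of the scores matching (event, sessions).

    ``scores`` has columns subject, session, event, score.  ``sessions``
    of ``None`` selects all sessions.
    """
    selected = scores[scores["event"] == event]
    if sessions is not None:
        selected = selected[selected["session"].isin(list(sessions))]
    if selected.empty:
        raise ThresholdError(
            f"no scores match event={event!r}, sessions={sessions!r}"
        )
    return float(selected["score"].mean())


def derive_policy(scores: pd.DataFrame, physical_sessions=None) -> LabelPolicy:
    """Derive both thresholds from a cohort's scores.

    The physical threshold uses s2 scores from ``physical_sessions``
    (default: the highest session index present, i.e. the high-intensity
    day); the mental threshold uses s3 scores from all sessions.
    """
    if physical_sessions is None:
        physical_sessions = (int(scores["session"].max()),)
    physical = derive_threshold(scores, "s2", sessions=physical_sessions)
    mental = derive_threshold(scores, "s3", sessions=None)
    return LabelPolicy(physical_threshold=physical, mental_threshold=mental)


def assign_label(score: float, threshold: float) -> int:
    """1 iff ``score >= threshold`` (inclusive at the boundary)."""
    return int(score >= threshold)


def build_modelling_table(
    feature_table: pd.DataFrame,
    scores: pd.DataFrame,
    policy: LabelPolicy,
    channel_set=CHANNELS,
) -> pd.DataFrame:
    """One labelled row per (subject, session, task event).

    Feature blocks of the selected channels are concatenated in canonical
    channel order (columns ``<channel>_<feature>``).  Rows with a missing
    score or an incomplete channel block are excluded with a warning.
    """
    channel_set = canonical_channels(channel_set)
    thresholds = {
        "s1": policy.baseline_threshold,
        "s2": policy.physical_threshold,
        "s3": policy.mental_threshold,
    }
    score_map = {
        (r.subject, r.session, r.event): r.score for r in scores.itertuples()
    }
    feature_map = {
        (r["subject"], r["session"], r["channel"], r["event"]): r
        for _, r in feature_table.iterrows()
    }

    keys = sorted(
        {(r["subject"], r["session"]) for _, r in feature_table.iterrows()},
        key=lambda k: (str(k[0]), int(k[1])),
    )
    rows = []
    n_dropped = 0
    for subject, session in keys:
        for event in TASK_EVENTS:
            score = score_map.get((subject, session, event))
            blocks = [
                feature_map.get((subject, session, ch, event)) for ch in channel_set
            ]
            if score is None or any(b is None for b in blocks):
                n_dropped += 1
                continue
            row = {
                "subject": subject,
                "session": session,
                "task_event": event,
                "context": TASK_CONTEXT[event],
                "score": float(score),
                "label": assign_label(float(score), thresholds[event]),
            }
            for ch, block in zip(channel_set, blocks):
                for name in FEATURE_NAMES:
                    row[f"{ch}_{name}"] = block[name]
            rows.append(row)
    if n_dropped:
        logger.warning(
            "modelling table: dropped %d row(s) with missing scores or features",
            n_dropped,
        )
    return pd.DataFrame(rows)
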