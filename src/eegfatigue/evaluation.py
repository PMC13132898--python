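"""Metrics (including the cost-weighted Score), channel-combination
ranking, feature-group ablation and task-stratified confusion analysis.

The Score weights recall (detecting fatigue) above specificity:

    Score = (w * recall + (1 - w) * specificity) * 100,   default w = 0.8

so missed-fatigue errors cost more than false alarms.  Confusion counts
are pooled over all LOSO folds before metrics are computed; displayed /
ranked Scores are rounded half-away-from-zero to integers, while the
unrounded values are kept for ranking and tie detection.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eegfatigue.constants import (
    CHANNELS,
    CONTEXTS,
    FEATURE_GROUPS,
    canonical_channels,
    feature_columns,
)
from eegfatigue.errors import ConfigurationError, MetricError
from eegfatigue.modelling import FoldPrediction, fit_predict_loso

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT = 0.8

#: The seven ablation configurations, in presentation order.
ABLATION_CONFIGS = (
    "all",
    "statistical",
    "frequency",
    "entropy",
    "entropy+frequency",
    "entropy+statistical",
    "statistical+frequency",
)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion tallies; the positive class is fatigued (label 1)."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    def to_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from binary label arrays."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise MetricError("cannot tally an empty prediction set")
    if y_true.shape != y_pred.shape:
        raise MetricError("y_true and y_pred have different lengths")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def pooled_confusion(predictions: list[FoldPrediction]) -> ConfusionCounts:
    """Pool counts over all (non-flagged) LOSO folds."""
    usable = [p for p in predictions if not p.flagged]
    if not usable:
        raise MetricError("no usable fold predictions")
    y_true = np.concatenate([p.y_true for p in usable])
    y_pred = np.concatenate([p.y_pred for p in usable])
    return confusion_counts(y_true, y_pred)


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, F1, recall, specificity and the weighted Score."""

    accuracy: float
    f1: float
    recall: float
    specificity: float
    w: float
    score: float  # unrounded, in [0, 100]

    @property
    def score_rounded(self) -> int:
        return round_half_away(self.score)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "recall": self.recall,
            "specificity": self.specificity,
            "w": self.w,
            "score": self.score,
            "score_rounded": self.score_rounded,
        }


def score_from_rates(recall: float, specificity: float, w: float = DEFAULT_WEIGHT) -> float:
    """The weighted Score from already-computed rates, in [0, 100]."""
    if not 0 <= w <= 1:
        raise MetricError(f"w must be in [0, 1], got {w}")
    return (w * recall + (1.0 - w) * specificity) * 100.0


def compute_metrics(counts: ConfusionCounts, w: float = DEFAULT_WEIGHT) -> MetricSet:
    """Derive the metric set from pooled confusion counts.

    If a rate's denominator is zero (no positives, or no negatives) the
    affected rate and the Score are NaN-flagged rather than silently
    computed.
    """
    if counts.total == 0:
        raise MetricError("cannot compute metrics from zero counts")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    recall = counts.tp / pos if pos > 0 else float("nan")
    specificity = counts.tn / neg if neg > 0 else float("nan")
    if pos == 0 or neg == 0:
        logger.warning("one class absent: recall/specificity/Score flagged undefined")
        score = float("nan")
    else:
        score = score_from_rates(recall, specificity, w)
    accuracy = (counts.tp + counts.tn) / counts.total
    f1_den = 2 * counts.tp + counts.fp + counts.fn
    f1 = 2 * counts.tp / f1_den if f1_den > 0 else float("nan")
    return MetricSet(
        accuracy=accuracy, f1=f1, recall=recall,
        specificity=specificity, w=w, score=score,
    )


# ---------------------------------------------------------------------------
# Channel combinations
# ---------------------------------------------------------------------------

def enumerate_channel_combos(channels=CHANNELS) -> list[tuple[str, ...]]:
    """All non-empty channel subsets, ordered by size then montage order."""
    channels = canonical_channels(channels)
    if not channels:
        raise ConfigurationError("channel list must be non-empty")
    if len(channels) > 8:
        raise ConfigurationError("at most 8 channels supported")
    combos: list[tuple[str, ...]] = []
    for size in range(1, len(channels) + 1):
        combos.extend(itertools.combinations(channels, size))
    return combos


@dataclass
class ChannelComboResult:
    """Pooled LOSO evaluation of one channel subset."""

    channels: tuple[str, ...]
    counts: ConfusionCounts
    metrics: MetricSet
    predictions: list[FoldPrediction] = field(default_factory=list, repr=False)
    rank: int | None = None


def evaluate_combo(
    combo,
    table: pd.DataFrame,
    family: str,
    params: dict,
    w: float = DEFAULT_WEIGHT,
    seed: int = 0,
    k_neighbors: int = 5,
) -> ChannelComboResult:
    """LOSO-evaluate one channel subset with the frozen hyperparameters."""
    combo = canonical_channels(combo)
    cols = feature_columns(combo)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ConfigurationError(f"modelling table lacks feature column(s) {missing[:4]}...")
    loso = fit_predict_loso(
        table, cols, family, params, seed=seed, k_neighbors=k_neighbors
    )
    counts = pooled_confusion(loso.predictions)
    return ChannelComboResult(
        channels=combo,
        counts=counts,
        metrics=compute_metrics(counts, w=w),
        predictions=loso.predictions,
    )


def evaluate_all_combos(
    table: pd.DataFrame,
    family: str,
    params: dict,
    channels=CHANNELS,
    w: float = DEFAULT_WEIGHT,
    seed: int = 0,
    k_neighbors: int = 5,
) -> list[ChannelComboResult]:
    return [
        evaluate_combo(combo, table, family, params, w=w, seed=seed,
                       k_neighbors=k_neighbors)
        for combo in enumerate_channel_combos(channels)
    ]


def rank_combos(results: list[ChannelComboResult]) -> list[ChannelComboResult]:
    """Rank descending by unrounded Score; ties by recall, then fewer
    channels, then montage order.  Input order never matters."""
    if not results:
        raise ConfigurationError("nothing to rank")

    def sort_key(res: ChannelComboResult):
        order = tuple(CHANNELS.index(c) for c in res.channels)
        return (-res.metrics.score, -res.metrics.recall, len(res.channels), order)

    ranked = sorted(results, key=sort_key)
    for i, res in enumerate(ranked):
        res.rank = i + 1
    return ranked


def ranking_table(ranked: list[ChannelComboResult]) -> pd.DataFrame:
    """Heatmap-style table: one row per combo with all metrics."""
    rows = []
    for res in ranked:
        row = {"rank": res.rank, "channels": "+".join(res.channels),
               "n_channels": len(res.channels)}
        row.update(res.metrics.to_dict())
        row.update(res.counts.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature-group ablation
# ---------------------------------------------------------------------------

def _ablation_features(config: str) -> list[str]:
    if config == "all":
        groups = list(FEATURE_GROUPS)
    else:
        groups = config.split("+")
    unknown = [g for g in groups if g not in FEATURE_GROUPS]
    if unknown:
        raise ConfigurationError(f"unknown feature group(s) {unknown}")
    return [name for g in groups for name in FEATURE_GROUPS[g]]


def ablate_feature_groups(
    combo,
    table: pd.DataFrame,
    family: str,
    params: dict,
    w: float = DEFAULT_WEIGHT,
    seed: int = 0,
    k_neighbors: int = 5,
) -> pd.DataFrame:
    """Evaluate the seven feature-group configurations on one channel set
    under the identical LOSO protocol and frozen hyperparameters."""
    combo = canonical_channels(combo)
    rows = []
    for config in ABLATION_CONFIGS:
        names = _ablation_features(config)
        cols = [f"{ch}_{name}" for ch in combo for name in names]
        loso = fit_predict_loso(
            table, cols, family, params, seed=seed, k_neighbors=k_neighbors
        )
        metrics = compute_metrics(pooled_confusion(loso.predictions), w=w)
        row = {"feature_group": config, "n_features": len(cols)}
        row.update(metrics.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Task-stratified confusion analysis
# ---------------------------------------------------------------------------

def stratify_by_task(predictions: list[FoldPrediction]) -> dict[str, ConfusionCounts]:
    """Per-context confusion counts plus the pooled tally.

    The pooled counts equal the element-wise sum across contexts by
    construction; every prediction must carry a context tag.
    """
    usable = [p for p in predictions if not p.flagged]
    if not usable:
        raise MetricError("no usable fold predictions")
    y_true = np.concatenate([p.y_true for p in usable])
    y_pred = np.concatenate([p.y_pred for p in usable])
    contexts = np.concatenate([p.contexts for p in usable])
    known = set(CONTEXTS)
    bad = [c for c in np.unique(contexts) if c not in known]
    if bad:
        raise MetricError(f"missing/unknown context tag(s): {bad}")
    out: dict[str, ConfusionCounts] = {}
    for ctx in CONTEXTS:
        mask = contexts == ctx
        if mask.any():
            out[ctx] = confusion_counts(y_true[mask], y_pred[mask])
        else:
            out[ctx] = ConfusionCounts()
    out["pooled"] = confusion_counts(y_true, y_pred)
    return out
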