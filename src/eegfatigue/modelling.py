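"""Subject-independent classifier training.

Leave-one-subject-out (LOSO) folds, training-fold-only minority
oversampling (SMOTE-style convex interpolation between minority
neighbours), exhaustive hyperparameter grid search for three classifier
families, and base-classifier selection with recall as the tie-breaker.

Features are standardised with training-fold statistics only, and
synthetic minority rows are created after standardisation; test folds
only ever contain original rows of the held-out subject.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from eegfatigue._seeds import child_seed, rng_for
from eegfatigue.errors import ConfigurationError, OversamplingError

logger = logging.getLogger(__name__)

#: Documented family order, used as the final tie-break.
FAMILY_ORDER = ("logistic", "gradient-boosting", "svm")

#: Exhaustive hyperparameter grids per family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {
        "C": [0.1, 1, 10, 100],
        "penalty": ["l1", "l2"],
        "solver": ["liblinear", "lbfgs"],
    },
    "gradient-boosting": {
        "learning_rate": [0.01, 0.1, 1],
        "n_estimators": [50, 100, 300],
        "max_depth": [3, 5, 7],
    },
    "svm": {
        "C": [0.1, 1, 5, 10],
        "gamma": [0.1, 1, 10],
        "coef0": [0.0, 0.5, 1.0],
        "kernel": ["linear", "rbf", "poly"],
    },
}


# ---------------------------------------------------------------------------
# LOSO folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    """One LOSO fold: positional indices into the modelling table."""

    subject: str
    train_index: np.ndarray
    test_index: np.ndarray


def loso_folds(table: pd.DataFrame) -> list[Fold]:
    """One fold per subject; folds partition the table."""
    subjects = sorted(map(str, table["subject"].unique()))
    if len(subjects) < 2:
        raise ConfigurationError(
            f"leave-one-subject-out needs >= 2 subjects, got {len(subjects)}"
        )
    positions = np.arange(len(table))
    subject_col = table["subject"].astype(str).to_numpy()
    folds = []
    for subject in subjects:
        mask = subject_col == subject
        folds.append(Fold(subject, positions[~mask], positions[mask]))
    return folds


# ---------------------------------------------------------------------------
# Minority oversampling
# ---------------------------------------------------------------------------

def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority interpolation.

    Each synthetic sample is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``,
    between a random minority row and one of its ``k`` nearest minority
    neighbours (Euclidean).  Returns ``(X_out, y_out, synthetic_mask)``
    where the mask flags generated rows.  Balanced input is returned
    unchanged; a minority class with fewer than 2 members is an error;
    ``k`` is reduced (with a warning) when the minority is small.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise OversamplingError(f"expected 2 classes, got {list(classes)}")
    if counts[0] == counts[1]:
        return X, y, np.zeros(len(y), dtype=bool)
    minority = classes[np.argmin(counts)]
    n_minority = int(counts.min())
    n_needed = int(counts.max() - counts.min())
    if n_minority < 2:
        raise OversamplingError(
            f"minority class {minority!r} has {n_minority} sample(s); need >= 2"
        )
    if k_neighbors >= n_minority:
        k = n_minority - 1
        logger.warning(
            "reducing k_neighbors from %d to %d (minority size %d)",
            k_neighbors, k, n_minority,
        )
    else:
        k = k_neighbors

    Xm = X[y == minority]
    # pairwise Euclidean distances within the minority class
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]

    rng = rng_for(seed, "smote")
    base_idx = rng.integers(0, n_minority, size=n_needed)
    nn_pick = rng.integers(0, k, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    bases = Xm[base_idx]
    neighbours = Xm[nn[base_idx, nn_pick]]
    synthetic = bases + u[:, None] * (neighbours - bases)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    mask = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(n_needed, dtype=bool)])
    return X_out, y_out, mask


# ---------------------------------------------------------------------------
# Estimators and candidate canonicalisation
# ---------------------------------------------------------------------------

def make_estimator(family: str, params: dict, seed: int = 0):
    seed = int(seed) % (2**31)  # sklearn accepts 32-bit random_state only
    if family == "logistic":
        params = dict(params)
        # grids speak 'penalty'; recent sklearn wants l1_ratio instead
        penalty = params.pop("penalty", None)
        if penalty is not None:
            params["l1_ratio"] = {"l1": 1.0, "l2": 0.0}[penalty]
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if family == "gradient-boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "svm":
        return SVC(random_state=seed, **params)
    raise ConfigurationError(f"unknown classifier family {family!r}")


def candidate_status(family: str, params: dict) -> tuple[bool, dict]:
    """(valid, canonical_params) for one grid candidate.

    Invalid combinations (l1 penalty with the lbfgs solver) are flagged;
    hyperparameters ignored by the chosen kernel (gamma for linear, coef0
    for linear/rbf) are dropped from the canonical form so duplicate
    candidates are fitted once.
    """
    params = dict(params)
    if family == "logistic":
        if params.get("penalty") == "l1" and params.get("solver") == "lbfgs":
            return False, params
        return True, params
    if family == "svm":
        kernel = params.get("kernel")
        canonical = dict(params)
        if kernel == "linear":
            canonical.pop("gamma", None)
            canonical.pop("coef0", None)
        elif kernel == "rbf":
            canonical.pop("coef0", None)
        return True, canonical
    return True, params


def enumerate_grid(grid: dict[str, list]) -> list[dict]:
    """Cartesian product of the grid, in deterministic key order."""
    keys = list(grid)
    return [dict(zip(keys, values)) for values in itertools.product(*(grid[k] for k in keys))]


# ---------------------------------------------------------------------------
# LOSO fit/predict
# ---------------------------------------------------------------------------

@dataclass
class FoldPrediction:
    """Held-out predictions of one LOSO fold."""

    subject: str
    row_index: np.ndarray         # positional indices of the test rows
    y_true: np.ndarray
    y_pred: np.ndarray
    contexts: np.ndarray
    n_synthetic_train: int = 0
    flagged: bool = False         # degenerate training fold


@dataclass
class LosoResult:
    predictions: list[FoldPrediction] = field(default_factory=list)
    n_flagged_folds: int = 0

    @property
    def y_true(self) -> np.ndarray:
        return np.concatenate([p.y_true for p in self.predictions])

    @property
    def y_pred(self) -> np.ndarray:
        return np.concatenate([p.y_pred for p in self.predictions])


def _standardise(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def fit_predict_loso(
    table: pd.DataFrame,
    feature_cols: list[str],
    family: str,
    params: dict,
    seed: int = 0,
    k_neighbors: int = 5,
    oversample: bool = True,
) -> LosoResult:
    """Full LOSO pass: standardise, oversample (train only), fit, predict.

    Standardisation statistics come from the original training rows only;
    synthetic minority rows are interpolated in standardised space and
    never reach a test fold.  A training fold with a single class is
    flagged and skipped, not silently scored.
    """
    X_all = table[feature_cols].to_numpy(dtype=float)
    y_all = table["label"].to_numpy(dtype=int)
    contexts = table["context"].to_numpy()
    result = LosoResult()
    for fold_i, fold in enumerate(loso_folds(table)):
        X_train, y_train = X_all[fold.train_index], y_all[fold.train_index]
        X_test, y_test = X_all[fold.test_index], y_all[fold.test_index]
        if len(np.unique(y_train)) < 2:
            logger.warning("fold %s: single-class training data; flagged", fold.subject)
            result.predictions.append(
                FoldPrediction(
                    subject=fold.subject,
                    row_index=fold.test_index,
                    y_true=y_test,
                    y_pred=np.full(len(y_test), -1, dtype=int),
                    contexts=contexts[fold.test_index],
                    flagged=True,
                )
            )
            result.n_flagged_folds += 1
            continue
        X_train, X_test = _standardise(X_train, X_test)
        n_synth = 0
        if oversample:
            X_train, y_train, synth_mask = smote_oversample(
                X_train, y_train, k_neighbors=k_neighbors,
                seed=child_seed(seed, fold_i),
            )
            n_synth = int(synth_mask.sum())
        est = make_estimator(family, params, seed=child_seed(seed, fold_i, "fit"))
        est.fit(X_train, y_train)
        y_pred = est.predict(X_test)
        result.predictions.append(
            FoldPrediction(
                subject=fold.subject,
                row_index=fold.test_index,
                y_true=y_test,
                y_pred=np.asarray(y_pred, dtype=int),
                contexts=contexts[fold.test_index],
                n_synthetic_train=n_synth,
            )
        )
    return result


# ---------------------------------------------------------------------------
# Grid search and base-classifier selection
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    family: str
    best_params: dict
    best_objective: float
    candidates: pd.DataFrame   # one row per grid candidate (duplicates marked)
    best_metrics: dict


def grid_search_loso(
    family: str,
    grid: dict[str, list],
    table: pd.DataFrame,
    feature_cols: list[str],
    w: float = 0.8,
    objective: str = "score",
    seed: int = 0,
    k_neighbors: int = 5,
) -> GridSearchResult:
    """Evaluate every grid candidate by full LOSO with in-fold oversampling.

    The objective is the pooled-confusion metric named by ``objective``
    ("score" by default: the recall-weighted Score at weight ``w``).
    All candidate results are retained; equivalent candidates (canonical
    duplicates) are fitted once and share their metrics.
    """
    from eegfatigue.evaluation import compute_metrics, pooled_confusion

    candidates = enumerate_grid(grid)
    if not candidates:
        raise ConfigurationError("empty hyperparameter grid")
    cache: dict[str, dict] = {}
    rows = []
    best = None
    for cand in candidates:
        valid, canonical = candidate_status(family, cand)
        key = json.dumps(canonical, sort_keys=True)
        row = {"family": family, "params": json.dumps(cand, sort_keys=True),
               "canonical": key, "valid": valid, "duplicate": key in cache}
        if not valid:
            row.update(accuracy=np.nan, f1=np.nan, recall=np.nan,
                       specificity=np.nan, score=np.nan, objective=np.nan,
                       n_flagged_folds=0)
            rows.append(row)
            logger.info("skipping invalid candidate %s: %s", family, cand)
            continue
        if key not in cache:
            loso = fit_predict_loso(
                table, feature_cols, family, canonical,
                seed=seed, k_neighbors=k_neighbors,
            )
            counts = pooled_confusion(loso.predictions)
            metrics = compute_metrics(counts, w=w)
            cache[key] = {
                "accuracy": metrics.accuracy, "f1": metrics.f1,
                "recall": metrics.recall, "specificity": metrics.specificity,
                "score": metrics.score,
                "n_flagged_folds": loso.n_flagged_folds,
            }
        stats = cache[key]
        obj = stats[objective]
        if stats["n_flagged_folds"] > 0:
            logger.warning(
                "candidate %s %s had %d flagged fold(s)", family, cand,
                stats["n_flagged_folds"],
            )
        row.update(**stats, objective=obj)
        rows.append(row)
        if np.isfinite(obj) and (best is None or obj > best[0]):
            best = (obj, canonical, stats)
    if best is None:
        raise ConfigurationError(f"no valid candidate in the {family} grid")
    return GridSearchResult(
        family=family,
        best_params=best[1],
        best_objective=best[0],
        candidates=pd.DataFrame(rows),
        best_metrics=best[2],
    )


def select_base_classifier(results: dict[str, GridSearchResult]) -> tuple[str, dict]:
    """Pick the winning family: accuracy and F1 first, recall as tie-break.

    Exact three-way ties fall back to the documented family order.  The
    winner's hyperparameters are frozen for all channel-specific models.
    """
    if len(results) < 2:
        raise ConfigurationError("base-classifier selection needs >= 2 families")

    def sort_key(item):
        family, res = item
        m = res.best_metrics
        return (
            -m["accuracy"], -m["f1"], -m["recall"],
            FAMILY_ORDER.index(family) if family in FAMILY_ORDER else len(FAMILY_ORDER),
        )

    ranked = sorted(results.items(), key=sort_key)
    family, res = ranked[0]
    logger.info("selected base classifier %s with params %s", family, res.best_params)
    return family, res.best_params
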