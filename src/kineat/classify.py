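"""Random-forest food-item classification with OOB one-vs-all metrics.

Eating-labeled IUs are classified into the 13 food items with a random
forest of 500 trees.  The number of candidate features per split
(``mtry``) is chosen by stratified 5-fold cross-validation over the full
range 1..p, maximizing global validation accuracy; ties break toward
the smallest candidate.  A final forest is then refit on all eating IUs
with the chosen mtry.

Performance is estimated out-of-bag: each IU is predicted by majority
vote among the trees whose bootstrap draw excluded it, and one-vs-all
sensitivity and specificity are tallied per food.  Variable importance
is the mean over trees of the Gini impurity decrease attributed to each
feature, min-max scaled to 0-100.

Trees are grown to purity (no depth cap, minimum leaf size 1) and class
imbalance is left unadjusted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

try:  # bootstrap-draw reconstruction helper (stable across 1.x releases)
    from sklearn.ensemble._forest import _generate_sample_indices

    def _bootstrap_indices(random_state, n_samples: int) -> np.ndarray:
        # with the default max_samples the bootstrap draws n_samples rows
        try:
            return _generate_sample_indices(random_state, n_samples, n_samples, None)
        except TypeError:  # older signature without sample_weight
            return _generate_sample_indices(random_state, n_samples, n_samples)

except ImportError:  # pragma: no cover - mirrors sklearn's documented draw

    def _bootstrap_indices(random_state, n_samples: int) -> np.ndarray:
        rs = np.random.RandomState(random_state)
        return rs.randint(0, n_samples, n_samples).astype(np.int32)


logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


@dataclass
class ForestSettings:
    """Forest and model-selection hyperparameters."""

    n_trees: int = 500
    mtry: int | None = None
    cv_folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class FoodMetrics:
    """One food item's one-vs-all OOB confusion summary."""

    food_id: str
    sensitivity: float
    specificity: float
    support: int


@dataclass(frozen=True)
class ImportanceRow:
    variable_name: str
    raw_gini_decrease: float
    scaled_0_100: float


@dataclass
class ForestModel:
    """A fitted forest plus the training matrix needed for OOB tallies."""

    rf: RandomForestClassifier
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray

    @property
    def classes_(self) -> np.ndarray:
        return self.rf.classes_


def feature_matrix(iu_table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Extract (X, y, feature_names) from an IU table.

    Features are the ``*_slope`` columns in table order; the target is
    the food id.
    """
    cols = [c for c in iu_table.columns if c.endswith("_slope")]
    if not cols:
        raise ValueError("IU table has no slope feature columns")
    X = iu_table[cols].to_numpy(dtype=float)
    y = iu_table["food_id"].to_numpy()
    return X, y, cols


def _make_rf(n_trees: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        min_samples_leaf=1,
        random_state=int(seed) % _SEED_MOD,
        n_jobs=1,
    )


def select_mtry_cv(
    iu_table: pd.DataFrame, settings: ForestSettings
) -> tuple[int, dict[int, float]]:
    """Choose mtry by stratified k-fold CV over candidates 1..p.

    Returns the accuracy-maximizing mtry (ties toward the smallest) and
    the full candidate -> mean validation accuracy curve.
    """
    X, y, cols = feature_matrix(iu_table)
    p = X.shape[1]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("mtry selection needs at least two food classes")
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError(
            f"every food class needs >= 2 IUs for CV; minimum is {min_count}"
        )
    folds = settings.cv_folds
    if min_count < folds:
        logger.warning(
            "reducing CV folds from %d to %d (smallest class has %d IUs)",
            folds,
            min_count,
            min_count,
        )
        folds = min_count
    if p == 1:
        return 1, {1: float("nan")}

    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(settings.seed) % _SEED_MOD
    )
    splits = list(skf.split(X, y))
    candidates = range(1, p + 1)
    curve: dict[int, float] = {}
    for mtry in candidates:
        correct = 0
        for k, (tr, va) in enumerate(splits):
            rf = _make_rf(settings.n_trees, mtry, settings.seed + 7919 * (k + 1))
            rf.fit(X[tr], y[tr])
            correct += int((rf.predict(X[va]) == y[va]).sum())
        curve[mtry] = correct / len(y)
    best = max(curve, key=lambda m: (curve[m], -m))
    logger.info("CV accuracy curve: %s; chosen mtry=%d", curve, best)
    return best, curve


def fit_forest(iu_table: pd.DataFrame, settings: ForestSettings) -> ForestModel:
    """Fit a bootstrap forest on the eating IUs with a fixed mtry."""
    X, y, cols = feature_matrix(iu_table)
    if len(X) == 0:
        raise ValueError("empty IU table")
    p = X.shape[1]
    mtry = settings.mtry if settings.mtry is not None else max(1, int(math.sqrt(p)))
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}], got {mtry}")
    rf = _make_rf(settings.n_trees, mtry, settings.seed)
    rf.fit(X, y)
    return ForestModel(rf=rf, feature_names=cols, X=X, y=y)


def oob_votes(model: ForestModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample OOB vote tallies.

    Returns ``(votes, n_oob_trees)`` where ``votes[i, c]`` counts trees
    that were not trained on sample i and voted for class c, and
    ``n_oob_trees[i]`` is the number of such trees (row sums of
    ``votes``).
    """
    n = len(model.X)
    classes = model.classes_
    votes = np.zeros((n, len(classes)), dtype=np.int64)
    n_oob = np.zeros(n, dtype=np.int64)
    for est in model.rf.estimators_:
        inbag = np.bincount(_bootstrap_indices(est.random_state, n), minlength=n)
        oob = np.flatnonzero(inbag == 0)
        if len(oob) == 0:
            continue
        # trees inside a forest predict encoded class indices (0..k-1)
        pred_idx = est.predict(model.X[oob]).astype(np.int64)
        votes[oob, pred_idx] += 1
        n_oob[oob] += 1
    return votes, n_oob


def oob_predictions(model: ForestModel) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote OOB class per sample and a validity mask.

    Samples that were in-bag for every tree get an invalid entry (mask
    False); argmax ties break toward the lowest food id because classes
    are sorted ascending.
    """
    votes, n_oob = oob_votes(model)
    valid = n_oob > 0
    if not valid.all():
        logger.warning(
            "%d IUs were in-bag for all %d trees and are excluded from OOB metrics",
            int((~valid).sum()),
            model.rf.n_estimators,
        )
    pred = model.classes_[np.argmax(votes, axis=1)]
    return pred, valid


def oob_metrics(
    model: ForestModel,
    iu_table: pd.DataFrame,
    all_foods: Sequence[str] | None = None,
) -> list[FoodMetrics]:
    """One-vs-all OOB sensitivity/specificity per food item.

    ``iu_table`` must be the table the model was fit on (checked by
    length).  Foods listed in ``all_foods`` but absent from the table
    are reported with NaN sensitivity rather than dropped.
    """
    X, y, _ = feature_matrix(iu_table)
    if len(y) != len(model.y) or not np.array_equal(y, model.y):
        raise ValueError("iu_table does not match the table the model was fit on")
    pred, valid = oob_predictions(model)
    y, pred = y[valid], pred[valid]

    foods = sorted(set(map(str, all_foods or [])) | set(map(str, np.unique(y))))
    out: list[FoodMetrics] = []
    for food in foods:
        is_pos = y == food
        is_pred = pred == food
        tp = int((is_pos & is_pred).sum())
        fn = int((is_pos & ~is_pred).sum())
        fp = int((~is_pos & is_pred).sum())
        tn = int((~is_pos & ~is_pred).sum())
        support = tp + fn
        if support == 0:
            logger.warning("food %s has no IUs; sensitivity undefined", food)
            sens = float("nan")
        else:
            sens = tp / support
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        out.append(FoodMetrics(food, sens, spec, support))
    return out


def scaled_importance(model: ForestModel) -> list[ImportanceRow]:
    """Mean per-tree Gini impurity decrease, min-max scaled to 0-100.

    With a single feature, or when every feature has the same raw
    importance, scaling is degenerate; all variables are reported at 100
    with a warning.
    """
    trees = model.rf.estimators_
    if not trees:
        raise ValueError("model has no fitted trees")
    raw = np.mean(
        [t.tree_.compute_feature_importances(normalize=False) for t in trees],
        axis=0,
    )
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo <= 1e-12 * max(hi, 1.0):
        logger.warning("degenerate importance scaling; reporting all variables at 100")
        scaled = np.full_like(raw, 100.0)
    else:
        scaled = ((raw - lo) / (hi - lo)) * 100.0  # ratio first: max is exactly 100
    return [
        ImportanceRow(name, float(r), float(s))
        for name, r, s in zip(model.feature_names, raw, scaled)
    ]
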