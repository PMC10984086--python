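"""Random-forest discrimination of DZ vs LZ nuclei from chrometric features.

The evaluation protocol mirrors the imaging analysis it reproduces: a
balanced subsample of the two classes, 10-fold stratified cross-validation,
row-normalized confusion matrices averaged across folds, and a one-sided
Wilcoxon signed-rank test of the per-fold accuracies against the
no-information rate (NIR, the accuracy of always predicting the majority
class; 0.5 for a balanced sample).  Feature importances are the forest's
mean impurity decrease, normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.utils.validation import check_is_fitted

from .containers import CellMap

__all__ = [
    "ModelConfig",
    "CVResult",
    "ImportanceRanking",
    "balanced_subsample",
    "fit_forest",
    "run_stratified_cv",
    "nir_wilcoxon_test",
    "feature_importance_ranking",
    "holdout_spatial_prediction",
]


@dataclass
class ModelConfig:
    """Forest hyperparameters (500 trees, unlimited depth, √p features)."""

    n_trees: int = 500
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    seed: int = 0


@dataclass
class CVResult:
    fold_confusions: list[pd.DataFrame]      # row-normalized, held-out folds
    fold_accuracies: np.ndarray
    mean_confusion: pd.DataFrame
    accuracy: float
    nir: float
    nir_p: float
    nir_flagged: bool
    k: int
    seed: int
    classes: list[str] = field(default_factory=list)


@dataclass
class ImportanceRanking:
    table: pd.DataFrame                      # feature, importance; sorted desc

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])


def _check_xy(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    if len(X) != len(y):
        raise ValueError("feature matrix and labels have different lengths")
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values; drop flagged rows first")
    classes = pd.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    return X, pd.Series(np.asarray(y), index=X.index)


def balanced_subsample(
    X: pd.DataFrame, y: pd.Series, seed: int = 0, size: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample equal per-class counts without replacement.

    ``size`` is the per-class count (default: the minority class size).
    Reproducible under a fixed seed.
    """
    X, y = _check_xy(X, y)
    counts = y.value_counts()
    per_class = int(counts.min()) if size is None else int(size)
    if per_class > counts.min():
        raise ValueError(
            f"requested {per_class} per class but smallest class has {counts.min()}"
        )
    rng = np.random.default_rng(seed)
    keep = []
    for cls in sorted(counts.index):
        pos = np.flatnonzero((y == cls).to_numpy())
        keep.append(rng.choice(pos, size=per_class, replace=False))
    idx = np.sort(np.concatenate(keep))
    return X.iloc[idx], y.iloc[idx]


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=0).replace(0.0, 1.0)
    return (X - X.mean()) / sd


def fit_forest(X: pd.DataFrame, y: pd.Series, cfg: ModelConfig | None = None) -> RandomForestClassifier:
    """Fit the random forest on standardized features."""
    cfg = cfg or ModelConfig()
    X, y = _check_xy(X, y)
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        max_features=cfg.max_features,
        random_state=cfg.seed,
    )
    model.fit(_standardize(X).to_numpy(), y.to_numpy())
    return model


def run_stratified_cv(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: ModelConfig | None = None,
    k: int = 10,
) -> CVResult:
    """k-fold stratified cross-validation of the DZ/LZ forest.

    Folds preserve the class ratio; each held-out fold yields a
    row-normalized confusion matrix (rows = true class) and an accuracy.
    The averaged confusion matrix averages the per-fold normalized matrices,
    so each of its rows still sums to one.  The NIR is the maximum class
    prior of the input table; its one-sided signed-rank p-value comes from
    :func:`nir_wilcoxon_test`.
    """
    cfg = cfg or ModelConfig()
    if k < 2:
        raise ValueError("k must be at least 2")
    X, y = _check_xy(X, y)
    counts = y.value_counts()
    if counts.min() < k:
        raise ValueError(f"need at least k={k} examples per class")

    classes = sorted(counts.index)
    nir = float(counts.max() / counts.sum())

    Xs = _standardize(X).to_numpy()
    ya = y.to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    confusions, accs = [], []
    for tr, te in skf.split(Xs, ya):
        model = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            max_features=cfg.max_features,
            random_state=cfg.seed,
        )
        model.fit(Xs[tr], ya[tr])
        pred = model.predict(Xs[te])
        cm = confusion_matrix(ya[te], pred, labels=classes, normalize="true")
        confusions.append(pd.DataFrame(cm, index=classes, columns=classes))
        accs.append(float((pred == ya[te]).mean()))

    accs = np.asarray(accs)
    mean_cm = sum(confusions) / k
    p, flagged = nir_wilcoxon_test(accs, nir)
    return CVResult(
        fold_confusions=confusions,
        fold_accuracies=accs,
        mean_confusion=mean_cm,
        accuracy=float(accs.mean()),
        nir=nir,
        nir_p=p,
        nir_flagged=flagged,
        k=k,
        seed=cfg.seed,
        classes=list(classes),
    )


def _exact_signed_rank_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under uniform random signs, by dynamic programming.

    Midranks may be half-integers, so ranks are doubled to integers and the
    distribution of the positive-rank sum is built by convolution; exact for
    any tie pattern.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_obs * 2))
    return float(counts[w2:].sum())


def nir_wilcoxon_test(
    fold_accuracies: np.ndarray, nir: float, exact_max_k: int = 25
) -> tuple[float, bool]:
    """One-sided Wilcoxon signed-rank p for accuracies exceeding the NIR.

    Zero differences are dropped (declared convention).  For k ≤ 25
    non-zero folds the exact sign-flip null distribution is used (ties via
    midranks); larger k falls back to the normal approximation with tie
    correction.  Returns ``(p, flagged)``; all-zero differences give
    ``p = 1`` flagged.
    """
    acc = np.asarray(fold_accuracies, dtype=float)
    if acc.size < 5:
        raise ValueError("need at least 5 folds")
    d = acc - nir
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0, True
    ranks = stats.rankdata(np.abs(d))  # midranks
    w_pos = float(ranks[d > 0].sum())
    if d.size <= exact_max_k:
        return _exact_signed_rank_sf(ranks, w_pos), False
    n = d.size
    mu = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    var = (ranks**2).sum() / 4.0
    z = (w_pos - mu - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z)), False


def feature_importance_ranking(
    model: RandomForestClassifier, feature_names: list[str]
) -> ImportanceRanking:
    """Mean impurity-decrease importances, normalized, sorted descending."""
    try:
        check_is_fitted(model)
    except NotFittedError as err:
        raise ValueError("model must be trained before ranking importances") from err
    imp = np.asarray(model.feature_importances_, dtype=float)
    if len(imp) != len(feature_names):
        raise ValueError("feature name count does not match the fitted model")
    s = imp.sum()
    if s > 0:
        imp = imp / s
    table = (
        pd.DataFrame({"feature": feature_names, "importance": imp})
        .sort_values("importance", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return ImportanceRanking(table)


def holdout_spatial_prediction(
    X: pd.DataFrame,
    y: pd.Series,
    cellmap: CellMap,
    cfg: ModelConfig | None = None,
    k: int = 10,
) -> pd.DataFrame:
    """Predict each cell's compartment with a model that never saw it.

    Feature rows are joined to the cell map by nucleus/cell id; unjoinable
    ids are reported in the ``joined`` column of the returned frame and
    skipped.  Predictions come from k-fold stratified cross-validation
    (each row predicted by the fold that held it out) and are returned with
    coordinates for map rendering.
    """
    cfg = cfg or ModelConfig()
    X, y = _check_xy(X, y)
    cells = cellmap.cells.set_index("cell_id")
    joinable = X.index.isin(cells.index)
    Xj, yj = X.loc[joinable], y.loc[joinable]
    if not len(Xj):
        raise ValueError("no feature rows join to the cell map")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        max_features=cfg.max_features,
        random_state=cfg.seed,
    )
    pred = cross_val_predict(model, _standardize(Xj).to_numpy(), yj.to_numpy(), cv=skf)
    out = pd.DataFrame(
        {
            "x_um": cells.loc[Xj.index, "x_um"].to_numpy(),
            "y_um": cells.loc[Xj.index, "y_um"].to_numpy(),
            "true_label": yj.to_numpy(),
            "predicted_label": pred,
        },
        index=Xj.index.rename("cell_id"),
    )
    skipped = list(X.index[~joinable])
    out.attrs["skipped_ids"] = skipped
    return out
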