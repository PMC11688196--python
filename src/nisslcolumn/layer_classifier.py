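"""Cell-level cortical layer classification.

Each segmented cell is assigned one of the seven layer classes (LI, LII,
LIII, LIV, LV, LVIa, LVIb) — or, in the merged paradigm, LII/III instead
of LII and LIII — from per-cell morphometric and positional features and
their 50-µm neighborhood-smoothed counterparts.  Feature selection uses
permutation importance (mean held-out accuracy drop over repeated column
permutations, keeping only features with positive impact); the models
are a K-nearest-neighbor and a random-forest classifier, evaluated with
image-grouped 10-fold cross-validation and macro-averaged metrics so
every layer contributes equally regardless of its cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GroupKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from nisslcolumn.io_formats import LAYER_ORDER, RegionSet, SchemaError, ensure_area

__all__ = [
    "BASE_FEATURES",
    "ClassifierReport",
    "assemble_features",
    "select_features",
    "make_model",
    "train_evaluate",
    "predict",
    "merge_l23",
]

#: Per-cell base features assembled from the measurement table.
BASE_FEATURES = ("x_um", "y_um", "dist_pia_um", "area_um2",
                 "d_max_um", "d_min_um", "aspect", "equiv_diam_um")

#: Default hyperparameters, overridable per call.
DEFAULT_RF_TREES = 500
DEFAULT_KNN_K = 15


@dataclass
class ClassifierReport:
    """Cross-validated evaluation of one model on one paradigm."""

    model_kind: str
    classes: list[str]
    confusion: np.ndarray  # rows = truth, cols = prediction
    per_class: pd.DataFrame  # precision / recall / f1 / accuracy per class
    macro: dict[str, float]
    cv_folds: int
    selected_features: list[str] = field(default_factory=list)
    feature_importance: pd.DataFrame | None = None
    hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "classes": self.classes,
            "confusion_matrix": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "macro": self.macro,
            "cv_folds": self.cv_folds,
            "selected_features": self.selected_features,
            "hyperparameters": self.hyperparameters,
        }


def merge_l23(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Map LII and LIII onto the merged LII/III class (merged paradigm)."""
    arr = np.asarray(labels, dtype=object)
    return np.where(np.isin(arr, ("LII", "LIII")), "LII/III", arr)


def assemble_features(cells: pd.DataFrame, regions: RegionSet | None = None,
                      radius_um: float = 50.0) -> pd.DataFrame:
    """Assemble the per-cell feature table, with smoothed counterparts.

    The smoothed value of feature f for cell i is the unweighted mean of
    f over all cells of the same image within ``radius_um`` of i, self
    included (so an isolated cell keeps its own value, and a spatially
    constant feature is unchanged by smoothing).  ``dist_pia_um`` is
    recomputed from the pia geometry when absent.
    """
    cells = ensure_area(cells)
    if ("dist_pia_um" not in cells.columns or cells["dist_pia_um"].isna().any()):
        if regions is None or regions.outside_pia is None:
            raise SchemaError("dist_pia_um absent and no pia geometry given")
        import shapely
        pts = shapely.points(cells[["x_um", "y_um"]].to_numpy(float))
        cells = cells.copy()
        cells["dist_pia_um"] = shapely.distance(regions.outside_pia, pts)
    feats = cells.copy()
    feats["aspect"] = feats["d_min_um"].to_numpy(float) / feats["d_max_um"].to_numpy(float)
    feats["equiv_diam_um"] = 2.0 * np.sqrt(feats["area_um2"].to_numpy(float) / np.pi)
    base = [f for f in BASE_FEATURES if f in feats.columns]
    smoothed = {f"smoothed50_{f}": np.empty(len(feats)) for f in base}
    for _, idx in feats.groupby("image_id", sort=False).indices.items():
        xy = feats.iloc[idx][["x_um", "y_um"]].to_numpy(float)
        tree = cKDTree(xy)
        neigh = tree.query_ball_point(xy, r=radius_um)
        for f in base:
            vals = feats.iloc[idx][f].to_numpy(float)
            smoothed[f"smoothed50_{f}"][idx] = [vals[nb].mean() for nb in neigh]
    for name, col in smoothed.items():
        feats[name] = col
    feats.attrs["feature_names"] = base + list(smoothed)
    return feats


def feature_names(features: pd.DataFrame) -> list[str]:
    names = features.attrs.get("feature_names")
    if names is None:
        names = [f for f in features.columns
                 if f in BASE_FEATURES or f.startswith("smoothed50_")]
    return list(names)


def make_model(model_kind: str, seed: int = 0, **hyper):
    """A KNN or random-forest classifier with the package defaults."""
    if model_kind == "knn":
        k = hyper.pop("n_neighbors", DEFAULT_KNN_K)
        return make_pipeline(
            StandardScaler(),
            KNeighborsClassifier(n_neighbors=k, weights="distance", **hyper),
        )
    if model_kind == "rf":
        n = hyper.pop("n_estimators", DEFAULT_RF_TREES)
        return RandomForestClassifier(n_estimators=n, random_state=seed,
                                      n_jobs=1, **hyper)
    raise ValueError(f"unknown model kind: {model_kind!r}")


def select_features(features: pd.DataFrame, labels,
                    model_kind: str = "rf", n_repeats: int = 5,
                    seed: int = 0, test_size: float = 0.25,
                    **hyper) -> tuple[list[str], pd.DataFrame]:
    """Permutation-importance feature selection on a held-out split.

    Importance of a feature is the mean drop in held-out accuracy over
    ``n_repeats`` independent permutations of its column; features with
    positive mean importance are retained, reported as mean ± sd.
    """
    names = feature_names(features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes for feature selection")
    X = features[names].to_numpy(float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y)
    model = make_model(model_kind, seed=seed, **hyper).fit(X_tr, y_tr)
    res = permutation_importance(model, X_te, y_te, n_repeats=n_repeats,
                                 random_state=seed, scoring="accuracy")
    table = pd.DataFrame({
        "feature": names,
        "importance_mean": res.importances_mean,
        "importance_sd": res.importances_std,
    }).sort_values("importance_mean", ascending=False, ignore_index=True)
    selected = table.loc[table["importance_mean"] > 0, "feature"].tolist()
    return selected, table


def _per_class_metrics(conf: np.ndarray, classes: list[str]) -> pd.DataFrame:
    """Precision/recall/F1/accuracy per class from a pooled confusion matrix."""
    tp = np.diag(conf).astype(float)
    support = conf.sum(axis=1).astype(float)
    predicted = conf.sum(axis=0).astype(float)
    total = conf.sum()
    del total
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, np.nan)
        recall = np.where(support > 0, tp / support, np.nan)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), np.nan)
        # per-class accuracy = fraction of the class's cells classified
        # correctly, so the macro average is the balanced accuracy
        accuracy = recall.copy()
    return pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1,
         "accuracy": accuracy, "support": support.astype(int)},
        index=classes,
    )


def train_evaluate(features: pd.DataFrame, labels, model_kind: str = "rf",
                   folds: int = 10, seed: int = 0,
                   selected: list[str] | None = None,
                   **hyper) -> ClassifierReport:
    """Image-grouped k-fold cross-validation of one model.

    Folds are split by image so all cells of an image stay together
    (cells within an image are strongly spatially dependent).  The
    confusion matrix is pooled over folds; per-class and macro metrics
    follow from it, macro metrics being unweighted class means over the
    classes with defined metrics.
    """
    y = np.asarray(labels)
    groups = features["image_id"].to_numpy()
    n_images = len(np.unique(groups))
    if n_images < folds:
        raise ValueError(f"need at least {folds} labeled images, have {n_images}")
    names = selected if selected is not None else feature_names(features)
    X = features[names].to_numpy(float)
    classes = sorted(np.unique(y), key=lambda c: _class_sort_key(c))
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    cv = GroupKFold(n_splits=folds)
    base = make_model(model_kind, seed=seed, **hyper)
    for train_idx, test_idx in cv.split(X, y, groups):
        model = clone(base).fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        conf += confusion_matrix(y[test_idx], pred, labels=classes)
    per_class = _per_class_metrics(conf, classes)
    macro = {
        "accuracy": float(np.nanmean(per_class["accuracy"])),
        "precision": float(np.nanmean(per_class["precision"])),
        "recall": float(np.nanmean(per_class["recall"])),
        "f1": float(np.nanmean(per_class["f1"])),
        "micro_accuracy": float(np.trace(conf) / conf.sum()),
    }
    return ClassifierReport(
        model_kind=model_kind, classes=classes, confusion=conf,
        per_class=per_class, macro=macro, cv_folds=folds,
        selected_features=list(names),
        hyperparameters={"model_kind": model_kind, "seed": seed, **hyper},
    )


def _class_sort_key(label: str) -> int:
    order = list(LAYER_ORDER) + ["LII/III", "none"]
    return order.index(label) if label in order else len(order)


def fit(features: pd.DataFrame, labels, model_kind: str = "rf", seed: int = 0,
        selected: list[str] | None = None, **hyper):
    """Fit a final model on all labeled cells; returns (model, feature names)."""
    names = selected if selected is not None else feature_names(features)
    model = make_model(model_kind, seed=seed, **hyper)
    model.fit(features[names].to_numpy(float), np.asarray(labels))
    return model, names


def predict(model, features: pd.DataFrame,
            selected: list[str]) -> pd.DataFrame:
    """Predict a layer per cell; exposes probabilities when available.

    Row order is preserved; an empty feature table yields an empty
    result.  A missing selected feature is a schema error.
    """
    missing = [f for f in selected if f not in features.columns]
    if missing:
        raise SchemaError(f"features missing from input: {missing}")
    out = features.copy()
    if not len(features):
        out["predicted_layer"] = pd.Series([], dtype=object)
        return out
    X = features[selected].to_numpy(float)
    out["predicted_layer"] = model.predict(X)
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        out["predicted_proba"] = proba.max(axis=1)
    return out
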