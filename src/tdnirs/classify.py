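"""Supervised classification of depression status from hemodynamic features.

Four conventional models are evaluated on small feature subsets: a linear
support vector machine, linear discriminant analysis (equal priors),
shallow decision trees (at most 3 splits) and Gaussian naive Bayes.
Performance is quantified as resubstitution accuracy plus stratified
five-fold cross-validation (mean +/- SD over folds), with confusion-matrix
sensitivity/specificity, and - for two-feature subsets - a dense decision-
boundary grid for the visualized classifier plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODELS = ("linear_svm", "lda", "decision_tree", "gaussian_nb")

#: feature subsets reported for the task-rest ratio families
TABLE_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "F3_F7": ("F3", "F7"),
    "F6_F7": ("F6", "F7"),
    "F7_F8": ("F7", "F8"),
    "F7_F12": ("F7", "F12"),
    "5D": ("F3", "F6", "F7", "F8", "F12"),
}


@dataclass(frozen=True)
class ClassifierSpec:
    model: str
    features: tuple[str, ...]
    standardize: bool | None = None  # None -> on except for trees
    cv_folds: int = 5
    cv_seed: int = 0
    stratified: bool = True
    tree_max_splits: int = 3
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not self.features:
            raise ValueError("feature subset must be nonempty")

    @property
    def standardize_effective(self) -> bool:
        if self.standardize is None:
            return self.model != "decision_tree"
        return self.standardize


@dataclass
class ConfusionMetrics:
    """Confusion counts with accuracy/sensitivity/specificity.

    Raw ratios are retained; ``as_percent`` rounds to one decimal for
    display.  Undefined ratios (zero denominator) are reported as None.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fn + self.tn + self.fp == 0:
            raise ValueError("confusion counts must sum to a positive total")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def as_percent(self) -> dict[str, float | None]:
        def pct(x: float | None) -> float | None:
            return None if x is None else round(100.0 * x, 1)

        return {
            "accuracy": pct(self.accuracy),
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
        }


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> ConfusionMetrics:
    """Accuracy, sensitivity and specificity from confusion counts."""
    return ConfusionMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass
class ClassifierReport:
    spec: ClassifierSpec
    n_samples: int
    n_dropped: int
    confusion: ConfusionMetrics
    fold_accuracies: tuple[float, ...]
    feature_ranges: dict[str, tuple[float, float]]
    estimator: object = field(repr=False, default=None)
    positive_label: str = "MDD"

    @property
    def resub_accuracy(self) -> float:
        return self.confusion.accuracy

    @property
    def cv_mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def cv_sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": self.spec.model,
            "features": list(self.spec.features),
            "n_samples": self.n_samples,
            "n_dropped": self.n_dropped,
            "confusion": {
                "tp": self.confusion.tp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
            },
            "resubstitution": self.confusion.as_percent(),
            "cv": {
                "folds": list(np.round(np.array(self.fold_accuracies) * 100.0, 1)),
                "mean": round(self.cv_mean * 100.0, 1),
                "sd": round(self.cv_sd * 100.0, 1),
            },
            "positive_label": self.positive_label,
        }


def make_estimator(spec: ClassifierSpec):
    if spec.model == "linear_svm":
        clf = SVC(kernel="linear", C=spec.svm_c)
    elif spec.model == "lda":
        clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    elif spec.model == "decision_tree":
        # a cap of k binary splits bounds the leaves at k + 1
        clf = DecisionTreeClassifier(
            max_leaf_nodes=spec.tree_max_splits + 1, random_state=spec.cv_seed
        )
    else:
        clf = GaussianNB()
    if spec.standardize_effective:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return Pipeline([("clf", clf)])


def fit_predict(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    label_col: str = "group",
    positive: str = "MDD",
) -> ClassifierReport:
    """Fit the model and evaluate resubstitution + k-fold CV accuracy.

    Rows with missing values in the selected features are dropped (and
    counted).  Rows are processed in canonical sample order so the report
    is invariant to the incoming row order; standardization statistics are
    fit on training folds only.
    """
    cols = list(spec.features)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    df = table.copy()
    if "sample_id" in df.columns:
        df = df.sort_values("sample_id", kind="mergesort")
    kept = df.dropna(subset=cols)
    n_dropped = len(df) - len(kept)
    x = kept[cols].to_numpy(float)
    y = (kept[label_col] == positive).to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    est = make_estimator(spec)
    est.fit(x, y)
    pred = est.predict(x)
    tp = int(np.sum((y == 1) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))

    if spec.stratified:
        splitter = StratifiedKFold(
            n_splits=spec.cv_folds, shuffle=True, random_state=spec.cv_seed
        )
    else:
        splitter = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.cv_seed)
    folds = []
    for train, test in splitter.split(x, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                "a training fold contains one class only; use stratified CV or "
                "rebalance the groups"
            )
        fold_est = make_estimator(spec)
        fold_est.fit(x[train], y[train])
        folds.append(float(np.mean(fold_est.predict(x[test]) == y[test])))

    ranges = {c: (float(kept[c].min()), float(kept[c].max())) for c in cols}
    return ClassifierReport(
        spec=spec,
        n_samples=len(kept),
        n_dropped=n_dropped,
        confusion=ConfusionMetrics(tp=tp, fn=fn, tn=tn, fp=fp),
        fold_accuracies=tuple(folds),
        feature_ranges=ranges,
        estimator=est,
        positive_label=positive,
    )


@dataclass
class BoundaryGrid:
    """Dense prediction grid over two features, for scatter+boundary plots."""

    feature_x: str
    feature_y: str
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray  # (len(y), len(x)) of 0/1 predictions

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                self.feature_x: xx.ravel(),
                self.feature_y: yy.ravel(),
                "label": self.labels.ravel(),
            }
        )


def boundary_grid(
    report: ClassifierReport,
    resolution: int = 200,
    margin: float = 0.10,
) -> BoundaryGrid:
    """Label a dense grid spanning the observed 2-D feature ranges +/-10%.

    Every grid point is labeled by the fitted model, so the rendered
    boundary is exactly the model's decision surface at grid resolution.
    """
    if len(report.spec.features) != 2:
        raise ValueError("boundary grids require exactly 2 features")
    fx, fy = report.spec.features
    axes = []
    for name in (fx, fy):
        lo, hi = report.feature_ranges[name]
        span = hi - lo
        if span <= 0:
            raise ValueError(f"feature {name!r} has zero range; cannot grid it")
        axes.append(np.linspace(lo - margin * span, hi + margin * span, resolution))
    gx, gy = axes
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    labels = report.estimator.predict(pts).reshape(len(gy), len(gx))
    return BoundaryGrid(feature_x=fx, feature_y=fy, x=gx, y=gy, labels=labels)
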