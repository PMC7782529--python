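"""Hub evaluation as case/control classifier feature panels.

Each hub's member genes, read off the merged expression matrix, form a
feature panel.  A roster of classification algorithms is run under repeated
stratified k-fold cross-validation (default 10 folds × 10 repeats);
confusion counts are pooled over all folds and repeats, and sensitivity,
specificity, accuracy and the Matthews correlation coefficient are computed
from the pooled matrix.  Features are standardized inside each training fold
only, so no test information leaks into the scaler.  Hubs are then ranked by
their median accuracy across the roster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core_io import GROUP_CASE, ExpressionStudy, logger
from .hub_detection import Hub


def _roster_factory() -> dict[str, object]:
    return {
        "naive_bayes": GaussianNB(),
        "logistic": LogisticRegression(max_iter=2000),
        "lda": LinearDiscriminantAnalysis(),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "decision_tree": DecisionTreeClassifier(random_state=0),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=0),
        "gradient_boosting": GradientBoostingClassifier(random_state=0),
        "svm_linear": SVC(kernel="linear"),
        "svm_rbf": SVC(kernel="rbf"),
        "ridge": RidgeClassifier(),
    }


DEFAULT_ROSTER = tuple(_roster_factory())
#: Fast subset for large experiment grids (no tree ensembles).
FAST_ROSTER = ("naive_bayes", "logistic", "lda", "knn", "ridge")


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp + tn + fp + fn == 0:
        raise ValueError("all confusion counts are 0")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class ClassificationReport:
    hub_id: str
    algorithm: str
    tp: int
    tn: int
    fp: int
    fn: int
    folds: int
    repeats: int
    seed: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total

    @property
    def mcc(self) -> float:
        return mcc(self.tp, self.tn, self.fp, self.fn)


def extract_hub_features(merged: ExpressionStudy, hub: Hub,
                         ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Samples × hub-genes feature matrix and binary labels (1 = case).

    Genes absent from the matrix are returned for reporting; zero overlap
    raises, naming the hub.
    """
    present = sorted(hub.members & set(merged.genes))
    absent = sorted(hub.members - set(merged.genes))
    if not present:
        raise ValueError(f"hub {hub.hub_id}: no member gene in the merged matrix")
    if absent:
        logger.warning("hub %s: %d gene(s) absent from the matrix: %s",
                       hub.hub_id, len(absent), ", ".join(absent))
    X = merged.matrix.loc[present].T
    y = np.array([1 if merged.groups[s] == GROUP_CASE else 0 for s in X.index])
    return X, y, absent


def crossval_classify(X: pd.DataFrame | np.ndarray, y: np.ndarray,
                      algorithm: str = "logistic", folds: int = 10,
                      repeats: int = 10, seed: int = 0,
                      hub_id: str = "") -> ClassificationReport:
    """Repeated stratified k-fold CV with pooled confusion counts.

    Standardization happens inside each training fold only (pipeline), so
    the scaler never sees test data.
    """
    roster = _roster_factory()
    if algorithm not in roster:
        raise ValueError(f"unknown algorithm {algorithm!r}; roster: "
                         f"{sorted(roster)}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    smaller = min(np.bincount(y.astype(int)))
    if folds > smaller:
        raise ValueError(f"folds={folds} exceeds the smaller class size {smaller}")
    model = Pipeline([("scale", StandardScaler()),
                      ("clf", clone(roster[algorithm]))])
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    tp = tn = fp = fn = 0
    for train, test in cv.split(X, y):
        m = clone(model)
        m.fit(X[train], y[train])
        pred = m.predict(X[test])
        truth = y[test]
        tp += int(((pred == 1) & (truth == 1)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
    return ClassificationReport(hub_id=hub_id or "hub", algorithm=algorithm,
                                tp=tp, tn=tn, fp=fp, fn=fn,
                                folds=folds, repeats=repeats, seed=seed)


def evaluate_hubs(merged: ExpressionStudy, hubs: list[Hub],
                  roster: tuple[str, ...] = DEFAULT_ROSTER,
                  folds: int = 10, repeats: int = 10,
                  seed: int = 0) -> list[ClassificationReport]:
    """Run the whole roster on every hub's feature panel."""
    reports = []
    for hub in hubs:
        X, y, _ = extract_hub_features(merged, hub)
        for algo in roster:
            reports.append(crossval_classify(X, y, algorithm=algo, folds=folds,
                                             repeats=repeats, seed=seed,
                                             hub_id=hub.hub_id))
    return reports


def rank_hubs(reports: list[ClassificationReport], top_k: int = 5,
              statistic: str = "median") -> list[tuple[str, float]]:
    """Rank hubs by accuracy aggregated across the algorithm roster.

    Default aggregate is the median accuracy over algorithms (mean and max
    available); ties break on median MCC, then on hub ID.  Returns the top_k
    (all hubs when top_k exceeds the count) as (hub_id, aggregate accuracy).
    """
    if statistic not in ("median", "mean", "max"):
        raise ValueError("statistic must be median, mean or max")
    agg = {"median": np.median, "mean": np.mean, "max": np.max}[statistic]
    by_hub: dict[str, list[ClassificationReport]] = {}
    for r in reports:
        by_hub.setdefault(r.hub_id, []).append(r)
    rosters = {tuple(sorted(r.algorithm for r in rs)) for rs in by_hub.values()}
    if len(rosters) > 1:
        raise ValueError("hubs evaluated on different algorithm rosters")
    scored = []
    for hub_id, rs in by_hub.items():
        acc = float(agg([r.accuracy for r in rs]))
        m = float(np.median([r.mcc for r in rs]))
        scored.append((hub_id, acc, m))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [(hub_id, acc) for hub_id, acc, _ in scored[:top_k]]


def reports_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "hub": r.hub_id, "algorithm": r.algorithm,
        "sensitivity": r.sensitivity, "specificity": r.specificity,
        "accuracy": r.accuracy, "mcc": r.mcc,
        "folds": r.folds, "repeats": r.repeats, "seed": r.seed,
    } for r in reports])
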