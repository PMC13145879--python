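"""Feature tables, stratified folds and the six-classifier evaluation.

The unit of classification is either one image (``adaxial``,
``abaxial``, ``combined_pool`` modes) or one leaf with the two surface
vectors concatenated (``combined_concat``, 210 features).  Evaluation
is stratified k-fold cross-validation with fold-local z-scoring: the
scaler (and, for the feature-selecting forest, the selection itself)
is fit on the training split only.

Classifier roster
-----------------
``knn_local``
    Adaptive-k nearest neighbors: per query, the largest k <= 15 whose
    k-th neighbor lies within 3x the median 1-NN spacing of the
    training set; inverse-distance-weighted vote.
``knn_weighted``
    Inverse-distance-weighted KNN with k chosen once per training
    split by leave-one-out accuracy over k in 1..20 (smallest k wins
    ties).
``random_forest``
    500 trees, Gini, sqrt(p) features per split, bootstrap.
``optimized_forest``
    A preliminary 200-tree forest ranks features by impurity
    importance; the top ceil(p/2) are kept and a 500-tree forest is
    refit on the subset.
``svm_rbf``
    One-vs-rest RBF SVM, C=10, gamma=1/p on z-scored features;
    probability scores are a softmax over the decision values (a
    deliberate Platt-free surrogate).
``mlp``
    One hidden layer of 64 rectified units, softmax output, Adam,
    at most 500 epochs with 10% early-stopping validation.

All stochastic fits are seeded and all ties break on alphabetical
class order, so a fixed (table, spec, folds) triple reproduces the
result bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

SURFACE_MODES = ("adaxial", "abaxial", "combined_concat", "combined_pool")
CLASSIFIER_NAMES = (
    "knn_local", "knn_weighted", "random_forest", "optimized_forest",
    "svm_rbf", "mlp",
)
#: classifiers whose inputs must be z-scored
SCALED_CLASSIFIERS = ("knn_local", "knn_weighted", "svm_rbf", "mlp")

META_COLUMNS = ("leaf_id", "surface", "plant_id", "folk_type")


@dataclass
class FeatureTable:
    """Instances x named features plus label and plant group."""

    X: pd.DataFrame
    y: pd.Series          # folk-type label per instance
    groups: pd.Series     # plant_id per instance
    surface_mode: str
    ids: pd.Series        # leaf_id (or leaf_id/surface) per instance

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def classes(self) -> list[str]:
        return sorted(self.y.unique())


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")


@dataclass
class FoldAssignment:
    fold: np.ndarray      # fold index per instance, 0..k-1
    k: int
    stratified: bool = True
    group_aware: bool = False


@dataclass
class CVResult:
    """Cross-validation output: per-fold metrics, pooled confusion
    counts and per-instance predictions with class-probability scores."""

    classifier: str
    surface_mode: str
    fold_metrics: pd.DataFrame      # fold, accuracy, weighted_f, roc_auc
    per_class: pd.DataFrame         # fold, class, precision, recall, f, support
    confusion: pd.DataFrame         # labels x labels pooled integer counts
    predictions: pd.DataFrame       # id, fold, true, predicted, p_<class>...

    @property
    def pooled_accuracy(self) -> float:
        cm = self.confusion.to_numpy()
        return float(np.trace(cm) / cm.sum())


def build_feature_table(features: pd.DataFrame, mode: str) -> FeatureTable:
    """Arrange an extraction table (one row per image) for one surface
    mode.

    ``adaxial``/``abaxial``: rows of that surface only.
    ``combined_concat``: one row per leaf; adaxial features prefixed
    ``ad_``, abaxial ``ab_`` (210 columns).  Every leaf must have both
    surfaces.
    ``combined_pool``: every image row, both surfaces stacked.
    """
    if mode not in SURFACE_MODES:
        raise ValueError(f"unknown surface mode {mode!r}")
    feat_cols = [c for c in features.columns if c not in META_COLUMNS]
    if mode in ("adaxial", "abaxial"):
        sub = features[features["surface"] == mode]
        return FeatureTable(
            X=sub[feat_cols].reset_index(drop=True),
            y=sub["folk_type"].reset_index(drop=True),
            groups=sub["plant_id"].reset_index(drop=True),
            surface_mode=mode,
            ids=sub["leaf_id"].reset_index(drop=True),
        )
    if mode == "combined_pool":
        return FeatureTable(
            X=features[feat_cols].reset_index(drop=True),
            y=features["folk_type"].reset_index(drop=True),
            groups=features["plant_id"].reset_index(drop=True),
            surface_mode=mode,
            ids=(features["leaf_id"] + "/" + features["surface"]).reset_index(drop=True),
        )
    # combined_concat
    ad = features[features["surface"] == "adaxial"].set_index("leaf_id")
    ab = features[features["surface"] == "abaxial"].set_index("leaf_id")
    missing = sorted(set(ad.index) ^ set(ab.index))
    if missing:
        raise ValueError(
            f"combined_concat requires both surfaces per leaf; missing for: {missing}"
        )
    ad = ad.sort_index()
    ab = ab.loc[ad.index]
    X = pd.concat(
        [ad[feat_cols].add_prefix("ad_"), ab[feat_cols].add_prefix("ab_")], axis=1
    )
    return FeatureTable(
        X=X.reset_index(drop=True),
        y=ad["folk_type"].reset_index(drop=True),
        groups=ad["plant_id"].reset_index(drop=True),
        surface_mode=mode,
        ids=pd.Series(ad.index, name="leaf_id").reset_index(drop=True),
    )


def make_folds(
    table: FeatureTable, k: int, seed: int, group_aware: bool = False
) -> FoldAssignment:
    """Deterministic stratified fold assignment.

    Without grouping, each class is shuffled and dealt round-robin with
    a global counter, so per-class fold counts differ by at most one
    and overall fold sizes stay balanced.  With ``group_aware``, plants
    are atomic: per class (largest groups first) each plant goes to the
    currently smallest fold, a best-effort group-level stratification.
    Classes with fewer than k members are allowed but warned about.
    """
    n = table.n
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range for n={n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.intp)
    y = table.y.to_numpy()
    classes = table.classes
    small = [c for c in classes if (y == c).sum() < k]
    if small and not group_aware:
        warnings.warn(
            f"classes with fewer than k={k} instances: {small}; "
            "their fold counts cannot be balanced",
            stacklevel=2,
        )
    if not group_aware:
        counter = 0
        for c in classes:
            idx = np.flatnonzero(y == c)
            for i in rng.permutation(idx):
                fold[i] = counter % k
                counter += 1
        return FoldAssignment(fold=fold, k=k, group_aware=False)
    groups = table.groups.to_numpy()
    sizes = np.zeros(k, dtype=np.intp)
    for c in classes:
        cls_groups = sorted(
            set(groups[y == c]),
            key=lambda g: (-(groups == g).sum(), g),
        )
        for g in cls_groups:
            idx = np.flatnonzero(groups == g)
            target = int(np.argmin(sizes))
            fold[idx] = target
            sizes[target] += idx.size
    return FoldAssignment(fold=fold, k=k, group_aware=True)


@dataclass
class Scaler:
    """Per-feature z-score with train-only parameters; zero-variance
    features map to 0."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def fit_scaler(X: np.ndarray) -> Scaler:
    if len(X) == 0:
        raise ValueError("cannot fit scaler on empty training set")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return Scaler(mean=mean, std=std)


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X)


# ----------------------------------------------------------- classifiers


def _weighted_vote(
    dists: np.ndarray, labels: np.ndarray, classes: np.ndarray, ks: np.ndarray
) -> np.ndarray:
    """Inverse-distance-weighted votes for pre-sorted neighbor arrays.

    ``dists``/``labels``: (n_query, n_train) sorted by distance;
    ``ks``: neighbors to use per query.  Returns (n_query, n_classes)
    normalized scores; ties resolve to the alphabetically first class
    downstream via argmax on the sorted class axis.
    """
    n_query = dists.shape[0]
    scores = np.zeros((n_query, classes.size))
    class_idx = {c: j for j, c in enumerate(classes)}
    lab_idx = np.vectorize(class_idx.get)(labels)
    w = 1.0 / (dists + 1e-12)
    for i in range(n_query):
        k = int(ks[i])
        np.add.at(scores[i], lab_idx[i, :k], w[i, :k])
    total = scores.sum(axis=1, keepdims=True)
    return scores / np.where(total > 0, total, 1.0)


def _knn_local(Xtr, ytr, Xte, classes, k_max=15, radius_factor=3.0):
    d_tr = cdist(Xtr, Xtr)
    np.fill_diagonal(d_tr, np.inf)
    med_1nn = float(np.median(d_tr.min(axis=1)))
    radius = radius_factor * med_1nn
    d = cdist(Xte, Xtr)
    order = np.argsort(d, axis=1, kind="stable")
    ds = np.take_along_axis(d, order, axis=1)
    labs = ytr[order]
    kmax = min(k_max, Xtr.shape[0])
    within = ds[:, :kmax] <= radius
    ks = np.maximum(within.sum(axis=1), 1)
    return _weighted_vote(ds, labs, classes, ks)


def _loo_best_k(Xtr, ytr, classes, k_range=range(1, 21)) -> int:
    d = cdist(Xtr, Xtr)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    ds = np.take_along_axis(d, order, axis=1)
    labs = ytr[order]
    best_k, best_acc = 1, -1.0
    n = Xtr.shape[0]
    for k in k_range:
        if k > n - 1:
            break
        scores = _weighted_vote(ds, labs, classes, np.full(n, k))
        pred = classes[np.argmax(scores, axis=1)]
        acc = float((pred == ytr).mean())
        if acc > best_acc:  # strict: smallest k wins ties
            best_acc, best_k = acc, k
    return best_k


def _knn_weighted(Xtr, ytr, Xte, classes):
    k = _loo_best_k(Xtr, ytr, classes)
    d = cdist(Xte, Xtr)
    order = np.argsort(d, axis=1, kind="stable")
    ds = np.take_along_axis(d, order, axis=1)
    labs = ytr[order]
    return _weighted_vote(ds, labs, classes, np.full(Xte.shape[0], k))


def select_top_features(
    Xtr: np.ndarray, ytr: np.ndarray, seed: int, n_trees: int = 200
) -> np.ndarray:
    """Indices of the top ceil(p/2) features by impurity importance of
    a preliminary seeded forest (the selection step of
    ``optimized_forest``)."""
    p = Xtr.shape[1]
    pre = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features="sqrt",
        bootstrap=True, random_state=seed,
    ).fit(Xtr, ytr)
    keep = int(np.ceil(p / 2))
    return np.sort(np.argsort(pre.feature_importances_, kind="stable")[::-1][:keep])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _align_proba(proba: np.ndarray, model_classes: np.ndarray, classes: np.ndarray):
    out = np.zeros((proba.shape[0], classes.size))
    for j, c in enumerate(model_classes):
        out[:, np.searchsorted(classes, c)] = proba[:, j]
    return out


def train_predict(
    spec: ClassifierSpec,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    classes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one classifier and score a test block.

    Returns predicted labels and an (n_test, n_classes) probability
    matrix over ``classes`` (alphabetical order).  Inputs for the
    distance/kernel/network classifiers are expected pre-scaled.
    """
    ytr = np.asarray(ytr)
    if classes is None:
        classes = np.array(sorted(set(ytr)))
    if len(set(ytr)) < 2:
        warnings.warn("single-class training set: constant predictor", stacklevel=2)
        proba = np.zeros((Xte.shape[0], classes.size))
        proba[:, np.searchsorted(classes, ytr[0])] = 1.0
        return np.full(Xte.shape[0], ytr[0], dtype=object), proba

    name = spec.name
    if name == "knn_local":
        proba = _knn_local(Xtr, ytr, Xte, classes)
    elif name == "knn_weighted":
        proba = _knn_weighted(Xtr, ytr, Xte, classes)
    elif name == "random_forest":
        model = RandomForestClassifier(
            n_estimators=500, criterion="gini", max_features="sqrt",
            bootstrap=True, random_state=spec.seed,
        ).fit(Xtr, ytr)
        proba = _align_proba(model.predict_proba(Xte), model.classes_, classes)
    elif name == "optimized_forest":
        keep = select_top_features(Xtr, ytr, spec.seed)
        model = RandomForestClassifier(
            n_estimators=500, criterion="gini", max_features="sqrt",
            bootstrap=True, random_state=spec.seed,
        ).fit(Xtr[:, keep], ytr)
        proba = _align_proba(model.predict_proba(Xte[:, keep]), model.classes_, classes)
    elif name == "svm_rbf":
        p = Xtr.shape[1]
        model = SVC(
            C=10.0, gamma=1.0 / p, kernel="rbf",
            decision_function_shape="ovr",
        ).fit(Xtr, ytr)
        dec = model.decision_function(Xte)
        if dec.ndim == 1:  # binary: decision is for classes_[1]
            dec = np.column_stack([-dec, dec])
        proba = _align_proba(_softmax(dec), model.classes_, classes)
    elif name == "mlp":
        n_min = min(np.bincount(np.searchsorted(classes, ytr), minlength=classes.size)[
            np.searchsorted(classes, np.unique(ytr))
        ])
        # early stopping needs a stratifiable 10% split; fall back on
        # tiny training sets rather than crash
        early = Xtr.shape[0] >= 40 and n_min >= 4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MLPClassifier(
                hidden_layer_sizes=(64,), activation="relu", solver="adam",
                max_iter=500, early_stopping=early, validation_fraction=0.1,
                n_iter_no_change=10, random_state=spec.seed,
            ).fit(Xtr, ytr)
        proba = _align_proba(model.predict_proba(Xte), model.classes_, classes)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(f"unknown classifier {name!r}")

    pred = classes[np.argmax(proba, axis=1)]
    return pred, proba


# -------------------------------------------------------------- metrics


def _fold_class_metrics(y_true, y_pred, classes) -> pd.DataFrame:
    rows = []
    for c in classes:
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append(
            {"class": c, "precision": prec, "recall": rec, "f": f,
             "support": int((y_true == c).sum())}
        )
    return pd.DataFrame(rows)


def weighted_ovr_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    """Support-weighted one-vs-rest ROC area from rank statistics.

    Per class, the area is the Mann-Whitney U of the class score
    between positives and negatives; classes without both positives
    and negatives in the block are skipped.
    """
    aucs, weights = [], []
    for j, c in enumerate(classes):
        pos = y_true == c
        n1, n0 = int(pos.sum()), int((~pos).sum())
        if n1 == 0 or n0 == 0:
            continue
        r = rankdata(proba[:, j])
        u = r[pos].sum() - n1 * (n1 + 1) / 2
        aucs.append(u / (n1 * n0))
        weights.append(n1)
    if not aucs:
        return float("nan")
    return float(np.average(aucs, weights=weights))


def cross_validate(
    table: FeatureTable, spec: ClassifierSpec, folds: FoldAssignment
) -> CVResult:
    """Run the fold loop: scale on train, fit, predict held-out.

    Every instance is predicted exactly once; pooled confusion counts
    therefore sum to the instance count.
    """
    classes = np.array(table.classes)
    X = table.X.to_numpy(dtype=np.float64)
    y = table.y.to_numpy()
    n = table.n
    pred = np.empty(n, dtype=object)
    proba = np.zeros((n, classes.size))
    fold_rows, class_rows = [], []
    for f in range(folds.k):
        te = folds.fold == f
        tr = ~te
        if not te.any():
            continue
        if len(set(y[tr])) < 2:
            raise ValueError(f"fold {f}: training split has fewer than 2 classes")
        Xtr, Xte = X[tr], X[te]
        if spec.name in SCALED_CLASSIFIERS:
            scaler = fit_scaler(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        p_lab, p_sc = train_predict(spec, Xtr, y[tr], Xte, classes)
        pred[te] = p_lab
        proba[te] = p_sc
        cm_f = _fold_class_metrics(y[te], p_lab, classes)
        cm_f.insert(0, "fold", f)
        class_rows.append(cm_f)
        sup = cm_f["support"].to_numpy()
        wf = float(np.average(cm_f["f"], weights=sup)) if sup.sum() else 0.0
        fold_rows.append(
            {
                "fold": f,
                "accuracy": float((p_lab == y[te]).mean()),
                "weighted_f": wf,
                "roc_auc": weighted_ovr_auc(y[te], p_sc, classes),
            }
        )
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, pred):
        cm.loc[t, p] += 1
    predictions = pd.DataFrame(
        {"id": table.ids, "fold": folds.fold, "true": y, "predicted": pred}
    )
    for j, c in enumerate(classes):
        predictions[f"p_{c}"] = proba[:, j]
    return CVResult(
        classifier=spec.name,
        surface_mode=table.surface_mode,
        fold_metrics=pd.DataFrame(fold_rows),
        per_class=pd.concat(class_rows, ignore_index=True),
        confusion=cm,
        predictions=predictions,
    )
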