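"""One-vs-one RBF-SVM ensemble with accuracy-weighted voting.

Three soft-margin binary SVMs are trained, one per class pair —
(viable, aged), (viable, non-viable), (aged, non-viable) — each on the
samples of its own two classes only.  At prediction time every binary
classifier casts a vote for one class, weighted by its normalized
training accuracy

    w_i = p_i / sum_j p_j,

and the class with the largest weight sum wins.  With equal training
accuracies the weights are uniform and the scheme reduces to plain
majority voting.  The quadratic programs behind the binary margins are
solved by scikit-learn's SVC; the pairing, weighting, voting, fold
handling and reporting live here.

Both the regularization parameter C and the RBF kernel width default
to 2, and model selection uses 5-fold cross-validation with random
(non-stratified) fold assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

__all__ = [
    "CLASS_ORDER",
    "KernelSpec",
    "BinaryModel",
    "EnsembleModel",
    "CVReport",
    "kernel",
    "kernel_matrix",
    "train_binary",
    "build_ensemble",
    "predict",
    "cross_validate",
    "accuracy_report",
]

logger = logging.getLogger(__name__)

CLASS_ORDER = ("viable", "aged", "non_viable")
PAIRS = (("viable", "aged"), ("viable", "non_viable"), ("aged", "non_viable"))


@dataclass(frozen=True)
class KernelSpec:
    """RBF kernel variant and width.

    ``squared_distance`` is the standard RBF exp(-gamma * ||x-y||^2)
    with ``width`` playing gamma.  ``unsquared`` is a Laplacian-like
    variant exp(-||x-y|| / width) occasionally seen in applied work,
    kept as an audit option; ``width`` then plays sigma^2.
    """

    form: str = "squared_distance"
    width: float = 2.0

    def __post_init__(self) -> None:
        if self.form not in ("squared_distance", "unsquared"):
            raise ValueError(f"unknown kernel form {self.form!r}")
        if self.width <= 0:
            raise ValueError("kernel width must be positive")


def kernel(x1, x2, spec: KernelSpec = KernelSpec()) -> float:
    """Similarity of two feature vectors; K(x, x) = 1, 0 < K <= 1."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x1.shape} vs {x2.shape}")
    d2 = float(((x1 - x2) ** 2).sum())
    if spec.form == "squared_distance":
        return float(np.exp(-spec.width * d2))
    return float(np.exp(-np.sqrt(d2) / spec.width))


def kernel_matrix(a: np.ndarray, b: np.ndarray,
                  spec: KernelSpec = KernelSpec()) -> np.ndarray:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    if spec.form == "squared_distance":
        return np.exp(-spec.width * cdist(a, b, "sqeuclidean"))
    return np.exp(-cdist(a, b, "euclidean") / spec.width)


@dataclass
class BinaryModel:
    """One pairwise soft-margin classifier.

    The decision function is f(x) = sum_i y_i alpha_i K(x_i, x) + b;
    its sign selects between the two classes of the pair.
    """

    class_pair: tuple[str, str]
    C: float
    spec: KernelSpec
    svc: SVC = field(repr=False)

    @property
    def support_vectors(self) -> np.ndarray:
        if self.spec.form == "squared_distance":
            return self.svc.support_vectors_
        return self._X[self.svc.support_]

    @property
    def dual_signed_alphas(self) -> np.ndarray:
        """y_i * alpha_i for each support vector."""
        return self.svc.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])

    def decision_value(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.svc.decision_function(X)

    def predict_pair(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.svc.predict(X)


def train_binary(X, y, C: float = 2.0,
                 spec: KernelSpec = KernelSpec()) -> BinaryModel:
    """Fit one soft-margin kernel SVM on a two-class sample.

    The dual solution satisfies 0 <= alpha_i <= C and
    sum_i y_i alpha_i = 0 (checked after fitting).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(
        set(y.tolist()),
        key=lambda c: ((0, CLASS_ORDER.index(c)) if c in CLASS_ORDER
                       else (1, str(c))))
    if len(classes) != 2:
        raise ValueError(f"binary training needs exactly two classes, got {classes}")
    if spec.form == "squared_distance":
        svc = SVC(C=C, kernel="rbf", gamma=spec.width)
    else:
        svc = SVC(C=C, kernel=lambda a, b: kernel_matrix(a, b, spec))
    svc.fit(X, y)
    model = BinaryModel(class_pair=tuple(classes), C=C, spec=spec, svc=svc)
    model._X = X
    signed = model.dual_signed_alphas
    if abs(signed.sum()) > 1e-6 * max(1.0, C):
        logger.warning("dual equality constraint violated by %.2e", signed.sum())
    return model


def _fit_scaler(X: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    if mode == "minmax":
        center = X.min(axis=0)
        scale = X.max(axis=0) - center
    elif mode == "zscore":
        center = X.mean(axis=0)
        scale = X.std(axis=0)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    scale[scale == 0.0] = 1.0
    return center, scale


@dataclass
class EnsembleModel:
    """Three pairwise SVMs plus normalized voting weights."""

    models: list[BinaryModel]
    training_accuracies: np.ndarray
    weights: np.ndarray
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.center is None:
            return X
        return (X - self.center) / self.scale


def _inner_cv_accuracy(X: np.ndarray, y: np.ndarray, C: float,
                       spec: KernelSpec, folds: int = 3) -> float:
    """Deterministic stratified inner CV accuracy for one class pair.

    Members of each class are dealt round-robin into folds, so the
    estimate needs no extra randomness.  Falls back to resubstitution
    when a split would lose a class.
    """
    assignment = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        assignment[idx] = np.arange(idx.size) % folds
    correct = 0
    for fold in range(folds):
        test = assignment == fold
        if not test.any():
            continue
        train = ~test
        if len(set(y[train].tolist())) < 2:
            logger.info("inner CV fold lost a class; using resubstitution")
            model = train_binary(X, y, C, spec)
            return float((model.predict_pair(X) == y).mean())
        model = train_binary(X[train], y[train], C, spec)
        correct += int((model.predict_pair(X[test]) == y[test]).sum())
    return correct / y.size


def build_ensemble(X, y, C: float = 2.0, spec: KernelSpec = KernelSpec(),
                   scaling: str = "minmax",
                   weighting: str = "training_accuracy",
                   p_mode: str = "resubstitution") -> EnsembleModel:
    """Train the three pairwise classifiers and their voting weights.

    Each binary model sees only the samples of its two classes; its
    weight derives from its resubstitution accuracy on that training
    subset (``weighting='uniform'`` gives plain majority voting;
    ``p_mode='inner_cv'`` estimates p_i by a deterministic inner
    3-fold CV instead of resubstitution).
    Per-column scaling is fitted on the training rows here and stored
    with the model, so test vectors are scaled identically.  The
    default maps each training column onto [0, 1] (min-max), which
    keeps pairwise squared distances of order one so the fixed-width
    RBF kernel stays informative regardless of feature units;
    ``scaling='zscore'`` standardizes instead, and ``scaling='none'``
    feeds raw features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    missing = [c for c in CLASS_ORDER if c not in set(y.tolist())]
    if missing:
        raise ValueError(f"training data lacks class(es): {missing}")
    if weighting not in ("training_accuracy", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")

    center = scale = None
    if scaling != "none":
        center, scale = _fit_scaler(X, scaling)
        X = (X - center) / scale

    if p_mode not in ("resubstitution", "inner_cv"):
        raise ValueError(f"unknown p_mode {p_mode!r}")
    models = []
    accs = []
    for pair in PAIRS:
        sel = np.isin(y, pair)
        model = train_binary(X[sel], y[sel], C, spec)
        if p_mode == "inner_cv":
            acc = _inner_cv_accuracy(X[sel], y[sel], C, spec)
        else:
            acc = float((model.predict_pair(X[sel]) == y[sel]).mean())
        models.append(model)
        accs.append(acc)
    accs = np.asarray(accs)
    if weighting == "uniform" or accs.sum() == 0.0:
        weights = np.full(3, 1.0 / 3.0)
    else:
        weights = accs / accs.sum()
    return EnsembleModel(models=models, training_accuracies=accs,
                         weights=weights, center=center, scale=scale)


def predict(ensemble: EnsembleModel, X) -> np.ndarray:
    """Weighted-vote class prediction for one or more feature vectors.

    Ties in the weight sums are broken by the larger total |decision
    value| among the tied classes, then by fixed class order
    (viable < aged < non_viable).
    """
    Xs = ensemble.transform(X)
    n = Xs.shape[0]
    votes = np.zeros((n, len(CLASS_ORDER)))
    margins = np.zeros((n, len(CLASS_ORDER)))
    for model, weight in zip(ensemble.models, ensemble.weights):
        pred = model.predict_pair(Xs)
        dec = np.abs(model.decision_value(Xs))
        for ci, cls in enumerate(CLASS_ORDER):
            sel = pred == cls
            votes[sel, ci] += weight
            margins[sel, ci] += dec[sel]
    out = np.empty(n, dtype=object)
    for i in range(n):
        best = np.flatnonzero(votes[i] == votes[i].max())
        if best.size > 1:
            tied = best[margins[i, best] == margins[i, best].max()]
            best = tied
        out[i] = CLASS_ORDER[best[0]]
    return out


@dataclass
class CVReport:
    """k-fold cross-validation results in the misjudgment/total layout."""

    fold_assignment: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    folds: list[dict]
    confusion: pd.DataFrame  # rows: predicted class, columns: true class

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for cls in CLASS_ORDER:
            total = int((self.y_true == cls).sum())
            if total:
                correct = int(((self.y_true == cls)
                               & (self.y_pred == cls)).sum())
                out[cls] = correct / total
        return out

    @property
    def overall_accuracy(self) -> float:
        return float((self.y_true == self.y_pred).mean())

    def fold_table(self) -> pd.DataFrame:
        """Per-fold counts and accuracies, folds as columns."""
        cols = {}
        for f in self.folds:
            col = {"training_number": f["train_n"],
                   "prediction_number": f["predict_n"]}
            for cls in CLASS_ORDER:
                m, t = f["misjudged"][cls], f["totals"][cls]
                col[f"{cls}_misjudged/total"] = f"{m}/{t}"
                col[f"{cls}_accuracy"] = (t - m) / t if t else np.nan
            col["fold_accuracy"] = f["accuracy"]
            cols[f"fold_{f['fold']}"] = col
        return pd.DataFrame(cols)

    def class_table(self) -> pd.DataFrame:
        """Pooled confusion and per-class accuracies, classes as columns."""
        table = self.confusion.copy()
        mis = {}
        acc = {}
        for cls in CLASS_ORDER:
            total = int(table[cls].sum())
            correct = int(table.loc[cls, cls])
            mis[cls] = f"{total - correct}/{total}"
            acc[cls] = (correct / total) if total else np.nan
        table.loc["misjudged/total"] = pd.Series(mis)
        table.loc["accuracy"] = pd.Series(acc)
        return table


def _draw_folds(n: int, k: int, rng: np.random.Generator,
                y: np.ndarray, stratified: bool,
                max_redraws: int = 20) -> np.ndarray:
    """Fold assignment such that every training set keeps all classes."""
    classes = np.unique(y)
    for attempt in range(max_redraws):
        assignment = np.empty(n, dtype=int)
        if stratified:
            for cls in classes:
                idx = np.flatnonzero(y == cls)
                rng.shuffle(idx)
                for fold, chunk in enumerate(np.array_split(idx, k)):
                    assignment[chunk] = fold
        else:
            perm = rng.permutation(n)
            for fold, chunk in enumerate(np.array_split(perm, k)):
                assignment[chunk] = fold
        ok = all(
            set(classes) <= set(y[assignment != fold].tolist())
            for fold in range(k)
        )
        if ok:
            if attempt:
                logger.info("fold draw accepted after %d redraws", attempt)
            return assignment
        logger.info("fold draw %d left a training set without all classes; "
                    "redrawing", attempt)
    raise ValueError(f"could not draw {k} folds keeping all classes in "
                     f"every training set after {max_redraws} attempts")


def cross_validate(X, y, k: int = 5, C: float = 2.0,
                   spec: KernelSpec = KernelSpec(), rng_seed: int = 0,
                   stratified: bool = False, scaling: str = "minmax",
                   weighting: str = "training_accuracy") -> CVReport:
    """Random k-fold cross-validation of the voting ensemble.

    Folds partition the cohort into near-equal held-out sets; scaling
    and the three binary models are refitted on each training split.
    Identical ``rng_seed`` gives identical folds and reports.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= {n}, got k={k}")
    rng = np.random.default_rng(rng_seed)
    assignment = _draw_folds(n, k, rng, y, stratified)

    y_pred = np.empty(n, dtype=object)
    folds = []
    for fold in range(k):
        test = assignment == fold
        train = ~test
        ens = build_ensemble(X[train], y[train], C, spec,
                             scaling=scaling, weighting=weighting)
        pred = predict(ens, X[test])
        y_pred[test] = pred
        misjudged = {}
        totals = {}
        for cls in CLASS_ORDER:
            sel = y[test] == cls
            totals[cls] = int(sel.sum())
            misjudged[cls] = int((pred[sel] != cls).sum())
        folds.append({
            "fold": fold + 1,
            "train_n": int(train.sum()),
            "predict_n": int(test.sum()),
            "misjudged": misjudged,
            "totals": totals,
            "accuracy": float((pred == y[test]).mean()),
        })

    confusion = pd.DataFrame(0, index=list(CLASS_ORDER),
                             columns=list(CLASS_ORDER))
    for true_cls, pred_cls in zip(y, y_pred):
        confusion.loc[pred_cls, true_cls] += 1
    return CVReport(fold_assignment=assignment, y_true=y, y_pred=y_pred,
                    folds=folds, confusion=confusion)


def accuracy_report(misjudged: dict[str, int],
                    totals: dict[str, int]) -> dict[str, float]:
    """Per-class and overall accuracy from misjudgment/total counts.

    Per-class accuracy is (total - misjudged)/total; overall accuracy
    is 1 - sum(misjudged)/sum(totals).  Values are fractions in [0, 1].
    """
    if set(misjudged) != set(totals):
        raise ValueError("misjudged and totals must cover the same classes")
    out = {}
    for cls, total in totals.items():
        if total <= 0:
            raise ValueError(f"class {cls!r} has zero prediction count")
        m = misjudged[cls]
        if not 0 <= m <= total:
            raise ValueError(f"class {cls!r}: misjudged {m} outside [0, {total}]")
        out[cls] = (total - m) / total
    out["overall"] = 1.0 - sum(misjudged.values()) / sum(totals.values())
    return out
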