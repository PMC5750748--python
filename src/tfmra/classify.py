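"""Multi-class artifact classification, CV metrics, PCA, and comparisons.

Three predictive models mirror common EEG-artifact practice: a soft-margin
SVM with a Gaussian (RBF) kernel, a deep information-gain decision tree, and
a 1-nearest-neighbour classifier.  Evaluation uses stratified k-fold
cross-validation in which each sample is validated exactly once; features
are standardized per training fold to avoid leakage.  Method comparisons
use a one-tailed exact Wilcoxon signed-rank test (full enumeration of sign
patterns for small n) and Welch's two-sample t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_KINDS = ("svm_rbf", "complex_tree", "knn1")


@dataclass
class ModelSpec:
    """Classifier choice and hyperparameters.

    ``svm_gamma="auto"`` means scikit-learn's ``"scale"`` heuristic,
    1 / (n_features * feature variance). ``tree_max_splits`` caps the number
    of internal splits of the otherwise unconstrained tree.
    """

    kind: str = "svm_rbf"
    svm_c: float = 10.0
    svm_gamma: float | str = "auto"
    tree_max_splits: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model {self.kind!r}; "
                             f"choose from {MODEL_KINDS}")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.tree_max_splits < 1:
            raise ValueError("tree_max_splits must be >= 1")

    def build(self):
        if self.kind == "svm_rbf":
            gamma = "scale" if self.svm_gamma == "auto" else self.svm_gamma
            return SVC(C=self.svm_c, kernel="rbf", gamma=gamma,
                       decision_function_shape="ovo",
                       random_state=self.seed)
        if self.kind == "complex_tree":
            return DecisionTreeClassifier(
                criterion="entropy",
                max_leaf_nodes=self.tree_max_splits + 1,
                random_state=self.seed)
        return KNeighborsClassifier(n_neighbors=1)


@dataclass
class CvResult:
    """Aggregated cross-validation outcome."""

    fold_assignment: np.ndarray
    predictions: np.ndarray
    confusion: np.ndarray
    class_names: list[str]
    per_class_sensitivity: np.ndarray  # percent; NaN when a class is absent
    per_class_specificity: np.ndarray  # percent
    total_accuracy: float              # percent


@dataclass
class PcaModel:
    """Fitted principal-component reduction with feature loadings."""

    components: np.ndarray              # (n_kept, n_features) orthonormal rows
    explained_variance_ratio: np.ndarray
    n_kept: int
    loadings: np.ndarray                # same shape as components
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    kept_columns: np.ndarray

    def contributions(self, component: int = 0) -> np.ndarray:
        """Percent contribution of each input feature to one component."""
        w = self.loadings[component] ** 2
        return 100.0 * w / w.sum()


def _as_matrix(features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2D table (samples x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def run_cv(features, labels, model: ModelSpec | None = None,
           k_folds: int = 10, seed: int = 0,
           standardize: bool = True) -> CvResult:
    """Stratified k-fold cross-validation with per-fold standardization.

    Each sample is held out exactly once; the confusion matrix and rates are
    aggregated over all folds.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if model is None:
        model = ModelSpec()
    class_names = [str(c) for c in np.unique(y)]
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    too_small = [c for c, n in counts.items() if n < k_folds]
    if too_small:
        raise ValueError(
            f"classes {too_small} have fewer samples than {k_folds} folds")

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_assignment = np.full(len(y), -1, dtype=int)
    predictions = np.empty(len(y), dtype=object)
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_assignment[test_idx] = fold
        X_tr, X_te = X[train_idx], X[test_idx]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
            X_tr = (X_tr - scaler.mean_) / scale
            X_te = (X_te - scaler.mean_) / scale
        clf = model.build()
        clf.fit(X_tr, y[train_idx])
        predictions[test_idx] = clf.predict(X_te)

    lut = {c: i for i, c in enumerate(class_names)}
    confusion = np.zeros((len(class_names), len(class_names)), dtype=int)
    for true, pred in zip(y, predictions):
        confusion[lut[str(true)], lut[str(pred)]] += 1
    sens, spec, acc = confusion_metrics(confusion)
    return CvResult(fold_assignment, np.array([str(p) for p in predictions]),
                    confusion, class_names, sens, spec, acc)


def confusion_metrics(confusion: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-class sensitivity and specificity (percent) and total accuracy.

    sensitivity_c = TP_c / (TP_c + FN_c); specificity_c = TN_c / (TN_c +
    FP_c); accuracy = trace / total.  A class with no true samples has
    undefined sensitivity, reported as NaN.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    total = cm.sum()
    tp = np.diag(cm)
    row = cm.sum(axis=1)  # true counts per class
    col = cm.sum(axis=0)  # predicted counts per class
    fp = col - tp
    tn = total - row - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = np.where(row > 0, tp / row * 100.0, np.nan)
        specificity = np.where((tn + fp) > 0, tn / (tn + fp) * 100.0, np.nan)
    accuracy = float(tp.sum() / total * 100.0) if total > 0 else float("nan")
    return sensitivity, specificity, accuracy


def pca_reduce(features, n_components: int = 10,
               feature_names: list[str] | None = None,
               unit_scale: bool = True) -> tuple[PcaModel, np.ndarray]:
    """Center (and unit-scale) columns, project onto the top components.

    Constant feature columns are dropped with a warning before scaling.
    Returns the fitted model (with per-feature loadings for
    contribution-to-PC reports) and the reduced table.
    """
    X = _as_matrix(features)
    n_samples, n_feat = X.shape
    if n_samples <= n_components:
        raise ValueError("need more samples than components")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_feat)]
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant feature columns",
            stacklevel=2)
    X = X[:, keep]
    names = [n for n, k in zip(feature_names, keep) if k]
    mean = X.mean(axis=0)
    scale = X.std(axis=0) if unit_scale else np.ones(X.shape[1])
    Xs = (X - mean) / scale
    pca = PCA(n_components=min(n_components, Xs.shape[1]), svd_solver="full")
    reduced = pca.fit_transform(Xs)
    model = PcaModel(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_kept=pca.n_components_,
        loadings=pca.components_ * np.sqrt(pca.explained_variance_)[:, None],
        feature_names=names,
        mean=mean,
        scale=scale,
        kept_columns=np.nonzero(keep)[0],
    )
    return model, reduced


# ---------------------------------------------------------------------------
# Statistical method comparisons
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(ranks: np.ndarray, t_obs: float) -> float:
    """P(T+ >= t_obs) under the exact signed-rank null for these ranks."""
    n = len(ranks)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        t = sum(r for s, r in zip(signs, ranks) if s)
        if t >= t_obs - 1e-12:
            count += 1
    return count / 2 ** n


def wilcoxon_onetailed(acc_a, acc_b) -> tuple[float, float]:
    """One-tailed Wilcoxon signed-rank test of "a > b" on paired accuracies.

    Zero differences are dropped (Wilcoxon convention); |differences| are
    ranked with average ranks for ties and the one-sided p-value of the
    positive-rank sum is computed by full enumeration of the 2^n sign
    patterns for n <= 15, by a normal approximation with continuity
    correction beyond.  Returns (p_value, confidence percent = (1-p)*100).
    All-zero differences give p = 1 by convention.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0, 0.0
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    n = len(d)
    if n <= 15:
        p = _signed_rank_exact_p(ranks, t_plus)
    else:
        mu = n * (n + 1) / 4.0
        ties = np.unique(ranks, return_counts=True)[1]
        var = (n * (n + 1) * (2 * n + 1) - ((ties ** 3 - ties) / 2).sum()) / 24.0
        z = (t_plus - mu - 0.5) / np.sqrt(var)
        p = float(stats.norm.sf(z))
    p = min(max(p, 0.0), 1.0)
    return p, (1.0 - p) * 100.0


def ttest_two_sample(acc_a, acc_b, alpha: float = 0.005
                     ) -> tuple[float, float, bool]:
    """Welch two-sample t-test (two-sided); reject iff p < alpha.

    Two zero-variance samples with equal means give (0, 1, False).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var() == 0 and b.var() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < alpha)
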