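"""Linear-SVM discrimination of patients vs controls from dALFF features.

The default feature is a single scalar per subject: the mean CV of windowed
ALFF within the group-difference cluster.  Generalization is estimated with
leave-one-out or stratified k-fold cross-validation; significance of the
cross-validated accuracy comes from a full label-permutation test (labels
shuffled, the entire CV re-run, add-one p-value).

Feature standardization uses training-fold mean/SD only; the held-out fold is
transformed with the training parameters.  Predictions at a decision score of
exactly 0 are assigned to the control class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "CvResult",
    "PermutationResult",
    "LinearDecisionRule",
    "extract_cluster_feature",
    "train_linear_classifier",
    "loocv_classify",
    "kfold_classify",
    "roc_auc",
    "label_permutation_test",
]

logger = logging.getLogger(__name__)

PATIENT, CONTROL = 1, 0


@dataclass
class FeatureMatrix:
    """Rows = subjects, columns = features; labels patient=1 / control=0."""

    X: np.ndarray
    labels: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] == 1 and np.asarray(self.labels).size > 1:
            self.X = self.X.T
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[0] != self.labels.size:
            raise ValueError("labels must align with feature rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain missing/non-finite values")


@dataclass
class CvResult:
    """Held-out predictions and aggregate performance of one CV scheme."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    scheme: str

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores, scheme: str) -> "CvResult":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        scores = np.asarray(scores, dtype=float)
        tp = int(((y_true == PATIENT) & (y_pred == PATIENT)).sum())
        tn = int(((y_true == CONTROL) & (y_pred == CONTROL)).sum())
        n_pos = int((y_true == PATIENT).sum())
        n_neg = int((y_true == CONTROL).sum())
        return cls(y_true, y_pred, scores,
                   accuracy=(tp + tn) / y_true.size,
                   sensitivity=tp / n_pos if n_pos else np.nan,
                   specificity=tn / n_neg if n_neg else np.nan,
                   auc=roc_auc(scores, y_true), scheme=scheme)

    def roc_points(self) -> np.ndarray:
        """(threshold, FPR, TPR) triples from the pooled held-out scores."""
        order = np.argsort(-self.scores)
        ys = self.y_true[order]
        tpr = np.cumsum(ys == PATIENT) / max((ys == PATIENT).sum(), 1)
        fpr = np.cumsum(ys == CONTROL) / max((ys == CONTROL).sum(), 1)
        return np.column_stack([self.scores[order], fpr, tpr])


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_perm: int


@dataclass
class LinearDecisionRule:
    """Linear rule in raw feature units: score = weights . x + bias."""

    weights: np.ndarray
    bias: float

    def decision(self, X) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        return (self.decision(X) > 0).astype(int)


def extract_cluster_feature(maps: np.ndarray, cluster_mask: np.ndarray,
                            labels=None, subject_ids=None,
                            voxelwise: bool = False) -> FeatureMatrix | np.ndarray:
    """Per-subject mean of each map over the cluster voxels (default), or the
    raw voxel values as columns (``voxelwise=True``)."""
    maps = np.asarray(maps, dtype=float)
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("cluster mask is empty")
    vals = maps[:, cluster_mask]
    X = vals if voxelwise else vals.mean(axis=1, keepdims=True)
    if labels is None:
        return X
    return FeatureMatrix(X, labels, subject_ids)


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")


_TOL = 1e-9


def _svm1d_oriented(x: np.ndarray, s: np.ndarray, C: float):
    """KKT enumeration for the 1-D soft-margin SVM restricted to w > 0.

    s is the +1/-1 label vector.  Returns (w, b, objective) of the best
    KKT-consistent candidate with w > 0, or None.  Candidates are (a) one free
    support vector per class (two linear equations in their dual weights) and
    (b) no free support vectors (k bound violators per class, the margin lines
    falling between order statistics).  Any KKT point of this convex QP is a
    global optimum.
    """
    xp = np.sort(x[s > 0])
    xn = np.sort(x[s < 0])
    np_, nn = xp.size, xn.size
    best = None

    def objective(w, b):
        margins = 1.0 - s * (w * x + b)
        return 0.5 * w * w + C * np.maximum(margins, 0.0).sum()

    # (a) free SVs at x_p (+ class) and x_q (- class), x_p > x_q
    csum_p = np.concatenate([[0.0], np.cumsum(xp)])       # sum of + below rank
    csum_n_desc = np.concatenate([[0.0], np.cumsum(xn[::-1])])
    P, Q = np.meshgrid(np.arange(np_), np.arange(nn), indexing="ij")
    xpv, xqv = xp[P], xn[Q]
    gap = xpv - xqv
    ok = gap > _TOL
    n_viol_p = P                      # + points strictly below x_p
    n_viol_n = nn - 1 - Q             # - points strictly above x_q
    S = csum_p[P] - (csum_n_desc[nn - 1 - Q])
    delta = C * (n_viol_n - n_viol_p).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_q = (2.0 / gap - C * S - delta * xpv) / gap
    a_p = a_q + delta
    feas = ok & (a_p > -_TOL) & (a_p < C + _TOL) & \
        (a_q > -_TOL) & (a_q < C + _TOL)
    if feas.any():
        idx = np.argwhere(feas)
        w_cand = 2.0 / gap[feas]
        b_cand = 1.0 - w_cand * xpv[feas]
        for w, b in zip(w_cand, b_cand):
            obj = objective(w, b)
            if best is None or obj < best[2] - 1e-12:
                best = (w, b, obj)

    # (b) no free SVs: k bound violators per class
    for k in range(1, min(np_, nn) + 1):
        w = C * (csum_p[k] - csum_n_desc[k])
        if w <= _TOL:
            continue
        # m_plus in [xp[k-1], xp[k] or +inf], m_minus in [-inf or xn[nn-k-1], xn[nn-k]]
        mp_lo, mp_hi = xp[k - 1], (xp[k] if k < np_ else np.inf)
        mn_lo = xn[nn - k - 1] if k < nn else -np.inf
        mn_hi = xn[nn - k]
        lo = max(mp_lo, mn_lo + 2.0 / w)
        hi = min(mp_hi, mn_hi + 2.0 / w)
        if lo <= hi + _TOL:
            m_plus = (lo + hi) / 2.0 if np.isfinite(lo + hi) else \
                (lo if np.isfinite(lo) else hi)
            b = 1.0 - w * m_plus
            obj = objective(w, b)
            if best is None or obj < best[2] - 1e-12:
                best = (w, b, obj)
    return best


def _svm1d(x: np.ndarray, y: np.ndarray, C: float) -> tuple[float, float]:
    """Exact soft-margin linear SVM for a single feature.

    Solves the same primal as a linear-kernel SVC by enumerating
    KKT-consistent configurations in both orientations; used as a fast path
    when the feature matrix has one column (the cluster-mean feature), where
    permutation testing re-runs the full CV thousands of times.
    """
    s = np.where(y == PATIENT, 1.0, -1.0)
    cand = _svm1d_oriented(x, s, C)
    mirror = _svm1d_oriented(-x, s, C)
    if mirror is not None:
        m = (-mirror[0], mirror[1], mirror[2])
        if cand is None or m[2] < cand[2]:
            cand = m
    if cand is None:  # fully degenerate; fall back to the reference solver
        clf = SVC(kernel="linear", C=C).fit(x[:, None], y)
        return float(clf.coef_[0, 0]), float(clf.intercept_[0])
    return float(cand[0]), float(cand[1])


def _fit_fold(X_tr, y_tr, X_te, C: float) -> np.ndarray:
    """Fit scaler+linear SVM on the training fold, return held-out scores."""
    X_tr = np.asarray(X_tr, dtype=float)
    X_te = np.asarray(X_te, dtype=float)
    if X_tr.shape[1] == 1:
        mu = X_tr.mean()
        sd = X_tr.std()
        sd = sd if sd > 0 else 1.0
        w, b = _svm1d((X_tr.ravel() - mu) / sd, np.asarray(y_tr), C)
        return w * (X_te.ravel() - mu) / sd + b
    scaler = StandardScaler().fit(X_tr)
    clf = SVC(kernel="linear", C=C).fit(scaler.transform(X_tr), y_tr)
    return clf.decision_function(scaler.transform(X_te))


def train_linear_classifier(features, labels, C: float = 1.0
                            ) -> LinearDecisionRule:
    """Maximum-margin linear rule (hinge loss at cost C) on all subjects,
    returned in raw feature units with the standardization folded in."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    scaler = StandardScaler().fit(X)
    clf = SVC(kernel="linear", C=C).fit(scaler.transform(X), y)
    w_std = clf.coef_.ravel()
    b_std = float(clf.intercept_[0])
    w_raw = w_std / scaler.scale_
    b_raw = b_std - float(w_raw @ scaler.mean_)
    return LinearDecisionRule(w_raw, b_raw)


def loocv_classify(features, labels, C: float = 1.0) -> CvResult:
    """Leave-one-out CV: each subject predicted by a model trained on the
    remaining n-1; metrics aggregated over held-out predictions only."""
    fm = FeatureMatrix(features, labels)
    n = fm.labels.size
    scores = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        _check_two_classes(fm.labels[tr])
        scores[i] = _fit_fold(fm.X[tr], fm.labels[tr], fm.X[[i]], C)[0]
    preds = (scores > 0).astype(int)
    return CvResult.from_predictions(fm.labels, preds, scores, "loocv")


def kfold_classify(features, labels, k: int = 10, seed: int = 0,
                   C: float = 1.0) -> CvResult:
    """Stratified k-fold CV seeded for a reproducible partition.

    ``k = n`` reduces to LOOCV.  If a class has fewer than k members, k is
    reduced to the smallest class size with a warning.
    """
    fm = FeatureMatrix(features, labels)
    n = fm.labels.size
    if k > n:
        raise ValueError("k must be <= n")
    if k == n:
        res = loocv_classify(fm.X, fm.labels, C)
        return CvResult.from_predictions(res.y_true, res.y_pred, res.scores,
                                         f"kfold({k}, seed={seed})")
    min_class = int(np.bincount(fm.labels).min())
    if k > min_class:
        logger.warning("k=%d exceeds smallest class size %d; using k=%d",
                       k, min_class, min_class)
        k = min_class
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(n)
    for tr, te in skf.split(fm.X, fm.labels):
        scores[te] = _fit_fold(fm.X[tr], fm.labels[tr], fm.X[te], C)
    preds = (scores > 0).astype(int)
    return CvResult.from_predictions(fm.labels, preds, scores,
                                     f"kfold({k}, seed={seed})")


def roc_auc(scores, labels) -> float:
    """AUC as the rank statistic: probability a random patient outscores a
    random control, ties counting one half."""
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def label_permutation_test(features, labels, n_perm: int = 5000,
                           seed: int = 0, scheme: str = "loocv",
                           k: int = 10, C: float = 1.0) -> PermutationResult:
    """Permutation test of cross-validated accuracy.

    Each iteration shuffles the label vector (preserving group sizes) and
    re-runs the full CV; p = (1 + #{null >= observed}) / (1 + n_perm), never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fm = FeatureMatrix(features, labels)

    def run(y):
        if scheme == "loocv":
            return loocv_classify(fm.X, y, C).accuracy
        elif scheme == "kfold":
            return kfold_classify(fm.X, y, k=k, seed=seed, C=C).accuracy
        raise ValueError(f"unknown scheme {scheme!r}")

    observed = run(fm.labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = run(rng.permutation(fm.labels))
    p = float((1 + (null >= observed).sum()) / (1 + n_perm))
    return PermutationResult(observed, null, p, n_perm)
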