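"""Biomarker evaluation: ROC with Youden cut-off, bootstrap AUC CI, and a
PCA + AdaBoost leave-one-out baseline on first-derivative spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .core import ValidationError

__all__ = [
    "RocResult",
    "ConfusionMatrix",
    "roc_youden",
    "bootstrap_auc_ci",
    "pca_scores",
    "loocv_adaboost",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    direction: str  # lower_is_case | higher_is_case
    auc_ci: tuple[float, float] | None = None
    youden: float = float("nan")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


def _validate_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    if len(set(labels.tolist())) != 2:
        raise ValidationError("both classes must be present")
    return scores, labels


def roc_youden(scores, labels, direction: str = "higher_is_case") -> RocResult:
    """Empirical ROC with the Youden-index optimal cut-off.

    ``labels`` are 0 (control) / 1 (case).  With ``lower_is_case`` the
    score sign is flipped internally so a *low* biomarker flags disease.
    The cut-off maximizing J = sensitivity + specificity − 1 is reported
    as the midpoint between the adjacent observed scores (on the original
    scale); J-ties break toward higher specificity.
    """
    scores, labels = _validate_scores(scores, labels)
    if direction not in ("higher_is_case", "lower_is_case"):
        raise ValueError(f"unknown direction {direction!r}")
    s = -scores if direction == "lower_is_case" else scores
    auc = float(roc_auc_score(labels, s))

    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    uniq = np.unique(s_sorted)
    # candidate thresholds: midpoints between consecutive distinct scores,
    # plus one below the minimum and one above the maximum
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_case = int(labels.sum())
    n_ctrl = int(labels.size - n_case)
    best = None
    for thr in cands:
        pred = s > thr
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        sens = tp / n_case
        spec = tn / n_ctrl
        j = sens + spec - 1.0
        # strict improvement, or same J with higher specificity
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, thr, (tp + tn) / labels.size)
    j, sens, spec, thr, acc = best
    cutoff = -thr if direction == "lower_is_case" else thr
    return RocResult(
        auc=auc, cutoff=float(cutoff), sensitivity=float(sens),
        specificity=float(spec), accuracy=float(acc), direction=direction,
        youden=float(j),
    )


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 2000, seed: int = 0, direction: str = "higher_is_case"
) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% interval for the AUC.

    Resampling is within-class, so degenerate one-class resamples cannot
    occur; reproducible from ``seed``.
    """
    scores, labels = _validate_scores(scores, labels)
    s = -scores if direction == "lower_is_case" else scores
    rng = np.random.default_rng(seed)
    idx_case = np.nonzero(labels == 1)[0]
    idx_ctrl = np.nonzero(labels == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx_case, size=idx_case.size, replace=True),
             rng.choice(idx_ctrl, size=idx_ctrl.size, replace=True)]
        )
        aucs[b] = roc_auc_score(labels[take], s[take])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def pca_scores(X, n_components: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Leading principal-component scores of row-wise observations.

    Returns ``(scores, explained_variance_ratio)``.
    """
    X = np.asarray(X, dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        raise ValidationError(
            f"n_components={n_components} exceeds the maximum {max_comp} for this data"
        )
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def loocv_adaboost(
    X,
    labels,
    seed: int = 0,
    n_components: int = 5,
    n_estimators: int = 50,
    learning_rate: float = 1.0,
    pca_in_fold: bool = True,
) -> ConfusionMatrix:
    """Leave-one-out AdaBoost (decision stumps) on principal components.

    By default PCA is refit inside every training fold so the held-out
    sample never leaks into the projection; ``pca_in_fold=False`` fits
    PCA once on all samples (a common but leaky shortcut, kept for
    comparison).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] < 4:
        raise ValidationError("need at least 4 samples for leave-one-out evaluation")
    if len(set(y.tolist())) != 2:
        raise ValidationError("both classes must be present")
    n_components = min(n_components, X.shape[0] - 2, X.shape[1])

    if not pca_in_fold:
        Z_all = PCA(n_components=n_components).fit_transform(X)

    tp = fp = tn = fn = 0
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        if len(set(y[mask].tolist())) != 2:
            raise ValidationError("single-class training fold in leave-one-out")
        if pca_in_fold:
            pca = PCA(n_components=n_components).fit(X[mask])
            Z_train, Z_test = pca.transform(X[mask]), pca.transform(X[i : i + 1])
        else:
            Z_train, Z_test = Z_all[mask], Z_all[i : i + 1]
        clf = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            random_state=seed,
        )
        clf.fit(Z_train, y[mask])
        pred = int(clf.predict(Z_test)[0])
        if y[i] == 1 and pred == 1:
            tp += 1
        elif y[i] == 1 and pred == 0:
            fn += 1
        elif y[i] == 0 and pred == 1:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
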