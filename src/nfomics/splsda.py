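"""Sparse partial least squares discriminant analysis (sPLS-DA).

Two-class sPLS-DA: the class is dummy-coded, and per component the feature
loading is the dominant singular direction of the X-Y cross-covariance,
soft-thresholded so exactly ``keepX`` entries remain nonzero, renormalized,
and used to score and deflate X.  On top of the fit sit the selection
machinery of the analysis: keepX tuning by stratified ten-fold
cross-validated balanced error, stability selection of component-1 features
across repeated CV refits (strict > threshold), and leave-one-out ROC/AUC
with a centroid-distance prediction rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class SplsdaModel:
    classes: np.ndarray                 # two class labels; classes[1] is "positive"
    feature_names: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray                # p x ncomp, each column unit L2 norm
    deflation: np.ndarray               # p x ncomp regression loadings c_k
    scores: np.ndarray                  # n x ncomp training scores
    centroids: np.ndarray               # 2 x ncomp class centroids in score space
    keepX: tuple[int, ...] = ()
    dropped_features: list = field(default_factory=list)

    @property
    def ncomp(self) -> int:
        return self.loadings.shape[1]

    def support(self, comp: int = 1) -> np.ndarray:
        """Names of features with nonzero loading on the given component."""
        a = self.loadings[:, comp - 1]
        return self.feature_names[a != 0]

    def transform(self, X) -> np.ndarray:
        """Scores of new samples, with sequential training-loading deflation."""
        Xd = (np.asarray(X, dtype=float) - self.means) / self.sds
        T = np.empty((Xd.shape[0], self.ncomp))
        for k in range(self.ncomp):
            T[:, k] = Xd @ self.loadings[:, k]
            Xd = Xd - np.outer(T[:, k], self.deflation[:, k])
        return T

    def decision_scores(self, X) -> np.ndarray:
        """Signed centroid-distance score: positive means closer to classes[1]."""
        T = self.transform(X)
        d0 = ((T - self.centroids[0]) ** 2).sum(axis=1)
        d1 = ((T - self.centroids[1]) ** 2).sum(axis=1)
        return d0 - d1

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_scores(X) > 0, self.classes[1], self.classes[0])


def _sparse_direction(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so the ``keep`` largest-|u| entries stay nonzero.

    The threshold is the largest excluded magnitude; index order breaks
    magnitude ties.  The result is renormalized to unit L2 norm.
    """
    p = len(u)
    if keep >= p:
        thr = 0.0
    else:
        order = np.argsort(-np.abs(u), kind="stable")
        thr = np.abs(u[order[keep]])
    a = np.sign(u) * np.maximum(np.abs(u) - thr, 0.0)
    nrm = np.linalg.norm(a)
    if nrm == 0:
        raise ValueError("sparsification removed every loading entry")
    return a / nrm


def fit_splsda(X, y, ncomp: int = 1, keepX=None) -> SplsdaModel:
    """Fit a two-class sPLS-DA model.

    ``keepX`` is an int or per-component sequence of nonzero-loading counts
    (default: all features, i.e. dense PLS-DA).  Columns of X are centered
    and unit-variance scaled; constant columns are dropped with a warning.
    The fit is deterministic.
    """
    X = pd.DataFrame(X)
    names = X.columns.to_numpy()
    y = np.asarray(pd.Series(list(y)).to_numpy())
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("sPLS-DA here is two-class only")
    Xm = X.to_numpy(dtype=float)
    sds = Xm.std(axis=0, ddof=1)
    constant = sds == 0
    dropped = list(names[constant])
    if dropped:
        logger.warning("dropping %d constant features", len(dropped))
        Xm, names, sds = Xm[:, ~constant], names[~constant], sds[~constant]
    means = Xm.mean(axis=0)
    Xd = (Xm - means) / sds

    n, p = Xd.shape
    if keepX is None:
        keepX = [p] * ncomp
    elif np.isscalar(keepX):
        keepX = [int(keepX)] * ncomp
    keepX = [min(int(k), p) for k in keepX]
    if len(keepX) != ncomp:
        raise ValueError("keepX must have one entry per component")
    if any(k < 1 for k in keepX):
        raise ValueError("keepX entries must be >= 1")

    Y = np.column_stack([(y == c).astype(float) for c in classes])
    Yd = Y - Y.mean(axis=0)

    loadings = np.zeros((p, ncomp))
    deflation = np.zeros((p, ncomp))
    scores = np.zeros((n, ncomp))
    Xk, Yk = Xd.copy(), Yd.copy()
    for k in range(ncomp):
        M = Xk.T @ Yk
        u, _, _ = np.linalg.svd(M, full_matrices=False)
        a = _sparse_direction(u[:, 0], keepX[k])
        # sign convention: largest-magnitude loading positive
        if a[np.abs(a).argmax()] < 0:
            a = -a
        t = Xk @ a
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"degenerate component {k + 1}: zero score variance")
        c = (Xk.T @ t) / tt
        loadings[:, k], deflation[:, k], scores[:, k] = a, c, t
        Xk = Xk - np.outer(t, c)
        Yk = Yk - np.outer(t, (Yk.T @ t) / tt)

    centroids = np.vstack([scores[y == c].mean(axis=0) for c in classes])
    return SplsdaModel(
        classes=classes, feature_names=names, means=means, sds=sds,
        loadings=loadings, deflation=deflation, scores=scores,
        centroids=centroids, keepX=tuple(keepX), dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# tuning, stability, evaluation
# ---------------------------------------------------------------------------

def _balanced_error(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> float:
    errs = []
    for c in classes:
        mask = y_true == c
        if mask.any():
            errs.append(float((y_pred[mask] != c).mean()))
    return float(np.mean(errs))


def tune_splsda(
    X, y, keepX_grid, ncomp_max: int = 1, folds: int = 10,
    repeats: int = 3, seed: int = 0, rule: str = "1se",
):
    """Choose per-component keepX (and a component count) by ten-fold CV.

    Components are tuned sequentially on mean CV balanced error given the
    previously chosen values.  ``rule="min"`` takes the error-minimizing
    keepX with ties to the smallest; the default ``rule="1se"`` takes the
    smallest keepX whose mean error is within one standard error of the
    minimum — the error curve is flat once every informative feature is in,
    so this keeps chance-correlated features out of the stability stage.
    Folds are stratified by class and shuffled deterministically from
    ``seed``.  Returns (ncomp, keepX list, CV error table).
    """
    X = pd.DataFrame(X)
    y = np.asarray(pd.Series(list(y)).to_numpy())
    classes = np.unique(y)
    keepX_grid = sorted(int(k) for k in keepX_grid)
    chosen: list[int] = []
    records = []
    best_per_comp = []
    for comp in range(1, ncomp_max + 1):
        errors = {k: [] for k in keepX_grid}
        for rep in range(repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
            for train, test in skf.split(X, y):
                for k in keepX_grid:
                    model = fit_splsda(
                        X.iloc[train], y[train], ncomp=comp, keepX=chosen + [k]
                    )
                    pred = model.predict(X.iloc[test].to_numpy())
                    errors[k].append(_balanced_error(y[test], pred, classes))
        mean_err = {k: float(np.mean(v)) for k, v in errors.items()}
        best = min(keepX_grid, key=lambda k: (mean_err[k], k))
        if rule == "1se":
            se = float(np.std(errors[best], ddof=1)) / np.sqrt(len(errors[best]))
            best = min(k for k in keepX_grid if mean_err[k] <= mean_err[best] + se)
        elif rule != "min":
            raise ValueError("rule must be 'min' or '1se'")
        chosen.append(best)
        best_per_comp.append(mean_err[best])
        for k, e in mean_err.items():
            records.append({"comp": comp, "keepX": k, "cv_balanced_error": e})
    # smallest component count achieving the minimum error
    best_err = min(best_per_comp)
    ncomp = 1 + best_per_comp.index(best_err)
    return ncomp, chosen, pd.DataFrame(records)


def stability_select_splsda(
    X, y, keepX, ncomp: int = 1, threshold: float = 0.90,
    folds: int = 10, repeats: int = 10, seed: int = 0,
) -> pd.DataFrame:
    """Component-1 selection frequencies over repeated CV refits.

    The model is refit on every CV training split (``repeats x folds`` fits)
    and each feature's frequency is the fraction of fits in which it carried
    a nonzero component-1 loading.  The stable set applies the strict
    ``frequency > threshold`` rule.  Returns a frame with columns
    ``frequency`` and ``stable``, indexed by feature.
    """
    X = pd.DataFrame(X)
    y = np.asarray(pd.Series(list(y)).to_numpy())
    counts = pd.Series(0.0, index=X.columns)
    n_fits = 0
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train, _ in skf.split(X, y):
            model = fit_splsda(X.iloc[train], y[train], ncomp=ncomp, keepX=keepX)
            counts[model.support(comp=1)] += 1
            n_fits += 1
    freq = counts / n_fits
    return pd.DataFrame({"frequency": freq, "stable": freq > threshold})


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized rank sum of positive-class scores (tie-corrected)."""
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes for AUC")
    r = rankdata(scores)
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def loocv_auc(X, y, keepX, ncomp: int = 1):
    """Leave-one-out cross-validated ROC.

    Each sample is scored by a model fit on all other samples, using the
    signed centroid-distance rule; the AUC is the rank statistic of those
    held-out scores (classes[1], the lexicographically larger label, is the
    positive class).  Returns (AUC, roc frame with threshold/tpr/fpr,
    held-out score vector).
    """
    from sklearn.metrics import roc_curve

    X = pd.DataFrame(X)
    y = np.asarray(pd.Series(list(y)).to_numpy())
    classes = np.unique(y)
    n = len(X)
    held_out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_splsda(X.iloc[mask], y[mask], ncomp=ncomp, keepX=keepX)
        held_out[i] = model.decision_scores(X.iloc[[i]].to_numpy())[0]
    positive = y == classes[1]
    auc = rank_auc(held_out, positive)
    fpr, tpr, thr = roc_curve(positive, held_out)
    roc = pd.DataFrame({"threshold": thr, "tpr": tpr, "fpr": fpr})
    return auc, roc, held_out
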