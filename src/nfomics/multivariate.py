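"""Unsupervised structure and univariate screening.

PCA ordination, Bray-Curtis PERMANOVA (one-factor Anderson partitioning with
a permutation null), per-metabolite Welch t-tests with Benjamini-Hochberg
correction, and Euclidean/complete-linkage hierarchical clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def bray_curtis_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); a pair of all-zero profiles
    gets distance 0 by convention.  Values must be non-negative and complete.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("Bray-Curtis requires a complete matrix")
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    D = squareform(pdist(X, metric="braycurtis"))
    D = np.nan_to_num(D, nan=0.0)  # all-zero vs all-zero pairs
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _ss_within(D2: np.ndarray, groups: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        ss += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss


def permanova(
    dist: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    strata=None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Partitions squared distances: SS_total = sum over all pairs d^2 / N,
    SS_within = per-group pair sums, R^2 = 1 - SS_within/SS_total, and
    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)).  The p-value counts
    permuted pseudo-F values >= the observed one, including the observed
    statistic in numerator and denominator.  Labels are permuted freely by
    default; ``strata`` restricts permutations to within-stratum shuffles
    (e.g. patient-blocked).
    """
    D = np.asarray(dist, dtype=float)
    groups = np.asarray(pd.Series(list(groups)).to_numpy())
    n = len(groups)
    if D.shape != (n, n):
        raise ValueError("group vector length does not match distance matrix")
    labels, inv = np.unique(groups, return_inverse=True)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least two groups")
    D2 = D**2
    ss_total = D2.sum() / (2 * n)
    ss_w = _ss_within(D2, inv, np.arange(a))
    ss_b = ss_total - ss_w
    f_obs = (ss_b / (a - 1)) / (ss_w / (n - a))
    r2 = 1.0 - ss_w / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    # indicator matrix trick: for permuted labels P (n_perm x n), the
    # within-group pair sum per group g is diag(A_g D2 A_g^T)/2 with A_g the
    # 0/1 indicator rows; vectorized over permutations via matmul.
    perms = np.empty((n_perm, n), dtype=np.intp)
    base = np.arange(n)
    if strata is None:
        for b in range(n_perm):
            perms[b] = rng.permutation(n)
    else:
        strata = np.asarray(pd.Series(list(strata)).to_numpy())
        for b in range(n_perm):
            p = base.copy()
            for s in np.unique(strata):
                idx = np.flatnonzero(strata == s)
                p[idx] = idx[rng.permutation(len(idx))]
            perms[b] = p
    perm_inv = inv[perms]  # n_perm x n permuted group codes
    ss_w_perm = np.zeros(n_perm)
    for g in range(a):
        A = (perm_inv == g).astype(float)  # n_perm x n
        ss_w_perm += np.einsum("bi,ij,bj->b", A, D2, A) / (2 * A.sum(axis=1))
    ss_b_perm = ss_total - ss_w_perm
    f_perm = (ss_b_perm / (a - 1)) / (ss_w_perm / (n - a))
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_perm)
    return PermanovaResult(r2=float(r2), pseudo_f=float(f_obs), p_value=float(p), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# univariate screening
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def welch_volcano(
    matrix: pd.DataFrame,
    groups: pd.Series,
    values_are_log: bool = True,
    pre_label: str = "pre-NF",
    post_label: str = "post-NF",
) -> pd.DataFrame:
    """Per-metabolite two-sided Welch t-test of post vs pre, with BH q-values.

    Returns a frame indexed by metabolite with columns mean_pre, mean_post,
    log2fc (post over pre), t, p, q.  Metabolites with zero variance in both
    groups get t=0, p=1 by convention (logged).  When ``values_are_log`` the
    input is natural-log concentrations and the fold change is the group
    log-mean difference divided by ln 2; otherwise it is log2 of the ratio
    of group means.
    """
    g = groups.reindex(matrix.index)
    pre = matrix.loc[(g == pre_label).to_numpy()]
    post = matrix.loc[(g == post_label).to_numpy()]
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("each group needs at least two samples")
    t, p = stats.ttest_ind(post, pre, equal_var=False, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d metabolites had zero variance in both groups (p set to 1)",
                    int(degenerate.sum()))
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    mean_pre = pre.mean(axis=0).to_numpy()
    mean_post = post.mean(axis=0).to_numpy()
    if values_are_log:
        lfc = (mean_post - mean_pre) / np.log(2)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(mean_post / mean_pre)
    return pd.DataFrame(
        {
            "mean_pre": mean_pre,
            "mean_post": mean_post,
            "log2fc": lfc,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        },
        index=matrix.columns,
    )


# ---------------------------------------------------------------------------
# ordination & clustering
# ---------------------------------------------------------------------------

def pca(matrix: pd.DataFrame, scale: bool = True, n_components: int | None = None):
    """Centered (optionally unit-variance scaled) PCA.

    Returns (scores, loadings, variance_explained).  Sign convention: the
    largest-magnitude loading of each component is positive.  Variance
    fractions over all possible components sum to 1.
    """
    X = np.asarray(matrix, dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    k = n_components or min(X.shape)
    model = _SkPCA(n_components=min(k, min(X.shape)))
    scores = model.fit_transform(X)
    loadings = model.components_.T  # features x components
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip
    evr = model.explained_variance_ratio_
    comp_names = [f"PC{i+1}" for i in range(loadings.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        pd.Series(evr, index=comp_names, name="variance_explained"),
    )


def hierarchical_cluster(matrix: pd.DataFrame):
    """Complete-linkage agglomeration on Euclidean distances.

    Returns (linkage matrix in scipy format, leaf order as sample labels).
    """
    X = np.asarray(matrix, dtype=float)
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return Z, [matrix.index[i] for i in order]
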