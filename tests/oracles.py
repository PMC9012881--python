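"""Independent brute-force oracles used to verify the implementations.

Everything here is deliberately naive and self-contained: enumerations and
textbook formulas that are slow but obviously correct, kept free of any code
path they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import linalg


def constrained_lasso_oracle(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Global optimum of the zero-sum lasso by sign-pattern enumeration (p <= 4).

    For every sign pattern s in {-1, 0, +1}^p, solve the equality-constrained
    least squares with the active set fixed to the nonzeros of s and the L1
    term replaced by lam * s' beta; keep sign-consistent solutions and return
    the best (beta, objective).  The true optimum is sign-consistent for its
    own pattern, so it is always among the candidates.
    """
    n, p = Z.shape
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()

    def objective(beta):
        r = yc - Zc @ beta
        return 0.5 / n * float(r @ r) + lam * float(np.abs(beta).sum())

    best_beta, best_obj = np.zeros(p), objective(np.zeros(p))
    for s in itertools.product((-1.0, 0.0, 1.0), repeat=p):
        s = np.asarray(s)
        S = np.flatnonzero(s)
        if len(S) in (0, 1):  # zero-sum forces |S| != 1
            continue
        k = len(S)
        K = np.zeros((k + 1, k + 1))
        K[:k, :k] = Zc[:, S].T @ Zc[:, S] / n
        K[:k, k] = K[k, :k] = 1.0
        rhs = np.concatenate([Zc[:, S].T @ yc / n - lam * s[S], [0.0]])
        try:
            sol = linalg.solve(K, rhs)
        except linalg.LinAlgError:
            continue
        beta_S = sol[:k]
        if (beta_S * s[S] < 0).any():
            continue
        beta = np.zeros(p)
        beta[S] = beta_S
        obj = objective(beta)
        if obj < best_obj:
            best_beta, best_obj = beta, obj
    return best_beta, best_obj


def p2_soft_threshold(Z: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form zero-sum lasso for p = 2: a 1-D lasso on the difference."""
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    w = Zc[:, 0] - Zc[:, 1]
    n = len(y)
    rho = w @ yc / n
    denom = w @ w / n
    b1 = np.sign(rho) * max(abs(rho) - 2 * lam, 0.0) / denom
    return np.array([b1, -b1])


def naive_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH from the definition: q_(i) = min_{j>=i} p_(j) m / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def brute_force_permanova(D: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Pseudo-F, R^2 and exhaustive-permutation p from the definition.

    Sums of squares computed pair-by-pair in pure loops; the p-value
    enumerates every distinct assignment of labels to positions (feasible
    only for tiny n), counting F >= F_observed with the identity assignment
    included in numerator and denominator.
    """
    groups = np.asarray(groups)
    n = len(groups)

    def f_and_r2(g):
        ss_total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                ss_total += D[i, j] ** 2
        ss_total /= n
        ss_within = 0.0
        labels = sorted(set(g))
        for lab in labels:
            idx = [i for i in range(n) if g[i] == lab]
            acc = 0.0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    acc += D[idx[a], idx[b]] ** 2
            ss_within += acc / len(idx)
        a = len(labels)
        ss_between = ss_total - ss_within
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        return f, 1 - ss_within / ss_total

    f_obs, r2 = f_and_r2(groups)
    count, total = 0, 0
    for perm in itertools.permutations(range(n)):
        g = groups[list(perm)]
        f, _ = f_and_r2(g)
        total += 1
        if f >= f_obs - 1e-12:
            count += 1
    return f_obs, r2, count / total


def concordant_pair_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the fraction of concordant (positive, negative) pairs, ties = 1/2."""
    pos = scores[positive]
    neg = scores[~positive]
    total = conc = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                conc += 0.5
    return conc / total
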