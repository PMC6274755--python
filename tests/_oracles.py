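"""Independent oracles used by the test suite.

Everything here recomputes quantities by a route disjoint from the package's
closed forms: maximum likelihood by least squares / covariance determinants
(and, where asked, by explicit numerical optimization of the log-likelihood),
tail probabilities by adaptive quadrature of the null density, PR areas by
brute-force threshold enumeration, hypergeometric tails by exact counting.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, optimize, stats


# ---------------------------------------------------------------------------
# maximized Gaussian log-likelihoods via numerical least squares
# ---------------------------------------------------------------------------

def _ml_marginal(y: np.ndarray) -> float:
    n = y.size
    s2 = np.mean((y - y.mean()) ** 2)
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)

def _ml_regression(y: np.ndarray, regressors: list[np.ndarray]) -> float:
    n = y.size
    X = np.column_stack([np.ones(n)] + regressors)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = np.sum((y - X @ beta) ** 2)
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)

def _ml_saturated(e, a, b) -> float:
    n = e.size
    m = np.vstack([e, a, b])
    cov = np.cov(m, bias=True)  # 1/n MLE covariance
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return -0.5 * n * (3 * math.log(2 * math.pi) + logdet + 3.0)


def ml_llrs(e: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict[int, float]:
    """The five LLRs as differences of numerically maximized log-likelihoods.

    Null / alternative models (each variable Gaussian, mean linear in its
    regulators, saturated = full trivariate Gaussian):

    1. E,A independent            vs  A ~ E
    2. E,B independent            vs  B ~ E
    3. chain p(E)p(A|E)p(B|A)     vs  saturated
    4. p(E)p(A|E)p(B)             vs  saturated
    5. p(E)p(A|E)p(B|E)           vs  saturated
    """
    l_e = _ml_marginal(e)
    l_a = _ml_marginal(a)
    l_b = _ml_marginal(b)
    l_a_e = _ml_regression(a, [e])
    l_b_e = _ml_regression(b, [e])
    l_b_a = _ml_regression(b, [a])
    sat = _ml_saturated(e, a, b)
    return {
        1: (l_e + l_a_e) - (l_e + l_a),
        2: (l_e + l_b_e) - (l_e + l_b),
        3: sat - (l_e + l_a_e + l_b_a),
        4: sat - (l_e + l_a_e + l_b),
        5: sat - (l_e + l_a_e + l_b_e),
    }


# ---------------------------------------------------------------------------
# the same maximizations by direct numerical optimization (slow; spot checks)
# ---------------------------------------------------------------------------

def _opt_marginal(y) -> float:
    def nll(th):
        mu, logs = th
        return -np.sum(stats.norm.logpdf(y, mu, np.exp(logs)))
    res = optimize.minimize(nll, [y.mean(), 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return -res.fun

def _opt_regression(y, regressors) -> float:
    X = np.column_stack([np.ones(y.size)] + regressors)
    k = X.shape[1]
    def nll(th):
        beta, logs = th[:k], th[k]
        return -np.sum(stats.norm.logpdf(y, X @ beta, np.exp(logs)))
    res = optimize.minimize(nll, np.r_[np.zeros(k), 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return -res.fun

def _opt_saturated(e, a, b) -> float:
    data = np.column_stack([e, a, b])
    def nll(th):
        mu = th[:3]
        L = np.zeros((3, 3))
        L[np.tril_indices(3)] = th[3:]
        L[np.diag_indices(3)] = np.exp(np.diag(L))
        cov = L @ L.T
        try:
            return -np.sum(stats.multivariate_normal.logpdf(data, mu, cov))
        except np.linalg.LinAlgError:
            return 1e12
    x0 = np.r_[data.mean(0), [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]]
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 100000,
                                     "maxfev": 100000})
    return -res.fun


def optimizer_llrs(e, a, b) -> dict[int, float]:
    """All five LLRs with every model fitted by a generic optimizer."""
    l_e = _opt_marginal(e)
    l_a = _opt_marginal(a)
    l_b = _opt_marginal(b)
    l_a_e = _opt_regression(a, [e])
    l_b_e = _opt_regression(b, [e])
    l_b_a = _opt_regression(b, [a])
    sat = _opt_saturated(e, a, b)
    return {
        1: (l_e + l_a_e) - (l_e + l_a),
        2: (l_e + l_b_e) - (l_e + l_b),
        3: sat - (l_e + l_a_e + l_b_a),
        4: sat - (l_e + l_a_e + l_b),
        5: sat - (l_e + l_a_e + l_b_e),
    }


# ---------------------------------------------------------------------------
# null-density quadrature
# ---------------------------------------------------------------------------

def null_density(z, k1: float, k2: float):
    """The printed D(k1, k2) density, written directly (no log-space tricks)."""
    from scipy.special import beta as beta_fn

    z = np.asarray(z, dtype=float)
    out = np.where(
        z > 0,
        2.0 / beta_fn(k1 / 2.0, k2 / 2.0)
        * (1.0 - np.exp(-2.0 * z)) ** (k1 / 2.0 - 1.0)
        * np.exp(-k2 * z),
        0.0,
    )
    return out


def quadrature_pvalue(llr: float, n: int, k1: float, k2: float) -> float:
    lo = llr / n
    mid = max(lo, 1.0)
    v1, _ = integrate.quad(null_density, lo, mid, args=(k1, k2), limit=400)
    v2, _ = integrate.quad(null_density, mid, np.inf, args=(k1, k2), limit=400)
    return v1 + v2


# ---------------------------------------------------------------------------
# two-group ANOVA, PR area, hypergeometric enumeration
# ---------------------------------------------------------------------------

def anova_llr(groups: np.ndarray, y: np.ndarray) -> float:
    """-(n/2) ln(RSS_group / RSS_total) from an explicit two-group mean fit."""
    n = y.size
    rss_total = np.sum((y - y.mean()) ** 2)
    rss_group = 0.0
    for g in np.unique(groups):
        yg = y[groups == g]
        rss_group += np.sum((yg - yg.mean()) ** 2)
    return -0.5 * n * math.log(rss_group / rss_total)


def brute_force_pr_area(scores: np.ndarray, truth: np.ndarray) -> float:
    """Step-integral PR area by enumerating every distinct score threshold."""
    order = np.unique(scores)[::-1]
    pos = truth.sum()
    area = 0.0
    prev_recall = 0.0
    for t in order:
        sel = scores >= t
        tp = int((truth[sel] == 1).sum())
        precision = tp / sel.sum()
        recall = tp / pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def exact_hypergeom_upper(overlap: int, universe: int, truth_n: int, pred_n: int) -> float:
    """P(X >= overlap) by exact summation of counting ratios."""
    total = math.comb(universe, pred_n)
    s = 0
    for k in range(overlap, min(truth_n, pred_n) + 1):
        s += math.comb(truth_n, k) * math.comb(universe - truth_n, pred_n - k)
    return s / total
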