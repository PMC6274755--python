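"""Core statistics for causal inference with a continuous or binary anchor.

Each trio (E, A, B) — an enhancer E near the promoter of a transcription
factor A, and a candidate target gene B — is scored with five likelihood-ratio
tests built on Gaussian linear models of rank-normalized expression:

1. primary linkage       E -> A
2. secondary linkage     E -> B
3. conditional independence   E and B independent given A (supports E->A->B)
4. relevance             B regulated by E or A
5. controlled (pleiotropy)    A -> B persists after conditioning on E

All tests are nested, so each log-likelihood ratio (LLR) is non-negative.
Under the null, LLR/n follows the two-parameter family D(k1, k2), which is a
Beta(k1/2, k2/2) distribution after the change of variable
``x = 1 - exp(-2 z)``; p-values are therefore exact regularized
incomplete-Beta tails. Per-test p-values pooled over all candidate targets of
one anchor/TF pair are converted to empirical-Bayes posterior probabilities
of the alternative via a local-FDR scheme (Grenander density estimate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "NullSpec",
    "TrioStatistics",
    "DegenerateVariableError",
    "InsufficientSamplesError",
    "SingularCorrelationError",
    "rank_normal_transform",
    "pair_correlation",
    "llr_linkage",
    "llr_conditional_independence",
    "llr_relevance",
    "llr_controlled",
    "null_spec_for_test",
    "null_log_density",
    "null_pvalue",
    "posteriors_from_pvalues",
    "encode_binary_anchor",
    "trio_statistics",
]

MIN_SAMPLES = 5

#: clamp |rho| at 1 - RHO_CLAMP before taking logs (duplicate features in
#: real CAGE tables produce exact +/-1 correlations)
RHO_CLAMP = 1e-12

_LLR_TOL = 1e-9


class DegenerateVariableError(ValueError):
    """A variable is constant (or an anchor is all-zero / all-nonzero)."""


class InsufficientSamplesError(ValueError):
    """Fewer samples than the null family supports."""


class SingularCorrelationError(ValueError):
    """The implied correlation matrix is singular (|rho| >= 1)."""


@dataclass(frozen=True)
class NullSpec:
    """Parameters (k1, k2) of the null family D(k1, k2) for LLR/n.

    The density vanishes for z <= 0 and for z > 0 equals

        p(z | k1, k2) = 2 / B(k1/2, k2/2) * (1 - e^{-2z})^{k1/2 - 1} * e^{-k2 z}

    which is the Beta(k1/2, k2/2) law of x = 1 - e^{-2z}.
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError(f"k1 and k2 must be positive, got ({self.k1}, {self.k2})")


@dataclass(frozen=True)
class TrioStatistics:
    """Per-trio results: five LLRs (nats), p-values and posteriors."""

    llr: np.ndarray
    pvalue: np.ndarray
    posterior: np.ndarray

    def __post_init__(self) -> None:
        for name in ("llr", "pvalue", "posterior"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape[0] != 5:
                raise ValueError(f"{name} must have five entries (tests 1-5)")
        if np.any(np.asarray(self.llr) < -_LLR_TOL):
            raise ValueError("negative LLR beyond tolerance")


def _as_1d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D vector, got shape {arr.shape}")
    return arr


def rank_normal_transform(values, axis: int = -1) -> np.ndarray:
    """Rank-based inverse normal transform with exact re-standardization.

    Ranks (average rank for ties) are mapped to standard-normal quantiles at
    (r - 0.5)/n, then the result is re-centred and re-scaled so the sample
    mean is exactly 0 and the sample variance (1/n convention) exactly 1.
    Strictly monotone in the input ranks, hence invariant under any strictly
    increasing transform of the input.

    Accepts a vector or a 2-D array (transformed along ``axis``).
    """
    arr = np.asarray(values, dtype=float)
    n = arr.shape[axis]
    if n < MIN_SAMPLES:
        raise InsufficientSamplesError(f"need at least {MIN_SAMPLES} samples, got {n}")
    arr = np.moveaxis(arr, axis, -1)
    if np.any(np.ptp(arr, axis=-1) == 0):
        raise DegenerateVariableError("constant input vector cannot be rank-normalized")
    ranks = stats.rankdata(arr, method="average", axis=-1)
    out = special.ndtri((ranks - 0.5) / n)
    out = out - out.mean(axis=-1, keepdims=True)
    sd = out.std(axis=-1, keepdims=True)  # 1/n convention
    if np.any(sd == 0):
        raise DegenerateVariableError("degenerate vector after rank transform")
    out = out / sd
    return np.moveaxis(out, -1, axis)


def pair_correlation(x, y) -> float:
    """(1/n) sum x_i y_i for two normalized (mean-0, var-1) vectors."""
    x = _as_1d_float(x)
    y = _as_1d_float(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(x @ y / x.size)


def _clamp_rho(rho):
    return np.clip(rho, -1.0 + RHO_CLAMP, 1.0 - RHO_CLAMP)


def _check_rho(rho) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1.0 + 1e-9):
        raise SingularCorrelationError("correlation outside [-1, 1]")
    return _clamp_rho(rho)


def llr_linkage(rho, n: int):
    """LLR of the (primary or secondary) linkage test: -(n/2) ln(1 - rho^2).

    Scalar or vector ``rho``; even in rho and non-negative.
    """
    rho = _check_rho(rho)
    out = -(n / 2.0) * np.log1p(-(rho**2))
    return float(out) if np.isscalar(rho) or out.ndim == 0 else out


def _neg_log1p_ratio(q, n: int):
    """-(n/2) log(1 - q) for a nesting ratio q in [0, 1); q >= 1 is singular.

    Each trio LLR reduces to this form with q an explicit non-negative
    ratio, which makes non-negativity exact in floating point even when the
    correlation matrix is nearly singular (the naive determinant expression
    cancels catastrophically there).
    """
    q = np.asarray(q)
    if np.any(q >= 1.0):
        raise SingularCorrelationError("singular 3x3 correlation matrix")
    out = -(n / 2.0) * np.log1p(-q)
    return float(out) if out.ndim == 0 else out


def llr_conditional_independence(rho_ea, rho_eb, rho_ab, n: int):
    """LLR of test 3; 0 exactly when rho_EB = rho_EA * rho_AB (pure chain).

    Equal to -(n/2) ln[det / ((1-rho_EA^2)(1-rho_AB^2))] with det the 3x3
    correlation determinant, computed via the exact factorization
    (1-rho_EA^2)(1-rho_AB^2) - det = (rho_EA t - rho_EB (1-rho_EA^2))^2,
    t = rho_AB - rho_EA rho_EB.
    """
    rho_ea, rho_eb, rho_ab = (_check_rho(r) for r in (rho_ea, rho_eb, rho_ab))
    t = rho_ab - rho_ea * rho_eb
    num = (rho_ea * t - rho_eb * (1.0 - rho_ea**2)) ** 2
    denom = (1.0 - rho_ea**2) * (1.0 - rho_ab**2)
    return _neg_log1p_ratio(num / denom, n)


def llr_relevance(rho_ea, rho_eb, rho_ab, n: int):
    """LLR of test 4; 0 when B is unrelated to both E and A.

    Equal to -(n/2) ln[det / (1-rho_EA^2)] via the identity
    1 - det/(1-rho_EA^2) = rho_EB^2 + (rho_AB - rho_EA rho_EB)^2/(1-rho_EA^2).
    """
    rho_ea, rho_eb, rho_ab = (_check_rho(r) for r in (rho_ea, rho_eb, rho_ab))
    t = rho_ab - rho_ea * rho_eb
    q = rho_eb**2 + t**2 / (1.0 - rho_ea**2)
    return _neg_log1p_ratio(q, n)


def llr_controlled(rho_ea, rho_eb, rho_ab, n: int):
    """LLR of test 5; 0 exactly when rho_AB = rho_EA * rho_EB (pure pleiotropy).

    Equal to -(n/2) ln[det / ((1-rho_EA^2)(1-rho_EB^2))]; the numerator of
    the nesting ratio is the squared partial covariance
    (rho_AB - rho_EA rho_EB)^2.
    """
    rho_ea, rho_eb, rho_ab = (_check_rho(r) for r in (rho_ea, rho_eb, rho_ab))
    num = (rho_ab - rho_ea * rho_eb) ** 2
    denom = (1.0 - rho_ea**2) * (1.0 - rho_eb**2)
    return _neg_log1p_ratio(num / denom, n)


def null_spec_for_test(test_id: int, n: int) -> NullSpec:
    """Null family D(k1, k2) of LLR/n for each of the five tests.

    Tests 1-2: D(1, n-2); tests 3 and 5: D(1, n-3); test 4: D(2, n-3).
    """
    if test_id in (1, 2):
        k1, k2 = 1.0, n - 2.0
    elif test_id in (3, 5):
        k1, k2 = 1.0, n - 3.0
    elif test_id == 4:
        k1, k2 = 2.0, n - 3.0
    else:
        raise ValueError(f"test_id must be 1..5, got {test_id}")
    if k2 <= 0:
        raise InsufficientSamplesError(f"n={n} too small for test {test_id}")
    return NullSpec(k1, k2)


def null_log_density(z, spec: NullSpec):
    """log p(z | k1, k2); -inf for z <= 0.

    Evaluated in log space through log-Gamma so large k2 (= n - 2 or n - 3,
    with n in the hundreds for real CAGE sets) stays finite.
    """
    z = np.asarray(z, dtype=float)
    a, b = spec.k1 / 2.0, spec.k2 / 2.0
    log_norm = np.log(2.0) - (special.gammaln(a) + special.gammaln(b) - special.gammaln(a + b))
    with np.errstate(divide="ignore", invalid="ignore"):
        body = (a - 1.0) * np.log1p(-np.exp(-2.0 * np.where(z > 0, z, 1.0))) - spec.k2 * z
    out = np.where(z > 0, log_norm + body, -np.inf)
    return float(out) if out.ndim == 0 else out


def null_pvalue(llr, n: int, test_id: int):
    """Upper-tail p-value P(LLR_null >= llr) under D(k1, k2).

    Exact via the Beta identity: x = 1 - exp(-2 LLR / n) ~ Beta(k1/2, k2/2),
    so p = I-bar_x(k1/2, k2/2) (regularized incomplete Beta upper tail).
    """
    spec = null_spec_for_test(test_id, n)
    llr = np.asarray(llr, dtype=float)
    if np.any(llr < -_LLR_TOL):
        raise ValueError("negative LLR")
    llr = np.maximum(llr, 0.0)
    x = -np.expm1(-2.0 * llr / n)
    out = np.clip(stats.beta.sf(x, spec.k1 / 2.0, spec.k2 / 2.0), 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# empirical-Bayes posteriors
# ---------------------------------------------------------------------------

#: below this many pooled candidates the Grenander estimate is unstable and
#: the conservative fallback posterior 1 - p is used instead
MIN_CANDIDATES_FOR_EB = 50


def grenander_density(pvalues: np.ndarray, eval_at: np.ndarray) -> np.ndarray:
    """Grenander (non-increasing) density estimate of p-values on [0, 1].

    Slopes of the least concave majorant of the ECDF, evaluated at
    ``eval_at``. The estimate is piecewise constant and non-increasing.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    # ECDF knots, deduplicated on x keeping the highest y, plus both endpoints
    x = np.concatenate([[0.0], p, [1.0]])
    y = np.concatenate([[0.0], np.arange(1, n + 1) / n, [1.0]])
    keep = np.r_[x[1:] != x[:-1], True]
    x, y = x[keep], y[keep]

    # least concave majorant via a monotone-slope stack
    xs = [x[0]]
    ys = [y[0]]
    for xi, yi in zip(x[1:], y[1:]):
        while len(xs) >= 2:
            s_new = (yi - ys[-1]) / (xi - xs[-1])
            s_old = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            if s_new > s_old:  # concavity violated: merge
                xs.pop()
                ys.pop()
            else:
                break
        xs.append(xi)
        ys.append(yi)
    xs = np.asarray(xs)
    slopes = np.diff(ys) / np.diff(xs)
    idx = np.clip(np.searchsorted(xs, eval_at, side="right") - 1, 0, slopes.size - 1)
    return slopes[idx]


def estimate_pi0(pvalues: np.ndarray) -> float:
    """Null-proportion estimate: min(1, 2 * mean(p > 0.5))."""
    p = np.asarray(pvalues, dtype=float)
    return float(min(1.0, 2.0 * np.mean(p > 0.5)))


def posteriors_from_pvalues(pvalues, side: str = "alt") -> np.ndarray:
    """Per-hypothesis posterior probability from a pooled p-value vector.

    Local-FDR empirical Bayes: the p-values are a mixture
    f(p) = pi0 * 1 + (1 - pi0) f1(p) with f1 decreasing; the posterior of the
    alternative at p is 1 - pi0 / f_hat(p), with f_hat a Grenander monotone
    density estimate and pi0 = min(1, 2 mean(p > 0.5)), clipped to [0, 1].
    Monotone non-increasing in p.

    With fewer than ``MIN_CANDIDATES_FOR_EB`` p-values a conservative
    fallback ``1 - p`` is used.  ``side="null"`` returns the complementary
    posterior probability of the null (used by the conditional-independence
    test, whose *null* is the supported causal model).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if side not in ("alt", "null"):
        raise ValueError("side must be 'alt' or 'null'")
    if p.size < MIN_CANDIDATES_FOR_EB:
        warnings.warn(
            f"only {p.size} candidates; using conservative posterior 1 - p",
            stacklevel=2,
        )
        post = 1.0 - p
    else:
        pi0 = estimate_pi0(p)
        f_hat = grenander_density(p, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfdr = np.where(f_hat > 0, pi0 / f_hat, np.inf)
        post = np.clip(1.0 - lfdr, 0.0, 1.0)
    return 1.0 - post if side == "null" else post


def encode_binary_anchor(raw) -> np.ndarray:
    """Standardized two-level indicator of zero vs non-zero expression.

    Zeros map to the low value, non-zeros to the high value; the output has
    mean 0 and variance 1 (1/n). Feeding it through the continuous LLR
    formulas reproduces the two-group ANOVA (group-mean) model exactly, with
    linkage null D(1, n-2) — the binary-anchor method is therefore the
    categorical method with two categories.
    """
    raw = _as_1d_float(raw)
    if raw.size < MIN_SAMPLES:
        raise InsufficientSamplesError(f"need at least {MIN_SAMPLES} samples")
    ind = (raw != 0).astype(float)
    k = ind.sum()
    if k == 0 or k == ind.size:
        raise DegenerateVariableError("anchor is all-zero or all-nonzero")
    ind -= ind.mean()
    return ind / ind.std()


def trio_statistics(e, a, b, pool_pvalues: bool = False) -> TrioStatistics:
    """Five tests on one trio of normalized vectors (mainly for exploration).

    Posteriors for a single trio use the conservative 1 - p fallback; the
    pipeline pools p-values across all candidate targets instead.
    """
    n = len(e)
    rho_ea = pair_correlation(e, a)
    rho_eb = pair_correlation(e, b)
    rho_ab = pair_correlation(a, b)
    llrs = np.array(
        [
            llr_linkage(rho_ea, n),
            llr_linkage(rho_eb, n),
            llr_conditional_independence(rho_ea, rho_eb, rho_ab, n),
            llr_relevance(rho_ea, rho_eb, rho_ab, n),
            llr_controlled(rho_ea, rho_eb, rho_ab, n),
        ]
    )
    pvals = np.array([null_pvalue(llrs[i], n, i + 1) for i in range(5)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = 1.0 - pvals
    return TrioStatistics(llr=llrs, pvalue=pvals, posterior=post)
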