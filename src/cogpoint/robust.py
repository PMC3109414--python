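"""Elementary robust and rank statistics, implemented from first principles.

This module provides the statistical primitives the change-point analysis
rests on: MM-estimation robust simple regression (high-breakdown S-estimate
of scale followed by an efficient bisquare M-step), robust Lowess smoothing,
Spearman rank correlation, the Wilcoxon-Mann-Whitney two-sample rank test
(exact by enumeration at small n), the variance-ratio F test, and Pearson
chi-square / Fisher exact tests for 2x2 tables. Only distribution functions
(normal, F, chi-square) come from scipy; the estimators themselves are
written out so their breakdown and tie-handling behaviour is explicit and
testable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _dist

__all__ = [
    "RobustFit",
    "RankTestResult",
    "mm_regression",
    "lowess_fit",
    "spearman_rho",
    "mann_whitney",
    "variance_ratio_test",
    "VarianceRatioResult",
    "categorical_tests",
    "CategoricalTestResult",
    "midranks",
    "TUNING_S",
    "TUNING_M",
]

# Canonical bisquare tuning constants: 1.548 gives a 50% breakdown S-scale,
# 4.685 gives 95% efficiency at the normal for the M-step.
TUNING_S = 1.548
TUNING_M = 4.685
_BREAKDOWN_DELTA = 0.5  # E_Phi[rho_c(Z)] / rho(inf) at c = 1.548

WMW_EXACT_CAP = 12  # combined sample size up to which the exact p is enumerated


@dataclass
class RobustFit:
    """Result of an MM-regression of y on x (simple linear model)."""

    intercept: float
    slope: float
    scale: float
    weights: np.ndarray
    stderr_intercept: float
    stderr_slope: float
    t_intercept: float
    t_slope: float
    n: int
    df: int
    converged: bool
    iterations: int


@dataclass
class RankTestResult:
    """Two-sample rank test result (U statistic for the first sample)."""

    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"


@dataclass
class VarianceRatioResult:
    statistic: float
    df: tuple
    p_value: float
    flagged_infinite: bool = False


@dataclass
class CategoricalTestResult:
    chi2: float
    chi2_p: float
    fisher_p: float


# ---------------------------------------------------------------------------
# bisquare helpers


def _rho(u: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare rho normalized so rho(inf) = 1."""
    z = np.clip(np.abs(u) / c, 0.0, 1.0)
    return 1.0 - (1.0 - z**2) ** 3


def _psi(u: np.ndarray, c: float) -> np.ndarray:
    """Derivative of the unnormalized bisquare rho: u (1 - (u/c)^2)^2 on |u|<=c."""
    z = u / c
    out = u * (1.0 - z**2) ** 2
    out[np.abs(u) > c] = 0.0
    return out


def _psi_prime(u: np.ndarray, c: float) -> np.ndarray:
    z = (u / c) ** 2
    out = (1.0 - z) * (1.0 - 5.0 * z)
    out[np.abs(u) > c] = 0.0
    return out


def _bisquare_weight(u: np.ndarray, c: float) -> np.ndarray:
    """psi(u)/u, in [0, 1]."""
    z = np.clip(np.abs(u) / c, 0.0, 1.0)
    return (1.0 - z**2) ** 2


def _m_scale(resid: np.ndarray, c: float = TUNING_S, delta: float = _BREAKDOWN_DELTA,
             tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve mean(rho(r/s)) = delta for s (the M-estimate of scale)."""
    r = np.abs(np.asarray(resid, dtype=float))
    if np.all(r == 0):
        return 0.0
    s = np.median(r[r > 0]) / 0.6745 if np.any(r > 0) else 0.0
    if s == 0:
        return 0.0
    for _ in range(max_iter):
        m = float(np.mean(_rho(r / s, c)))
        if m <= 0:
            return 0.0
        s_new = s * math.sqrt(m / delta)
        if abs(s_new - s) <= tol * s:
            return s_new
        s = s_new
    return s


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line; returns (intercept, slope)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        raise ZeroDivisionError("degenerate weighted design")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return ym - slope * xm, slope


def mm_regression(x, y, max_iter: int = 200, tol: float = 1e-8,
                  n_subsamples: int = 50, seed: int = 1203) -> RobustFit:
    """MM-estimation robust simple linear regression.

    Stage 1 (S-estimate): candidate lines through random 2-point subsets are
    scored by the 50%-breakdown bisquare M-scale of their residuals
    (tuning 1.548); the best candidate is refined by iteratively reweighted
    least squares, re-solving the scale each step. Stage 2 (M-step): IRLS
    with bisquare tuning 4.685 (95% efficiency at the normal), holding the
    S-scale fixed, started from the S-estimate.

    Standard errors use the standard asymptotic M-estimator covariance with
    df = n - 2; the ``converged`` flag is False if the M-step hit the
    iteration cap. Internal subsampling is deterministic (fixed seed), so
    identical inputs give identical fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: degenerate design")

    rng = np.random.default_rng(seed)

    # --- Stage 1: S-estimate by subsampling + IRLS refinement
    best = None  # (scale, intercept, slope)
    # include the L1-ish starting point: least squares on the full data
    ones = np.ones(n)
    a0, b0 = _wls_line(x, y, ones)
    candidates = [(a0, b0)]
    for _ in range(n_subsamples):
        i, j = rng.choice(n, size=2, replace=False)
        if x[i] == x[j]:
            continue
        b = (y[j] - y[i]) / (x[j] - x[i])
        a = y[i] - b * x[i]
        candidates.append((a, b))
    for a, b in candidates:
        s = _m_scale(y - a - b * x)
        if best is None or s < best[0]:
            best = (s, a, b)
    s, a, b = best
    if s == 0.0:
        # exact fit already
        return _finalize_fit(x, y, a, b, 0.0, n, converged=True, iterations=0)

    # refine S-estimate: IRLS minimizing the M-scale
    for _ in range(50):
        r = y - a - b * x
        s = _m_scale(r)
        if s == 0.0:
            return _finalize_fit(x, y, a, b, 0.0, n, converged=True, iterations=0)
        w = _bisquare_weight(r / s, TUNING_S)
        if w.sum() <= 0 or (w * (x - x.mean()) ** 2).sum() <= 0:
            break
        a_new, b_new = _wls_line(x, y, w)
        if max(abs(a_new - a), abs(b_new - b)) <= tol * max(1.0, abs(a), abs(b)):
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    s_scale = _m_scale(y - a - b * x)
    if s_scale == 0.0:
        return _finalize_fit(x, y, a, b, 0.0, n, converged=True, iterations=0)

    # --- Stage 2: efficient M-step at fixed S-scale
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - a - b * x
        w = _bisquare_weight(r / s_scale, TUNING_M)
        if w.sum() <= 0 or (w * (x - (w * x).sum() / w.sum()) ** 2).sum() <= 0:
            break  # all points down-weighted to zero: keep S-estimate
        a_new, b_new = _wls_line(x, y, w)
        delta = max(abs(a_new - a), abs(b_new - b))
        a, b = a_new, b_new
        if delta <= tol * max(1.0, abs(a), abs(b)):
            converged = True
            break
    return _finalize_fit(x, y, a, b, s_scale, n, converged=converged, iterations=it)


def _finalize_fit(x, y, a, b, scale, n, converged, iterations) -> RobustFit:
    r = y - a - b * x
    df = n - 2
    if scale == 0.0:
        weights = np.ones(n)
        se_a = se_b = 0.0
        t_a = math.inf if a != 0 else 0.0
        t_b = math.inf if b != 0 else 0.0
        return RobustFit(a, b, 0.0, weights, se_a, se_b, t_a, t_b, n, df,
                         converged, iterations)
    u = r / scale
    weights = _bisquare_weight(u, TUNING_M)
    psi = _psi(u, TUNING_M)
    psip = _psi_prime(u, TUNING_M)
    denom = float(np.mean(psip))
    if denom <= 0:
        kappa = math.inf
    else:
        kappa = (float(np.sum(psi**2)) / df) / denom**2
    X = np.column_stack([np.ones(n), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = scale**2 * kappa * xtx_inv
    se_a = math.sqrt(max(cov[0, 0], 0.0))
    se_b = math.sqrt(max(cov[1, 1], 0.0))
    t_a = a / se_a if se_a > 0 else math.inf * np.sign(a) if a else 0.0
    t_b = b / se_b if se_b > 0 else math.inf * np.sign(b) if b else 0.0
    return RobustFit(float(a), float(b), float(scale), weights, se_a, se_b,
                     float(t_a), float(t_b), n, df, converged, iterations)


# ---------------------------------------------------------------------------
# Lowess


def lowess_fit(x, y, span: float = 2.0 / 3.0, robust_iters: int = 3):
    """Robust locally weighted regression (Lowess) fitted at each observed x.

    Local linear fits with tricube distance weights over the nearest
    ``ceil(span * n)`` neighbours, followed by ``robust_iters`` robustifying
    passes that bisquare-downweight large residuals (scaled by six times
    the median absolute residual). Returns fitted values aligned with the
    input order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError(f"need n >= 5 observations, got {n}")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    k = int(math.ceil(span * n))
    if k < 2:
        raise ValueError(f"span {span} gives a local window of {k} < 2 points")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    delta = np.ones(n)
    fitted_s = np.empty(n)

    for iteration in range(robust_iters + 1):
        lo = 0
        for i in range(n):
            # slide the k-nearest-neighbour window
            hi = lo + k
            while hi < n and xs[hi] - xs[i] < xs[i] - xs[lo]:
                lo += 1
                hi += 1
            xw = xs[lo:hi]
            yw = ys[lo:hi]
            d = np.abs(xw - xs[i])
            dmax = d.max()
            if dmax > 0:
                w = (1.0 - (d / dmax) ** 3) ** 3
            else:
                w = np.ones_like(d)
            w = w * delta[lo:hi]
            sw = w.sum()
            if sw <= 0:
                fitted_s[i] = yw.mean()
                continue
            xm = (w * xw).sum() / sw
            sxx = (w * (xw - xm) ** 2).sum()
            if sxx > 1e-12 * max(1.0, xm**2):
                ym = (w * yw).sum() / sw
                slope = (w * (xw - xm) * (yw - ym)).sum() / sxx
                fitted_s[i] = ym + slope * (xs[i] - xm)
            else:
                fitted_s[i] = (w * yw).sum() / sw
        if iteration == robust_iters:
            break
        resid = ys - fitted_s
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, 1.0) ** 2

    fitted = np.empty(n)
    fitted[order] = fitted_s
    return fitted


# ---------------------------------------------------------------------------
# rank statistics


def midranks(v) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    v = np.asarray(v)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    sv = v[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = midranks(x)
    ry = midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a (pairs where a > b, ties count 1/2)."""
    ranks = midranks(np.concatenate([a, b]))
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(a, b, exact_cap: int = WMW_EXACT_CAP) -> RankTestResult:
    """Wilcoxon-Mann-Whitney two-sample rank-sum test, two-sided.

    Exact p by full enumeration of group assignments when the combined
    sample size is at most ``exact_cap``; otherwise a normal approximation
    with tie and continuity corrections. The two-sided exact p doubles the
    smaller tail of the permutation distribution of U (capped at 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(a), len(b)
    u = _u_statistic(a, b)
    if n + m <= exact_cap:
        pooled = np.concatenate([a, b])
        ranks = midranks(pooled)
        offset = n * (n + 1) / 2.0
        us = np.array(
            [ranks[list(idx)].sum() - offset
             for idx in itertools.combinations(range(n + m), n)]
        )
        eps = 1e-9
        p_lo = np.mean(us <= u + eps)
        p_hi = np.mean(us >= u - eps)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return RankTestResult(u, float(p), "exact")
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return RankTestResult(u, 1.0, "normal-approximation")
    mean_u = n * m / 2.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * float(_dist.norm.sf(z))
    return RankTestResult(u, min(p, 1.0), "normal-approximation")


def variance_ratio_test(a, b) -> VarianceRatioResult:
    """Simple variance-ratio F test: larger sample variance over smaller.

    Two-sided p doubles the upper-tail F probability (capped at 1); the
    df pair follows the numerator/denominator orientation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va >= vb:
        num, den, dfn, dfd = va, vb, len(a) - 1, len(b) - 1
    else:
        num, den, dfn, dfd = vb, va, len(b) - 1, len(a) - 1
    if den == 0:
        return VarianceRatioResult(math.inf, (dfn, dfd), 0.0, flagged_infinite=True)
    f = num / den
    p = min(1.0, 2.0 * float(_dist.f.sf(f, dfn, dfd)))
    return VarianceRatioResult(f, (dfn, dfd), p)


def _hypergeom_pmf(k: int, row1: int, col1: int, total: int) -> float:
    """P(X = k) for the 2x2 table's top-left cell under fixed margins."""
    return (
        math.comb(col1, k)
        * math.comb(total - col1, row1 - k)
        / math.comb(total, row1)
    )


def categorical_tests(table) -> CategoricalTestResult:
    """Pearson chi-square (no continuity correction) and Fisher exact p
    for a 2x2 count table.

    The Fisher two-sided p sums, over the hypergeometric support with the
    observed margins, the probabilities of all tables no more probable than
    the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    t = np.rint(t).astype(int)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate table: a row or column is all zeros")
    total = int(t.sum())
    expected = np.outer(rows, cols) / total
    chi2 = float(((t - expected) ** 2 / expected).sum())
    chi2_p = float(_dist.chi2.sf(chi2, 1))

    k_obs = t[0, 0]
    k_min = max(0, rows[0] - (total - cols[0]))
    k_max = min(rows[0], cols[0])
    p_obs = _hypergeom_pmf(k_obs, rows[0], cols[0], total)
    fisher_p = 0.0
    for k in range(k_min, k_max + 1):
        pk = _hypergeom_pmf(k, rows[0], cols[0], total)
        if pk <= p_obs * (1.0 + 1e-7):
            fisher_p += pk
    return CategoricalTestResult(chi2, chi2_p, min(fisher_p, 1.0))
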