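"""Level change-point detection along the CAMCOG axis.

Detects a change in the *overall level* of a biomarker as cognition
declines: observations are ordered by CAMCOG score and a regression on a
constant (one mean per regime) is compared against a single pooled mean at
every admissible split. This yields the classical sequence of structural-
change F statistics over candidate break positions; the supremum-F position
and the residual-sum-of-squares-minimizing breakpoint coincide for this
model class. Significance of the supremum F is assessed by permutation of
the response against the CAMCOG ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructuralChangeScan",
    "BreakpointResult",
    "chow_f",
    "fstat_scan",
    "rss_breakpoint",
]


@dataclass
class StructuralChangeScan:
    """F statistics over candidate level-break positions."""

    split_sizes: np.ndarray  # left-regime sizes k for each candidate split
    candidate_camcog: np.ndarray  # CAMCOG at the last left observation per split
    f_stats: np.ndarray
    sup_f: float
    argmax_size: int  # left size at the supremum
    changepoint_camcog: float  # CAMCOG of the last observation of the left regime
    p_value: float | None
    n_permutations: int
    n: int

    def to_frame(self):
        """The scan as a (position, CAMCOG, F) table for export or plotting."""
        import pandas as pd

        return pd.DataFrame(
            {
                "position": self.split_sizes,
                "camcog": self.candidate_camcog,
                "f": self.f_stats,
            }
        )


@dataclass
class BreakpointResult:
    """RSS-minimizing single level breakpoint."""

    split_size: int  # observations in the left (low-CAMCOG) regime
    changepoint_camcog: float
    rss: float


def chow_f(y_left, y_right) -> float:
    """Structural-change F for a one-mean-per-regime model at a given split.

    F = ((RSS_pooled - RSS_split) / k) / (RSS_split / (n - 2k)) with k = 1
    parameter per regime. Returns ``inf`` when the split fits exactly
    (RSS_split = 0) while the pooled model does not.
    """
    yl = np.asarray(y_left, dtype=float)
    yr = np.asarray(y_right, dtype=float)
    if len(yl) < 2 or len(yr) < 2:
        raise ValueError("each side needs n >= 2 observations")
    n = len(yl) + len(yr)
    pooled = np.concatenate([yl, yr])
    rss_pooled = float(((pooled - pooled.mean()) ** 2).sum())
    rss_split = float(((yl - yl.mean()) ** 2).sum() + ((yr - yr.mean()) ** 2).sum())
    if rss_split == 0.0:
        return 0.0 if rss_pooled == 0.0 else math.inf
    return (rss_pooled - rss_split) / (rss_split / (n - 2))


def _split_rss_profile(Y: np.ndarray, k_lo: int, k_hi: int):
    """Within-side RSS for every split size k in [k_lo, k_hi].

    ``Y`` may be 1-d (one series) or 2-d of shape (B, n) (B series at once,
    e.g. permutations). Returns an array of shape (..., k_hi - k_lo + 1).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[1]
    S = np.cumsum(Y, axis=1)
    Q = np.cumsum(Y**2, axis=1)
    ks = np.arange(k_lo, k_hi + 1)
    Sk = S[:, ks - 1]
    Qk = Q[:, ks - 1]
    St = S[:, -1:]
    Qt = Q[:, -1:]
    rss_left = Qk - Sk**2 / ks
    rss_right = (Qt - Qk) - (St - Sk) ** 2 / (n - ks)
    return np.maximum(rss_left + rss_right, 0.0), ks


def _f_from_rss(rss_split: np.ndarray, rss_pooled: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_pooled - rss_split) / (rss_split / (n - 2))
    f = np.where(rss_split == 0.0, np.inf, f)
    return np.maximum(f, 0.0)


def _order_by_camcog(camcog: np.ndarray) -> np.ndarray:
    # stable sort: ties keep input order
    return np.argsort(camcog, kind="stable")


def fstat_scan(
    camcog,
    y,
    trim: float = 0.15,
    n_permutations: int = 1000,
    seed: int = 0,
) -> StructuralChangeScan:
    """Scan structural-change F statistics over a trimmed range of splits.

    Observations are sorted by CAMCOG (stable in input order for ties);
    the level-model F is evaluated at every split leaving at least
    ``ceil(trim * n)`` observations (and never fewer than 2) on each side.
    The permutation p-value shuffles y against the CAMCOG ordering
    ``n_permutations`` times and counts permuted supremum-F values at least
    as large as the observed one (add-one correction). ``n_permutations=0``
    skips the p-value.
    """
    camcog = np.asarray(camcog, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(camcog) != n:
        raise ValueError("camcog and y must have equal length")
    if n < 10:
        raise ValueError(f"need n >= 10 observations, got {n}")
    if not 0.0 < trim < 0.5:
        raise ValueError(f"trim must lie in (0, 0.5), got {trim}")
    k_lo = max(2, int(math.ceil(trim * n)))
    k_hi = min(n - 2, int(math.floor((1 - trim) * n)))
    if k_lo > k_hi:
        raise ValueError("no admissible split under the given trim")

    order = _order_by_camcog(camcog)
    ys = y[order]
    cs = camcog[order]
    total_rss = float(((ys - ys.mean()) ** 2).sum())
    rss_split, ks = _split_rss_profile(ys, k_lo, k_hi)
    f = _f_from_rss(rss_split[0], total_rss, n)
    i_max = int(np.argmax(f))
    sup_f = float(f[i_max])
    k_star = int(ks[i_max])

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.broadcast_to(ys, (n_permutations, n)), axis=1)
        rss_b, _ = _split_rss_profile(perms, k_lo, k_hi)
        f_b = _f_from_rss(rss_b, total_rss, n)
        sup_b = f_b.max(axis=1)
        p_value = float((1 + np.sum(sup_b >= sup_f)) / (n_permutations + 1))

    return StructuralChangeScan(
        split_sizes=ks,
        candidate_camcog=cs[ks - 1],
        f_stats=f,
        sup_f=sup_f,
        argmax_size=k_star,
        changepoint_camcog=float(cs[k_star - 1]),
        p_value=p_value,
        n_permutations=n_permutations,
        n=n,
    )


def default_min_seg(n: int) -> int:
    return max(5, int(math.ceil(0.15 * n)))


def rss_breakpoint(camcog, y, min_seg: int | None = None) -> BreakpointResult:
    """Exhaustive single-breakpoint search minimizing within-side RSS.

    The level model fits one mean per regime; all splits leaving at least
    ``min_seg`` observations per side are enumerated. Exact RSS ties are
    broken toward the split whose CAMCOG value is nearest the sample median
    CAMCOG (then toward the smaller split). The breakpoint is reported as
    the CAMCOG score of the last observation of the left (low-score) regime.
    """
    camcog = np.asarray(camcog, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if min_seg is None:
        min_seg = default_min_seg(n)
    if min_seg < 2:
        raise ValueError("min_seg must be >= 2")
    if n < 2 * min_seg:
        raise ValueError(f"need n >= 2 * min_seg = {2 * min_seg}, got {n}")

    order = _order_by_camcog(camcog)
    ys = y[order]
    cs = camcog[order]
    rss, ks = _split_rss_profile(ys, min_seg, n - min_seg)
    rss = rss[0]
    best = rss.min()
    tied = np.flatnonzero(rss == best)
    if len(tied) > 1:
        med = float(np.median(camcog))
        cams = cs[ks[tied] - 1]
        dist = np.abs(cams - med)
        tied = tied[dist == dist.min()]
    i_star = int(tied[0])
    k_star = int(ks[i_star])
    return BreakpointResult(
        split_size=k_star,
        changepoint_camcog=float(cs[k_star - 1]),
        rss=float(best),
    )
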