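"""Slope change-point detection via rank tie-splitting and segmentation.

CAMCOG scores are integers, so many participants share a score. To apply a
piecewise-linear segmentation that expects one observation per position of
an equally spaced series, the scores are ranked with ties split at random;
the biomarker values, ordered by those ranks, form the series. Segmentation
fits least-squares lines in adjacent sliding windows (both axes normalized
to unit range) and flags a change-point where the angle between successive
local slopes exceeds a tolerance; window size and tolerance escalate along
a schedule until exactly one change-point emerges. Because the random tie
order can move the detected point, the whole analysis repeats (1000 times
by default, each with its own derived seed) and the median of the
per-repetition change-points, mapped back to the CAMCOG scale, is the
slope change-point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TieSplitSeries",
    "SegmentationResult",
    "EscalationResult",
    "tie_split_ranks",
    "segment_series",
    "segment_series_detailed",
    "escalate_until_single",
    "slope_changepoint",
    "default_schedule",
]


@dataclass
class TieSplitSeries:
    """A biomarker series on equally spaced rank positions 1..n."""

    order: np.ndarray  # permutation: position -> original observation index
    series: np.ndarray  # biomarker values in rank order
    camcog: np.ndarray  # back-map: CAMCOG score at each rank position
    seed: int


@dataclass
class EscalationResult:
    index: int | None  # series position of the change-point (None if absent)
    window: int | None
    tolerance: float | None
    status: str  # "single" | "bridged" | "exhausted-multi" | "none"


@dataclass
class SegmentationResult:
    """Distribution of slope change-points over tie-splitting repetitions."""

    changepoints: np.ndarray  # per-repetition CAMCOG value (nan = no change-point)
    median: float  # median over successful repetitions (nan if analysis failed)
    repetitions: int
    n_failed: int
    analysis_failed: bool
    master_seed: int
    diagnostics: dict = field(default_factory=dict)


#: window sizes as fractions of the series length; a local slope estimated
#: from w points has standard error ~ sigma * sqrt(12/w^3) on the unit-scaled
#: axes, so fixed small windows are pure noise at realistic noise levels —
#: windows must grow with n for the angle criterion to see the slope contrast.
WINDOW_FRACTIONS = (1 / 4, 1 / 3, 5 / 12)
TOLERANCE_GRID = (10.0, 15.0, 20.0, 30.0, 45.0)


def default_schedule(n: int) -> list:
    """Escalating (window, tolerance-degrees) settings, window-major.

    Windows are length-scaled fractions of the series (never below 8, never
    above n/2, duplicates dropped), each crossed with the ascending
    tolerance grid.
    """
    windows = []
    for f in WINDOW_FRACTIONS:
        w = min(max(8, round(f * n)), n // 2)
        if w >= 3 and w not in windows:
            windows.append(w)
    return [(w, t) for w in windows for t in TOLERANCE_GRID]


def tie_split_ranks(camcog, y, seed: int) -> TieSplitSeries:
    """Rank observations by CAMCOG, breaking ties uniformly at random.

    Observations with strictly different scores never swap order; the
    internal order of each tie group is an independent uniform draw from
    ``seed``. Positions 1..n are equally spaced by construction.
    """
    camcog = np.asarray(camcog)
    y = np.asarray(y, dtype=float)
    n = len(camcog)
    if len(y) != n or n < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    rng = np.random.default_rng(seed)
    jitter = rng.random(n)
    order = np.lexsort((jitter, camcog))
    return TieSplitSeries(
        order=order,
        series=y[order],
        camcog=np.asarray(camcog, dtype=float)[order],
        seed=seed,
    )


def _window_slopes(yn: np.ndarray, xn: np.ndarray, w: int) -> np.ndarray:
    """OLS slope of each length-w window (start index i) on unit-scaled axes."""
    d = xn[:w] - xn[:w].mean()  # equally spaced: same deviation pattern everywhere
    denom = float((d**2).sum())
    num = np.convolve(yn, d[::-1], mode="valid")
    return num / denom


def segment_series_detailed(series, window: int, tolerance: float):
    """Candidate change-points with their slope-break angles.

    For each split position t (first index of the right regime) the least-
    squares slopes of the adjacent windows ``[t-window, t)`` and
    ``[t, t+window)`` are compared on axes normalized to unit range; the
    angle ``|atan(s_right) - atan(s_left)|`` (degrees) exceeding
    ``tolerance`` flags t. Runs of flagged positions closer than one window
    collapse to their maximal-angle member. Returns (indices, angles).
    """
    v = np.asarray(series, dtype=float)
    n = len(v)
    if window < 3:
        raise ValueError(f"window must be >= 3, got {window}")
    if window > n / 2:
        raise ValueError(f"window {window} larger than n/2 = {n / 2}")
    if not tolerance > 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")

    rng_v = np.ptp(v)
    if rng_v == 0:
        return np.empty(0, dtype=int), np.empty(0)
    xn = np.arange(n, dtype=float) / (n - 1)
    yn = (v - v.min()) / rng_v
    slopes = _window_slopes(yn, xn, window)  # slope of window starting at i
    ts = np.arange(window, n - window + 1)
    ang = np.abs(np.degrees(np.arctan(slopes[ts]) - np.arctan(slopes[ts - window])))
    flagged = ts[ang > tolerance]
    flagged_ang = ang[ang > tolerance]
    if len(flagged) == 0:
        return np.empty(0, dtype=int), np.empty(0)

    # collapse runs of flags closer than one window to the maximal-angle one
    keep_idx = []
    keep_ang = []
    start = 0
    for i in range(1, len(flagged) + 1):
        if i == len(flagged) or flagged[i] - flagged[i - 1] > window:
            grp = slice(start, i)
            j = int(np.argmax(flagged_ang[grp]))
            keep_idx.append(int(flagged[grp][j]))
            keep_ang.append(float(flagged_ang[grp][j]))
            start = i
    return np.array(keep_idx, dtype=int), np.array(keep_ang)


def segment_series(series, window: int, tolerance: float) -> list:
    """Change-point indices of an equally spaced series (see detailed form)."""
    idx, _ = segment_series_detailed(series, window, tolerance)
    return list(idx)


def _median_smooth(v: np.ndarray, width: int = 5) -> np.ndarray:
    """Running-median prefilter (reflected edges).

    Isolated gross outliers dominate any least-squares window they fall in;
    a short running median removes them entirely while preserving the
    piecewise-linear shape (corners are rounded by at most half the filter
    width). Applied to each tie-split series before segmentation.
    """
    if len(v) < width:
        return v
    half = width // 2
    padded = np.pad(v, half, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, width)
    return np.median(windows, axis=1)


def _winsorize(y: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Clip values at median +/- k scaled-MADs.

    The sliding-window fits and the local split refinement are least-squares
    operations, so a handful of gross outliers can dominate any window they
    fall in; clipping at five robust standard deviations bounds their
    influence while leaving the broken-stick structure (which spans a few
    robust SDs) untouched.
    """
    med = np.median(y)
    mad = 1.4826 * np.median(np.abs(y - med))
    if mad == 0:
        return y
    return np.clip(y, med - k * mad, med + k * mad)


def _prefix_line_rss(v: np.ndarray) -> np.ndarray:
    """RSS of an OLS line on each prefix v[:k]; entry k-1 holds prefix size k."""
    n = len(v)
    x = np.arange(n, dtype=float)
    k = np.arange(1, n + 1, dtype=float)
    sx = np.cumsum(x)
    sy = np.cumsum(v)
    sxx = np.cumsum(x * x)
    sxy = np.cumsum(x * v)
    syy = np.cumsum(v * v)
    cxx = sxx - sx**2 / k
    cxy = sxy - sx * sy / k
    cyy = syy - sy**2 / k
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = cyy - np.where(cxx > 0, cxy**2 / np.maximum(cxx, 1e-300), 0.0)
    return np.maximum(rss, 0.0)


def _refine_breakpoint(v: np.ndarray, t: int, window: int, min_seg: int = 3) -> int:
    """Sharpen a flagged split by a global two-segment least-squares fit.

    The angle criterion flags a broad plateau around a slope break (any
    split whose windows straddle the break shows a large angle) and is
    blind to a level jump falling exactly between its two windows, so the
    flagged index localizes poorly under noise. The split minimizing the
    total RSS of two independently fitted lines over the whole series pins
    the dominant break — kink or jump — sharply; noiseless broken sticks
    are recovered exactly, and with several breaks the dominant one wins,
    matching the escalation's own selection rule.
    """
    n = len(v)
    if n < 2 * min_seg:
        return t
    pre = _prefix_line_rss(v)
    suf = _prefix_line_rss(v[::-1])
    ks = np.arange(min_seg, n - min_seg + 1)
    total = pre[ks - 1] + suf[n - ks - 1]
    return int(ks[int(np.argmin(total))])


def escalate_until_single(series, schedule=None, refine: bool = True) -> EscalationResult:
    """Walk the escalation schedule until exactly one change-point emerges.

    Returns the change-point of the first setting yielding exactly one.
    If the count jumps from >= 2 straight to 0 between consecutive
    settings, the maximal-angle point of the last multi-point setting is
    returned ("bridged"); a schedule exhausted while still seeing several
    points falls back the same way ("exhausted-multi"). A schedule that
    never yields any change-point gives a no-change-point flag
    (``index=None``), not an exception. With ``refine`` the accepted index
    is sharpened by a local two-segment least-squares fit.
    """
    v = np.asarray(getattr(series, "series", series), dtype=float)
    if schedule is None:
        schedule = default_schedule(len(v))
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    n = len(v)

    def _done(idx, window, tol, status):
        idx = int(idx)
        if refine:
            idx = _refine_breakpoint(v, idx, window)
        return EscalationResult(idx, window, tol, status)

    last_multi = None  # (indices, angles, window, tol)
    for window, tol in schedule:
        if window > n / 2:
            continue
        idx, ang = segment_series_detailed(v, window, tol)
        if len(idx) == 1:
            return _done(idx[0], window, tol, "single")
        if len(idx) >= 2:
            last_multi = (idx, ang, window, tol)
        elif last_multi is not None:
            i, a, w0, t0 = last_multi
            return _done(i[int(np.argmax(a))], w0, t0, "bridged")
    if last_multi is not None:
        i, a, w0, t0 = last_multi
        return _done(i[int(np.argmax(a))], w0, t0, "exhausted-multi")
    return EscalationResult(None, None, None, "none")


def slope_changepoint(
    camcog,
    y,
    repetitions: int = 1000,
    master_seed: int = 0,
    schedule=None,
) -> SegmentationResult:
    """Median slope change-point over random tie-splitting repetitions.

    Each repetition draws its own tie-splitting seed from ``master_seed``
    by a counter-based scheme, escalates the segmentation until a single
    change-point emerges, and maps the change index back to the CAMCOG
    score of the observation at that series position. The result stores
    every per-repetition CAMCOG value (nan where no change-point was
    found) and their median; if more than half the repetitions fail, the
    whole analysis is flagged failed (median = nan) with diagnostics.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    camcog = np.asarray(camcog)
    y = _winsorize(np.asarray(y, dtype=float))
    values = np.full(repetitions, np.nan)
    statuses: dict = {}
    for rep in range(repetitions):
        rep_seed = np.random.SeedSequence([master_seed, rep])
        ts = _tie_split_from_seedseq(camcog, y, rep_seed, master_seed)
        res = escalate_until_single(_median_smooth(ts.series), schedule)
        statuses[res.status] = statuses.get(res.status, 0) + 1
        if res.index is not None:
            values[rep] = ts.camcog[res.index]
    n_failed = int(np.isnan(values).sum())
    failed = n_failed > repetitions / 2
    median = float("nan") if failed else float(np.nanmedian(values))
    return SegmentationResult(
        changepoints=values,
        median=median,
        repetitions=repetitions,
        n_failed=n_failed,
        analysis_failed=failed,
        master_seed=master_seed,
        diagnostics={"status_counts": statuses},
    )


def _tie_split_from_seedseq(camcog, y, seedseq, master_seed) -> TieSplitSeries:
    rng = np.random.default_rng(seedseq)
    n = len(camcog)
    jitter = rng.random(n)
    order = np.lexsort((jitter, camcog))
    return TieSplitSeries(
        order=order,
        series=np.asarray(y, dtype=float)[order],
        camcog=np.asarray(camcog, dtype=float)[order],
        seed=master_seed,
    )
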