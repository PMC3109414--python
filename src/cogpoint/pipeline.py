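"""Per-biomarker change-point analysis pipeline and cohort-level summaries.

For each biomarker: run the level change-point scan and breakpoint search,
the tie-splitting slope change-point analysis, combine the two change-points
by their mean, validate the combined point with side-specific statistics
(median, variance, Spearman rho, MM-robust slope, and between-side
variance-ratio and rank tests), compare the two-regime fit against a single
line with a nested least-squares F test, and overlay the four competing
models (category means, global robust line, two-regime robust fit, Lowess)
in one figure. Cohort-level outputs are the demographics summary and the
inflection MANOVA.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _dist

from .cohort import BIOMARKERS, default_scenarios, generate_cohort
from .levelcp import fstat_scan, rss_breakpoint
from .manova import DEFAULT_INFLECTION, inflection_manova
from .robust import (
    categorical_tests,
    mann_whitney,
    mm_regression,
    lowess_fit,
    spearman_rho,
    variance_ratio_test,
)
from .slopecp import slope_changepoint

__all__ = [
    "AnalysisConfig",
    "ChangePointEstimate",
    "SideStats",
    "ModelComparison",
    "combine_changepoints",
    "side_statistics",
    "segmented_vs_linear",
    "run_biomarker",
    "run_study",
    "demographics_table",
]

MIN_SIDE_N = 3


@dataclass
class AnalysisConfig:
    """Tunable parameters of the per-biomarker analysis."""

    trim: float = 0.15
    n_permutations: int = 1000
    repetitions: int = 1000
    schedule: list | None = None
    inflect_at: float = DEFAULT_INFLECTION
    min_side_n: int = MIN_SIDE_N
    lowess_span: float = 2.0 / 3.0
    seed: int = 0


@dataclass
class ChangePointEstimate:
    level: float | None
    slope: float | None
    combined: float
    fallback: bool  # True when one component was missing
    slope_distribution: dict = field(default_factory=dict)


@dataclass
class SideStats:
    side: str  # "above" | "below"
    n: int
    median: float
    variance: float
    spearman: float
    robust_slope: float
    robust_t: float
    robust_df: int
    flagged: bool = False


@dataclass
class ModelComparison:
    rss_linear: float
    rss_segmented: float
    f: float
    df: tuple
    p_value: float
    flagged_exact_fit: bool = False


def combine_changepoints(level_cp, slope_cp) -> ChangePointEstimate:
    """Mean of the level and slope change-points; falls back when one is missing."""
    level_ok = level_cp is not None and np.isfinite(level_cp)
    slope_ok = slope_cp is not None and np.isfinite(slope_cp)
    if not level_ok and not slope_ok:
        raise ValueError("both change-point components are missing")
    if level_ok and slope_ok:
        return ChangePointEstimate(float(level_cp), float(slope_cp),
                                   (float(level_cp) + float(slope_cp)) / 2.0, False)
    if level_ok:
        return ChangePointEstimate(float(level_cp), None, float(level_cp), True)
    return ChangePointEstimate(None, float(slope_cp), float(slope_cp), True)


def _one_side_stats(camcog, values, side, min_side_n) -> SideStats:
    n = len(values)
    if n < min_side_n:
        return SideStats(side, n, math.nan, math.nan, math.nan, math.nan,
                         math.nan, max(n - 2, 0), flagged=True)
    med = float(np.median(values))
    var = float(np.var(values, ddof=1))
    if np.ptp(camcog) == 0 or np.ptp(values) == 0:
        rho = math.nan
        slope = t = math.nan
        df = n - 2
        flagged = True
    else:
        rho = spearman_rho(camcog, values)
        fit = mm_regression(camcog, values)
        slope, t, df = fit.slope, fit.t_slope, fit.df
        flagged = False
    return SideStats(side, n, med, var, rho, slope, t, df, flagged=flagged)


def side_statistics(table: pd.DataFrame, biomarker: str, cp, min_side_n: int = MIN_SIDE_N):
    """Per-side summaries and between-side tests at a change-point.

    "Above" is the strict inequality camcog > cp (the boundary score joins
    the lower regime). Returns ``(above, below, between)`` where ``between``
    holds the Wilcoxon-Mann-Whitney p for the medians and the variance-ratio
    F test, or is ``None`` when either side is below the minimum size.
    """
    cp_value = cp.combined if isinstance(cp, ChangePointEstimate) else float(cp)
    sub = table[["camcog", biomarker]].dropna()
    camcog = sub["camcog"].to_numpy(dtype=float)
    values = sub[biomarker].to_numpy(dtype=float)
    mask_above = camcog > cp_value
    above = _one_side_stats(camcog[mask_above], values[mask_above], "above", min_side_n)
    below = _one_side_stats(camcog[~mask_above], values[~mask_above], "below", min_side_n)
    between = None
    if not above.flagged and not below.flagged:
        wmw = mann_whitney(values[mask_above], values[~mask_above])
        vr = variance_ratio_test(values[mask_above], values[~mask_above])
        between = {
            "wmw_p": wmw.p_value,
            "variance_f": vr.statistic,
            "variance_df": vr.df,
            "variance_p": vr.p_value,
        }
    return above, below, between


def _ols_rss(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float((r**2).sum())


def segmented_vs_linear(table: pd.DataFrame, biomarker: str, cp) -> ModelComparison:
    """Nested least-squares F test: one global line vs two lines split at cp.

    F = ((RSS0 - RSS1)/2) / (RSS1/(n - 4)) on (2, n - 4) df. Ordinary least
    squares (not MM) is used here so the nested-F distribution theory holds.
    """
    cp_value = cp.combined if isinstance(cp, ChangePointEstimate) else float(cp)
    sub = table[["camcog", biomarker]].dropna()
    camcog = sub["camcog"].to_numpy(dtype=float)
    values = sub[biomarker].to_numpy(dtype=float)
    mask = camcog > cp_value
    if mask.sum() < MIN_SIDE_N or (~mask).sum() < MIN_SIDE_N:
        raise ValueError("need at least 3 observations on each side of the change-point")
    n = len(values)
    rss0 = _ols_rss(camcog, values)
    rss1 = _ols_rss(camcog[mask], values[mask]) + _ols_rss(camcog[~mask], values[~mask])
    rss1 = min(rss1, rss0)
    df = (2, n - 4)
    if rss1 <= 1e-12 * max(1.0, rss0):
        return ModelComparison(rss0, rss1, math.inf, df, 0.0, flagged_exact_fit=True)
    f = ((rss0 - rss1) / 2.0) / (rss1 / (n - 4))
    p = float(_dist.f.sf(f, *df))
    return ModelComparison(rss0, rss1, float(f), df, p)


def _seed_for(base_seed: int, biomarker: str, purpose: str) -> int:
    # stable across processes (unlike hash())
    tag = zlib.crc32(f"{biomarker}:{purpose}".encode()) % (2**31)
    ss = np.random.SeedSequence([base_seed, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def run_biomarker(table: pd.DataFrame, biomarker: str, config: AnalysisConfig | None = None,
                  figure_path=None) -> dict:
    """Full change-point analysis of one biomarker; returns a result bundle.

    The bundle is a plain dict (JSON-serializable via :func:`to_record`)
    holding the structural-change scan, the RSS breakpoint, the slope
    change-point distribution, the combined change-point, side statistics
    with between-side tests, the segmented-vs-linear comparison and the
    Lowess curve. When ``figure_path`` is given, the four-model overlay
    figure is written there.
    """
    config = config or AnalysisConfig()
    sub = table[["camcog", biomarker]].dropna()
    camcog = sub["camcog"].to_numpy(dtype=float)
    values = sub[biomarker].to_numpy(dtype=float)

    scan = fstat_scan(camcog, values, trim=config.trim,
                      n_permutations=config.n_permutations,
                      seed=_seed_for(config.seed, biomarker, "perm"))
    bp = rss_breakpoint(camcog, values)
    seg = slope_changepoint(camcog, values, repetitions=config.repetitions,
                            master_seed=_seed_for(config.seed, biomarker, "ties"),
                            schedule=config.schedule)
    slope_cp = None if seg.analysis_failed else seg.median
    cp = combine_changepoints(bp.changepoint_camcog, slope_cp)
    cp.slope_distribution = {
        "median": seg.median,
        "iqr": _nan_iqr(seg.changepoints),
        "n_failed": seg.n_failed,
        "repetitions": seg.repetitions,
    }
    above, below, between = side_statistics(table, biomarker, cp,
                                            min_side_n=config.min_side_n)
    comparison = segmented_vs_linear(table, biomarker, cp)
    smooth = lowess_fit(camcog, values, span=config.lowess_span)

    result = {
        "biomarker": biomarker,
        "n": len(values),
        "scan": scan,
        "breakpoint": bp,
        "segmentation": seg,
        "changepoint": cp,
        "above": above,
        "below": below,
        "between": between,
        "model_comparison": comparison,
        "lowess": smooth,
    }
    if figure_path is not None:
        from .plots import four_model_overlay

        four_model_overlay(table, biomarker, result, path=figure_path)
    return result


def _nan_iqr(v: np.ndarray) -> float:
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return math.nan
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 - q1)


def to_record(result: dict) -> dict:
    """Flatten a run_biomarker bundle into a JSON-serializable record."""
    scan = result["scan"]
    bp = result["breakpoint"]
    seg = result["segmentation"]
    cp = result["changepoint"]
    cmp_ = result["model_comparison"]

    def _side(s: SideStats) -> dict:
        d = dataclasses.asdict(s)
        return {k: _jsonify(v) for k, v in d.items()}

    return {
        "biomarker": result["biomarker"],
        "n": result["n"],
        "level_changepoint": _jsonify(bp.changepoint_camcog),
        "level_sup_f": _jsonify(scan.sup_f),
        "level_p": _jsonify(scan.p_value),
        "slope_changepoint": _jsonify(seg.median),
        "slope_cp_iqr": _jsonify(cp.slope_distribution.get("iqr")),
        "slope_failed_repetitions": seg.n_failed,
        "combined_changepoint": _jsonify(cp.combined),
        "combined_fallback": cp.fallback,
        "above": _side(result["above"]),
        "below": _side(result["below"]),
        "between": {k: _jsonify(v) for k, v in (result["between"] or {}).items()},
        "segmented_vs_linear": {
            "f": _jsonify(cmp_.f),
            "df": list(cmp_.df),
            "p": _jsonify(cmp_.p_value),
            "rss_linear": _jsonify(cmp_.rss_linear),
            "rss_segmented": _jsonify(cmp_.rss_segmented),
            "flagged_exact_fit": cmp_.flagged_exact_fit,
        },
    }


def _jsonify(v):
    if v is None:
        return None
    if isinstance(v, (tuple, list)):
        return [_jsonify(x) for x in v]
    if isinstance(v, np.ndarray):
        return [_jsonify(x) for x in v.tolist()]
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (float, np.floating)):
        v = float(v)
        if math.isnan(v):
            return None
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return v
    return v


def _fmt_median_iqr(v: np.ndarray) -> str:
    med, q1, q3 = (np.percentile(v, q) for q in (50, 25, 75))

    def f(x):
        return f"{x:.0f}" if float(x).is_integer() else f"{x:.1f}"

    return f"{f(med)} ({f(q1)}-{f(q3)})"


def demographics_table(table: pd.DataFrame) -> dict:
    """Group-wise demographic summary with between-group tests.

    Per group: n by gender and median (IQR) for age, MMSE and CAMCOG
    formatted like "99 (81-106)". Between groups: Wilcoxon-Mann-Whitney p
    for the continuous contrasts, Fisher exact and Pearson chi-square for
    gender.
    """
    groups = table["group"].unique()
    out: dict = {"groups": {}, "tests": {}, "flags": []}
    for g in groups:
        sub = table[table["group"] == g]
        entry = {"n": int(len(sub))}
        if "gender" in sub.columns:
            counts = sub["gender"].value_counts()
            entry["gender"] = f"{counts.get('F', 0)}F: {counts.get('M', 0)}M"
        for col in ("age", "mmse", "camcog"):
            if col in sub.columns:
                vals = sub[col].dropna().to_numpy(dtype=float)
                entry[col] = _fmt_median_iqr(vals) if len(vals) else None
        out["groups"][g] = entry
    if len(groups) != 2:
        out["flags"].append(f"expected 2 groups, found {len(groups)}; tests skipped")
        return out
    g1, g2 = groups
    a = table[table["group"] == g1]
    b = table[table["group"] == g2]
    for col in ("age", "mmse", "camcog"):
        if col in table.columns:
            out["tests"][f"{col}_wmw_p"] = mann_whitney(
                a[col].dropna(), b[col].dropna()
            ).p_value
    if "gender" in table.columns:
        t = [
            [int((a["gender"] == "F").sum()), int((a["gender"] == "M").sum())],
            [int((b["gender"] == "F").sum()), int((b["gender"] == "M").sum())],
        ]
        cat = categorical_tests(t)
        out["tests"]["gender_fisher_p"] = cat.fisher_p
        out["tests"]["gender_chi2_p"] = cat.chi2_p
    return out


def summary_table(results: dict) -> pd.DataFrame:
    """Biomarker x (Above, Below) table of median, variance, Spearman rho
    and robust slope — the per-side parameter summary schema."""
    rows = []
    for name, res in results.items():
        for stat in ("median", "variance", "spearman", "robust_slope"):
            rows.append(
                {
                    "biomarker": name,
                    "parameter": stat,
                    "above": getattr(res["above"], stat),
                    "below": getattr(res["below"], stat),
                }
            )
    return pd.DataFrame(rows)


def run_study(
    table: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    biomarkers=BIOMARKERS,
    n_control: int = 95,
    n_ad: int = 97,
    figure_dir=None,
) -> dict:
    """Run the full analysis on a cohort (generated from the default
    scenarios when none is supplied): demographics, inflection MANOVA and
    the per-biomarker change-point pipeline."""
    config = config or AnalysisConfig()
    if table is None:
        table = generate_cohort(default_scenarios(), n_control, n_ad, seed=config.seed)
    results = {}
    for bm in biomarkers:
        if bm not in table.columns:
            continue
        fig_path = None
        if figure_dir is not None:
            from pathlib import Path

            fig_path = Path(figure_dir) / f"{bm}_overlay.png"
        results[bm] = run_biomarker(table, bm, config, figure_path=fig_path)
    manova = None
    try:
        manova = inflection_manova(table, config.inflect_at)
    except ValueError:
        pass
    demo = demographics_table(table) if "group" in table.columns else None
    return {
        "table": table,
        "config": config,
        "biomarkers": results,
        "summary": summary_table(results),
        "manova": manova,
        "demographics": demo,
    }


def study_record(study: dict) -> dict:
    """JSON-serializable record of a run_study result."""
    rec = {
        "biomarkers": {bm: to_record(res) for bm, res in study["biomarkers"].items()},
        "demographics": study["demographics"],
    }
    if study["manova"] is not None:
        rec["manova"] = {
            term: {
                "wilks_lambda": r.wilks_lambda,
                "f": r.f,
                "df": [r.df_num, r.df_den],
                "p": r.p_value,
                "n": r.n,
            }
            for term, r in study["manova"].items()
        }
    return rec


def write_study_json(study: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(study_record(study), fh, indent=2, sort_keys=True)
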