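"""Omnibus multivariate tests for an inflection in biomarker-cognition relations.

All four CSF biomarkers are regressed jointly on covariates (age, gender,
storage time, assay group) and the CAMCOG score, with two additional
single-df terms encoding an inflection at a configurable score c: a
level-shift indicator 1[camcog < c] and a hinge term
(camcog - c) * 1[camcog < c] encoding a change of slope below c. Each term
is tested across the four responses with Wilks' lambda converted to its
exact F (for a single-df hypothesis all four classical multivariate
statistics coincide in this conversion). Degrees of freedom come from the
complete cases actually analysed, never from the nominal sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _dist

from .cohort import BIOMARKERS

__all__ = [
    "InflectionDesign",
    "ManovaResult",
    "DegenerateDesignError",
    "design_with_inflection",
    "manova_term_test",
    "inflection_manova",
]

DEFAULT_INFLECTION = 89.0

_TERM_COLUMNS = {"level": "below", "slope": "hinge"}


class DegenerateDesignError(ValueError):
    """Raised when the design matrix is rank-deficient; names the columns."""


@dataclass
class InflectionDesign:
    X: np.ndarray
    columns: list
    Y: np.ndarray
    responses: list
    inflect_at: float
    n: int
    index: np.ndarray  # row labels of the complete cases used


@dataclass
class ManovaResult:
    term: str
    wilks_lambda: float
    f: float
    df_num: int
    df_den: int
    p_value: float
    coefficients: dict  # per-response univariate coefficient of the term
    n: int


def design_with_inflection(
    table: pd.DataFrame,
    inflect_at: float = DEFAULT_INFLECTION,
    responses=BIOMARKERS,
    check_rank: bool = True,
) -> InflectionDesign:
    """Build the multivariate design with level-shift and hinge terms.

    Columns: intercept, age, gender (indicator for M), storage time, assay
    group (indicator coding, first group as reference), camcog, ``below``
    = 1[camcog < inflect_at], ``hinge`` = (camcog - inflect_at) * below.
    The boundary score belongs to the upper regime (indicator 0). Rows with
    any missing response or covariate are dropped listwise.
    """
    responses = [r for r in responses if r in table.columns]
    if not responses:
        raise ValueError("no response columns present in the table")
    covars = [c for c in ("age", "gender", "storage_time", "assay_group") if c in table.columns]
    needed = ["camcog"] + covars + responses
    data = table[needed].dropna()
    camcog = data["camcog"].to_numpy(dtype=float)
    if len(camcog) == 0:
        raise ValueError("no complete cases")
    if not camcog.min() <= inflect_at <= camcog.max():
        raise ValueError(
            f"inflection {inflect_at} outside observed CAMCOG range "
            f"[{camcog.min():g}, {camcog.max():g}]"
        )

    cols: dict = {"intercept": np.ones(len(camcog))}
    if "age" in covars:
        cols["age"] = data["age"].to_numpy(dtype=float)
    if "gender" in covars:
        cols["gender_M"] = (data["gender"] == "M").to_numpy(dtype=float)
    if "storage_time" in covars:
        cols["storage_time"] = data["storage_time"].to_numpy(dtype=float)
    if "assay_group" in covars:
        groups = np.sort(data["assay_group"].unique())
        for g in groups[1:]:  # first group is the reference level
            cols[f"assay_{g}"] = (data["assay_group"] == g).to_numpy(dtype=float)
    cols["camcog"] = camcog
    below = (camcog < inflect_at).astype(float)
    cols["below"] = below
    cols["hinge"] = (camcog - inflect_at) * below

    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    design = InflectionDesign(
        X=X,
        columns=names,
        Y=data[responses].to_numpy(dtype=float),
        responses=list(responses),
        inflect_at=float(inflect_at),
        n=len(camcog),
        index=data.index.to_numpy(),
    )
    if check_rank:
        _check_full_rank(design)
    return design


def _check_full_rank(design: InflectionDesign) -> None:
    X = design.X
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        _, r, piv = _qr_pivoted(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = sorted(design.columns[p] for p in piv[np.sum(diag > tol):])
        raise DegenerateDesignError(f"design is rank-deficient; collinear columns: {bad}")


def _qr_pivoted(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def manova_term_test(design: InflectionDesign, term: str) -> ManovaResult:
    """Wilks' lambda test of a single design term across all responses.

    ``term`` is "level" (the below-indicator) or "slope" (the hinge term),
    or any design column name. For a single-df hypothesis with m responses,
    the exact F is ((1 - L)/L) * (n - r - m + 1)/m on (m, n - r - m + 1)
    df, where r is the design rank.
    """
    col = _TERM_COLUMNS.get(term, term)
    if col not in design.columns:
        raise ValueError(f"term {term!r} (column {col!r}) not in design: {design.columns}")
    X, Y = design.X, design.Y
    n, p = X.shape
    m = Y.shape[1]
    if n <= p + m:
        raise ValueError(f"complete-case n = {n} too small for p = {p}, m = {m}")
    _check_full_rank(design)

    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid

    j = design.columns.index(col)
    Lb = B[j : j + 1, :]  # 1 x m
    lxl = xtx_inv[j, j]
    H = (Lb.T @ Lb) / lxl

    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_eh, logdet_eh = np.linalg.slogdet(E + H)
    if sign_e <= 0 or sign_eh <= 0:
        raise ValueError("singular error cross-product matrix")
    lam = float(np.exp(logdet_e - logdet_eh))
    df_den = n - p - m + 1
    f = (1.0 - lam) / lam * df_den / m
    p_value = float(_dist.f.sf(f, m, df_den))
    coefs = {resp: float(B[j, k]) for k, resp in enumerate(design.responses)}
    return ManovaResult(
        term=term,
        wilks_lambda=lam,
        f=float(f),
        df_num=m,
        df_den=int(df_den),
        p_value=p_value,
        coefficients=coefs,
        n=n,
    )


def inflection_manova(
    table: pd.DataFrame,
    inflect_at: float = DEFAULT_INFLECTION,
    responses=BIOMARKERS,
) -> dict:
    """Convenience wrapper: level-shift and slope-change tests at one inflection."""
    design = design_with_inflection(table, inflect_at, responses=responses)
    return {
        "level": manova_term_test(design, "level"),
        "slope": manova_term_test(design, "slope"),
    }
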