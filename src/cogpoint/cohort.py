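"""Synthetic cohorts with piecewise-linear, heteroscedastic biomarker responses.

The generator emulates the joint structure a cross-sectional memory-clinic
cohort presents to a change-point analysis: a bimodal distribution of CAMCOG
total scores (a non-demented cluster concentrated near the ceiling and an
Alzheimer's-disease group spread over the low range), and CSF biomarker
concentrations whose mean is a broken-stick function of CAMCOG with a
change-point near the lower boundary of the normal cognitive range, an
optional level jump between the regimes, different residual variances on
either side of the change-point, and optional batch effects, covariate
effects and heavy-tailed contamination.

Every draw is reproducible from an integer seed, so downstream change-point
detectors can be tested against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CAMCOG_MAX",
    "BIOMARKERS",
    "COHORT_COLUMNS",
    "ScenarioConfig",
    "ScenarioError",
    "sample_camcog",
    "piecewise_mean",
    "generate_cohort",
    "default_scenarios",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "scenarios_to_yaml",
    "scenarios_from_yaml",
]

CAMCOG_MAX = 107
BIOMARKERS = ("abeta40", "abeta42", "tau", "ptau")

COHORT_COLUMNS = [
    "participant_id",
    "group",
    "camcog",
    "mmse",
    "age",
    "gender",
    "storage_time",
    "assay_group",
    *BIOMARKERS,
]

# Piecewise-linear quantile anchors (probability, score) for the two groups.
# Median/IQR anchors reproduce the published cohort's demographics table:
# non-demented median 99 (IQR 81-106), AD median 57 (IQR 10-96).
_CONTROL_QUANTILES = ((0.0, 45.0), (0.25, 81.0), (0.5, 99.0), (0.75, 106.0), (1.0, 107.0))
_AD_QUANTILES = ((0.0, 0.0), (0.25, 10.0), (0.5, 57.0), (0.75, 96.0), (1.0, 107.0))


class ScenarioError(ValueError):
    """Raised when a ScenarioConfig field is invalid; names the field."""


@dataclass
class ScenarioConfig:
    """Generative parameters for one synthetic biomarker archetype.

    The mean response is a broken stick anchored at ``level_at_theta``:

        mu(c) = level_at_theta + level_shift + slope_above * (c - theta)   if c > theta
        mu(c) = level_at_theta + slope_below * (c - theta)                 if c <= theta

    With ``level_shift = 0`` (the default) the mean is continuous at theta.
    A non-zero shift adds a level jump between the regimes: the side-median
    contrasts the analysis is meant to detect are far larger than a
    continuous stick can produce, so realistic archetypes carry a jump.

    Residual noise is Gaussian with side-specific standard deviation
    (``sd_above`` for c > theta, ``sd_below`` otherwise). A
    ``contamination_rate`` fraction of observations has its noise inflated
    by ``contamination_scale`` (symmetric variance inflation, exercising
    robust estimators without shifting the mean).

    Parameters are in pg/mL (levels, SDs) and pg/mL per CAMCOG point
    (slopes); ``theta`` is on the CAMCOG scale.
    """

    name: str
    theta: float
    slope_above: float
    slope_below: float
    level_at_theta: float
    sd_above: float
    sd_below: float
    level_shift: float = 0.0
    contamination_rate: float = 0.0
    contamination_scale: float = 10.0
    batch_effects: dict = field(default_factory=dict)
    covariate_coeffs: dict = field(default_factory=dict)

    _COVARIATES = ("age", "gender", "storage_time")

    def validate(self) -> None:
        if not 0.0 <= self.theta <= CAMCOG_MAX:
            raise ScenarioError(
                f"theta must lie in [0, {CAMCOG_MAX}], got {self.theta!r}"
            )
        if not self.sd_above > 0:
            raise ScenarioError(f"sd_above must be > 0, got {self.sd_above!r}")
        if not self.sd_below > 0:
            raise ScenarioError(f"sd_below must be > 0, got {self.sd_below!r}")
        if not 0.0 <= self.contamination_rate <= 0.5:
            raise ScenarioError(
                f"contamination_rate must lie in [0, 0.5], got {self.contamination_rate!r}"
            )
        if not self.contamination_scale > 0:
            raise ScenarioError(
                f"contamination_scale must be > 0, got {self.contamination_scale!r}"
            )
        for key in self.covariate_coeffs:
            if key not in self._COVARIATES:
                raise ScenarioError(
                    f"covariate_coeffs key {key!r} not one of {self._COVARIATES}"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["batch_effects"] = {int(k): float(v) for k, v in self.batch_effects.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "batch_effects" in d and d["batch_effects"]:
            d["batch_effects"] = {int(k): float(v) for k, v in d["batch_effects"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _sample_quantile_scores(n: int, anchors, rng: np.random.Generator) -> np.ndarray:
    """Draw integer scores via inverse-CDF interpolation through the anchors."""
    if n == 0:
        return np.empty(0, dtype=int)
    probs = np.array([a[0] for a in anchors])
    vals = np.array([a[1] for a in anchors])
    u = rng.random(n)
    scores = np.interp(u, probs, vals)
    return np.clip(np.rint(scores), 0, CAMCOG_MAX).astype(int)


def sample_camcog(n_control: int, n_ad: int, seed: int) -> pd.DataFrame:
    """Sample CAMCOG total scores for a two-group cohort.

    Non-demented scores concentrate near the ceiling (median ~99,
    IQR ~81-106); AD scores spread widely over the low range (median ~57,
    IQR ~10-96). Scores are integers in [0, 107].

    Returns a DataFrame with columns ``group`` ("non-demented" | "AD") and
    ``camcog``. Deterministic given ``seed``.
    """
    if n_control < 0 or n_ad < 0:
        raise ValueError(f"group sizes must be non-negative, got {n_control}, {n_ad}")
    rng = np.random.default_rng(seed)
    ctrl = _sample_quantile_scores(n_control, _CONTROL_QUANTILES, rng)
    ad = _sample_quantile_scores(n_ad, _AD_QUANTILES, rng)
    return pd.DataFrame(
        {
            "group": ["non-demented"] * n_control + ["AD"] * n_ad,
            "camcog": np.concatenate([ctrl, ad]),
        }
    )


def piecewise_mean(camcog, cfg: ScenarioConfig):
    """Expected biomarker level at the given CAMCOG score(s).

    Broken stick anchored at ``cfg.level_at_theta``; the boundary score
    ``theta`` itself belongs to the lower arm, and ``cfg.level_shift``
    (zero by default, i.e. continuous at theta) offsets the upper arm.
    """
    c = np.asarray(camcog, dtype=float)
    above = c > cfg.theta
    slope = np.where(above, cfg.slope_above, cfg.slope_below)
    out = cfg.level_at_theta + above * cfg.level_shift + slope * (c - cfg.theta)
    if np.isscalar(camcog) or np.ndim(camcog) == 0:
        return float(out)
    return out


def _sample_covariates(groups: np.ndarray, rng: np.random.Generator) -> dict:
    n = len(groups)
    is_ad = groups == "AD"
    age = np.where(
        is_ad,
        rng.normal(74.6, 7.5, size=n),
        rng.normal(72.0, 8.0, size=n),
    )
    age = np.clip(age, 60.0, 95.0).round(1)
    p_female = np.where(is_ad, 60 / 97, 48 / 95)
    gender = np.where(rng.random(n) < p_female, "F", "M")
    storage_time = rng.uniform(0.5, 15.0, size=n).round(2)
    assay_group = rng.integers(1, 5, size=n)
    return {
        "age": age,
        "gender": gender,
        "storage_time": storage_time,
        "assay_group": assay_group,
    }


def _mmse_from_camcog(camcog: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # Rough monotone mapping calibrated to medians 29 (controls, CAMCOG 99)
    # and 15 (AD, CAMCOG 57); MMSE is a coarser 0-30 instrument.
    raw = camcog * 0.30 - 1.0 + rng.normal(0.0, 1.5, size=len(camcog))
    return np.clip(np.rint(raw), 0, 30).astype(int)


def generate_cohort(
    cfgs: dict,
    n_control: int,
    n_ad: int,
    seed: int,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Generate a tidy per-participant cohort table.

    ``cfgs`` maps biomarker name -> :class:`ScenarioConfig`. Each biomarker
    is ``piecewise_mean(camcog) + batch offset + covariate effects +
    side-specific Gaussian noise``; a ``contamination_rate`` fraction of
    rows receives noise inflated by ``contamination_scale``. Negative draws
    are clipped to zero (concentrations are non-negative). ``missing_rate``
    blanks biomarker cells completely at random.

    Fully reproducible given ``seed``.
    """
    for name, cfg in cfgs.items():
        try:
            cfg.validate()
        except ScenarioError as exc:
            raise ScenarioError(f"scenario {name!r}: {exc}") from exc
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must lie in [0, 1), got {missing_rate}")

    rng = np.random.default_rng(seed)
    base = sample_camcog(n_control, n_ad, int(rng.integers(2**31)))
    camcog = base["camcog"].to_numpy()
    groups = base["group"].to_numpy()
    n = len(camcog)

    cov = _sample_covariates(groups, rng)
    mmse = _mmse_from_camcog(camcog, rng)

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "group": groups,
            "camcog": camcog,
            "mmse": mmse,
            **cov,
        }
    )

    gender_num = (table["gender"] == "M").to_numpy(dtype=float)
    for name, cfg in cfgs.items():
        mu = piecewise_mean(camcog, cfg) if n else np.empty(0)
        coeffs = cfg.covariate_coeffs
        mu = mu + coeffs.get("age", 0.0) * cov["age"]
        mu = mu + coeffs.get("gender", 0.0) * gender_num
        mu = mu + coeffs.get("storage_time", 0.0) * cov["storage_time"]
        if cfg.batch_effects:
            offsets = np.array(
                [cfg.batch_effects.get(int(g), 0.0) for g in cov["assay_group"]]
            )
            mu = mu + offsets
        sd = np.where(camcog > cfg.theta, cfg.sd_above, cfg.sd_below)
        if cfg.contamination_rate > 0:
            contaminated = rng.random(n) < cfg.contamination_rate
            sd = np.where(contaminated, sd * cfg.contamination_scale, sd)
        values = np.maximum(mu + rng.normal(0.0, 1.0, size=n) * sd, 0.0)
        if missing_rate > 0:
            values = np.where(rng.random(n) < missing_rate, np.nan, values)
        table[name] = values

    return table


def default_scenarios() -> dict:
    """The four built-in biomarker archetypes.

    Change-points, slope signs, side-level contrasts (the ``level_shift``
    jumps, taken from the published above/below side-median differences)
    and variance orientations follow the published per-biomarker pattern:
    Abeta40 biphasic at CAMCOG 90 with much higher levels above, Abeta42
    declining above its change-point at 90 and flat below, total Tau (94)
    and phospho-Tau (93) higher and more variable below their change-points
    but related to CAMCOG essentially only above. Slope and SD magnitudes
    are package design choices scaled to each analyte's pg/mL range so the
    regimes are detectable at cohort size ~200; these configs are test
    fixtures, not claims about any real cohort.
    """
    return {
        "abeta40": ScenarioConfig(
            name="abeta40",
            theta=90.0,
            slope_above=93.0,
            slope_below=-6.0,
            level_at_theta=3900.0,
            level_shift=1100.0,
            sd_above=800.0,
            sd_below=600.0,
        ),
        "abeta42": ScenarioConfig(
            name="abeta42",
            theta=90.0,
            slope_above=-15.0,
            slope_below=-0.3,
            level_at_theta=380.0,
            level_shift=330.0,
            sd_above=130.0,
            sd_below=180.0,
        ),
        "tau": ScenarioConfig(
            name="tau",
            theta=94.0,
            slope_above=12.0,
            slope_below=0.5,
            level_at_theta=570.0,
            level_shift=-310.0,
            sd_above=90.0,
            sd_below=160.0,
        ),
        "ptau": ScenarioConfig(
            name="ptau",
            theta=93.0,
            slope_above=1.5,
            slope_below=0.05,
            level_at_theta=80.0,
            level_shift=-30.0,
            sd_above=9.0,
            sd_below=18.0,
        ),
    }


def validate_cohort(table: pd.DataFrame, require_biomarkers: bool = True) -> None:
    """Check the cohort-table contract; raise ValueError on violation."""
    required = ["participant_id", "group", "camcog"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if require_biomarkers:
        demo = set(COHORT_COLUMNS) - set(BIOMARKERS)
        marker_cols = [c for c in table.columns
                       if c in BIOMARKERS
                       or (c not in demo and np.issubdtype(table[c].dtype, np.number))]
        if not marker_cols:
            raise ValueError("cohort table has no biomarker columns")
    camcog = table["camcog"]
    if not np.issubdtype(camcog.dtype, np.integer):
        if not np.allclose(camcog, np.rint(camcog)):
            raise ValueError("camcog scores must be integers")
    if camcog.min() < 0 or camcog.max() > CAMCOG_MAX:
        raise ValueError(f"camcog scores must lie in [0, {CAMCOG_MAX}]")
    for b in BIOMARKERS:
        if b in table.columns:
            vals = table[b].dropna()
            if (vals < 0).any():
                raise ValueError(f"biomarker {b!r} has negative values")


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with the documented fixed header."""
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    table = pd.read_csv(path)
    validate_cohort(table, require_biomarkers=False)
    return table


def scenarios_to_yaml(cfgs: dict, path) -> None:
    payload = {name: cfg.to_dict() for name, cfg in cfgs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def scenarios_from_yaml(path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {name: ScenarioConfig.from_dict(d) for name, d in payload.items()}
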