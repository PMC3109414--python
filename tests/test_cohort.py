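"""Synthetic cohort generator: score mixture, broken-stick means, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogpoint import (
    CAMCOG_MAX,
    ScenarioConfig,
    ScenarioError,
    default_scenarios,
    generate_cohort,
    piecewise_mean,
    read_cohort,
    sample_camcog,
    scenarios_from_yaml,
    scenarios_to_yaml,
    validate_cohort,
    write_cohort,
)


def _plain_cfg(**kw):
    base = dict(
        name="x", theta=90.0, slope_above=1.0, slope_below=-1.0,
        level_at_theta=100.0, sd_above=5.0, sd_below=5.0,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestSampleCamcog:
    def test_sizes_and_labels(self):
        s = sample_camcog(95, 97, seed=1)
        assert len(s) == 192
        assert (s.group == "non-demented").sum() == 95
        assert (s.group == "AD").sum() == 97

    def test_empty(self):
        assert len(sample_camcog(0, 0, seed=3)) == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sample_camcog(-1, 5, seed=0)

    def test_support_is_integer_in_range(self):
        s = sample_camcog(500, 500, seed=11)
        assert np.issubdtype(s.camcog.dtype, np.integer)
        assert s.camcog.between(0, CAMCOG_MAX).all()

    def test_group_quantile_targets(self):
        # mixture targets: non-demented median ~99 (IQR 81-106), AD ~57 (10-96)
        s = sample_camcog(5000, 5000, seed=7)
        ctrl = s[s.group == "non-demented"].camcog
        ad = s[s.group == "AD"].camcog
        assert abs(ctrl.median() - 99) <= 2
        assert abs(ad.median() - 57) <= 3
        assert abs(np.percentile(ctrl, 25) - 81) <= 3
        assert abs(np.percentile(ad, 75) - 96) <= 3

    def test_deterministic(self):
        a = sample_camcog(50, 50, seed=5)
        b = sample_camcog(50, 50, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestPiecewiseMean:
    def test_anchor_at_theta(self):
        cfg = _plain_cfg()
        assert piecewise_mean(cfg.theta, cfg) == cfg.level_at_theta

    def test_equal_slopes_collinear(self):
        cfg = _plain_cfg(slope_above=2.0, slope_below=2.0)
        c = np.arange(0, 108, dtype=float)
        line = cfg.level_at_theta + 2.0 * (c - cfg.theta)
        assert np.allclose(piecewise_mean(c, cfg), line)

    def test_theta_is_extremum_of_biphasic_config(self):
        # slope_above > 0 and slope_below < 0 make both arms rise away from
        # theta: the anchor is the meeting point and the minimum of the mean.
        cfg = _plain_cfg(theta=90.0, slope_above=93.0, slope_below=-15.0)
        at_theta = piecewise_mean(90.0, cfg)
        assert at_theta < piecewise_mean(70.0, cfg)
        assert at_theta < piecewise_mean(105.0, cfg)

    def test_level_shift_offsets_upper_arm_only(self):
        cfg = _plain_cfg(level_shift=50.0)
        assert piecewise_mean(cfg.theta, cfg) == cfg.level_at_theta
        assert piecewise_mean(cfg.theta + 1, cfg) == pytest.approx(
            cfg.level_at_theta + 50.0 + cfg.slope_above
        )


class TestGenerateCohort:
    def test_noiseless_limit_recovers_mean(self):
        cfg = _plain_cfg(sd_above=1e-9, sd_below=1e-9)
        t = generate_cohort({"x": cfg}, 60, 60, seed=2)
        mu = piecewise_mean(t.camcog.to_numpy(float), cfg)
        assert np.allclose(t["x"], np.maximum(mu, 0.0), atol=1e-6)

    def test_side_variance_ratio(self):
        cfg = _plain_cfg(theta=90.0, sd_above=12.0, sd_below=4.0,
                         level_at_theta=1000.0)
        t = generate_cohort({"x": cfg}, 1000, 1000, seed=3)
        resid = t["x"].to_numpy(float) - piecewise_mean(t.camcog.to_numpy(float), cfg)
        above = t.camcog > cfg.theta
        ratio = resid[above].var(ddof=1) / resid[~above].var(ddof=1)
        assert abs(ratio / (cfg.sd_above / cfg.sd_below) ** 2 - 1) < 0.15

    def test_sidewise_slope_recovery(self):
        # least-squares slopes on clean data within 3 MC SEs of the truth
        cfg = _plain_cfg(theta=90.0, slope_above=2.0, slope_below=-0.5,
                         level_at_theta=500.0, sd_above=10.0, sd_below=10.0)
        t = generate_cohort({"x": cfg}, 3000, 3000, seed=9)
        for side, truth in ((t.camcog > 90, 2.0), (t.camcog <= 90, -0.5)):
            x = t.camcog[side].to_numpy(float)
            y = t["x"][side].to_numpy(float)
            slope, _ = np.polyfit(x, y, 1)
            se = 10.0 / (x.std() * np.sqrt(len(x)))
            assert abs(slope - truth) < 3 * se

    def test_contamination_inflates_variance(self):
        clean = _plain_cfg(level_at_theta=1000.0)
        dirty = _plain_cfg(level_at_theta=1000.0, contamination_rate=0.2,
                           contamination_scale=10.0)
        tc = generate_cohort({"x": clean}, 500, 500, seed=4)
        td = generate_cohort({"x": dirty}, 500, 500, seed=4)
        resid_c = tc["x"] - piecewise_mean(tc.camcog.to_numpy(float), clean)
        resid_d = td["x"] - piecewise_mean(td.camcog.to_numpy(float), dirty)
        assert resid_d.var() > 3 * resid_c.var()

    def test_deterministic_and_csv_roundtrip(self, tmp_path, scenarios):
        a = generate_cohort(scenarios, 30, 30, seed=12)
        b = generate_cohort(scenarios, 30, 30, seed=12)
        pd.testing.assert_frame_equal(a, b)
        path = tmp_path / "cohort.csv"
        write_cohort(a, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(a, back, check_dtype=False)

    def test_invalid_config_names_field(self):
        bad = _plain_cfg(sd_above=-1.0)
        with pytest.raises(ScenarioError, match="sd_above"):
            generate_cohort({"x": bad}, 10, 10, seed=0)
        with pytest.raises(ScenarioError, match="contamination_rate"):
            generate_cohort({"x": _plain_cfg(contamination_rate=0.9)}, 10, 10, seed=0)

    def test_missing_rate_blanks_cells(self):
        cfg = _plain_cfg(level_at_theta=1000.0)
        t = generate_cohort({"x": cfg}, 200, 200, seed=5, missing_rate=0.3)
        frac = t["x"].isna().mean()
        assert 0.2 < frac < 0.4
        validate_cohort(t)


class TestDefaultScenarios:
    def test_changepoints_and_slope_signs(self, scenarios):
        assert scenarios["abeta40"].theta == 90
        assert scenarios["abeta42"].theta == 90
        assert scenarios["tau"].theta == 94
        assert scenarios["ptau"].theta == 93
        # biphasic Abeta40; declining Abeta42 above, ~flat below;
        # Tau/pTau positive on both sides, dominated by the upper side
        a40 = scenarios["abeta40"]
        assert a40.slope_above > 0 > a40.slope_below
        a42 = scenarios["abeta42"]
        assert a42.slope_above < 0 and abs(a42.slope_below) < abs(a42.slope_above) / 10
        for name in ("tau", "ptau"):
            cfg = scenarios[name]
            assert cfg.slope_above > 0 and cfg.slope_below > 0
            assert cfg.slope_above > cfg.slope_below

    def test_yaml_roundtrip(self, tmp_path, scenarios):
        path = tmp_path / "scenarios.yaml"
        scenarios_to_yaml(scenarios, path)
        back = scenarios_from_yaml(path)
        assert back == scenarios


@settings(derandomize=True, max_examples=30)
@given(
    camcog=st.integers(min_value=0, max_value=107),
    theta=st.floats(min_value=1, max_value=106),
    s_a=st.floats(min_value=-50, max_value=50),
    s_b=st.floats(min_value=-50, max_value=50),
)
def test_piecewise_mean_matches_formula(camcog, theta, s_a, s_b):
    cfg = _plain_cfg(theta=theta, slope_above=s_a, slope_below=s_b)
    slope = s_a if camcog > theta else s_b
    expected = cfg.level_at_theta + slope * (camcog - theta)
    assert piecewise_mean(camcog, cfg) == pytest.approx(expected)
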