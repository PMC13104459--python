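"""MI engine: Rubin pooling arithmetic, chained equations, delta machinery."""

import numpy as np
import pandas as pd
import pytest

from cohortmi import (
    DeltaConfig,
    MIConfig,
    VariableMeta,
    calibrate_delta,
    delta_adjust,
    impute,
    pool,
    pooled_mean,
)
from cohortmi.errors import ConfigError, ConvergenceError


def mcar_frame(seed=0, n=2000, miss_frac=0.4, rho=0.7):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    miss = rng.random(n) < miss_frac
    yobs = y.copy()
    yobs[miss] = np.nan
    data = pd.DataFrame({"x": x, "y": yobs})
    meta = {
        "x": VariableMeta("x", 1, "continuous"),
        "y": VariableMeta("y", 1, "continuous"),
    }
    return data, meta, y, miss


NORM = {"continuous": "norm"}


class TestPooling:
    def test_worked_arithmetic(self):
        pe = pool([0.5, 0.7], [0.04, 0.04])
        assert pe.point == pytest.approx(0.6)
        assert pe.W == pytest.approx(0.04)
        assert pe.B == pytest.approx(0.02)
        assert pe.T == pytest.approx(0.07)

    def test_identical_points_give_zero_between_variance(self):
        pe = pool([0.42] * 5, [0.01] * 5)
        assert pe.B == 0.0
        assert pe.T == pe.W
        assert np.isinf(pe.df)

    def test_mean_and_sample_variance_identities(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal(50)
        vs = rng.random(50) + 0.1
        pe = pool(pts, vs)
        assert pe.point == pytest.approx(pts.mean())
        assert pe.B == pytest.approx(pts.var(ddof=1))
        assert pe.W == pytest.approx(vs.mean())

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            pool([0.1, 0.2], [0.3])


class TestImpute:
    def test_no_missingness_returns_identical_copies(self):
        data = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        meta = {"x": VariableMeta("x", 1, "continuous")}
        out = impute(data, meta, MIConfig(m=3, seed=0))
        assert len(out) == 3
        for df in out:
            pd.testing.assert_frame_equal(df, data)

    def test_observed_cells_immutable(self):
        data, meta, y, miss = mcar_frame()
        for df in impute(data, meta, MIConfig(m=3, n_iterations=2, seed=1)):
            assert (df.loc[~miss, "y"].to_numpy() == y[~miss]).all()
            assert (df["x"].to_numpy() == data["x"].to_numpy()).all()
            assert df["y"].notna().all()

    def test_seed_reproducibility(self):
        data, meta, *_ = mcar_frame()
        a = impute(data, meta, MIConfig(m=3, n_iterations=2, seed=5))
        b = impute(data, meta, MIConfig(m=3, n_iterations=2, seed=5))
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da, db)

    def test_mcar_pooled_mean_near_full_data_mean(self):
        data, meta, y, _ = mcar_frame(seed=3, n=5000, miss_frac=0.2)
        cfg = MIConfig(m=10, n_iterations=3, seed=3, methods=NORM)
        pm = pooled_mean(impute(data, meta, cfg), "y")
        assert abs(pm.point - y.mean()) < 3 * pm.se

    def test_mixed_types_yield_valid_levels(self):
        rng = np.random.default_rng(11)
        n = 800
        x = rng.standard_normal(n)
        b = (rng.random(n) < 0.4).astype(float)
        cat = rng.choice(np.array(["u", "v", "w"], dtype=object), n)
        data = pd.DataFrame({"x": x, "b": b, "cat": cat})
        for col in ("b", "cat"):
            data.loc[rng.random(n) < 0.3, col] = np.nan
        meta = {
            "x": VariableMeta("x", 1, "continuous"),
            "b": VariableMeta("b", 1, "binary"),
            "cat": VariableMeta("cat", 1, "categorical",
                                category_labels=("u", "v", "w")),
        }
        for df in impute(data, meta, MIConfig(m=3, n_iterations=2, seed=2)):
            assert set(df["b"].unique()) <= {0.0, 1.0}
            assert set(df["cat"].unique()) <= {"u", "v", "w"}

    def test_fully_missing_column_rejected(self):
        data = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        meta = {
            "x": VariableMeta("x", 1, "continuous"),
            "y": VariableMeta("y", 1, "continuous"),
        }
        with pytest.raises(ConfigError, match="100% missing"):
            impute(data, meta, MIConfig(m=2, seed=0))

    def test_predictor_only_must_be_complete(self):
        data = pd.DataFrame({"x": [1.0, np.nan], "y": [0.5, 1.5]})
        meta = {
            "x": VariableMeta("x", 1, "continuous"),
            "y": VariableMeta("y", 1, "continuous"),
        }
        with pytest.raises(ConfigError, match="fully observed"):
            impute(data, meta, MIConfig(m=2, seed=0), predictors_only=["x"])


class TestDelta:
    def test_zero_delta_equals_plain_imputation(self):
        data, meta, *_ = mcar_frame()
        cfg = MIConfig(m=4, n_iterations=2, seed=8, methods=NORM)
        dc = DeltaConfig(target_variable="y")
        plain = impute(data, meta, cfg)
        adj = delta_adjust(data, meta, cfg, 0.0, dc)
        for a, b in zip(plain, adj):
            pd.testing.assert_frame_equal(a, b)

    def test_shift_scales_with_missing_fraction(self):
        data, meta, _, miss = mcar_frame(seed=2)
        cfg = MIConfig(m=10, n_iterations=2, seed=2, methods=NORM)
        dc = DeltaConfig(target_variable="y")
        base = pooled_mean(impute(data, meta, cfg), "y").point
        shifted = pooled_mean(delta_adjust(data, meta, cfg, 1.0, dc), "y").point
        assert shifted - base == pytest.approx(miss.mean(), abs=1e-9)

    def test_stratified_shifts_are_independent(self):
        rng = np.random.default_rng(4)
        n = 1000
        sex = (rng.random(n) < 0.5).astype(float)
        y = rng.standard_normal(n)
        miss = rng.random(n) < 0.5
        yobs = y.copy()
        yobs[miss] = np.nan
        data = pd.DataFrame({"sex": sex, "y": yobs})
        meta = {
            "sex": VariableMeta("sex", 1, "binary"),
            "y": VariableMeta("y", 1, "continuous"),
        }
        cfg = MIConfig(m=6, n_iterations=2, seed=4, methods=NORM)
        dc = DeltaConfig(target_variable="y", stratified=True,
                         stratum_variable="sex")
        base = impute(data, meta, cfg)
        adj = delta_adjust(data, meta, cfg, {1.0: 2.0, 0.0: 0.0}, dc)
        for b, a in zip(base, adj):
            m_men = (data["sex"] == 0.0)
            assert a.loc[m_men, "y"].mean() == pytest.approx(
                b.loc[m_men, "y"].mean()
            )
            assert a.loc[~m_men, "y"].mean() > b.loc[~m_men, "y"].mean()

    def test_pooled_mean_monotone_in_delta(self):
        data, meta, *_ = mcar_frame(seed=6)
        cfg = MIConfig(m=4, n_iterations=2, seed=6, methods=NORM)
        dc = DeltaConfig(target_variable="y")
        means = [
            pooled_mean(delta_adjust(data, meta, cfg, d, dc), "y").point
            for d in (-1.0, -0.5, 0.0, 0.5, 1.0)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_no_missing_target_warns_noop(self):
        data = pd.DataFrame({"x": [1.0, np.nan, 2.0], "y": [0.1, 0.2, 0.3]})
        meta = {
            "x": VariableMeta("x", 1, "continuous"),
            "y": VariableMeta("y", 1, "continuous"),
        }
        cfg = MIConfig(m=2, n_iterations=1, seed=0, methods=NORM)
        with pytest.warns(RuntimeWarning, match="no-op"):
            delta_adjust(data, meta, cfg, 1.0, DeltaConfig(target_variable="y"))


class TestCalibration:
    def test_self_benchmark_gives_zero_delta(self):
        data, meta, *_ = mcar_frame(seed=9)
        cfg = MIConfig(m=6, n_iterations=2, seed=9, methods=NORM)
        base = pooled_mean(impute(data, meta, cfg), "y").point
        res = calibrate_delta(
            data, meta, cfg,
            DeltaConfig(target_variable="y", benchmark=base, bracket=(-4, 4)),
        )
        assert abs(res["delta"]) < 0.01

    def test_unreachable_benchmark_reports_range(self):
        data, meta, *_ = mcar_frame(seed=10)
        cfg = MIConfig(m=4, n_iterations=2, seed=10, methods=NORM)
        with pytest.raises(ConvergenceError, match="attainable"):
            calibrate_delta(
                data, meta, cfg,
                DeltaConfig(target_variable="y", benchmark=50.0,
                            bracket=(-1, 1)),
            )
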