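import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emascan import (
    DegenerateFitError,
    EmaObservation,
    LocalStatConfig,
    UndefinedStatisticError,
    ValidationError,
    WindowSpec,
    compute_local_stat,
    detrend,
    extract_window,
    feature_table,
    moment,
)
from conftest import make_series


def _obs(prompt, subject="s1"):
    return EmaObservation(
        subject_id=subject, day_index=1, prompt_time=pd.Timestamp(prompt), affect=0.0
    )


class TestExtractWindow:
    def test_minus60_size10_covers_minus60_to_minus50(self, day_series):
        values, wear = extract_window(
            day_series, "2024-01-01 12:00", WindowSpec(location=-60, size=10)
        )
        # prompt at epoch 720; window = epochs 660..669 (11:00 .. 11:09)
        np.testing.assert_array_equal(values, np.arange(660, 670))
        assert wear.all()

    def test_location0_size60_starts_at_prompt(self, day_series):
        values, _ = extract_window(
            day_series, "2024-01-01 12:00", WindowSpec(location=0, size=60)
        )
        assert len(values) == 60
        np.testing.assert_array_equal(values, np.arange(720, 780))

    def test_window_before_recording_is_all_missing(self, day_series):
        values, wear = extract_window(
            day_series, "2024-01-01 00:30", WindowSpec(location=-120, size=60)
        )
        assert np.isnan(values).all() and not wear.any()

    @pytest.mark.parametrize("loc,size", [(-60, 10), (0, 120), (30, 45)])
    def test_exact_epoch_count(self, day_series, loc, size):
        values, wear = extract_window(
            day_series, "2024-01-01 12:00", WindowSpec(location=loc, size=size)
        )
        assert len(values) == len(wear) == size  # 1-min epochs

    def test_mid_epoch_prompt_floor_aligned(self, day_series):
        a, _ = extract_window(
            day_series, "2024-01-01 12:00:45", WindowSpec(location=-10, size=5)
        )
        b, _ = extract_window(
            day_series, "2024-01-01 12:00:00", WindowSpec(location=-10, size=5)
        )
        np.testing.assert_array_equal(a, b)


class TestDetrend:
    def test_exact_linear_gives_zero_residuals(self):
        y = 3.0 * np.arange(20) + 7.0
        np.testing.assert_allclose(detrend(y, 1), 0, atol=1e-9)

    def test_order0_is_demean(self):
        y = np.array([1.0, 5.0, 6.0])
        np.testing.assert_allclose(detrend(y, 0), y - y.mean(), atol=1e-12)

    def test_exact_quadratic_matches_lstsq_oracle(self):
        # independent oracle: Vandermonde least squares
        y = np.arange(10.0) ** 2
        x = np.arange(10.0)
        V = np.vander(x, 3, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        np.testing.assert_allclose(detrend(y, 2), y - V @ coef, atol=1e-9)
        np.testing.assert_allclose(detrend(y, 2), 0, atol=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(DegenerateFitError):
            detrend([1.0, 2.0], 2)

    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=40),
        st.integers(0, 3),
    )
    @settings(deadline=None, max_examples=100)
    def test_residuals_orthogonal_to_basis(self, values, order):
        y = np.asarray(values)
        r = detrend(y, order)
        x = np.arange(len(y), dtype=float)
        scale = max(1.0, np.abs(y).max())
        for d in range(order + 1):
            basis = x**d
            assert abs(np.dot(r, basis)) < 1e-6 * scale * np.linalg.norm(basis) * len(y)


def _g1_oracle(x):
    """Adjusted Fisher-Pearson skewness by direct formula evaluation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = np.std(x, ddof=1)
    return n / ((n - 1) * (n - 2)) * np.sum(((x - x.mean()) / s) ** 3)


def _g2_oracle(x):
    """Bias-adjusted excess kurtosis by direct formula evaluation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m2 = np.mean((x - x.mean()) ** 2)
    m4 = np.mean((x - x.mean()) ** 4)
    g2 = m4 / m2**2 - 3.0
    return ((n - 1) / ((n - 2) * (n - 3))) * ((n + 1) * g2 + 6.0)


class TestMoment:
    def test_mean_of_123(self):
        assert moment([1, 2, 3], "mean") == pytest.approx(2.0)

    def test_sd_uses_n_minus_1(self):
        assert moment([1.0, 3.0], "sd") == pytest.approx(np.sqrt(2.0))

    def test_symmetric_sample_has_zero_skewness(self):
        assert moment([-3, -1, 0, 1, 3], "skewness") == pytest.approx(0.0, abs=1e-9)

    def test_skewness_matches_formula_oracle_on_spike(self):
        x = [0, 0, 0, 0, 10]
        assert moment(x, "skewness") == pytest.approx(_g1_oracle(x), abs=1e-12)

    def test_moments_match_oracles_on_random_vectors(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            n = rng.integers(4, 51)
            x = rng.gamma(1.0, 10.0, size=n)
            assert moment(x, "skewness") == pytest.approx(_g1_oracle(x), rel=1e-9)
            assert moment(x, "kurtosis") == pytest.approx(_g2_oracle(x), rel=1e-9)

    @pytest.mark.parametrize(
        "stat,n", [("mean", 0), ("sd", 1), ("skewness", 2), ("kurtosis", 3)]
    )
    def test_insufficient_n_raises(self, stat, n):
        with pytest.raises(UndefinedStatisticError):
            moment(np.arange(n, dtype=float), stat)

    def test_zero_variance_skewness_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            moment([2.0, 2.0, 2.0, 2.0], "skewness")

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValidationError):
            moment([1.0, 2.0], "entropy")

    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=30).filter(
            lambda v: np.std(v, ddof=1) > 1e-2
        ),
        st.floats(0.1, 10),
        st.floats(-20, 20),
    )
    @settings(deadline=None, max_examples=100)
    def test_skewness_affine_invariance(self, values, a, b):
        base = moment(values, "skewness")
        assert moment(a * np.asarray(values) + b, "skewness") == pytest.approx(
            base, abs=1e-6
        )
        assert moment(-np.asarray(values), "skewness") == pytest.approx(
            -base, abs=1e-6
        )


class TestComputeLocalStat:
    def test_constant_window_mean(self):
        series = make_series(np.full(200, 7.0), start="2024-01-01 00:00")
        v = compute_local_stat(
            series, _obs("2024-01-01 02:00"), WindowSpec(-60, 60), LocalStatConfig()
        )
        assert v.value == pytest.approx(7.0)
        assert v.n_epochs_used == 60

    def test_coverage_rule_yields_missing(self):
        wear = np.ones(200, dtype=bool)
        wear[60:90] = False  # 50% of the window below
        series = make_series(np.full(200, 7.0), wear=wear)
        v = compute_local_stat(
            series, _obs("2024-01-01 02:00"), WindowSpec(-60, 60),
            LocalStatConfig(min_coverage=0.8),
        )
        assert v.is_missing
        assert v.n_epochs_used == 30

    def test_detrended_linear_window_degenerates(self):
        series = make_series(np.arange(200.0))
        cfg = LocalStatConfig(statistic="sd", detrend_order=1)
        v = compute_local_stat(
            series, _obs("2024-01-01 02:00"), WindowSpec(-60, 60), cfg
        )
        assert v.value == pytest.approx(0.0, abs=1e-9)
        cfg2 = LocalStatConfig(statistic="skewness", detrend_order=1)
        v2 = compute_local_stat(
            series, _obs("2024-01-01 02:00"), WindowSpec(-60, 60), cfg2
        )
        assert v2.is_missing  # zero variance after detrending

    def test_mean_invariant_to_detrend_none_path(self):
        rng = np.random.default_rng(5)
        series = make_series(rng.gamma(1, 10, size=300))
        spec = WindowSpec(-30, 30)
        a = compute_local_stat(
            series, _obs("2024-01-01 03:00"), spec, LocalStatConfig(statistic="mean")
        )
        b = compute_local_stat(
            series, _obs("2024-01-01 03:00"), spec,
            LocalStatConfig(statistic="mean", detrend_order=None),
        )
        assert a.value == pytest.approx(b.value)

    def test_day_scope_detrending_runs(self):
        rng = np.random.default_rng(6)
        series = make_series(rng.gamma(1, 10, size=1440))
        cfg = LocalStatConfig(statistic="skewness", detrend_order=2,
                              detrend_scope="day")
        v = compute_local_stat(
            series, _obs("2024-01-01 12:00"), WindowSpec(-60, 120), cfg
        )
        assert np.isfinite(v.value)

    def test_symmetric_distribution_mean_skewness_near_zero(self):
        # stochastic: windows of symmetric noise should average to skewness ~ 0
        rng = np.random.default_rng(7)
        vals = []
        series = make_series(rng.normal(100, 10, size=5000).clip(0))
        cfg = LocalStatConfig(statistic="skewness")
        for k in range(60):
            v = compute_local_stat(
                series, _obs(pd.Timestamp("2024-01-01") + pd.Timedelta(minutes=120 + 60 * k)),
                WindowSpec(-60, 60), cfg,
            )
            vals.append(v.value)
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_feature_table_shape(self, small_study):
        windows = [WindowSpec(-60, 60), WindowSpec(0, 30)]
        tbl = feature_table(
            small_study.activity, small_study.ema[:10], windows, LocalStatConfig()
        )
        assert len(tbl) == 20
        assert set(tbl["size"]) == {60, 30}
        assert tbl["value"].notna().any()
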