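import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emergence_pitch import (
    EmergenceConfig,
    MacroMicroSeries,
    concat_psi,
    gaussian_mutual_information,
    psi_statistic,
    sliding_window_psi,
)
from emergence_pitch.emergence import FLAG_DEGENERATE, FLAG_MASKED, EmergenceError


def correlated_pair(rng, n, r):
    """Scalar samples with sample correlation exactly r (under 1/n covariances)."""
    x = rng.standard_normal(n)
    x -= x.mean()
    x /= np.sqrt((x**2).mean())
    y = rng.standard_normal(n)
    y -= y.mean()
    y -= x * (x @ y) / (x @ x)
    y /= np.sqrt((y**2).mean())
    return x, r * x + np.sqrt(1 - r**2) * y


class TestGaussianMI:
    @pytest.mark.parametrize("r", [0.0, 0.3, 0.6, 0.9])
    def test_closed_form_bivariate(self, rng, r):
        x, y = correlated_pair(rng, 400, r)
        assert gaussian_mutual_information(x, y) == pytest.approx(
            -0.5 * np.log(1 - r**2), abs=1e-9
        )

    def test_duplicated_target_returns_infinity(self, rng):
        x = rng.standard_normal(100)
        assert np.isinf(gaussian_mutual_information(x, x))

    def test_orthogonalized_independence(self, rng):
        x, y = correlated_pair(rng, 200, 0.0)
        assert gaussian_mutual_information(x, y) == pytest.approx(0.0, abs=1e-10)

    def test_bits_conversion(self, rng):
        x, y = correlated_pair(rng, 300, 0.6)
        nats = gaussian_mutual_information(x, y, units="nats")
        bits = gaussian_mutual_information(x, y, units="bits")
        assert bits == pytest.approx(nats / np.log(2), rel=1e-12)

    def test_sample_count_guard(self, rng):
        X = rng.standard_normal((5, 2))
        Y = rng.standard_normal((5, 2))
        with pytest.raises(EmergenceError, match="n >= p \\+ q \\+ 2"):
            gaussian_mutual_information(X, Y)

    def test_non_finite_rejected(self, rng):
        x = rng.standard_normal(50)
        y = x.copy() + rng.standard_normal(50)
        y[3] = np.nan
        with pytest.raises(EmergenceError, match="finite"):
            gaussian_mutual_information(x, y)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((80, 2))
        Y = X @ rng.normal(size=(2, 2)) + 0.5 * rng.standard_normal((80, 2))
        assert gaussian_mutual_information(X, Y) == pytest.approx(
            gaussian_mutual_information(Y, X), abs=1e-10
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((120, 2))
        Y = X @ rng.normal(size=(2, 1)) + 0.7 * rng.standard_normal((120, 1))
        base = gaussian_mutual_information(X, Y)
        A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        mapped = gaussian_mutual_information(X @ A + 3.0, 2.5 * Y - 1.0)
        assert mapped == pytest.approx(base, abs=1e-6)

    def test_never_negative(self, rng):
        for _ in range(20):
            X = rng.standard_normal((30, 3))
            Y = rng.standard_normal((30, 2))
            assert gaussian_mutual_information(X, Y) >= 0.0


class TestPsiStatistic:
    def test_redundant_copies_give_one_minus_n_scaling(self, rng):
        n, N = 800, 10
        v, vp = correlated_pair(rng, n, 0.7)
        micro = np.repeat(v[:, None, None], N, axis=1)
        micro += 1e-6 * rng.standard_normal(micro.shape)
        psi, macro_mi, _ = psi_statistic(v, vp, micro)
        assert psi == pytest.approx((1 - N) * macro_mi, rel=1e-3)

    def test_uninformative_micro_leaves_macro_mi(self, rng):
        n = 400
        v, vp = correlated_pair(rng, n, 0.6)
        # orthogonalize each micro against the future macro
        micro = rng.standard_normal((n, 5, 1))
        for i in range(5):
            m = micro[:, i, 0]
            m -= m.mean()
            micro[:, i, 0] = m - vp * (vp @ m) / (vp @ vp)
        psi, macro_mi, micro_sum = psi_statistic(v, vp, micro)
        assert micro_sum == pytest.approx(0.0, abs=1e-8)
        assert psi == pytest.approx(macro_mi, abs=1e-8)

    def test_white_macro_gives_nonpositive_psi(self, rng):
        n = 500
        v, vp = correlated_pair(rng, n, 0.0)
        micro = 0.5 * np.repeat(vp[:, None, None], 3, axis=1) + 0.1 * rng.standard_normal(
            (n, 3, 1)
        )
        psi, macro_mi, micro_sum = psi_statistic(v, vp, micro)
        assert macro_mi == pytest.approx(0.0, abs=1e-9)
        assert psi <= 1e-9

    def test_mismatched_sample_counts(self, rng):
        with pytest.raises(EmergenceError):
            psi_statistic(rng.standard_normal(50), rng.standard_normal(49),
                          rng.standard_normal((50, 2, 1)))


def make_series(rng, T, n_players=4, valid=None):
    micro = rng.standard_normal((T, n_players, 2)).cumsum(axis=0) * 0.3
    micro -= micro.mean(axis=1, keepdims=True)
    macro_core = rng.standard_normal((T, 2)).cumsum(axis=0)
    micro += macro_core[:, None, :]
    return MacroMicroSeries(
        feature_name="com",
        team="home",
        times=np.arange(1.0, T + 1.0),
        macro=micro.mean(axis=1),
        micro=micro,
        valid=np.ones(T, bool) if valid is None else valid,
    )


class TestSlidingWindows:
    def test_window_and_pair_counting(self, rng):
        series = make_series(rng, 120)
        ps = sliding_window_psi(series, EmergenceConfig(window_s=60, step_s=1, lag_s=1))
        assert len(ps.times) == 61
        assert ps.times[0] == 60.0 and ps.times[-1] == 120.0
        assert ps.n_pairs == 59

    def test_non_overlapping_step(self, rng):
        series = make_series(rng, 120)
        ps = sliding_window_psi(series, EmergenceConfig(window_s=60, step_s=60))
        assert len(ps.times) == 2

    def test_short_series_rejected(self, rng):
        with pytest.raises(EmergenceError, match="shorter"):
            sliding_window_psi(make_series(rng, 30), EmergenceConfig(window_s=60))

    def test_constant_macro_flagged_degenerate(self):
        T = 80
        micro = np.zeros((T, 3, 2))
        series = MacroMicroSeries(
            "com", "home", np.arange(float(T)), micro.mean(axis=1), micro, np.ones(T, bool)
        )
        ps = sliding_window_psi(series, EmergenceConfig(window_s=60))
        assert (ps.flags == FLAG_DEGENERATE).all()
        assert np.isnan(ps.psi).all()

    def test_masked_frames_flag_their_windows(self, rng):
        valid = np.ones(130, bool)
        valid[70] = False
        ps = sliding_window_psi(
            make_series(rng, 130, valid=valid), EmergenceConfig(window_s=60)
        )
        # windows whose span [e-59, e] includes t=71 (1-based times)
        hit = (ps.times >= 71) & (ps.times <= 130) & (ps.times - 59 <= 71)
        assert (ps.flags[hit] == FLAG_MASKED).all()
        assert (ps.flags[~hit] == "").all()

    def test_decomposition_identity(self, rng):
        ps = sliding_window_psi(make_series(rng, 200), EmergenceConfig())
        ok = ps.valid
        np.testing.assert_array_equal(ps.psi[ok], ps.macro_mi[ok] - ps.micro_mi_sum[ok])

    def test_windows_agree_with_direct_estimator(self, rng):
        """Prefix-sum window covariances must reproduce the direct MI path."""
        series = make_series(rng, 90, n_players=3)
        cfg = EmergenceConfig(window_s=60, step_s=13, lag_s=1)
        ps = sliding_window_psi(series, cfg)
        for w, end_t in enumerate(ps.times):
            e = int(end_t) - 1  # times are 1-based here
            t_idx = np.arange(e - 59, e)  # pairs (t, t+1), 59 of them
            macro_mi = gaussian_mutual_information(
                series.macro[t_idx], series.macro[t_idx + 1], cfg
            )
            micro_sum = sum(
                gaussian_mutual_information(series.micro[t_idx, i, :], series.macro[t_idx + 1], cfg)
                for i in range(3)
            )
            assert ps.macro_mi[w] == pytest.approx(macro_mi, abs=1e-8)
            assert ps.psi[w] == pytest.approx(macro_mi - micro_sum, abs=1e-8)

    def test_concat(self, rng):
        a = sliding_window_psi(make_series(rng, 80), EmergenceConfig())
        b = sliding_window_psi(make_series(rng, 70), EmergenceConfig())
        c = concat_psi([a, b])
        assert len(c.times) == len(a.times) + len(b.times)


class TestConfig:
    def test_invalid_configs(self):
        with pytest.raises(EmergenceError):
            EmergenceConfig(window_s=1, lag_s=1)
        with pytest.raises(EmergenceError):
            EmergenceConfig(step_s=0)
        with pytest.raises(EmergenceError):
            EmergenceConfig(mi_units="dits")
        with pytest.raises(EmergenceError):
            EmergenceConfig(order_l=2)
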