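"""Feature-extraction tests with independent oracles for the nonlinear
machinery (mutual information, false nearest neighbours, Lyapunov exponent).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazedyn import features, simdata
from gazedyn.exceptions import (DegenerateInputError, EmbeddingError,
                                TruncationError)
from gazedyn.features import (EmbeddingParams, LleConfig, Segment,
                              ami_lag, dft_features, differentiate,
                              estimate_lle, extract_analysis_window, fnn_dim,
                              kinematic_features, segment_features,
                              takens_embed)


def logistic_orbit(n, x0=0.3, r=4.0):
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x


def make_segment(x=None, y=None):
    if x is None:
        x = np.zeros(features.SEGMENT_LEN)
    if y is None:
        y = np.zeros(features.SEGMENT_LEN)
    return Segment(x=x, y=y, dt=0.001)


class TestAnalysisWindow:
    def test_partition_of_first_thousand_samples(self, stimulus):
        prof = simdata.draw_profile(1, 3)
        rec = simdata.simulate_session(prof, stimulus, 1, seed=4)
        segs = extract_analysis_window(rec, 0)
        assert len(segs) == 10
        rebuilt = np.concatenate([s.x for s in segs])
        assert np.array_equal(rebuilt, rec.horizontal[:1000])

    def test_truncation_error_near_end(self, stimulus):
        prof = simdata.draw_profile(1, 3)
        rec = simdata.simulate_session(prof, stimulus, 1, seed=4)
        with pytest.raises(TruncationError):
            extract_analysis_window(rec, rec.n_samples - 500)


class TestDifferentiate:
    @pytest.mark.parametrize("series,expected", [
        (0.1 * np.arange(100), np.full(99, 100.0)),         # linear ramp
        (np.zeros(50), np.zeros(49)),                        # stillness
        (np.array([0.0, 1.0, 3.0]), np.array([1000.0, 2000.0])),
    ])
    def test_forward_difference(self, series, expected):
        np.testing.assert_allclose(differentiate(series, 0.001), expected)

    def test_too_short(self):
        with pytest.raises(DegenerateInputError):
            differentiate([1.0], 0.001)


class TestKinematicFeatures:
    def test_pythagorean_constant_velocity(self):
        # vx = 3 deg/s, vy = 4 deg/s -> vr = 5 exactly, all ranges zero
        n = features.SEGMENT_LEN
        seg = make_segment(x=3.0 * np.arange(n) * 0.001,
                           y=4.0 * np.arange(n) * 0.001)
        k = kinematic_features(seg)
        assert len(k) == 16
        vr_max, vr_min, vr_mean, vr_range = k[8:12]
        assert vr_max == pytest.approx(5.0)
        assert vr_min == pytest.approx(5.0)
        assert vr_mean == pytest.approx(5.0)
        assert vr_range == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(k[12:16], 0.0, atol=1e-6)  # ar stats

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=20, deadline=None)
    def test_ranges_are_max_minus_min(self, seed):
        rng = np.random.default_rng(seed)
        seg = make_segment(x=rng.normal(size=100), y=rng.normal(size=100))
        k = kinematic_features(seg)
        for base in (0, 4, 8, 12):
            vmax, vmin, _, vrange = k[base:base + 4]
            assert vrange == pytest.approx(vmax - vmin)
            assert vrange >= 0


class TestDftFeatures:
    def test_dc_only_spectrum(self):
        out = dft_features(np.full(99, 2.0))
        np.testing.assert_allclose(out, [198, 0, 0, 0, 0, 0], atol=1e-9)

    def test_cosine_line_by_direct_summation(self):
        n = 99
        x = np.cos(2 * np.pi * 2 * np.arange(n) / n)
        # oracle: direct summation of the transform definition
        oracle = np.array([np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
                           for k in range(6)]).real
        out = dft_features(x)
        np.testing.assert_allclose(out, oracle, atol=1e-9)
        assert out[2] == pytest.approx(n / 2, rel=1e-9)
        assert np.max(np.abs(np.delete(out, 2))) < 1e-9

    def test_output_length_and_magnitude_mode(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=99)
        assert len(dft_features(v)) == 6
        mag = dft_features(v, mode="magnitude")
        assert np.all(mag >= 0)
        assert mag[0] == pytest.approx(abs(v.sum()))

    @given(st.integers(min_value=0, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=99), rng.normal(size=99)
        a, b = rng.normal(), rng.normal()
        np.testing.assert_allclose(
            dft_features(a * u + b * v),
            a * dft_features(u) + b * dft_features(v), atol=1e-8)

    @given(st.integers(min_value=0, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_parseval_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=99)
        z = np.fft.fft(x)
        assert np.sum(np.abs(x) ** 2) == pytest.approx(
            np.sum(np.abs(z) ** 2) / len(x), rel=1e-9)

    def test_too_short(self):
        with pytest.raises(DegenerateInputError):
            dft_features([1.0, 2.0, 3.0])


def brute_force_ami(series, lag, bins=16):
    """Oracle: plain histogram mutual-information estimate."""
    a, b = series[:-lag], series[lag:]
    edges = np.linspace(series.min(), series.max(), bins + 1)
    mi = 0.0
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    total = joint.sum()
    px = joint.sum(axis=1) / total
    py = joint.sum(axis=0) / total
    for i in range(bins):
        for j in range(bins):
            pij = joint[i, j] / total
            if pij > 0:
                mi += pij * np.log(pij / (px[i] * py[j]))
    return mi


class TestAmiLag:
    def test_sine_quarter_period(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 40)
        tau = ami_lag(x, max_lag=30)
        # the AMI profile of a sampled sine is flat around the quarter-period
        # minimum; the chosen lag must sit inside that trough
        ami = np.array([brute_force_ami(x, k) for k in range(1, 31)])
        trough = np.flatnonzero(ami < ami.min() + 0.01) + 1
        assert tau in trough
        assert 5 <= tau <= 15

    def test_iid_noise_falls_back_to_one(self):
        rng = np.random.default_rng(1)
        assert ami_lag(rng.normal(size=2000), max_lag=30) == 1

    def test_constant_series_error(self):
        with pytest.raises(DegenerateInputError):
            ami_lag(np.ones(500), max_lag=10)

    def test_matches_brute_force_values(self):
        x = logistic_orbit(1500)
        for lag in (1, 3, 7):
            assert features.average_mutual_information(x, lag) == pytest.approx(
                brute_force_ami(x, lag), rel=1e-9)


class TestFnnDim:
    def test_logistic_map_low_dimensional(self):
        assert fnn_dim(logistic_orbit(1000), tau=1, max_m=5) <= 2

    def test_sine_embeds_in_two(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 40)
        assert fnn_dim(x, tau=10, max_m=5) == 2

    def test_monotone_ramp_is_one_dimensional(self):
        assert fnn_dim(np.linspace(0.0, 1.0, 1000), tau=1, max_m=5) == 1

    def test_too_short(self):
        with pytest.raises(EmbeddingError):
            fnn_dim(np.arange(10.0), tau=5, max_m=4)


class TestTakensEmbed:
    def test_row_count_and_content(self):
        x = np.arange(100.0)
        Y = takens_embed(x, m=3, tau=2)
        assert Y.shape == (96, 3)  # M = 100 - (3-1)*2
        np.testing.assert_array_equal(Y[0], [0.0, 2.0, 4.0])
        np.testing.assert_array_equal(Y[-1], [95.0, 97.0, 99.0])

    def test_identity_embedding(self):
        x = np.arange(50.0)
        Y = takens_embed(x, m=1, tau=7)
        assert Y.shape == (50, 1)
        np.testing.assert_array_equal(Y[:, 0], x)

    def test_infeasible(self):
        with pytest.raises(EmbeddingError):
            takens_embed(np.arange(100.0), m=51, tau=2)

    @given(st.integers(min_value=20, max_value=300),
           st.integers(min_value=1, max_value=6),
           st.integers(min_value=1, max_value=8))
    @settings(max_examples=50, deadline=None)
    def test_bookkeeping_law(self, n, m, tau):
        x = np.arange(float(n))
        expected = n - (m - 1) * tau
        if expected < 1:
            with pytest.raises(EmbeddingError):
                takens_embed(x, m, tau)
        else:
            assert takens_embed(x, m, tau).shape == (expected, m)


def oracle_divergence_slope(series, dt, m, tau, n_steps=8):
    """Independent divergence-curve implementation: nearest-neighbour pairs
    (Theiler window = tau), mean log separation, least-squares slope over
    the early steps."""
    n = len(series)
    M = n - (m - 1) * tau
    Y = np.array([[series[i + k * tau] for k in range(m)] for i in range(M)])
    pairs = []
    for i in range(M):
        best, bestd = -1, np.inf
        for j in range(M):
            if abs(i - j) <= tau:
                continue
            d = np.sqrt(np.sum((Y[i] - Y[j]) ** 2))
            if 1e-12 < d < bestd:
                bestd, best = d, j
        if best >= 0:
            pairs.append((i, best))
    curve = []
    for k in range(n_steps + 1):
        logs = [np.log(np.sqrt(np.sum((Y[i + k] - Y[j + k]) ** 2)))
                for i, j in pairs if i + k < M and j + k < M
                and np.sum((Y[i + k] - Y[j + k]) ** 2) > 0]
        curve.append(np.mean(logs))
    ks = np.arange(n_steps + 1) * dt
    return np.polyfit(ks, curve, 1)[0]


class TestEstimateLle:
    CFG = LleConfig(max_tau=5, max_m=4, fit_steps=15)

    def test_logistic_map_matches_analytic_exponent(self):
        """r=4 logistic map: lambda = ln 2, oracle = orbit average of
        ln|f'(x)| = ln|4(1 - 2x)| along the same orbit."""
        x = logistic_orbit(5000, x0=0.3)
        analytic = np.mean(np.log(np.abs(4.0 * (1.0 - 2.0 * x))))
        assert analytic == pytest.approx(np.log(2), abs=0.01)
        res = estimate_lle(x, dt=1.0, config=self.CFG)
        assert res.valid
        assert abs(res.value - analytic) < 0.1

    def test_sine_is_non_chaotic(self):
        x = np.sin(2 * np.pi * np.arange(5000) / 41.3)
        res = estimate_lle(x, dt=1.0, config=self.CFG)
        assert res.valid
        assert res.value <= 0.05

    def test_constant_series_gives_flagged_sentinel(self):
        res = estimate_lle(np.ones(500), dt=1.0, config=self.CFG)
        assert not res.valid
        assert res.value == self.CFG.sentinel
        assert res.curve is None

    def test_agrees_with_independent_oracle(self):
        """Divergence-curve estimate vs a separately coded reference on a
        1000-sample chaotic series."""
        x = logistic_orbit(1000, x0=0.41)
        res = estimate_lle(x, dt=1.0,
                           params=EmbeddingParams(tau=1, m=2), config=self.CFG)
        oracle = oracle_divergence_slope(x, 1.0, m=2, tau=1)
        assert res.valid
        assert abs(res.value - oracle) < 0.15

    def test_divergence_curve_diagnostics(self):
        res = estimate_lle(logistic_orbit(2000), dt=1.0, config=self.CFG)
        curve = res.curve
        assert np.all(np.diff(curve.steps) > 0)
        assert curve.initial_sep > 0
        assert curve.fit_range[0] < curve.fit_range[1] <= curve.steps[-1]
        assert curve.slope == res.value


class TestSegmentFeatures:
    def test_23_values_in_canonical_order(self):
        rng = np.random.default_rng(0)
        seg = make_segment(x=np.cumsum(rng.normal(size=100)) * 0.01,
                           y=np.cumsum(rng.normal(size=100)) * 0.01)
        sf = segment_features(seg)
        assert sf.values.shape == (23,)
        assert sf.vx_range == pytest.approx(sf.vx_max - sf.vx_min)

    def test_constant_position_maps_lle_sentinel(self):
        sf = segment_features(make_segment())
        np.testing.assert_allclose(sf.values[:16], 0.0)  # kinematics
        assert sf.values[16] == 0.0                      # DC of zero velocity
        assert sf.values[22] == 0.0                      # sentinel value
        assert not sf.lle_valid

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(size=100)) * 0.01
        y = np.cumsum(rng.normal(size=100)) * 0.01
        a = segment_features(make_segment(x=x.copy(), y=y.copy()))
        b = segment_features(make_segment(x=x.copy(), y=y.copy()))
        np.testing.assert_array_equal(a.values, b.values)

    def test_features_table_shape(self, stimulus):
        prof = simdata.draw_profile(1, 2)
        rec = simdata.simulate_session(prof, stimulus, 1, seed=8)
        table = features.features_table([rec])
        assert len(table) == 29 * 10
        assert list(table.columns[:4]) == ["subject", "session", "point",
                                           "segment"]
        assert list(table.columns[4:27]) == list(features.FEATURE_NAMES)
        assert not table[list(features.FEATURE_NAMES)].isna().any().any()
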