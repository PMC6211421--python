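"""Delay embedding, ED feature trajectories and normalization."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gaitdyn.errors import EmbeddingError, NormalizationError
from gaitdyn.gait_io import GaitTrial, Group
from gaitdyn.psr import (
    CLIP_LIMIT,
    FEATURE_CHANNELS,
    EmbeddingConfig,
    FeatureTrajectory,
    LagMode,
    build_features,
    embed,
    euclidean_distance_series,
    fit_normalizer,
    select_tau,
)


class TestSelectTau:
    def test_fixed_mode_returns_configured(self):
        assert select_tau([1.0, 2.0, 3.0], LagMode.FIXED, fixed_tau=1) == 1
        assert select_tau([1.0, 2.0, 3.0], LagMode.FIXED, fixed_tau=4) == 4

    def test_sinusoid_quarter_period(self):
        # autocorrelation of a sinusoid is a cosine: first zero at T/4
        t = np.arange(600) / 60.0
        series = np.sin(2 * np.pi * t / 1.0)
        assert select_tau(series, LagMode.AUTOCORR_FIRST_ZERO) == 15

    def test_white_noise_matches_first_crossing_oracle(self):
        """For white noise the selected lag agrees with a brute-force scan
        for the first sign change of the sample autocorrelation (usually the
        very first lag)."""
        for seed in range(8):
            series = np.random.default_rng(seed).normal(size=2000)
            tau = select_tau(series, LagMode.AUTOCORR_FIRST_ZERO)
            c = series - series.mean()
            denom = c @ c
            acf = np.array(
                [(c[:-k] @ c[k:]) / denom for k in range(1, 30)]
            )
            oracle = int(np.flatnonzero(acf <= 0)[0]) + 1  # first crossing lag
            assert max(1, oracle - 1) <= tau <= oracle  # rounding freedom

    def test_anticorrelated_sequence_tau_one(self):
        rng = np.random.default_rng(1)
        series = np.tile([1.0, -1.0], 500) + 0.1 * rng.normal(size=1000)
        assert select_tau(series, LagMode.AUTOCORR_FIRST_ZERO) == 1

    def test_constant_series_rejected(self):
        with pytest.raises(EmbeddingError):
            select_tau(np.ones(100), LagMode.AUTOCORR_FIRST_ZERO)

    def test_no_crossing_rejected(self):
        # frozen series whose sample autocorrelation stays strictly positive
        # at every searched lag (1..K/2): the lag search must fail loudly
        series = np.array(
            [-0.20062859, -0.75578915, 0.02560837, 0.1174565,
             -0.06555739, 0.87891027]
        )
        c = series - series.mean()
        assert all((c[:-k] @ c[k:]) > 0 for k in range(1, 4))  # premise
        with pytest.raises(EmbeddingError, match="fixed"):
            select_tau(series, LagMode.AUTOCORR_FIRST_ZERO)


class TestEmbed:
    def test_basic_rows(self):
        traj = embed([1, 2, 3, 4, 5], EmbeddingConfig(embedding_dim=3, time_lag=1))
        np.testing.assert_array_equal(
            traj.points, [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        )
        assert traj.n_points == 3

    def test_study_length_arithmetic(self):
        series = np.arange(900.0)  # 60 Hz x 15 s
        traj = embed(series, EmbeddingConfig())
        assert traj.n_points == 898

    def test_identity_embedding_d1(self):
        series = np.random.default_rng(0).normal(size=30)
        traj = embed(series, EmbeddingConfig(embedding_dim=1, time_lag=5))
        assert traj.points.shape == (30, 1)
        np.testing.assert_array_equal(traj.points[:, 0], series)

    def test_too_short_series_rejected(self):
        with pytest.raises(EmbeddingError, match="at least"):
            embed([1.0, 2.0], EmbeddingConfig(embedding_dim=3, time_lag=2))

    @given(
        series=arrays(np.float64, st.integers(7, 60),
                      elements=st.floats(-1e6, 1e6)),
        d=st.integers(1, 4),
        tau=st.integers(1, 3),
    )
    @settings(max_examples=60, deadline=None)
    def test_embedding_is_invertible(self, series, d, tau):
        """Column 0 plus the trailing entries of the last row reconstruct
        the input exactly."""
        if series.size <= (d - 1) * tau:
            return
        traj = embed(series, EmbeddingConfig(embedding_dim=d, time_lag=tau))
        m_rows = traj.n_points
        if m_rows < tau:
            # samples in residue classes beyond the rows are never embedded;
            # exact inversion requires M >= tau
            return
        recon = np.empty_like(series)
        recon[:m_rows] = traj.points[:, 0]
        for i in range(m_rows, series.size):
            # sample i appears in column m of row i - m*tau
            m = -(-(i - m_rows + 1) // tau)
            recon[i] = traj.points[i - m * tau, m]
        np.testing.assert_array_equal(recon, series)


class TestEuclideanDistance:
    def test_pythagorean_rows(self):
        traj = embed([3.0, 4.0, 0.0], EmbeddingConfig())
        assert euclidean_distance_series(traj)[0] == pytest.approx(5.0)

    def test_known_values(self):
        cfg = EmbeddingConfig()
        assert euclidean_distance_series(embed([0.0, 0.0, 0.0], cfg))[0] == 0.0
        assert euclidean_distance_series(embed([1.0, 1.0, 1.0], cfg))[0] == (
            pytest.approx(np.sqrt(3.0))
        )

    @given(
        points=arrays(np.float64, (17, 3), elements=st.floats(-1e3, 1e3)),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_bruteforce_oracle_and_symmetries(self, points):
        from gaitdyn.psr import PhaseSpaceTrajectory

        traj = PhaseSpaceTrajectory(points=points, source_channel="x",
                                    embedding_dim=3, time_lag=1)
        ed = euclidean_distance_series(traj)
        oracle = np.array([np.sqrt(sum(v * v for v in row)) for row in points])
        np.testing.assert_allclose(ed, oracle, rtol=1e-12, atol=1e-12)
        # permutation and sign-flip invariance of the norm
        flipped = PhaseSpaceTrajectory(points=-points[:, ::-1],
                                       source_channel="x",
                                       embedding_dim=3, time_lag=1)
        np.testing.assert_allclose(euclidean_distance_series(flipped), ed,
                                   rtol=1e-12, atol=1e-12)

    def test_circle_limit_constant_ed(self):
        """A sinusoid embedded in 2-D at quarter-period lag traces a circle:
        constant distance from the origin."""
        t = np.arange(0, 10, 1 / 60)
        series = np.sin(2 * np.pi * t)  # period 1 s -> quarter period 15
        traj = embed(series, EmbeddingConfig(embedding_dim=2, time_lag=15))
        ed = euclidean_distance_series(traj)
        np.testing.assert_allclose(ed, 1.0, atol=5e-3)


class TestBuildFeatures:
    def _trial(self, channels):
        return GaitTrial(subject_id="t", group=Group.ACL_I, channels=channels)

    def test_zero_channels_give_zero_features(self):
        channels = {c: np.zeros(100) for c in
                    ("VV", "IE", "FE", "AP", "PD", "ML")}
        feat = build_features(self._trial(channels), EmbeddingConfig())
        assert np.all(feat.states == 0.0)

    def test_dimension_arithmetic(self, small_cohort):
        feat = build_features(small_cohort.trials[0], EmbeddingConfig())
        assert feat.states.shape == (898, 4)

    def test_fe_scaling_scales_only_fe_column(self, valid_channels):
        feat0 = build_features(self._trial(valid_channels), EmbeddingConfig())
        doubled = dict(valid_channels)
        doubled["FE"] = 2.0 * valid_channels["FE"]
        feat2 = build_features(self._trial(doubled), EmbeddingConfig())
        fe_col = FEATURE_CHANNELS.index("FE")
        for j in range(4):
            factor = 2.0 if j == fe_col else 1.0
            np.testing.assert_allclose(feat2.states[:, j],
                                       factor * feat0.states[:, j])

    def test_vv_ml_never_used(self, valid_channels):
        feat0 = build_features(self._trial(valid_channels), EmbeddingConfig())
        changed = dict(valid_channels)
        changed["VV"] = changed["VV"] + 100.0
        changed["ML"] = -changed["ML"]
        feat1 = build_features(self._trial(changed), EmbeddingConfig())
        np.testing.assert_array_equal(feat0.states, feat1.states)


class TestNormalizer:
    def _feat(self, states):
        return FeatureTrajectory(states=np.asarray(states, float),
                                 sampling_rate_hz=60.0)

    def test_affine_endpoints(self):
        states = np.column_stack([np.linspace(0, 10, 11)] * 4)
        norm = fit_normalizer([self._feat(states)])
        out = norm.transform(states)
        assert out[0, 0] == pytest.approx(-1.0)
        assert out[-1, 0] == pytest.approx(1.0)
        assert norm.scale[0] == pytest.approx(0.2)
        assert norm.offset[0] == pytest.approx(-1.0)

    def test_training_data_lands_in_unit_interval(self, small_features):
        feats, _ = small_features
        for f in feats:
            assert f.states.min() >= -1.0 - 1e-12
            assert f.states.max() <= 1.0 + 1e-12

    def test_test_values_clipped_with_warning(self, caplog):
        states = np.column_stack([np.linspace(0, 10, 11)] * 4)
        norm = fit_normalizer([self._feat(states)])
        with caplog.at_level(logging.WARNING, logger="gaitdyn.psr"):
            out = norm.transform(np.full((1, 4), 12.0))
        assert out[0, 0] == pytest.approx(CLIP_LIMIT)
        assert any("clip" in r.message for r in caplog.records)

    def test_zero_range_column_rejected(self):
        states = np.column_stack(
            [np.linspace(0, 1, 5)] * 3 + [np.full(5, 2.0)]
        )
        with pytest.raises(NormalizationError, match="PD"):
            fit_normalizer([self._feat(states)])

    def test_empty_training_set_rejected(self):
        with pytest.raises(NormalizationError):
            fit_normalizer([])
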