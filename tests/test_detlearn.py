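"""RBF lattice, dynamical identifier and constant-weight extraction."""

import dataclasses

import numpy as np
import pytest

from gaitdyn.detlearn import (
    ACTIVATION_CUTOFF,
    LearnedPattern,
    TrainingConfig,
    _euler_numpy,
    build_lattice,
    predict_dynamics,
    rbf_activations,
    train_pattern,
)
from gaitdyn.errors import ConfigError
from gaitdyn.psr import FeatureTrajectory


def circle_trajectory(rate=240.0, period=1.08, radius=1.0, n_cycles=1):
    """Circular limit cycle with analytic derivative (-w x2, w x1)."""
    omega = 2 * np.pi / period
    t = np.arange(int(round(rate * period * n_cycles))) / rate
    x = radius * np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    phi = omega * np.column_stack([-x[:, 1], x[:, 0]])
    return FeatureTrajectory(states=x, sampling_rate_hz=rate, subject_id="toy"), phi


TOY_CONFIG = TrainingConfig(gamma=15.0, sigma=1e-4, epochs=300)


@pytest.fixture(scope="module")
def toy_pattern():
    feat, _ = circle_trajectory()
    lattice = build_lattice(nodes_per_dim=21, span=(-1.2, 1.2), state_dim=2,
                            width=1.5 * (2.4 / 20))
    return train_pattern(feat, lattice, TOY_CONFIG)


class TestLattice:
    def test_study_default_node_count(self):
        lattice = build_lattice()  # 17 per dim, 4 dims
        assert lattice.n_nodes == 83521
        assert lattice.spacing == pytest.approx(0.15)
        assert lattice.width == pytest.approx(0.15)

    def test_two_node_lattice_is_endpoints(self):
        lattice = build_lattice(nodes_per_dim=2, span=(0.0, 1.0), state_dim=1)
        np.testing.assert_array_equal(np.sort(lattice.centers[:, 0]), [0.0, 1.0])

    def test_node_cap_enforced(self):
        with pytest.raises(ConfigError, match="cap"):
            build_lattice(nodes_per_dim=50, state_dim=4, max_nodes=10_000)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            build_lattice(nodes_per_dim=1)
        with pytest.raises(ConfigError):
            build_lattice(span=(1.0, -1.0))


class TestActivations:
    def test_unit_at_own_center(self):
        lattice = build_lattice(nodes_per_dim=3, state_dim=2)
        s = rbf_activations(lattice, lattice.centers[4])
        assert s[4] == pytest.approx(1.0)

    def test_exp_minus_one_at_width_distance(self):
        lattice = build_lattice(nodes_per_dim=3, span=(-1.0, 1.0),
                                state_dim=1, width=0.5)
        z = lattice.centers[0] + np.array([0.5])
        s = rbf_activations(lattice, z)
        assert s[0] == pytest.approx(np.exp(-1.0))

    def test_range_and_cutoff(self):
        lattice = build_lattice(nodes_per_dim=9, state_dim=2, width=0.1)
        rng = np.random.default_rng(4)
        for _ in range(5):
            s = rbf_activations(lattice, rng.uniform(-1.2, 1.2, 2))
            assert np.all((s >= 0.0) & (s <= 1.0))
            assert np.all((s == 0.0) | (s >= ACTIVATION_CUTOFF))


class TestTraining:
    def test_constant_input_prediction_near_zero(self):
        """For x(t) = const the true dynamics are zero; leakage keeps the
        learned prediction near zero."""
        x0 = np.array([0.3, -0.2])
        feat = FeatureTrajectory(states=np.tile(x0, (240, 1)),
                                 sampling_rate_hz=60.0)
        lattice = build_lattice(nodes_per_dim=9, state_dim=2, width=0.6)
        pattern = train_pattern(feat, lattice,
                                TrainingConfig(sigma=1e-3, epochs=10))
        pred = predict_dynamics(pattern, x0)
        assert np.linalg.norm(pred) < 1e-3

    def test_limit_cycle_identification_beats_5pct(self, toy_pattern):
        """Along-trajectory relative RMSE of W_bar^T S(x) against the
        analytic derivative of a circular orbit is below 5%."""
        feat, phi = circle_trajectory()
        pred = predict_dynamics(toy_pattern, feat.states)
        rel = np.sqrt(np.mean((pred - phi) ** 2) / np.mean(phi**2))
        assert rel < 0.05

    def test_off_orbit_prediction_near_zero(self, toy_pattern):
        """Localized learning: far from the training orbit the learned field
        stays near zero."""
        feat, phi = circle_trajectory()
        scale = np.sqrt(np.mean(phi**2))
        pred_origin = predict_dynamics(toy_pattern, np.zeros(2))
        assert np.linalg.norm(pred_origin) < 0.05 * scale

    def test_tracking_error_decreases_across_epochs(self, small_features,
                                                    reduced_lattice):
        feats, _ = small_features
        pattern = train_pattern(feats[0], reduced_lattice,
                                TrainingConfig(epochs=12))
        d = pattern.diagnostics
        assert d["final_epoch_rms_error"] < 0.9 * d["first_epoch_rms_error"]

    def test_halving_dt_is_consistent(self):
        """Refining the integration step changes the learned field along the
        orbit by under a few percent (numerical consistency)."""
        feat_c, phi = circle_trajectory(rate=240.0)
        feat_f, _ = circle_trajectory(rate=480.0)
        lattice = build_lattice(nodes_per_dim=21, span=(-1.2, 1.2),
                                state_dim=2, width=1.5 * (2.4 / 20))
        p_c = train_pattern(feat_c, lattice, TOY_CONFIG)
        p_f = train_pattern(feat_f, lattice, TOY_CONFIG)
        pred_c = predict_dynamics(p_c, feat_c.states)
        pred_f = predict_dynamics(p_f, feat_c.states)
        rel = np.sqrt(np.mean((pred_c - pred_f) ** 2) / np.mean(pred_f**2))
        assert rel < 0.01

    def test_numba_and_numpy_paths_agree(self, small_features, reduced_lattice):
        """The accelerated kernel reproduces the pure-numpy reference."""
        import gaitdyn.detlearn as dl

        feats, _ = small_features
        cfg = TrainingConfig(epochs=2)
        p_fast = train_pattern(feats[0], reduced_lattice, cfg)
        have = dl._HAVE_NUMBA
        dl._HAVE_NUMBA = False
        try:
            p_ref = train_pattern(feats[0], reduced_lattice, cfg)
        finally:
            dl._HAVE_NUMBA = have
        np.testing.assert_allclose(p_fast.weights, p_ref.weights,
                                   rtol=1e-9, atol=1e-12)

    def test_unstable_leakage_rejected(self):
        feat = FeatureTrajectory(states=np.zeros((10, 2)), sampling_rate_hz=1.0)
        lattice = build_lattice(nodes_per_dim=3, state_dim=2)
        from gaitdyn.errors import IntegrationError

        with pytest.raises(IntegrationError):
            train_pattern(feat, lattice, TrainingConfig(sigma=10.0, gamma=1.5))


class TestPredict:
    def test_zero_weights_zero_prediction(self, reduced_lattice):
        pattern = LearnedPattern(
            subject_id="z", group=None,
            active_idx=np.arange(10),
            weights=np.zeros((10, 4)),
            lattice=reduced_lattice, normalizer=None,
        )
        rng = np.random.default_rng(0)
        assert np.all(predict_dynamics(pattern, rng.uniform(-1, 1, 4)) == 0.0)

    def test_one_hot_weight_at_own_center(self, reduced_lattice):
        k = 37
        w = np.zeros((1, 4))
        w[0, 2] = 1.0
        pattern = LearnedPattern(
            subject_id="h", group=None, active_idx=np.array([k]),
            weights=w, lattice=reduced_lattice, normalizer=None,
        )
        pred = predict_dynamics(pattern, reduced_lattice.centers[k])
        assert pred[2] == pytest.approx(1.0)
        assert pred[0] == pred[1] == pred[3] == 0.0

    def test_linearity_in_weights(self, toy_pattern):
        feat, _ = circle_trajectory()
        doubled = dataclasses.replace(toy_pattern)
        doubled = LearnedPattern(
            subject_id="2x", group=None, active_idx=toy_pattern.active_idx,
            weights=2.0 * toy_pattern.weights, lattice=toy_pattern.lattice,
            normalizer=None,
        )
        np.testing.assert_allclose(
            predict_dynamics(doubled, feat.states),
            2.0 * predict_dynamics(toy_pattern, feat.states),
            rtol=1e-12,
        )

    def test_dimension_mismatch_rejected(self, toy_pattern):
        with pytest.raises(ConfigError):
            predict_dynamics(toy_pattern, np.zeros(4))
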