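"""Shared fixtures: small synthetic cohorts and reduced lattices.

Everything is generated programmatically and seeded; the reduced lattice
(7 or 9 nodes per dimension instead of the full 17) keeps the suite at desk
scale while exercising the same code paths.
"""

import numpy as np
import pytest

from gaitdyn.config import LatticeConfig, PipelineConfig
from gaitdyn.detlearn import TrainingConfig, build_lattice
from gaitdyn.gait_io import GaitTrial, Group
from gaitdyn.psr import EmbeddingConfig, build_features, fit_normalizer
from gaitdyn.simulate import (
    GroupKinematicParams,
    SimulatorConfig,
    simulate_cohort,
    simulate_trial,
)


def reduced_lattice_config(nodes_per_dim: int = 7) -> LatticeConfig:
    spacing = 2.4 / (nodes_per_dim - 1)
    return LatticeConfig(nodes_per_dim=nodes_per_dim, width=2.0 * spacing)


def reduced_pipeline_config(
    nodes_per_dim: int = 7, epochs: int = 12, seed: int = 0
) -> PipelineConfig:
    import dataclasses

    cfg = PipelineConfig(
        lattice=reduced_lattice_config(nodes_per_dim),
        training=TrainingConfig(epochs=epochs),
    )
    return dataclasses.replace(
        cfg, simulator=dataclasses.replace(cfg.simulator, seed=seed)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size study cohort (18 ACL-D + 28 ACL-I), default settings."""
    return simulate_cohort(SimulatorConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject cohort (5 + 5) for estimator-bank tests."""
    return simulate_cohort(
        SimulatorConfig(
            params_acl_d=GroupKinematicParams.acl_deficient(5),
            params_acl_i=GroupKinematicParams.acl_intact(5),
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Normalized feature trajectories of the 10-subject cohort."""
    feats = [build_features(t, EmbeddingConfig()) for t in small_cohort]
    norm = fit_normalizer(feats)
    return [norm.apply(f) for f in feats], norm


@pytest.fixture(scope="session")
def reduced_lattice():
    cfg = reduced_lattice_config(9)
    return build_lattice(
        nodes_per_dim=cfg.nodes_per_dim, span=cfg.span, width=cfg.width, state_dim=4
    )


@pytest.fixture(scope="session")
def noiseless_trial():
    """Deterministic, jitter- and noise-free trial with exact ROM means."""
    config = SimulatorConfig(seed=3).noiseless()
    params = GroupKinematicParams.acl_intact(1)
    zero_sd = GroupKinematicParams(
        rom_mean=params.rom_mean, rom_sd={c: 0.0 for c in params.rom_sd},
        cycle_period_s=params.cycle_period_s, n_subjects=1,
    )
    rng = np.random.default_rng(3)
    return simulate_trial(zero_sd, config, rng, subject_id="noiseless",
                          group=Group.ACL_I)


@pytest.fixture
def valid_channels():
    rng = np.random.default_rng(0)
    return {c: rng.normal(size=120) for c in
            ("VV", "IE", "FE", "AP", "PD", "ML")}
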