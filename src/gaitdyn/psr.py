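"""Phase-space reconstruction and Euclidean-distance feature trajectories.

A scalar kinematic series ``V`` of length ``K`` is delay-embedded into the
``M x d`` trajectory matrix with rows ``(V_j, V_{j+tau}, ..., V_{j+(d-1)tau})``,
``M = K - (d-1) tau``.  The Euclidean distance (ED) of each embedded point
from the origin is the scalar feature; the four reference channels whose ROM
differs significantly between groups (IE, FE, AP, PD) are embedded with d=3,
tau=1 and stacked into the 4-dimensional feature trajectory
``x = [ED_IE, ED_FE, ED_AP, ED_PD]^T`` that drives the learning stage.

Feature columns are affinely normalized to [-1, 1] using training-set
min/max only, so trajectories live inside the RBF lattice span [-1.2, 1.2]
with a 0.2 margin for test-set overshoot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from gaitdyn.errors import EmbeddingError, NormalizationError
from gaitdyn.gait_io import GaitTrial

logger = logging.getLogger(__name__)

#: Reference channels feeding the feature vector, in fixed column order.
FEATURE_CHANNELS: Tuple[str, ...] = ("IE", "FE", "AP", "PD")

#: Test-time values outside the fitted [-1, 1] range are clipped here — the
#: edge of the default RBF lattice span.
CLIP_LIMIT = 1.2


class LagMode(str, Enum):
    FIXED = "fixed"
    AUTOCORR_FIRST_ZERO = "autocorr_first_zero"


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding settings (study defaults d=3, tau=1)."""

    embedding_dim: int = 3
    time_lag: int = 1
    lag_mode: LagMode = LagMode.FIXED

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise EmbeddingError("embedding_dim must be >= 1")
        if self.time_lag < 1:
            raise EmbeddingError("time_lag must be >= 1")


@dataclass(frozen=True)
class PhaseSpaceTrajectory:
    """Delay-embedding trajectory matrix of one channel."""

    points: np.ndarray  # M x d
    source_channel: str
    embedding_dim: int
    time_lag: int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class FeatureTrajectory:
    """Time-indexed 4-vector feature state driving the learning ODEs."""

    states: np.ndarray  # T x 4, columns FEATURE_CHANNELS order (ED of each)
    sampling_rate_hz: float
    normalization: Optional["FeatureNormalizer"] = None
    subject_id: str = ""
    group: Optional[object] = None  # gait_io.Group when built from a trial

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz


def select_tau(series: Sequence[float], mode: LagMode, fixed_tau: int = 1) -> int:
    """Choose the embedding lag.

    ``fixed`` returns ``fixed_tau``; ``autocorr_first_zero`` returns the first
    zero crossing of the sample autocorrelation (linear-interpolated, rounded,
    minimum 1).
    """
    if mode == LagMode.FIXED:
        if fixed_tau < 1:
            raise EmbeddingError("fixed tau must be >= 1")
        return fixed_tau
    arr = np.asarray(series, dtype=float)
    if arr.size < 3:
        raise EmbeddingError("need at least 3 samples for autocorrelation lag")
    centered = arr - arr.mean()
    denom = float(centered @ centered)
    if denom == 0.0:
        raise EmbeddingError("constant series has no autocorrelation zero crossing")
    max_lag = arr.size // 2
    prev = 1.0
    for lag in range(1, max_lag + 1):
        r = float(centered[:-lag] @ centered[lag:]) / denom
        if r <= 0.0:
            # linear interpolation of the crossing between lag-1 and lag
            frac = prev / (prev - r) if prev != r else 1.0
            return max(1, int(round(lag - 1 + frac)))
        prev = r
    raise EmbeddingError(
        f"autocorrelation has no zero crossing within {max_lag} lags; "
        "use fixed lag mode"
    )


def embed(series: Sequence[float], config: EmbeddingConfig,
          channel: str = "") -> PhaseSpaceTrajectory:
    """Delay-embed a scalar series into its trajectory matrix."""
    arr = np.asarray(series, dtype=float)
    d, tau = config.embedding_dim, config.time_lag
    m = arr.size - (d - 1) * tau
    if m < 1:
        raise EmbeddingError(
            f"series of length {arr.size} too short for d={d}, tau={tau}; "
            f"need at least {(d - 1) * tau + 1} samples"
        )
    idx = np.arange(m)[:, None] + tau * np.arange(d)[None, :]
    return PhaseSpaceTrajectory(
        points=arr[idx], source_channel=channel, embedding_dim=d, time_lag=tau
    )


def euclidean_distance_series(traj: PhaseSpaceTrajectory) -> np.ndarray:
    """Per-point distance from the phase-space origin (row-wise 2-norm)."""
    return np.linalg.norm(traj.points, axis=1)


def build_features(trial: GaitTrial, config: EmbeddingConfig) -> FeatureTrajectory:
    """Embed the four reference channels and stack their ED series.

    Columns are ordered (ED_IE, ED_FE, ED_AP, ED_PD); VV and ML are never
    used.  All columns are truncated to the shortest embedding length.
    """
    eds = []
    for c in FEATURE_CHANNELS:
        traj = embed(trial.channel(c), config, channel=c)
        eds.append(euclidean_distance_series(traj))
    t = min(e.size for e in eds)
    states = np.column_stack([e[:t] for e in eds])
    return FeatureTrajectory(
        states=states,
        sampling_rate_hz=trial.sampling_rate_hz,
        subject_id=trial.subject_id,
        group=trial.group,
    )


@dataclass(frozen=True)
class FeatureNormalizer:
    """Per-column affine map fitted on training data: min/max -> [-1, 1].

    ``transform`` applies the frozen parameters verbatim; test values may
    exceed [-1, 1] slightly and are clipped at +-CLIP_LIMIT (lattice edge)
    with a logged warning.
    """

    scale: np.ndarray  # per column
    offset: np.ndarray  # per column; normalized = scale * x + offset

    def transform(self, states: np.ndarray) -> np.ndarray:
        out = states * self.scale[None, :] + self.offset[None, :]
        over = np.abs(out) > CLIP_LIMIT
        if np.any(over):
            logger.warning(
                "clipping %d normalized feature values to +-%.2f (outside "
                "the fitted training range)",
                int(over.sum()),
                CLIP_LIMIT,
            )
            out = np.clip(out, -CLIP_LIMIT, CLIP_LIMIT)
        return out

    def apply(self, features: FeatureTrajectory) -> FeatureTrajectory:
        return FeatureTrajectory(
            states=self.transform(features.states),
            sampling_rate_hz=features.sampling_rate_hz,
            normalization=self,
            subject_id=features.subject_id,
            group=features.group,
        )

    def key(self) -> bytes:
        """Stable byte key identifying the fitted parameters (for caching)."""
        return self.scale.tobytes() + self.offset.tobytes()

    def to_dict(self) -> dict:
        return {"scale": self.scale.tolist(), "offset": self.offset.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureNormalizer":
        return cls(
            scale=np.asarray(d["scale"], dtype=float),
            offset=np.asarray(d["offset"], dtype=float),
        )


def fit_normalizer(training_features: Iterable[FeatureTrajectory]) -> FeatureNormalizer:
    """Fit per-column min/max over all training trajectories -> [-1, 1]."""
    feats = list(training_features)
    if not feats:
        raise NormalizationError("cannot fit a normalizer on an empty training set")
    stacked = np.vstack([f.states for f in feats])
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    rng = hi - lo
    if np.any(rng <= 0):
        col = int(np.flatnonzero(rng <= 0)[0])
        raise NormalizationError(
            f"feature column {FEATURE_CHANNELS[col]} has zero range; "
            "cannot normalize"
        )
    scale = 2.0 / rng
    offset = -1.0 - lo * scale
    return FeatureNormalizer(scale=scale, offset=offset)
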