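"""Estimator-bank classification by smallest synchronization error.

Each learned pattern ``W_bar^k`` defines a dynamical estimator

    chi_bar' = -B (chi_bar - x) + W_bar^k{}^T S(x)

driven by the test feature trajectory ``x``.  The estimator whose stored
dynamics match the test subject's dynamics synchronizes best, so its state
error ``chi_tilde = chi_bar - x`` stays smallest.  Errors are compared through
the gait-cycle-windowed average L1 norm

    ||chi_tilde_i(t)||_1 = (1/Tc) * integral_{t-Tc}^{t} |chi_tilde_i| dtau

and the test pattern is assigned the group label of the argmin estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from gaitdyn.detlearn import LearnedPattern, activation_matrix, predict_dynamics
from gaitdyn.errors import ConfigError, IntegrationError
from gaitdyn.gait_io import Group
from gaitdyn.psr import FeatureTrajectory

logger = logging.getLogger(__name__)

#: Aggregation of the four per-state error curves into one score.
AGGREGATES = ("mean_states", "min_state")


@dataclass
class EstimatorBank:
    """A bank of frozen estimators, one per training subject.

    ``b`` is the (positive, stable) estimator gain magnitude; the study
    configuration uses 30 per state with Tc = 1.08 s.
    """

    patterns: List[LearnedPattern]
    b: float = 30.0
    tc_s: float = 1.08

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ConfigError("estimator bank must contain at least one pattern")
        if self.b <= 0:
            raise ConfigError("estimator gain b must be positive")
        ref = self.patterns[0]
        for p in self.patterns[1:]:
            if p.lattice.to_dict() != ref.lattice.to_dict():
                raise ConfigError("all patterns in a bank must share the lattice")
            if (p.normalizer is None) != (ref.normalizer is None) or (
                p.normalizer is not None
                and p.normalizer.key() != ref.normalizer.key()
            ):
                raise ConfigError("all patterns in a bank must share the normalizer")

    def __len__(self) -> int:
        return len(self.patterns)


@dataclass
class ClassificationResult:
    """Per-estimator windowed L1 error curves and the smallest-error decision."""

    scores: np.ndarray  # (M,) scalar score per estimator
    error_curves: List[np.ndarray]  # per estimator: (T-w+1, n) L1 curves
    matched_pattern: int
    predicted_group: Optional[Group]
    margin: float
    tc_s: float
    pattern_ids: List[str] = field(default_factory=list)
    pattern_groups: List[Optional[Group]] = field(default_factory=list)


def run_estimator(
    pattern: LearnedPattern,
    features: FeatureTrajectory,
    b: float = 30.0,
    dt: Optional[float] = None,
    prediction: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Integrate one test-error system; returns chi_tilde(t), shape (T, n).

    Explicit Euler with zero-order-hold input, chi_bar(0) = x(0) — the same
    discretization as training.  Requires b * dt < 2 for stability.  The
    recurrence chi_{t+1} = (1 - b dt) chi_t + dt (b x_t + pred_t) is evaluated
    as a linear filter.  ``prediction`` may supply precomputed W_bar^T S(x)
    values along the trajectory (used by :func:`classify_pattern` to share
    activations across a bank).
    """
    x = np.asarray(features.states, dtype=float)
    if dt is None:
        dt = features.dt
    if b <= 0:
        raise ConfigError("estimator gain b must be positive")
    if b * dt >= 2.0:
        raise IntegrationError(
            f"explicit Euler unstable: b*dt = {b * dt:.3f} >= 2; reduce dt or b"
        )
    pred = predict_dynamics(pattern, x) if prediction is None else prediction
    alpha = 1.0 - b * dt
    drive = dt * (b * x + pred)  # (T, n)
    # chi[0] = x[0]; chi[t] = alpha chi[t-1] + drive[t-1]
    z = np.vstack([x[0][None, :], drive[:-1]])
    chi = lfilter([1.0], [1.0, -alpha], z, axis=0)
    chi_tilde = chi - x
    if not np.all(np.isfinite(chi_tilde)):
        raise IntegrationError("estimator state diverged; reduce dt or b")
    return chi_tilde


def l1_error(error_series: np.ndarray, tc_s: float, dt: float) -> np.ndarray:
    """Sliding gait-cycle-window mean of |error| per state.

    Window length w = round(tc_s / dt) samples (65 at the study defaults);
    output row t corresponds to original time index t + w - 1, i.e. the
    windowed norm is defined for t >= Tc.
    """
    err = np.atleast_2d(np.asarray(error_series, dtype=float))
    if err.ndim != 2:
        raise ConfigError("error series must be (T,) or (T, n)")
    w = int(round(tc_s / dt))
    if w < 1:
        raise ConfigError("window shorter than one sample")
    if err.shape[0] < w:
        raise ConfigError(
            f"series of length {err.shape[0]} shorter than the {w}-sample window"
        )
    kernel = np.ones(w) / w
    cols = [np.convolve(np.abs(err[:, i]), kernel, mode="valid") for i in
            range(err.shape[1])]
    return np.column_stack(cols)


def classify_pattern(
    bank: EstimatorBank,
    features: FeatureTrajectory,
    aggregate: str = "mean_states",
) -> ClassificationResult:
    """Run every estimator on a test trajectory and apply the argmin rule.

    score_k = time-average (over t >= Tc) of the state-aggregated windowed L1
    error of estimator k; the matched pattern is the argmin, ties broken by
    lowest index (logged).
    """
    if aggregate not in AGGREGATES:
        raise ConfigError(f"aggregate must be one of {AGGREGATES}")
    dt = features.dt
    x = np.asarray(features.states, dtype=float)
    # activations of the test trajectory are shared by all estimators
    s_test = activation_matrix(bank.patterns[0].lattice, x).tocsc()
    curves: List[np.ndarray] = []
    scores = np.empty(len(bank))
    for k, pattern in enumerate(bank.patterns):
        pred = s_test[:, pattern.active_idx] @ pattern.weights
        pred = np.asarray(pred)
        chi_tilde = run_estimator(pattern, features, b=bank.b, dt=dt,
                                  prediction=pred)
        curve = l1_error(chi_tilde, bank.tc_s, dt)
        curves.append(curve)
        per_state = curve.mean(axis=0)  # time-average per state
        if aggregate == "mean_states":
            scores[k] = float(per_state.mean())
        else:
            scores[k] = float(per_state.min())
    matched = int(np.argmin(scores))
    ties = np.flatnonzero(scores == scores[matched])
    if ties.size > 1:
        logger.info(
            "estimator score tie among indices %s; matched lowest index %d",
            ties.tolist(),
            matched,
        )
    order = np.sort(scores)
    margin = float(order[1] - order[0]) if scores.size > 1 else 0.0
    return ClassificationResult(
        scores=scores,
        error_curves=curves,
        matched_pattern=matched,
        predicted_group=bank.patterns[matched].group,
        margin=margin,
        tc_s=bank.tc_s,
        pattern_ids=[p.subject_id for p in bank.patterns],
        pattern_groups=[p.group for p in bank.patterns],
    )
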