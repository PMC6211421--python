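"""Deterministic-learning identification of gait dynamics with RBF networks.

The unknown gait dynamics ``x' = phi(x)`` along a recurrent feature trajectory
are identified by a dynamical radial-basis-function observer

    x_hat' = -A (x_hat - x) + W_hat^T S(x)
    W_hat_i' = -Gamma_i S(x) x_tilde_i - sigma_i Gamma_i W_hat_i

with Gaussian activations ``s_i(z) = exp(-||z - mu_i||^2 / eta_i^2)`` on a
regular lattice of centers.  Along a periodic (persistently exciting) orbit
the locally active weights converge; their time-average over a window after
the transient, ``W_bar``, stores the dynamics as a constant pattern, and
``W_bar^T S(z)`` reproduces ``phi(z)`` along (and only along) the orbit.

The leakage term ``sigma`` is a small sigma-modification constant for
robustness; it biases the converged weights toward zero, so it must stay well
below the persistent-excitation level (default 1e-3).  Gains, lattice span
and width default to the study configuration (a_i = 0.5, Gamma = 1.5 I,
eta = grid spacing = 0.15 at 17 nodes/dim on [-1.2, 1.2]^4, N = 83521).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

from gaitdyn.errors import ConfigError, IntegrationError
from gaitdyn.gait_io import Group
from gaitdyn.psr import FeatureNormalizer, FeatureTrajectory

logger = logging.getLogger(__name__)

#: Gaussian activations below this are treated as exactly zero (locality
#: cutoff); the induced truncation error is below 1e-8 per node.
ACTIVATION_CUTOFF = 1e-8

#: Refuse to build lattices beyond this many nodes unless overridden.
DEFAULT_MAX_NODES = 5_000_000

try:  # optional acceleration; the numpy path is the reference implementation
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class RBFLattice:
    """Regular Cartesian grid of Gaussian RBF centers."""

    centers: np.ndarray  # N x n
    width: float
    nodes_per_dim: int
    span: Tuple[float, float]
    state_dim: int

    @property
    def n_nodes(self) -> int:
        return self.centers.shape[0]

    @property
    def spacing(self) -> float:
        return (self.span[1] - self.span[0]) / (self.nodes_per_dim - 1)

    def to_dict(self) -> dict:
        return {
            "nodes_per_dim": self.nodes_per_dim,
            "span": list(self.span),
            "width": self.width,
            "state_dim": self.state_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFLattice":
        return build_lattice(
            nodes_per_dim=d["nodes_per_dim"],
            span=tuple(d["span"]),
            width=d["width"],
            state_dim=d["state_dim"],
        )


def build_lattice(
    nodes_per_dim: int = 17,
    span: Tuple[float, float] = (-1.2, 1.2),
    width: Optional[float] = None,
    state_dim: int = 4,
    max_nodes: int = DEFAULT_MAX_NODES,
) -> RBFLattice:
    """Build a regular RBF lattice.

    ``width`` defaults to the grid spacing (0.15 for the 17-node default on
    [-1.2, 1.2], matching the study width eta = 0.15).
    """
    if nodes_per_dim < 2:
        raise ConfigError("nodes_per_dim must be >= 2")
    if state_dim < 1:
        raise ConfigError("state_dim must be >= 1")
    if not span[1] > span[0]:
        raise ConfigError("span must be an increasing interval")
    n_nodes = nodes_per_dim**state_dim
    if n_nodes > max_nodes:
        raise ConfigError(
            f"lattice would have {n_nodes} nodes (> cap {max_nodes}); "
            "reduce nodes_per_dim or raise max_nodes"
        )
    grid = np.linspace(span[0], span[1], nodes_per_dim)
    spacing = (span[1] - span[0]) / (nodes_per_dim - 1)
    if width is None:
        width = spacing
    if width <= 0:
        raise ConfigError("width must be positive")
    mesh = np.meshgrid(*([grid] * state_dim), indexing="ij")
    centers = np.column_stack([m.ravel() for m in mesh])
    return RBFLattice(
        centers=centers,
        width=float(width),
        nodes_per_dim=nodes_per_dim,
        span=(float(span[0]), float(span[1])),
        state_dim=state_dim,
    )


def rbf_activations(lattice: RBFLattice, z: Sequence[float]) -> np.ndarray:
    """Gaussian activation vector S(z); values below the cutoff are zeroed."""
    z = np.asarray(z, dtype=float)
    if z.shape != (lattice.state_dim,):
        raise ConfigError(
            f"state has shape {z.shape}, lattice expects ({lattice.state_dim},)"
        )
    if not np.all(np.isfinite(z)):
        raise ConfigError("state vector must be finite")
    sq = np.sum((lattice.centers - z[None, :]) ** 2, axis=1)
    s = np.exp(-sq / lattice.width**2)
    s[s < ACTIVATION_CUTOFF] = 0.0
    return s


def activation_matrix(
    lattice: RBFLattice, states: np.ndarray, chunk: int = 256
) -> sparse.csr_matrix:
    """Sparse T x N activation matrix along a trajectory (cutoff applied)."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    blocks = []
    for start in range(0, states.shape[0], chunk):
        d2 = cdist(states[start : start + chunk], lattice.centers, "sqeuclidean")
        s = np.exp(-d2 / lattice.width**2)
        s[s < ACTIVATION_CUTOFF] = 0.0
        blocks.append(sparse.csr_matrix(s))
    return sparse.vstack(blocks, format="csr")


@dataclass(frozen=True)
class TrainingConfig:
    """Identifier gains and integration settings.

    ``a``: observer gain per state (study value 0.5). ``gamma``: learning rate
    (study value 1.5). ``sigma``: leakage; kept small (1e-3) so the converged
    weights are not biased away from the dynamics. ``epochs``: passes over
    the (cyclically repeated) trajectory. ``averaging_window_frac``: trailing
    fraction of the training horizon averaged into the constant weights.
    """

    a: float = 0.5
    gamma: float = 1.5
    sigma: float = 1e-3
    dt: Optional[float] = None  # default: feature sampling interval
    epochs: int = 12
    weight_convergence_tol: float = 1e-3
    averaging_window_frac: float = 0.25
    integrator: str = "euler"  # or "rk4"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.gamma <= 0 or self.sigma <= 0:
            raise ConfigError("stability requires a > 0, gamma > 0, sigma > 0")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not (0.0 < self.averaging_window_frac <= 1.0):
            raise ConfigError("averaging_window_frac must be in (0, 1]")
        if self.integrator not in ("euler", "rk4"):
            raise ConfigError("integrator must be 'euler' or 'rk4'")
        if self.dt is not None and self.dt <= 0:
            raise ConfigError("dt must be positive")


@dataclass
class LearnedPattern:
    """Constant weights identifying one training subject's gait dynamics.

    Weights are stored sparsely: ``active_idx`` are lattice node indices that
    were ever excited by the training orbit; all other weights are exactly
    zero (they receive no update and start at zero).
    """

    subject_id: str
    group: Optional[Group]
    active_idx: np.ndarray  # (n_act,)
    weights: np.ndarray  # (n_act, n) -- column i is W_bar_i on active nodes
    lattice: RBFLattice
    normalizer: Optional[FeatureNormalizer]
    diagnostics: Dict[str, float] = field(default_factory=dict)

    @property
    def state_dim(self) -> int:
        return self.weights.shape[1]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group.value if self.group is not None else None,
            "active_idx": self.active_idx.tolist(),
            "weights": self.weights.tolist(),
            "lattice": self.lattice.to_dict(),
            "normalizer": self.normalizer.to_dict() if self.normalizer else None,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LearnedPattern":
        return cls(
            subject_id=d["subject_id"],
            group=Group(d["group"]) if d.get("group") else None,
            active_idx=np.asarray(d["active_idx"], dtype=np.int64),
            weights=np.asarray(d["weights"], dtype=float),
            lattice=RBFLattice.from_dict(d["lattice"]),
            normalizer=(
                FeatureNormalizer.from_dict(d["normalizer"])
                if d.get("normalizer")
                else None
            ),
            diagnostics=dict(d.get("diagnostics", {})),
        )


def save_pattern(pattern: LearnedPattern, path) -> None:
    Path(path).write_text(json.dumps(pattern.to_dict()) + "\n")


def load_pattern(path) -> LearnedPattern:
    return LearnedPattern.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _euler_kernel(
        s_data, s_indices, s_indptr, x, a, gamma, sigma, dt,
        epochs, w, w_sum, window_start, err_per_epoch,
    ):  # pragma: no cover - exercised via train_pattern
        t_len, n = x.shape
        x_hat = x[0].copy()
        decay = 1.0 - dt * sigma * gamma
        step = 0
        count = 0
        for ep in range(epochs):
            acc = 0.0
            for t in range(t_len):
                lo, hi = s_indptr[t], s_indptr[t + 1]
                # semi-implicit (symplectic) ordering: advance the observer
                # state with the old weights, then drive the weight update
                # with the *new* tracking error -- keeps the oscillatory
                # error/weight pair on the stable side of the Euler step.
                for i in range(n):
                    pred = 0.0
                    for p in range(lo, hi):
                        pred += s_data[p] * w[s_indices[p], i]
                    xt = x_hat[i] - x[t, i]
                    acc += xt * xt
                    x_hat[i] += dt * (-a[i] * xt + pred)
                    xt_new = x_hat[i] - x[t, i]
                    gdt = dt * gamma[i]
                    for p in range(lo, hi):
                        w[s_indices[p], i] -= gdt * s_data[p] * xt_new
                # uniform leakage decay on all stored weights
                for j in range(w.shape[0]):
                    for i in range(n):
                        w[j, i] *= decay[i]
                if step >= window_start:
                    for j in range(w.shape[0]):
                        for i in range(n):
                            w_sum[j, i] += w[j, i]
                    count += 1
                step += 1
            err_per_epoch[ep] = math.sqrt(acc / t_len)
        return count

else:  # pragma: no cover - fallback exercised only without numba
    _euler_kernel = None


def _euler_numpy(
    s_comp: sparse.csr_matrix,
    x: np.ndarray,
    a: np.ndarray,
    gamma: np.ndarray,
    sigma: float,
    dt: float,
    epochs: int,
    window_start: int,
):
    """Pure-numpy reference implementation of the Euler training loop."""
    t_len, n = x.shape
    n_act = s_comp.shape[1]
    w = np.zeros((n_act, n))
    w_sum = np.zeros_like(w)
    x_hat = x[0].copy()
    decay = 1.0 - dt * sigma * gamma
    err_per_epoch = np.zeros(epochs)
    data, indices, indptr = s_comp.data, s_comp.indices, s_comp.indptr
    step = 0
    count = 0
    for ep in range(epochs):
        acc = 0.0
        for t in range(t_len):
            lo, hi = indptr[t], indptr[t + 1]
            s_vals = data[lo:hi]
            s_idx = indices[lo:hi]
            pred = s_vals @ w[s_idx]
            x_tilde = x_hat - x[t]
            acc += float(x_tilde @ x_tilde)
            # symplectic ordering: observer first, weights from new error
            x_hat = x_hat + dt * (-a * x_tilde + pred)
            x_tilde_new = x_hat - x[t]
            w[s_idx] -= dt * s_vals[:, None] * (gamma * x_tilde_new)[None, :]
            w *= decay[None, :]
            if step >= window_start:
                w_sum += w
                count += 1
            step += 1
        err_per_epoch[ep] = math.sqrt(acc / t_len)
    return w, w_sum, count, err_per_epoch


def _rk4_numpy(
    s_comp: sparse.csr_matrix,
    x: np.ndarray,
    a: np.ndarray,
    gamma: np.ndarray,
    sigma: float,
    dt: float,
    epochs: int,
    window_start: int,
):
    """Classical RK4 with zero-order-hold input (S(x) constant per step)."""
    t_len, n = x.shape
    n_act = s_comp.shape[1]
    w = np.zeros((n_act, n))
    w_sum = np.zeros_like(w)
    x_hat = x[0].copy()
    err_per_epoch = np.zeros(epochs)
    s_dense = np.asarray(s_comp.todense())
    step = 0
    count = 0
    for ep in range(epochs):
        acc = 0.0
        for t in range(t_len):
            s = s_dense[t]
            xt = x[t]
            acc_err = x_hat - xt
            acc += float(acc_err @ acc_err)

            def rhs(xh, ww):
                e = xh - xt
                dxh = -a * e + s @ ww
                dww = -np.outer(s, gamma * e) - (sigma * gamma)[None, :] * ww
                return dxh, dww

            k1x, k1w = rhs(x_hat, w)
            k2x, k2w = rhs(x_hat + 0.5 * dt * k1x, w + 0.5 * dt * k1w)
            k3x, k3w = rhs(x_hat + 0.5 * dt * k2x, w + 0.5 * dt * k2w)
            k4x, k4w = rhs(x_hat + dt * k3x, w + dt * k3w)
            x_hat = x_hat + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            w = w + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
            if step >= window_start:
                w_sum += w
                count += 1
            step += 1
        err_per_epoch[ep] = math.sqrt(acc / t_len)
    return w, w_sum, count, err_per_epoch


def train_pattern(
    features: FeatureTrajectory,
    lattice: RBFLattice,
    config: TrainingConfig = TrainingConfig(),
) -> LearnedPattern:
    """Identify one subject's gait dynamics from a (normalized) trajectory.

    The trajectory is repeated cyclically for ``config.epochs`` passes with
    zero-order-hold input and zero initial weights; the constant pattern is
    the time-average of the weights over the trailing
    ``averaging_window_frac`` of the training horizon.
    """
    x = np.asarray(features.states, dtype=float)
    if x.ndim != 2 or x.shape[1] != lattice.state_dim:
        raise ConfigError(
            f"feature states have shape {x.shape}; lattice expects "
            f"(T, {lattice.state_dim})"
        )
    span = lattice.span
    if x.min() < span[0] - 1e-9 or x.max() > span[1] + 1e-9:
        logger.warning(
            "feature trajectory leaves the lattice span %s; did you apply "
            "the fitted normalizer?",
            span,
        )
    dt = config.dt if config.dt is not None else features.dt
    n = lattice.state_dim
    a = np.full(n, config.a)
    gamma = np.full(n, config.gamma)
    if dt * config.sigma * config.gamma >= 1.0:
        raise IntegrationError(
            "explicit Euler unstable for the leakage term: sigma*gamma*dt >= 1"
        )

    s_full = activation_matrix(lattice, x)
    active_idx = np.unique(s_full.indices)
    if active_idx.size == 0:
        raise IntegrationError("trajectory excites no lattice node")
    col_map = np.full(lattice.n_nodes, -1, dtype=np.int64)
    col_map[active_idx] = np.arange(active_idx.size)
    s_comp = sparse.csr_matrix(
        (s_full.data, col_map[s_full.indices], s_full.indptr),
        shape=(x.shape[0], active_idx.size),
    )

    total_steps = config.epochs * x.shape[0]
    window = max(1, int(math.ceil(config.averaging_window_frac * total_steps)))
    window_start = total_steps - window

    if config.integrator == "rk4":
        w, w_sum, count, err = _rk4_numpy(
            s_comp, x, a, gamma, config.sigma, dt, config.epochs, window_start
        )
    elif _HAVE_NUMBA:
        w = np.zeros((active_idx.size, n))
        w_sum = np.zeros_like(w)
        err = np.zeros(config.epochs)
        count = _euler_kernel(
            s_comp.data,
            s_comp.indices,
            s_comp.indptr,
            x,
            a,
            gamma,
            config.sigma,
            dt,
            config.epochs,
            w,
            w_sum,
            window_start,
            err,
        )
    else:
        w, w_sum, count, err = _euler_numpy(
            s_comp, x, a, gamma, config.sigma, dt, config.epochs, window_start
        )

    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(err))):
        bad_epoch = int(np.flatnonzero(~np.isfinite(err))[0]) if err.size else -1
        raise IntegrationError(
            f"non-finite state during training (around epoch {bad_epoch}); "
            "reduce dt or the gains"
        )
    w_bar = w_sum / count
    drift = float(np.linalg.norm(w - w_bar) / max(np.linalg.norm(w_bar), 1e-30))
    diagnostics = {
        "first_epoch_rms_error": float(err[0]),
        "final_epoch_rms_error": float(err[-1]),
        "weight_drift_rel": drift,
        "epochs": float(config.epochs),
        "dt": float(dt),
        "n_active_nodes": float(active_idx.size),
    }
    if drift > config.weight_convergence_tol:
        logger.info(
            "weights of %s still drifting (rel. %.2e > tol %.2e) after %d "
            "epochs; consider more epochs",
            features.subject_id,
            drift,
            config.weight_convergence_tol,
            config.epochs,
        )
    return LearnedPattern(
        subject_id=features.subject_id,
        group=features.group if isinstance(features.group, Group) else None,
        active_idx=active_idx,
        weights=w_bar,
        lattice=lattice,
        normalizer=features.normalization,
        diagnostics=diagnostics,
    )


def predict_dynamics(pattern: LearnedPattern, z) -> np.ndarray:
    """Learned dynamics estimate phi_hat(z) = W_bar^T S(z).

    Accepts a single state (n,) or a batch (m, n).  Only the pattern's active
    nodes contribute (all other weights are exactly zero).
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    zz = np.atleast_2d(z)
    if zz.shape[1] != pattern.lattice.state_dim:
        raise ConfigError(
            f"state dimension {zz.shape[1]} != lattice dimension "
            f"{pattern.lattice.state_dim}"
        )
    lo, hi = pattern.lattice.span
    if zz.min() < lo or zz.max() > hi:
        logger.warning("predicting outside the lattice span %s", pattern.lattice.span)
    centers = pattern.lattice.centers[pattern.active_idx]
    d2 = cdist(zz, centers, "sqeuclidean")
    s = np.exp(-d2 / pattern.lattice.width**2)
    s[s < ACTIVATION_CUTOFF] = 0.0
    out = s @ pattern.weights
    return out[0] if single else out
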