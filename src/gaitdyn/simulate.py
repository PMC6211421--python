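"""Seeded synthetic gait-cohort generator.

No public recording of the 6-DOF knee kinematics study cohort exists, so this
module stands in for the motion-capture acquisition: it synthesizes periodic
gait waveforms (cycle ~1.08 s at 3 km/h treadmill walking, 60 Hz for 15 s)
whose per-group range-of-motion (ROM) distributions match the published
group means/SDs, and whose per-channel waveform *shapes* are fixed low-order
Fourier templates chosen to mimic ensemble gait curves qualitatively.

Group differences enter only through the ROM distributions: the ACL-deficient
group walks with reduced flexion–extension, internal–external rotation and
proximal–distal excursion but increased anterior–posterior translation, which
is exactly the amplitude signal the downstream classifier must exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from gaitdyn.errors import ConfigError
from gaitdyn.gait_io import CHANNELS, Cohort, GaitTrial, Group

# ---------------------------------------------------------------------------
# cycle templates
# ---------------------------------------------------------------------------

#: Truncated Fourier series per channel: (harmonic k, amplitude, phase in
#: cycles), evaluated as sum_k amp * cos(2*pi*k*(phi - phase)).  Fixed,
#: documented constants: the flexion-extension (FE) template has the classic
#: small loading-response bump in early stance, near-extension around 30% of
#: the cycle and the dominant swing-flexion peak in the second half; the
#: others are generic low-order harmonic shapes.  Phase 0 is heel strike.
TEMPLATE_HARMONICS: Dict[str, Tuple[Tuple[int, float, float], ...]] = {
    "FE": ((1, 1.00, 0.72), (2, 0.45, 0.15), (3, 0.12, 0.05)),
    "IE": ((1, 1.00, 0.60), (2, 0.35, 0.10)),
    "AP": ((1, 1.00, 0.35), (2, 0.40, 0.80)),
    "PD": ((1, 0.55, 0.50), (2, 1.00, 0.20)),
    "VV": ((1, 1.00, 0.45), (2, 0.25, 0.90)),
    "ML": ((1, 1.00, 0.55), (3, 0.30, 0.20)),
}

#: Baseline (heel-strike-anchored) offsets per channel, in channel units.
#: Fixed constants: the ROM, not the absolute angle, carries the group signal.
BASELINE_OFFSETS: Dict[str, float] = {
    "VV": 0.0,
    "IE": 0.0,
    "FE": 0.0,
    "AP": 0.0,
    "PD": 0.0,
    "ML": 0.0,
}

_GRID = np.linspace(0.0, 1.0, 4096, endpoint=False)
_TEMPLATE_NORM: Dict[str, Tuple[float, float]] = {}


def _raw_template(channel: str, phase: np.ndarray) -> np.ndarray:
    harmonics = TEMPLATE_HARMONICS[channel]
    out = np.zeros_like(np.asarray(phase, dtype=float))
    for k, amp, ph in harmonics:
        out += amp * np.cos(2.0 * np.pi * k * (np.asarray(phase, float) - ph))
    return out


def _norm_constants(channel: str) -> Tuple[float, float]:
    if channel not in _TEMPLATE_NORM:
        vals = _raw_template(channel, _GRID)
        _TEMPLATE_NORM[channel] = (float(vals.min()), float(vals.max()))
    return _TEMPLATE_NORM[channel]


def cycle_template(channel: str, phase) -> np.ndarray:
    """Unit-normalized periodic waveform for one channel.

    Parameters
    ----------
    channel : str
        One of VV, IE, FE, AP, PD, ML.
    phase : float or array
        Gait phase in cycles; values outside [0, 1) wrap (period 1).

    Returns
    -------
    ndarray
        Template values with min 0 and max 1 over a cycle (to dense-grid
        accuracy).  Scalar input returns a 0-d array.
    """
    if channel not in TEMPLATE_HARMONICS:
        raise ConfigError(f"unknown channel {channel!r}")
    lo, hi = _norm_constants(channel)
    return (_raw_template(channel, np.mod(phase, 1.0)) - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupKinematicParams:
    """Per-group ROM distribution (mean, SD per channel) and cohort size.

    Defaults reproduce the published study cohort: ROM in degrees for the
    rotations and cm for the translations; gait cycle period 1.08 s.
    """

    rom_mean: Dict[str, float]
    rom_sd: Dict[str, float]
    cycle_period_s: float = 1.08
    n_subjects: int = 1

    def __post_init__(self) -> None:
        for c in CHANNELS:
            if c not in self.rom_mean or c not in self.rom_sd:
                raise ConfigError(f"ROM parameters missing channel {c}")
            if not self.rom_mean[c] > 0:
                raise ConfigError(f"rom_mean[{c}] must be > 0")
            if self.rom_sd[c] < 0:
                raise ConfigError(f"rom_sd[{c}] must be >= 0")
        if not self.cycle_period_s > 0:
            raise ConfigError("cycle_period_s must be positive")
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")

    @classmethod
    def acl_deficient(cls, n_subjects: int = 18) -> "GroupKinematicParams":
        """Published ACL-deficient group ROM means (SDs)."""
        return cls(
            rom_mean={"VV": 13.01, "IE": 18.87, "FE": 59.18,
                      "AP": 2.41, "PD": 1.94, "ML": 1.84},
            rom_sd={"VV": 5.45, "IE": 5.77, "FE": 8.49,
                    "AP": 0.81, "PD": 0.74, "ML": 0.49},
            n_subjects=n_subjects,
        )

    @classmethod
    def acl_intact(cls, n_subjects: int = 28) -> "GroupKinematicParams":
        """Published ACL-intact control group ROM means (SDs)."""
        return cls(
            rom_mean={"VV": 15.40, "IE": 22.45, "FE": 71.76,
                      "AP": 1.95, "PD": 2.38, "ML": 1.86},
            rom_sd={"VV": 4.17, "IE": 4.69, "FE": 6.93,
                    "AP": 0.52, "PD": 0.44, "ML": 0.37},
            n_subjects=n_subjects,
        )


def _default_noise_sd() -> Dict[str, float]:
    # Marker-based capture noise: ~0.25 deg on rotations, ~0.05 cm on
    # translations (sub-millimetre optical systems).
    return {"VV": 0.25, "IE": 0.25, "FE": 0.25, "AP": 0.05, "PD": 0.05, "ML": 0.05}


@dataclass(frozen=True)
class SimulatorConfig:
    """Cohort-level simulator settings (study protocol defaults)."""

    params_acl_d: GroupKinematicParams = field(
        default_factory=GroupKinematicParams.acl_deficient
    )
    params_acl_i: GroupKinematicParams = field(
        default_factory=GroupKinematicParams.acl_intact
    )
    sampling_rate_hz: float = 60.0
    duration_s: float = 15.0
    amplitude_jitter_cv: float = 0.03
    noise_sd: Dict[str, float] = field(default_factory=_default_noise_sd)
    phase_offset_random: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigError("sampling_rate_hz and duration_s must be positive")
        for p in (self.params_acl_d, self.params_acl_i):
            if self.duration_s * self.sampling_rate_hz < (
                p.cycle_period_s * self.sampling_rate_hz
            ):
                raise ConfigError("recording must span at least one gait cycle")
        if self.amplitude_jitter_cv < 0:
            raise ConfigError("amplitude_jitter_cv must be >= 0")
        for c, v in self.noise_sd.items():
            if v < 0:
                raise ConfigError(f"noise_sd[{c}] must be >= 0")

    def noiseless(self) -> "SimulatorConfig":
        """Copy with measurement noise and cycle jitter switched off."""
        return replace(
            self,
            amplitude_jitter_cv=0.0,
            noise_sd={c: 0.0 for c in CHANNELS},
            phase_offset_random=False,
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) resampled until positive (physical non-negativity)."""
    if sd == 0.0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise ConfigError(
        f"truncated-normal draw failed: mean={mean}, sd={sd} is almost surely <= 0"
    )


def simulate_trial(
    group_params: GroupKinematicParams,
    config: SimulatorConfig,
    rng: np.random.Generator,
    subject_id: str = "S0",
    group: Group = Group.ACL_I,
) -> GaitTrial:
    """Synthesize one subject's 6-channel trial.

    For each channel a subject ROM ``R_c ~ Normal(mean, sd)`` (truncated at 0)
    is drawn, and the signal is ``offset_c + R_c * (g(0) + J_k * (g(phi) -
    g(0))) + noise`` where ``g`` is the unit template, ``J_k`` a per-cycle
    multiplicative amplitude jitter (CV = ``amplitude_jitter_cv``) applied to
    the deviation from the heel-strike value so cycle boundaries stay
    continuous, and ``phi`` advances at ``1/cycle_period_s``.  Deterministic
    given the generator state.
    """
    if group_params.cycle_period_s <= 0:
        raise ConfigError("cycle_period_s must be positive")
    rate = config.sampling_rate_hz
    k = round(rate * config.duration_s)
    t = np.arange(k) / rate
    phase0 = rng.uniform(0.0, 1.0) if config.phase_offset_random else 0.0
    phi_total = phase0 + t / group_params.cycle_period_s
    cycle_idx = np.floor(phi_total).astype(int)
    n_cycles = int(cycle_idx.max()) + 1
    channels = {}
    for c in CHANNELS:
        r = _truncated_normal(rng, group_params.rom_mean[c], group_params.rom_sd[c])
        if config.amplitude_jitter_cv > 0:
            jit = rng.normal(1.0, config.amplitude_jitter_cv, size=n_cycles)
            jit = np.clip(jit, 0.0, None)
        else:
            jit = np.ones(n_cycles)
        g = np.asarray(cycle_template(c, phi_total), dtype=float)
        g0 = float(cycle_template(c, 0.0))
        signal = BASELINE_OFFSETS[c] + r * (g0 + jit[cycle_idx] * (g - g0))
        sd_noise = config.noise_sd.get(c, 0.0)
        if sd_noise > 0:
            signal = signal + rng.normal(0.0, sd_noise, size=k)
        channels[c] = signal
    return GaitTrial(
        subject_id=subject_id,
        group=group,
        channels=channels,
        sampling_rate_hz=rate,
        duration_s=config.duration_s,
    )


def simulate_cohort(config: SimulatorConfig) -> Cohort:
    """Generate the two-group cohort (defaults: 18 ACL-D + 28 ACL-I subjects).

    One root seed spawns an independent child stream per subject, so trial j
    is reproducible regardless of how many subjects precede it.
    """
    root = np.random.SeedSequence(config.seed)
    n_total = config.params_acl_d.n_subjects + config.params_acl_i.n_subjects
    children = root.spawn(n_total)
    trials = []
    i = 0
    for group, params in (
        (Group.ACL_D, config.params_acl_d),
        (Group.ACL_I, config.params_acl_i),
    ):
        for j in range(params.n_subjects):
            rng = np.random.default_rng(children[i])
            trials.append(
                simulate_trial(
                    params,
                    config,
                    rng,
                    subject_id=f"{group.value}_{j:03d}",
                    group=group,
                )
            )
            i += 1
    provenance = (
        f"gaitdyn.simulate seed={config.seed} "
        f"n_acl_d={config.params_acl_d.n_subjects} "
        f"n_acl_i={config.params_acl_i.n_subjects} "
        f"rate={config.sampling_rate_hz} duration={config.duration_s} "
        f"jitter_cv={config.amplitude_jitter_cv}"
    )
    return Cohort(trials=trials, provenance=provenance)
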