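"""Descriptive gait statistics: ROM, cycle normalization, t-tests, Cohen's d.

Reproduces the summary-statistic machinery of the study cohort table: per-trial
range of motion (ROM) of each kinematic channel, 101-point gait-cycle
normalization, two-sided equal-variance Student's t-tests on group summaries,
and pooled-SD Cohen's d effect sizes with the (ACL-I minus ACL-D) sign
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from gaitdyn.errors import CycleDetectionError, GaitDataError
from gaitdyn.gait_io import CHANNELS, Cohort, GaitTrial, Group


@dataclass(frozen=True)
class GroupSummary:
    """Per-channel summary statistics for the two groups (D = deficient)."""

    channel: str
    mean_d: float
    sd_d: float
    mean_i: float
    sd_i: float
    n_d: int
    n_i: int

    def __post_init__(self) -> None:
        if self.sd_d < 0 or self.sd_i < 0:
            raise GaitDataError("standard deviations must be >= 0")
        if self.n_d < 2 or self.n_i < 2:
            raise GaitDataError("group sizes must be >= 2")


@dataclass(frozen=True)
class EffectSizeResult:
    """t statistic / p-value and Cohen's d for one channel's ROM."""

    channel: str
    t_statistic: float
    p_value: float
    cohens_d: float
    pooled_sd: float


def rom(series: Sequence[float]) -> float:
    """Range of motion of a kinematic series: max - min (channel units)."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise GaitDataError("cannot compute ROM of an empty series")
    if not np.all(np.isfinite(arr)):
        raise GaitDataError("ROM input contains non-finite samples")
    return float(arr.max() - arr.min())


def normalize_cycle(
    series: Sequence[float], cycle_start: int, cycle_end: int
) -> np.ndarray:
    """Resample one cycle segment onto 101 points (0-100% at 1% steps).

    Linear interpolation; the first/last output points equal the segment's
    endpoint samples.
    """
    arr = np.asarray(series, dtype=float)
    if not (0 <= cycle_start < cycle_end < arr.size):
        raise GaitDataError(
            f"invalid cycle indices [{cycle_start}, {cycle_end}] "
            f"for series of length {arr.size}"
        )
    if cycle_end <= cycle_start + 1:
        raise GaitDataError("cycle must span at least two samples")
    seg = arr[cycle_start : cycle_end + 1]
    x_old = np.linspace(0.0, 1.0, seg.size)
    x_new = np.linspace(0.0, 1.0, 101)
    return np.interp(x_new, x_old, seg)


def detect_cycles(
    trial: GaitTrial, expected_period_s: Optional[float] = None
) -> List[Tuple[int, int]]:
    """Detect gait cycles as successive prominent minima of the FE channel.

    Heel strike coincides with near-extension of the knee, so cycle boundaries
    are taken at smoothed flexion-extension minima.  Returns half-open-ish
    (start, end) sample index pairs with end = next start.
    """
    fe = trial.channel("FE")
    if fe.size < 8 or float(fe.max() - fe.min()) < 1e-9:
        raise CycleDetectionError("no cycles detectable (flat or too-short FE)")
    rate = trial.sampling_rate_hz
    # light smoothing: ~80 ms moving average
    w = max(3, int(round(0.08 * rate)) | 1)
    kernel = np.ones(w) / w
    smooth = np.convolve(fe, kernel, mode="same")
    amp = float(smooth.max() - smooth.min())
    if amp < 1e-9:
        raise CycleDetectionError("no cycles detectable (flat FE after smoothing)")
    if expected_period_s is not None:
        min_dist = max(2, int(round(0.5 * expected_period_s * rate)))
    else:
        min_dist = max(2, int(round(0.4 * rate)))  # cycles slower than 2.5 Hz
    minima, _ = sp_signal.find_peaks(-smooth, distance=min_dist, prominence=0.25 * amp)
    if minima.size < 2:
        raise CycleDetectionError("no cycles detected (fewer than two heel strikes)")
    bounds = [(int(a), int(b)) for a, b in zip(minima[:-1], minima[1:])]
    if expected_period_s is not None:
        mean_len = float(np.mean([b - a for a, b in bounds]))
        target = expected_period_s * rate
        if abs(mean_len - target) > 0.2 * target:
            raise CycleDetectionError(
                f"detected mean cycle length {mean_len:.1f} samples deviates "
                f">20% from expected {target:.1f}"
            )
    return bounds


def pooled_sd(summary: GroupSummary) -> float:
    """Bessel-weighted pooled standard deviation of the two groups."""
    num = (summary.n_d - 1) * summary.sd_d**2 + (summary.n_i - 1) * summary.sd_i**2
    return float(np.sqrt(num / (summary.n_d + summary.n_i - 2)))


def cohens_d(summary: GroupSummary) -> EffectSizeResult:
    """Cohen's d = (mean_I - mean_D) / pooled SD.

    Sign convention: positive when the intact group's mean is larger.
    """
    sp = pooled_sd(summary)
    if sp == 0.0:
        raise GaitDataError("pooled SD is zero; effect size undefined")
    d = (summary.mean_i - summary.mean_d) / sp
    return EffectSizeResult(
        channel=summary.channel,
        t_statistic=float("nan"),
        p_value=float("nan"),
        cohens_d=float(d),
        pooled_sd=sp,
    )


def independent_t_test(summary: GroupSummary) -> EffectSizeResult:
    """Two-sided equal-variance Student's t-test from summary statistics."""
    sp = pooled_sd(summary)
    if sp == 0.0:
        raise GaitDataError("pooled SD is zero; t statistic undefined")
    se = sp * np.sqrt(1.0 / summary.n_d + 1.0 / summary.n_i)
    t = (summary.mean_i - summary.mean_d) / se
    df = summary.n_d + summary.n_i - 2
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    d = (summary.mean_i - summary.mean_d) / sp
    return EffectSizeResult(
        channel=summary.channel,
        t_statistic=float(t),
        p_value=float(p),
        cohens_d=float(d),
        pooled_sd=sp,
    )


# ---------------------------------------------------------------------------
# cohort-level table
# ---------------------------------------------------------------------------


def group_summary(cohort: Cohort, channel: str) -> GroupSummary:
    """Per-trial ROM summary statistics of one channel for both groups."""
    roms = {g: [rom(t.channel(channel)) for t in cohort.by_group(g)] for g in Group}
    for g, vals in roms.items():
        if len(vals) < 2:
            raise GaitDataError(f"group {g.value} needs >= 2 trials for a summary")
    d, i = np.asarray(roms[Group.ACL_D]), np.asarray(roms[Group.ACL_I])
    return GroupSummary(
        channel=channel,
        mean_d=float(d.mean()),
        sd_d=float(d.std(ddof=1)),
        mean_i=float(i.mean()),
        sd_i=float(i.std(ddof=1)),
        n_d=d.size,
        n_i=i.size,
    )


def rom_table(cohort: Cohort) -> pd.DataFrame:
    """Study-table-shaped ROM summary: mean (SD) per group, p, Cohen's d."""
    rows = []
    for c in CHANNELS:
        s = group_summary(cohort, c)
        r = independent_t_test(s)
        rows.append(
            {
                "channel": c,
                "acl_d_mean": s.mean_d,
                "acl_d_sd": s.sd_d,
                "acl_i_mean": s.mean_i,
                "acl_i_sd": s.sd_i,
                "t": r.t_statistic,
                "p_value": r.p_value,
                "cohens_d": r.cohens_d,
            }
        )
    return pd.DataFrame(rows)
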