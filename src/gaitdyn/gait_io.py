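"""Data model and delimited-text I/O for labeled 6-DOF knee kinematic trials.

A trial holds the six tibiofemoral degrees of freedom recorded by a knee
motion-capture system: three rotations — varus–valgus (VV), internal–external
(IE) and flexion–extension (FE), in degrees — and three translations —
anterior–posterior (AP), proximal–distal (PD) and medial–lateral (ML), in cm.

On disk a trial is a single self-describing CSV: ``#``-prefixed metadata lines
(``# subject_id=...``) above a standard header row.  A cohort is a JSON
manifest listing trial files and labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from gaitdyn.errors import (
    ChannelLengthError,
    DuplicateSubjectError,
    DurationMismatchError,
    MissingChannelError,
    NonFiniteSampleError,
    TrialParseError,
    UnknownGroupError,
)

#: Canonical channel order used everywhere (files, arrays, reports).
CHANNELS: Tuple[str, ...] = ("VV", "IE", "FE", "AP", "PD", "ML")

#: Physical unit per channel: rotations in degrees, translations in cm.
CHANNEL_UNITS: Dict[str, str] = {
    "VV": "degree",
    "IE": "degree",
    "FE": "degree",
    "AP": "cm",
    "PD": "cm",
    "ML": "cm",
}


class Group(str, Enum):
    """Knee status: ACL-deficient (patients) vs ACL-intact (controls)."""

    ACL_D = "ACL_D"
    ACL_I = "ACL_I"

    @classmethod
    def parse(cls, label: str) -> "Group":
        try:
            return cls(str(label).strip().upper().replace("-", "_"))
        except ValueError:
            raise UnknownGroupError(
                f"unknown group label {label!r}; expected ACL_D or ACL_I"
            ) from None


@dataclass(frozen=True)
class GaitTrial:
    """One subject's labeled multichannel knee kinematic recording.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier, unique within a cohort.
    group : Group
        ACL_D (deficient) or ACL_I (intact).
    channels : mapping
        Channel name -> 1-D float array.  All six channels must be present,
        equal-length and finite.
    sampling_rate_hz : float
        Sampling rate; the study protocol records at 60 Hz.
    duration_s : float, optional
        Nominal duration; when given, ``round(rate * duration)`` must equal
        the per-channel sample count.
    """

    subject_id: str
    group: Group
    channels: Mapping[str, np.ndarray]
    sampling_rate_hz: float = 60.0
    duration_s: Optional[float] = None
    units: Mapping[str, str] = field(default_factory=lambda: dict(CHANNEL_UNITS))

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sampling_rate_hz) and self.sampling_rate_hz > 0):
            raise GaitTrialInvalidRate(
                f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}"
            )
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise MissingChannelError(f"channel {missing[0]} absent")
        arrays = {}
        for c in CHANNELS:
            arr = np.asarray(self.channels[c], dtype=float)
            if arr.ndim != 1:
                raise ChannelLengthError(f"channel {c} is not a 1-D sequence")
            arrays[c] = arr
        lengths = {c: arrays[c].size for c in CHANNELS}
        k = lengths[CHANNELS[0]]
        if k < 1:
            raise ChannelLengthError("channels are empty (K must be >= 1)")
        if any(n != k for n in lengths.values()):
            raise ChannelLengthError(f"ragged channels: lengths {lengths}")
        for c in CHANNELS:
            if not np.all(np.isfinite(arrays[c])):
                bad = int(np.flatnonzero(~np.isfinite(arrays[c]))[0])
                raise NonFiniteSampleError(
                    f"channel {c} has a non-finite sample at row {bad}"
                )
        if self.duration_s is not None:
            expected = round(self.sampling_rate_hz * self.duration_s)
            if expected != k:
                raise DurationMismatchError(
                    f"K={k} but round(rate*duration)={expected}"
                )
        object.__setattr__(self, "channels", arrays)
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group.parse(self.group))

    @property
    def n_samples(self) -> int:
        return self.channels[CHANNELS[0]].size

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise MissingChannelError(f"channel {name} absent")
        return self.channels[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GaitTrial):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.group == other.group
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.duration_s == other.duration_s
            and all(
                np.array_equal(self.channels[c], other.channels[c]) for c in CHANNELS
            )
        )


class GaitTrialInvalidRate(ChannelLengthError):
    """Non-positive or non-finite sampling rate."""


@dataclass
class Cohort:
    """An ordered collection of trials with provenance metadata."""

    trials: List[GaitTrial]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for t in self.trials:
            if t.subject_id in seen:
                raise DuplicateSubjectError(
                    f"duplicate subject_id {t.subject_id!r} in cohort"
                )
            seen.add(t.subject_id)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def by_group(self, group: Group) -> List[GaitTrial]:
        return [t for t in self.trials if t.group == group]

    def counts(self) -> Dict[Group, int]:
        return {g: len(self.by_group(g)) for g in Group}


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_META_PREFIX = "# "


def write_trial(trial: GaitTrial, path) -> None:
    """Write a trial as a self-describing CSV (full decimal precision)."""
    path = Path(path)
    lines = [
        f"{_META_PREFIX}subject_id={trial.subject_id}",
        f"{_META_PREFIX}group={trial.group.value}",
        f"{_META_PREFIX}sampling_rate_hz={trial.sampling_rate_hz!r}",
    ]
    if trial.duration_s is not None:
        lines.append(f"{_META_PREFIX}duration_s={trial.duration_s!r}")
    lines.append(",".join(CHANNELS))
    cols = [trial.channels[c] for c in CHANNELS]
    for row in zip(*cols):
        lines.append(",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_trial(path) -> GaitTrial:
    """Parse a trial CSV written by :func:`write_trial` (column order free)."""
    path = Path(path)
    meta: Dict[str, str] = {}
    header: Optional[List[str]] = None
    rows: List[List[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
                continue
            if len(cells) != len(header):
                raise TrialParseError(
                    f"{path.name}: row {lineno} has {len(cells)} cells, "
                    f"expected {len(header)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise TrialParseError(
                    f"{path.name}: non-numeric cell at row {lineno}: {exc}"
                ) from None
    if header is None:
        raise TrialParseError(f"{path.name}: no header row found")
    for c in CHANNELS:
        if c not in header:
            raise MissingChannelError(f"channel {c} absent")
    if "subject_id" not in meta:
        raise TrialParseError(f"{path.name}: metadata field subject_id missing")
    if "group" not in meta:
        raise TrialParseError(f"{path.name}: metadata field group missing")
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, len(header)))
    channels = {c: data[:, header.index(c)].copy() for c in CHANNELS}
    duration = meta.get("duration_s")
    return GaitTrial(
        subject_id=meta["subject_id"],
        group=Group.parse(meta["group"]),
        channels=channels,
        sampling_rate_hz=float(meta.get("sampling_rate_hz", 60.0)),
        duration_s=float(duration) if duration is not None else None,
    )


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write each trial CSV plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in cohort:
        fname = f"{trial.subject_id}.csv"
        write_trial(trial, directory / fname)
        entries.append(
            {"file": fname, "subject_id": trial.subject_id, "group": trial.group.value}
        )
    manifest = {"provenance": cohort.provenance, "trials": entries}
    mpath = directory / "cohort.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return mpath


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort from a JSON manifest produced by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    trials = []
    for entry in manifest["trials"]:
        trial = read_trial(base / entry["file"])
        declared = Group.parse(entry["group"])
        if trial.group != declared:
            raise TrialParseError(
                f"{entry['file']}: manifest group {declared.value} disagrees "
                f"with file group {trial.group.value}"
            )
        trials.append(trial)
    return Cohort(trials=trials, provenance=manifest.get("provenance", ""))
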