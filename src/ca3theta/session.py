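"""In-memory data model for a recording session.

A :class:`Session` bundles everything one behavioral recording contributes to
the pipeline: per-unit spike timestamps, the position-tracking series, one or
more LFP channels and the trial intervals. Units are seconds, centimeters,
microvolts; phases everywhere else in the package are degrees on [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUP_LABELS = ("CTRL_DG", "LESION_DG", "CTRL_MEC", "LESION_MEC", "SYNTH")


class ValidationError(ValueError):
    """A session (or one of its components) violates an invariant."""


class FormatError(ValueError):
    """An on-disk session bundle is malformed or incomplete."""


@dataclass
class SpikeUnit:
    """A sorted single unit: id plus spike timestamps in seconds."""

    unit_id: str
    spike_times: np.ndarray

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float).ravel()

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def mean_rate(self, total_time: float) -> float:
        """Mean firing rate lambda = N / T over ``total_time`` seconds."""
        if total_time <= 0:
            raise ValueError("total_time must be positive")
        return self.n_spikes / float(total_time)

    def validate(self):
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike_times not nondecreasing")
        if not np.all(np.isfinite(self.spike_times)):
            raise ValidationError(f"unit {self.unit_id}: non-finite spike time")


@dataclass
class TrackingSeries:
    """Position samples (t in s, x/y in cm) at a fixed camera frame rate."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 29.97

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()

    def validate(self):
        if self.frame_rate <= 0:
            raise ValidationError("tracking frame_rate must be > 0")
        if not (self.t.size == self.x.size == self.y.size):
            raise ValidationError("tracking arrays must have equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("tracking timestamps must be strictly increasing")

    def position_at(self, times):
        """Linear interpolation of (x, y) at arbitrary times."""
        times = np.asarray(times, dtype=float)
        return (
            np.interp(times, self.t, self.x),
            np.interp(times, self.t, self.y),
        )


@dataclass
class LfpChannel:
    """One continuously sampled LFP channel (uV) at ``fs`` Hz."""

    channel_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def validate(self):
        if self.fs <= 0:
            raise ValidationError(f"channel {self.channel_id}: fs must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"channel {self.channel_id}: non-finite samples")


@dataclass
class Session:
    """One recording session: units, tracking, LFP, trial intervals."""

    session_id: str
    units: list
    tracking: TrackingSeries
    lfp: list
    trials: list
    group_label: str = "SYNTH"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.trials = [(float(a), float(b)) for a, b in self.trials]

    @property
    def total_trial_time(self) -> float:
        """Summed duration (s) of all behavioral trials."""
        return float(sum(b - a for a, b in self.trials))

    def unit(self, unit_id: str) -> SpikeUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def channel(self, channel_id: str) -> LfpChannel:
        for c in self.lfp:
            if c.channel_id == channel_id:
                return c
        raise KeyError(channel_id)

    def validate(self):
        if self.group_label not in GROUP_LABELS:
            raise ValidationError(f"unknown group label {self.group_label!r}")
        self.tracking.validate()
        for u in self.units:
            u.validate()
        for c in self.lfp:
            c.validate()
        for a, b in self.trials:
            if b <= a:
                raise ValidationError("trial interval with non-positive duration")
        for (a1, b1), (a2, b2) in zip(self.trials, self.trials[1:]):
            if a2 < b1:
                raise ValidationError("trial intervals must be ordered and non-overlapping")
        return self


def in_trials_mask(times, trials) -> np.ndarray:
    """Boolean mask selecting ``times`` falling inside any trial interval."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for a, b in trials:
        mask |= (times >= a) & (times <= b)
    return mask
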