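"""Core data containers shared across the pipeline.

Conventions used everywhere in this package:

* sample indices are 0-based;
* times are milliseconds from the start of the record;
* signals are float64 arrays in arbitrary "signal units" (the method is
  amplitude-normalised before classification, so absolute units never matter);
* per-subject class labels are the strings ``"healthy"`` / ``"arrhythmia"``
  (``"unknown"`` for unlabeled recordings), segment labels are
  ``"normal"`` / ``"moderate"`` / ``"arrhythmia"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HEALTHY = "healthy"
ARRHYTHMIA = "arrhythmia"
UNKNOWN = "unknown"

NORMAL_SEG = "normal"
MODERATE_SEG = "moderate"
ARRHYTHMIA_SEG = "arrhythmia"

ROLE_ABDOMINAL = "abdominal"
ROLE_THORACIC = "maternal_thoracic"


@dataclass
class AECGRecord:
    """Multichannel abdominal ECG recording.

    ``channels`` is an ``(n_channels, n_samples)`` array; ``channel_roles``
    assigns each row either the abdominal or the maternal-thoracic role.
    ``valid_mask`` marks samples that survived artifact screening (all True
    for a freshly read record).
    """

    subject_id: str
    channels: np.ndarray
    channel_roles: list[str]
    fs: float
    true_class: str = UNKNOWN
    channel_names: list[str] | None = None
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if len(self.channel_roles) != self.channels.shape[0]:
            raise ValueError("one role per channel required")
        if ROLE_ABDOMINAL not in self.channel_roles:
            raise ValueError("record needs at least one abdominal channel")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.channels.shape[1], dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def abdominal_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == ROLE_ABDOMINAL]

    def thoracic_index(self) -> int | None:
        for i, r in enumerate(self.channel_roles):
            if r == ROLE_THORACIC:
                return i
        return None


@dataclass
class FECGSignal:
    """Single-channel fetal ECG after maternal-component removal."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.size, dtype=bool)

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.fs * 1000.0


@dataclass
class RPeakSeries:
    """Fiducial heartbeat times in ms from record start, strictly increasing."""

    times: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RRISeries:
    """Inter-beat (RR) intervals in ms with the R-peak pair defining each.

    ``intervals[i] == end_times[i] - start_times[i]`` always holds.
    """

    intervals: np.ndarray
    start_times: np.ndarray
    end_times: np.ndarray
    subject_id: str = ""
    true_class: str = UNKNOWN

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).ravel()
        self.start_times = np.asarray(self.start_times, dtype=float).ravel()
        self.end_times = np.asarray(self.end_times, dtype=float).ravel()
        if not (
            self.intervals.size == self.start_times.size == self.end_times.size
        ):
            raise ValueError("interval/time arrays must align")
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size

    @classmethod
    def from_peaks(
        cls, peaks: RPeakSeries, true_class: str = UNKNOWN
    ) -> "RRISeries":
        t = peaks.times
        return cls(
            intervals=np.diff(t),
            start_times=t[:-1],
            end_times=t[1:],
            subject_id=peaks.subject_id,
            true_class=true_class,
        )


@dataclass
class Segment:
    """Fixed-length FECG window plus the RR intervals it fully contains."""

    subject_id: str
    start_time: float  # ms
    samples: np.ndarray
    contained_rris: np.ndarray
    subject_class: str = UNKNOWN

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        self.contained_rris = np.asarray(self.contained_rris, dtype=float).ravel()


@dataclass
class SegmentPrediction:
    """Per-segment classifier output; ``scores`` sums to 1 over classes."""

    subject_id: str
    start_time: float
    predicted: str
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class SubjectDecision:
    """Subject-level decision from the arrhythmia-segment ratio vs th."""

    subject_id: str
    n_arr_segments: int
    n_nr_segments: int
    n_mod_segments: int
    ratio: float
    th: float
    predicted: str
    true_class: str = UNKNOWN
    undefined: bool = False
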