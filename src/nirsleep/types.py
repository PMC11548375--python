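"""Shared domain types for the NIRS sleep-staging pipeline.

All time axes are seconds from recording start (0-based); one-minute
annotation epochs are half-open intervals [start, start + 60).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STATES = ("AS", "QS", "Wake")

EPOCH_SECONDS = 60.0


@dataclass
class SleepStateTimeline:
    """Per-minute behavioral sleep labels (AS / QS / Wake)."""

    labels: list[str]
    epoch_duration: float = EPOCH_SECONDS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        bad = sorted({l for l in self.labels} - set(STATES))
        if bad:
            raise ValueError(
                f"unknown sleep-state labels {bad}; allowed labels are {list(STATES)}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_duration

    def epoch_starts(self) -> np.ndarray:
        return self.start_time + self.epoch_duration * np.arange(len(self.labels))


@dataclass
class GroundTruth:
    """Simulator ground truth: 1 Hz HR/RR traces, artifact spans, timeline."""

    hr_trace: np.ndarray  # BPM, 1 Hz
    rr_trace: np.ndarray  # EPM, 1 Hz
    artifact_intervals: list[tuple[float, float]]
    timeline: SleepStateTimeline

    def __post_init__(self) -> None:
        n = int(self.timeline.duration_s)
        if len(self.hr_trace) != n or len(self.rr_trace) != n:
            raise ValueError(
                f"ground-truth traces must cover {n} s at 1 Hz "
                f"(got hr={len(self.hr_trace)}, rr={len(self.rr_trace)})"
            )
        for a, b in self.artifact_intervals:
            if not (0.0 <= a < b <= self.timeline.duration_s):
                raise ValueError(f"artifact interval ({a}, {b}) outside recording")


@dataclass
class ReferenceVitals:
    """Bedside-monitor style HR/RR reference stored at 0.4 Hz."""

    hr: np.ndarray  # BPM
    rr: np.ndarray  # EPM
    sample_rate: float = 0.4

    def __post_init__(self) -> None:
        if len(self.hr) != len(self.rr):
            raise ValueError("reference HR and RR must share one 0.4 Hz time base")

    def times(self) -> np.ndarray:
        return np.arange(len(self.hr)) / self.sample_rate


@dataclass
class RawIntensityRecording:
    """Per-wavelength raw light intensities for one or more optodes.

    ``intensities`` has shape (n_channels, n_wavelengths, n_samples) in
    arbitrary units; ``tsi`` is the device-computed tissue saturation index
    carried through as an auxiliary percentage series (no spatially resolved
    physics here).
    """

    sample_rate: float
    wavelengths: list[float]  # nm
    intensities: np.ndarray
    source_detector_distance: float  # cm
    tsi: np.ndarray | None = None  # %, same sample rate
    reference_intensity: np.ndarray | None = None  # per channel x wavelength
    recording_id: str = "rec"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (channels, wavelengths, samples)")
        if self.intensities.shape[1] != len(self.wavelengths):
            raise ValueError("wavelength axis does not match wavelength list")
        if np.any(self.intensities <= 0):
            idx = np.argwhere(self.intensities <= 0)[0]
            raise ValueError(
                "non-positive light intensity at (channel, wavelength, sample) "
                f"= {tuple(int(i) for i in idx)}"
            )

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class HemodynamicSeries:
    """Chromophore concentration changes (uM) plus pass-through TSI (%)."""

    o2hb: np.ndarray
    hhb: np.ndarray
    sample_rate: float
    tsi: np.ndarray | None = None
    channel_id: int = 0

    def __post_init__(self) -> None:
        self.o2hb = np.asarray(self.o2hb, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        if self.o2hb.shape != self.hhb.shape:
            raise ValueError("o2hb and hhb must have equal length")

    @property
    def thb(self) -> np.ndarray:
        return self.o2hb + self.hhb

    @property
    def n_samples(self) -> int:
        return len(self.o2hb)


@dataclass
class VitalsSeries:
    """Windowed HR/RR estimates plus their 1 Hz spline interpolations."""

    times: np.ndarray  # s, window centers
    hr: np.ndarray  # BPM
    rr: np.ndarray  # EPM
    hr_flagged: np.ndarray  # bool, no-estimate windows (held values)
    rr_flagged: np.ndarray
    window: float = 30.0
    stride: float = 7.5
    times_1hz: np.ndarray | None = None
    hr_1hz: np.ndarray | None = None
    rr_1hz: np.ndarray | None = None


@dataclass
class ModalitySet:
    """The eight 1 Hz feature modalities on one common time grid."""

    times: np.ndarray  # integer seconds
    o2hb_f: np.ndarray
    hhb_f: np.ndarray
    tsi_f: np.ndarray
    hr_1hz: np.ndarray
    rr_1hz: np.ndarray
    mov_std: np.ndarray
    mov_iqr: np.ndarray
    mov_corr: np.ndarray

    NAMES = ("o2hb_f", "hhb_f", "tsi_f", "hr_1hz", "rr_1hz",
             "mov_std", "mov_iqr", "mov_corr")

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in self.NAMES:
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"modality {name!r} not on the common 1 Hz grid")

    def matrix(self) -> np.ndarray:
        """Stack the eight modalities into an (8, n_seconds) array."""
        return np.stack([getattr(self, name) for name in self.NAMES])


@dataclass
class FeatureEpoch:
    """One 8-modality x 60-sample matrix aligned to a 1-minute label."""

    matrix: np.ndarray  # (8, 60)
    label: str  # AS or QS
    epoch_start: float
    recording_id: str = "rec"
    subject_id: str = "sub"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (8, 60):
            raise ValueError(f"feature matrix must be 8x60, got {self.matrix.shape}")
        if self.label not in ("AS", "QS"):
            raise ValueError("epoch label must be binary AS/QS (Wake excluded upstream)")


@dataclass
class QualityRating:
    """One 1-5 signal-quality score for a window of one channel."""

    window_start: float
    window_length: float
    score: int
    channel_id: int = 0

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError("quality score must be an integer in 1..5")
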