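"""The published study cohort: per-measurement manifest and the fixed
leave-measurement-out grouping, used as worked-example fixtures.

Subject 4 was recorded twice (measurements "4a" and "4b") and both
measurements share one fold, keeping every subject exclusive to one group.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class RecordingManifest:
    subject_id: str
    measurement_id: str
    ga_weeks: float
    pma_weeks: float
    sex: str
    birthweight_g: int
    duration_min: float
    qs_as_ratio: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("recording duration must be positive")


#: The ten analyzed measurements from nine preterm infants.
STUDY_COHORT: list[RecordingManifest] = [
    RecordingManifest("1", "1", 25.7, 34.8, "F", 635, 75.0, 0.21),
    RecordingManifest("2", "2", 31.7, 31.8, "M", 1355, 57.0, 0.12),
    RecordingManifest("3", "3", 34.6, 35.1, "M", 1700, 74.0, 0.68),
    RecordingManifest("4", "4a", 37.0, 38.1, "M", 2650, 99.0, 0.15),
    RecordingManifest("4", "4b", 37.0, 38.2, "M", 2650, 13.0, 1.60),
    RecordingManifest("5", "5", 34.6, 34.7, "F", 1976, 180.0, 0.34),
    RecordingManifest("6", "6", 30.9, 36.4, "M", 1900, 73.0, 0.40),
    RecordingManifest("7", "7", 31.3, 34.2, "F", 1550, 35.0, 0.59),
    RecordingManifest("8", "8", 31.7, 32.8, "M", 1710, 96.0, 0.34),
    RecordingManifest("9", "9", 35.0, 35.1, "F", 2350, 21.0, 4.25),
]

#: Published leave-measurement-out grouping (Group 1..5).
FIXTURE_FOLD_PLAN: list[tuple[str, str]] = [
    ("2", "9"),
    ("4a", "4b"),
    ("1", "3"),
    ("7", "8"),
    ("5", "6"),
]

#: Final-annotation epoch counts by state (one-minute epochs).
EPOCH_COUNTS = {"QS": 191, "AS": 532, "Wake": 38}


def binary_task_epoch_total() -> int:
    """Epochs entering the AS-vs-QS task once Wake is excluded."""
    return EPOCH_COUNTS["QS"] + EPOCH_COUNTS["AS"]


def manifest_by_measurement() -> dict[str, RecordingManifest]:
    return {m.measurement_id: m for m in STUDY_COHORT}


def fold_duration_min(fold: tuple[str, str]) -> float:
    """Summed recording duration of one fixture fold, minutes."""
    by_id = manifest_by_measurement()
    return sum(by_id[m].duration_min for m in fold)
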