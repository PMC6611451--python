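"""Per-frame fascicle measurements and comparison bookkeeping.

Automatic tracking digitizes every frame; manual measurements exist only
at a handful of frames (e.g. six frames at 0/20/40/60/80/100% of a
contraction, or at target joint angles).  This module turns per-frame
geometry into ordered measurement series, downsamples them to the
comparison frames, applies initial-offset correction, and enumerates the
study-design bookkeeping (videos x examiners x days x frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FascicleMeasurement",
    "MeasurementSeries",
    "StudyDesign",
    "sample_at_indices",
    "indices_from_fractions",
    "indices_from_angle_trace",
    "offset_correct",
    "percent_difference",
    "enumerate_measurement_plan",
    "filter_mistakes",
]


@dataclass(frozen=True)
class FascicleMeasurement:
    """One frame's fascicle geometry.

    ``superficial_extrapolated`` / ``deep_extrapolated`` flag attachment
    points that fell outside the imaged field of view, where the fitted
    lines were extrapolated to make the measurement.
    """

    frame_index: int
    time_s: float
    length_mm: float
    pennation_deg: float
    superficial_extrapolated: bool = False
    deep_extrapolated: bool = False
    n_valid_sup: int = 0
    n_valid_deep: int = 0
    n_valid_fas: int = 0


@dataclass
class MeasurementSeries:
    """Ordered per-frame measurements plus trial metadata.

    ``metadata`` carries free-form labels (subject, condition, trial,
    examiner, day, method in {automatic, manual}, ...).
    """

    measurements: list[FascicleMeasurement]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("measurement series must be non-empty")
        idx = [m.frame_index for m in self.measurements]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([m.frame_index for m in self.measurements], dtype=int)

    @property
    def lengths_mm(self) -> np.ndarray:
        return np.array([m.length_mm for m in self.measurements])

    @property
    def pennations_deg(self) -> np.ndarray:
        return np.array([m.pennation_deg for m in self.measurements])

    def values(self, field_name: str) -> np.ndarray:
        if field_name == "length":
            return self.lengths_mm
        if field_name == "pennation":
            return self.pennations_deg
        raise ValueError("field must be 'length' or 'pennation'")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_indices,
                "time_s": [m.time_s for m in self.measurements],
                "length_mm": self.lengths_mm,
                "pennation_deg": self.pennations_deg,
                "superficial_extrapolated": [
                    m.superficial_extrapolated for m in self.measurements
                ],
                "deep_extrapolated": [m.deep_extrapolated for m in self.measurements],
                "n_valid_sup": [m.n_valid_sup for m in self.measurements],
                "n_valid_deep": [m.n_valid_deep for m in self.measurements],
                "n_valid_fas": [m.n_valid_fas for m in self.measurements],
            }
        )


@dataclass(frozen=True)
class StudyDesign:
    """Counts describing a reliability study layout."""

    n_subjects: int
    n_conditions: int
    n_trials: int
    n_examiners: int
    n_days: int
    n_manual_frames: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1")


def sample_at_indices(series: MeasurementSeries, indices: list[int]) -> MeasurementSeries:
    """Subset a series at the given frame indices, preserving order and metadata."""
    if len(indices) == 0:
        raise ValueError("index list must be non-empty")
    by_index = {m.frame_index: m for m in series.measurements}
    missing = [i for i in indices if i not in by_index]
    if missing:
        raise KeyError(f"frame indices not present in series: {missing}")
    return MeasurementSeries(
        measurements=[by_index[i] for i in indices],
        metadata=dict(series.metadata),
    )


def indices_from_fractions(n_frames: int, fractions: list[float]) -> list[int]:
    """Frame indices at given fractions of a video's duration.

    ``index = round(fraction * (n_frames - 1))``; duplicates are removed
    preserving first occurrence (relevant for very short videos).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    out: list[int] = []
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
        idx = int(round(f * (n_frames - 1)))
        if idx not in out:
            out.append(idx)
    return out


def indices_from_angle_trace(angle_series: np.ndarray, targets: list[float]) -> list[int]:
    """For each target joint angle, the frame index whose recorded angle is
    closest (first minimiser on ties)."""
    angles = np.asarray(angle_series, dtype=float)
    if angles.size == 0:
        raise ValueError("angle trace is empty")
    return [int(np.argmin(np.abs(angles - t))) for t in targets]


def offset_correct(
    collection: list[MeasurementSeries],
    field_name: str,
    target: str = "grand_mean",
) -> list[MeasurementSeries]:
    """Remove initial-value offsets so all series share the same first value.

    Each series has (its first value - common target) subtracted from every
    element, so within-series frame-to-frame differences are preserved
    exactly and only the starting level is aligned.  ``target`` is the
    grand mean of the first values (default) or ``"first_series"``.
    """
    if len(collection) < 1:
        raise ValueError("need at least one series")
    ref_idx = collection[0].frame_indices
    for s in collection[1:]:
        if not np.array_equal(s.frame_indices, ref_idx):
            raise ValueError("all series must share identical frame indices")
    firsts = np.array([s.values(field_name)[0] for s in collection])
    common = float(firsts.mean()) if target == "grand_mean" else float(firsts[0])
    corrected = []
    for s, first in zip(collection, firsts):
        shift = float(first) - common
        attr = "length_mm" if field_name == "length" else "pennation_deg"
        new_ms = [replace(m, **{attr: getattr(m, attr) - shift}) for m in s.measurements]
        corrected.append(MeasurementSeries(new_ms, metadata=dict(s.metadata)))
    return corrected


def percent_difference(value: float, reference: float) -> float:
    """Signed percent difference 100 * (value - reference) / reference."""
    if reference == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    return 100.0 * (value - reference) / reference


def enumerate_measurement_plan(design: StudyDesign) -> dict[str, int]:
    """Bookkeeping counts for a reliability study.

    videos = subjects x conditions x trials; each video is tracked by every
    examiner on every day; each tracked video yields ``n_manual_frames``
    paired manual measurements.
    """
    n_videos = design.n_subjects * design.n_conditions * design.n_trials
    n_tracked = n_videos * design.n_examiners * design.n_days
    return {
        "n_videos": n_videos,
        "n_tracked_videos": n_tracked,
        "n_manual_measurements": n_tracked * design.n_manual_frames,
    }


def filter_mistakes(
    manual: np.ndarray,
    automatic: np.ndarray,
    threshold: float = 40.0,
) -> np.ndarray:
    """Mask of paired measurements to keep: |manual - automatic| <= threshold.

    Guards against gross manual digitisation mistakes (errant clicks); the
    default 40 mm threshold is far beyond any physiological disagreement
    in gastrocnemius fascicle length.
    """
    m = np.asarray(manual, dtype=float)
    a = np.asarray(automatic, dtype=float)
    if m.shape != a.shape:
        raise ValueError("paired arrays must have the same shape")
    return np.abs(m - a) <= threshold
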