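"""Core data model: frame schedules, time-activity curves, dynamic volumes.

Times are stored in seconds at the file boundary (the way acquisition
software prints frame schedules) and exposed in minutes for kinetic
modelling, where rate constants are conventionally min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "FrameSchedule",
    "TAC",
    "DynamicImage",
    "LabelVolume",
    "ScanRecord",
    "make_default_schedule",
    "frame_midpoints",
    "extract_regional_tac",
]


class ScheduleError(ValueError):
    """Raised for non-contiguous, overlapping or otherwise invalid frame timing."""


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frame timing starting at injection.

    Parameters
    ----------
    start_s, end_s : array-like
        Per-frame start and end times in seconds. Frames must tile
        ``[0, end_s[-1]]`` without gaps or overlap.
    """

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ScheduleError("start_s and end_s must be equal-length 1-D arrays")
        if start[0] != 0.0:
            raise ScheduleError(f"first frame must start at 0 s, got {start[0]}")
        if not np.all(end > start):
            raise ScheduleError("every frame must have end > start")
        if not np.allclose(start[1:], end[:-1]):
            gaps = np.flatnonzero(~np.isclose(start[1:], end[:-1]))
            raise ScheduleError(
                f"frames must be contiguous; gap/overlap after frame index {gaps[0]}"
            )

    @classmethod
    def from_durations(cls, durations_s) -> "FrameSchedule":
        d = np.asarray(durations_s, dtype=float)
        end = np.cumsum(d)
        return cls(start_s=end - d, end_s=end)

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def durations_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def mid_s(self) -> np.ndarray:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def duration_s(self) -> float:
        return float(self.end_s[-1])

    @property
    def duration_min(self) -> float:
        return float(self.end_s[-1]) / 60.0

    def __eq__(self, other) -> bool:  # dataclass eq fails on arrays
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start_s, other.start_s) and np.array_equal(
            self.end_s, other.end_s
        )

    def __hash__(self) -> int:
        return hash((self.start_s.tobytes(), self.end_s.tobytes()))


#: Frame durations (seconds) of the 90-min 39-frame mouse acquisition used
#: throughout: 12x10 s, 3x20 s, 3x30 s, 3x60 s, 3x150 s, 15x300 s.
DEFAULT_FRAME_DURATIONS_S = (
    [10.0] * 12 + [20.0] * 3 + [30.0] * 3 + [60.0] * 3 + [150.0] * 3 + [300.0] * 15
)


def make_default_schedule() -> FrameSchedule:
    """The 39-frame, 90-minute dynamic mouse acquisition schedule."""
    return FrameSchedule.from_durations(DEFAULT_FRAME_DURATIONS_S)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Per-frame midpoint times in minutes (strictly increasing)."""
    return schedule.mid_min


@dataclass(frozen=True)
class TAC:
    """Decay-corrected activity concentration (kBq/mL) per frame for one region.

    Negative frame values, which reconstructed PET can produce in cold
    regions, are accepted and passed through unmodified.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != self.schedule.n_frames:
            raise ValueError(
                f"TAC has {v.size} values for {self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC values must be finite")

    def with_values(self, values) -> "TAC":
        return replace(self, values=np.asarray(values, dtype=float))

    def scaled(self, factor: float) -> "TAC":
        return self.with_values(self.values * factor)


@dataclass(frozen=True)
class DynamicImage:
    """4-D dynamic PET volume (x, y, z, frame) in kBq/mL on a frame schedule."""

    voxels: np.ndarray
    voxel_size_mm: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        vs = np.asarray(self.voxel_size_mm, dtype=float)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size_mm", vs)
        if vox.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if vox.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"image has {vox.shape[3]} frames, schedule has {self.schedule.n_frames}"
            )
        if vs.shape != (3,) or not np.all(vs > 0):
            raise ValueError("voxel_size_mm must be 3 positive values")

    @property
    def shape3d(self) -> tuple:
        return self.voxels.shape[:3]

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass(frozen=True)
class LabelVolume:
    """Integer label volume on the dynamic-image grid with a label legend."""

    labels: np.ndarray
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 3:
            raise ValueError("label volume must be 3-D")
        present = set(np.unique(lab)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend missing entries for labels {sorted(missing)}")

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask of voxels carrying ``region``'s label."""
        ids = [k for k, v in self.legend.items() if v == region]
        if not ids:
            raise KeyError(f"region {region!r} not in legend {dict(self.legend)}")
        return np.isin(self.labels, ids)


@dataclass
class ScanRecord:
    """One dynamic scan: subject, genotype, session and its regional TACs."""

    subject_id: str
    genotype: str
    session: str
    tacs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for required in ("striatum", "cerebellum"):
            if required not in self.tacs:
                raise ValueError(f"scan {self.subject_id} missing {required} TAC")
        schedules = {t.schedule for t in self.tacs.values()}
        if len(schedules) != 1:
            raise ValueError("all TACs of a scan must share one schedule")

    @property
    def schedule(self) -> FrameSchedule:
        return next(iter(self.tacs.values())).schedule


def extract_regional_tac(
    img: DynamicImage, labels: LabelVolume, region: str
) -> TAC:
    """Unweighted mean TAC over all voxels carrying ``region``'s label.

    Raises
    ------
    ValueError
        If no voxel carries the label, or grids disagree.
    """
    if labels.labels.shape != img.shape3d:
        raise ValueError(
            f"label grid {labels.labels.shape} does not match image {img.shape3d}"
        )
    m = labels.mask(region)
    if not m.any():
        raise ValueError(f"region {region!r} contains no voxels")
    values = img.voxels[m].mean(axis=0)
    return TAC(schedule=img.schedule, values=values, region=region)
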