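"""Reading/writing the formats the pipeline touches, plus the shared domain types.

All times are seconds referenced to tracer injection at t = 0, all
concentrations are standardized uptake values (SUV, g/mL), and net influx
rates are per minute.  Curves derived from frame-averaged data are sampled
at frame midpoints.

Dynamic images travel as NIfTI with the frame axis as the fourth dimension
and spatial order (depth, height, width); frame timing travels in a CSV
sidecar with columns ``frame_index``, ``start_s``, ``duration_s``; blood
curves are two-column CSVs ``time_s``, ``suv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: The acquisition framing used throughout: 1 x 30 s, 24 x 5 s, 9 x 20 s,
#: 8 x 300 s = 42 frames covering 2730 s (45.5 min).
CANONICAL_GROUPS: tuple[tuple[int, float], ...] = ((1, 30.0), (24, 5.0), (9, 20.0), (8, 300.0))

#: Canonical whole-body grid (depth, height, width).
CANONICAL_SHAPE: tuple[int, int, int] = (96, 48, 48)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous list of acquisition frame starts and durations."""

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.size < 1 or starts.shape != durations.shape:
            raise ValueError("schedule needs matching 1-D starts and durations with >= 1 frame")
        if starts[0] < 0:
            raise ValueError("frame starts must be non-negative")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if starts.size > 1 and np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
            raise ValueError("frames must be contiguous (start[i+1] = start[i] + duration[i])")

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def end_time(self) -> float:
        return float(self.starts[-1] + self.durations[-1])

    def regroup(self) -> tuple[list[int], list[float]]:
        """Collapse consecutive equal durations back into (counts, durations)."""
        counts: list[int] = []
        durations: list[float] = []
        for d in self.durations:
            if durations and np.isclose(durations[-1], d):
                counts[-1] += 1
            else:
                counts.append(1)
                durations.append(float(d))
        return counts, durations

    def subset(self, index: slice) -> "FrameSchedule":
        """Contiguous sub-schedule re-anchored so the first retained frame starts at 0."""
        starts = self.starts[index]
        durations = self.durations[index]
        if starts.size == 0:
            raise ValueError("empty frame subset")
        return FrameSchedule(starts - starts[0], durations)


def build_schedule(
    group_counts: Sequence[int], group_durations: Sequence[float]
) -> FrameSchedule:
    """Expand grouped framing (e.g. 1x30 s, 24x5 s, ...) into a contiguous schedule.

    Parameters
    ----------
    group_counts
        Number of frames in each group (each >= 1).
    group_durations
        Frame duration in seconds for each group (each > 0).
    """
    if len(group_counts) != len(group_durations):
        raise ValueError("group_counts and group_durations must have equal length")
    if len(group_counts) == 0:
        raise ValueError("at least one frame group is required")
    durations_list: list[float] = []
    for count, duration in zip(group_counts, group_durations):
        if int(count) < 1:
            raise ValueError(f"group count must be >= 1, got {count}")
        if duration <= 0:
            raise ValueError(f"group duration must be > 0, got {duration}")
        durations_list.extend([float(duration)] * int(count))
    durations = np.array(durations_list)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


def canonical_schedule() -> FrameSchedule:
    """The 42-frame framing used by the whole-body mouse protocol."""
    counts, durations = zip(*CANONICAL_GROUPS)
    return build_schedule(list(counts), list(durations))


@dataclass
class DynamicPETImage:
    """A 4-D dynamic PET volume in SUV with its frame schedule.

    ``values`` is ordered (time, depth, height, width); ``spacing`` is the
    voxel size in mm per spatial axis.
    """

    values: np.ndarray
    schedule: FrameSchedule
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 4:
            raise ValueError("not a dynamic image: expected 4 dimensions (time, depth, height, width)")
        if self.values.shape[0] != self.schedule.n_frames:
            raise ValueError(
                f"time dimension ({self.values.shape[0]}) does not match "
                f"schedule ({self.schedule.n_frames} frames)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]


@dataclass
class BloodCurve:
    """Tracer concentration in blood over time (measured AIF, DLIF or plasma input)."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "whole-blood"

    _KINDS = ("whole-blood", "plasma")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size == 0:
            raise ValueError("empty blood curve")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")

    def __len__(self) -> int:
        return int(self.times.size)

    def interpolator(self):
        """Linear interpolant anchored at (0, 0), constant after the last sample.

        Concentration is taken as zero at injection; between t = 0 and the
        first sample the curve rises linearly.
        """
        t = self.times
        v = self.values
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            v = np.concatenate([[0.0], v])

        def f(x):
            return np.interp(x, t, v)

        return f


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def suv_normalize(activity: np.ndarray, body_weight_g: float, injected_dose_kBq: float) -> np.ndarray:
    """Convert activity concentration (kBq/mL) to SUV (g/mL).

    SUV = activity * body weight / injected dose.
    """
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    if injected_dose_kBq <= 0:
        raise ValueError("injected dose must be positive")
    return np.asarray(activity) * (body_weight_g / injected_dose_kBq)


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------

def write_dynamic_pet(image: DynamicPETImage, image_path, timing_path) -> None:
    """Write a dynamic image as 4-D NIfTI plus a frame-timing CSV sidecar.

    On disk the array is (depth, height, width, time) so the frame axis is
    the fourth NIfTI dimension; the affine carries the voxel spacing in mm.
    """
    data = np.transpose(image.values, (1, 2, 3, 0)).astype(np.float32)
    affine = np.diag(list(image.spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(image_path))
    pd.DataFrame(
        {
            "frame_index": np.arange(image.n_frames),
            "start_s": image.schedule.starts,
            "duration_s": image.schedule.durations,
        }
    ).to_csv(timing_path, index=False)


def read_dynamic_pet(image_path, timing_path) -> DynamicPETImage:
    """Read a 4-D NIfTI dynamic image and its frame-timing sidecar."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"not a dynamic image: {image_path} has {data.ndim} dimensions, expected 4")
    timing = pd.read_csv(timing_path)
    for col in ("frame_index", "start_s", "duration_s"):
        if col not in timing.columns:
            raise ValueError(f"timing sidecar missing column {col!r}")
    if len(timing) != data.shape[3]:
        raise ValueError(
            f"timing sidecar has {len(timing)} rows but the image has {data.shape[3]} frames"
        )
    schedule = FrameSchedule(timing["start_s"].to_numpy(float), timing["duration_s"].to_numpy(float))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    values = np.transpose(data, (3, 0, 1, 2))
    return DynamicPETImage(values=values, schedule=schedule, spacing=spacing)


# ---------------------------------------------------------------------------
# Blood-curve I/O
# ---------------------------------------------------------------------------

def write_blood_curve(curve: BloodCurve, csv_path) -> None:
    pd.DataFrame({"time_s": curve.times, "suv": curve.values}).to_csv(csv_path, index=False)


def read_blood_curve(csv_path, kind: str = "whole-blood") -> BloodCurve:
    df = pd.read_csv(csv_path)
    if df.empty:
        raise ValueError(f"empty blood-curve file: {csv_path}")
    for col in ("time_s", "suv"):
        if col not in df.columns:
            raise ValueError(f"blood-curve CSV missing column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="raise").to_numpy(float)
    values = pd.to_numeric(df["suv"], errors="raise").to_numpy(float)
    return BloodCurve(times=times, values=values, kind=kind)
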