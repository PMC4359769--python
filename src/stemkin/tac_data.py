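"""Frame schedules, time-activity curves, plant manifests, and their file I/O.

A dynamic PET scan is acquired in contiguous time frames; the activity
concentration in a stem region of interest (ROI), averaged per frame, forms a
time-activity curve (TAC).  Before modeling, each TAC is normalized to
concentration per vertical length of stem per total administered activity, so
its values carry units of 1/mm and curves from different plants are directly
comparable.

All modeling downstream runs on the administration time axis (t = 0 when
tracer feeding starts); files store scanner time and
:func:`rebase_to_administration` makes the shift explicit.

The on-disk TAC format is a UTF-8 tab-separated table with one row per
(ROI, frame) and columns ``roi_label, position_mm, frame_start_s,
frame_duration_s, value``; lines beginning with ``#`` are comments.  The plant
manifest is a small YAML mapping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import EmptyCurveError, FormatError, ScheduleError

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "PlantManifest",
    "standard_frame_schedule",
    "read_tac_file",
    "write_tac_file",
    "read_manifest",
    "write_manifest",
    "rebase_to_administration",
    "normalize_tac",
]

#: Default reconstruction slice thickness (mm): vertical extent of a
#: single-plane stem ROI.
DEFAULT_SLICE_THICKNESS_MM = 1.21

_TAC_COLUMNS = ("roi_label", "position_mm", "frame_start_s", "frame_duration_s", "value")

# Relative slack for the frame-contiguity check; frames are stored in seconds
# so this is far below any physical frame boundary jitter.
_CONTIGUITY_RTOL = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Temporal sampling grid of a dynamic scan.

    Frames must be contiguous and non-overlapping:
    ``start[i+1] == start[i] + duration[i]`` with all durations positive.
    ``mid_time`` (start + duration/2) is the time point each frame-averaged
    value is attributed to.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape:
            raise ScheduleError("frame start and duration must be 1-D arrays of equal length")
        if start.size == 0:
            raise ScheduleError("a frame schedule needs at least one frame")
        if np.any(duration <= 0):
            raise ScheduleError("all frame durations must be positive")
        expected = start[:-1] + duration[:-1]
        tol = _CONTIGUITY_RTOL * max(1.0, float(np.max(np.abs(start))) + float(np.max(duration)))
        if np.any(np.abs(start[1:] - expected) > tol):
            bad = int(np.argmax(np.abs(start[1:] - expected) > tol))
            raise ScheduleError(
                f"frames are not contiguous: frame {bad} ends at {expected[bad]:g} s "
                f"but frame {bad + 1} starts at {start[bad + 1]:g} s"
            )

    @property
    def mid_time(self) -> np.ndarray:
        """Frame mid-times in seconds (strictly increasing)."""
        return self.start + self.duration / 2.0

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def span_s(self) -> float:
        """Total scan span from first frame start to last frame end."""
        return float(self.end[-1] - self.start[0])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_frames


@dataclass(frozen=True)
class TimeActivityCurve:
    """One ROI's observed activity concentration per unit stem length vs time.

    ``values`` are normalized to (Bq/mm)/Bq administered, i.e. units of 1/mm.
    Small negative values are tolerated (scatter-corrected PET noise), but a
    curve whose mean is negative carries no fittable signal.

    ``position_mm`` is the signed height of the ROI above the administration
    node (positive = up-stem).
    """

    schedule: FrameSchedule
    values: np.ndarray
    roi_label: str
    position_mm: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise ScheduleError(
                f"curve {self.roi_label!r}: {values.size} values for "
                f"{self.schedule.n_frames} frames"
            )

    @property
    def mid_time(self) -> np.ndarray:
        return self.schedule.mid_time

    @property
    def is_fittable(self) -> bool:
        return float(np.mean(self.values)) >= 0.0


@dataclass(frozen=True)
class PlantManifest:
    """Per-plant administration metadata and ROI geometry.

    ``admin_offset_s`` is the delay between scan start and the start of
    petiolar administration (the petiole is cut 60 s into the scan by
    default).  ``roi_positions_mm`` maps each ROI label to its stem position.
    """

    plant_id: str
    administered_activity_bq: float
    administration_duration_s: float
    roi_positions_mm: dict[str, float]
    admin_offset_s: float = 60.0
    slice_thickness_mm: float = DEFAULT_SLICE_THICKNESS_MM
    age_days: float | None = None

    def __post_init__(self) -> None:
        if self.administered_activity_bq <= 0:
            raise ValueError("administered activity must be positive")
        if self.administration_duration_s <= 0:
            raise ValueError("administration duration must be positive")
        if self.admin_offset_s < 0:
            raise ValueError("administration offset must be non-negative")
        if len(self.roi_positions_mm) < 2:
            raise ValueError("at least 2 ROI positions are required for velocity fitting")

    @property
    def n_rois(self) -> int:
        return len(self.roi_positions_mm)


def standard_frame_schedule() -> FrameSchedule:
    """The scan protocol's frame grid: 20 x 1 min then 8 x 5 min (3600 s)."""
    duration = np.concatenate([np.full(20, 60.0), np.full(8, 300.0)])
    start = np.concatenate([[0.0], np.cumsum(duration)[:-1]])
    return FrameSchedule(start=start, duration=duration)


def _curves_to_frame(curves: list[TimeActivityCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        rows.append(
            pd.DataFrame(
                {
                    "roi_label": c.roi_label,
                    "position_mm": c.position_mm,
                    "frame_start_s": c.schedule.start,
                    "frame_duration_s": c.schedule.duration,
                    "value": c.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_tac_file(curves: list[TimeActivityCurve], path: str | Path) -> None:
    """Write curves to the TAC TSV format (full float precision)."""
    df = _curves_to_frame(list(curves))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# stemkin time-activity curves: one row per (ROI, frame)\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_tac_file(path: str | Path) -> list[TimeActivityCurve]:
    """Read a TAC TSV file into one curve per ROI (frames in time order).

    Raises :class:`FormatError` if a required column is missing and
    :class:`ScheduleError` if any ROI's frames are non-contiguous.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse TAC file {path}: {exc}") from exc
    for col in _TAC_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"TAC file {path} is missing required column {col!r}")
    curves: list[TimeActivityCurve] = []
    # groupby(sort=False) preserves the order ROIs first appear in the file
    for label, grp in df.groupby("roi_label", sort=False):
        grp = grp.sort_values("frame_start_s")
        positions = grp["position_mm"].to_numpy(dtype=float)
        if positions.size and np.ptp(positions) > 1e-9 * max(1.0, np.max(np.abs(positions))):
            raise FormatError(f"ROI {label!r} has inconsistent position_mm values")
        schedule = FrameSchedule(
            start=grp["frame_start_s"].to_numpy(dtype=float),
            duration=grp["frame_duration_s"].to_numpy(dtype=float),
        )
        curves.append(
            TimeActivityCurve(
                schedule=schedule,
                values=grp["value"].to_numpy(dtype=float),
                roi_label=str(label),
                position_mm=float(positions[0]),
            )
        )
    return curves


def write_manifest(manifest: PlantManifest, path: str | Path) -> None:
    """Write a plant manifest as a flat YAML mapping."""
    data = {
        "plant_id": manifest.plant_id,
        "administered_activity_bq": float(manifest.administered_activity_bq),
        "administration_duration_s": float(manifest.administration_duration_s),
        "admin_offset_s": float(manifest.admin_offset_s),
        "slice_thickness_mm": float(manifest.slice_thickness_mm),
        "roi_positions_mm": {k: float(v) for k, v in manifest.roi_positions_mm.items()},
    }
    if manifest.age_days is not None:
        data["age_days"] = float(manifest.age_days)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_manifest(path: str | Path) -> PlantManifest:
    """Read a plant manifest from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"manifest {path} is not a YAML mapping")
    required = (
        "plant_id",
        "administered_activity_bq",
        "administration_duration_s",
        "roi_positions_mm",
    )
    for key in required:
        if key not in data:
            raise FormatError(f"manifest {path} is missing required key {key!r}")
    return PlantManifest(
        plant_id=str(data["plant_id"]),
        administered_activity_bq=float(data["administered_activity_bq"]),
        administration_duration_s=float(data["administration_duration_s"]),
        roi_positions_mm={str(k): float(v) for k, v in data["roi_positions_mm"].items()},
        admin_offset_s=float(data.get("admin_offset_s", 60.0)),
        slice_thickness_mm=float(data.get("slice_thickness_mm", DEFAULT_SLICE_THICKNESS_MM)),
        age_days=(float(data["age_days"]) if data.get("age_days") is not None else None),
    )


def rebase_to_administration(
    curve: TimeActivityCurve, admin_offset_s: float
) -> TimeActivityCurve:
    """Shift a curve from scanner time to administration time.

    All frame starts move by ``-admin_offset_s``; frames whose mid-time
    becomes negative are dropped (they precede tracer arrival and the model
    domain starts at t = 0).  Durations and values are untouched.
    """
    if admin_offset_s < 0:
        raise ValueError("administration offset must be non-negative")
    new_start = curve.schedule.start - admin_offset_s
    keep = (new_start + curve.schedule.duration / 2.0) >= 0.0
    if not np.any(keep):
        raise EmptyCurveError(
            f"offset {admin_offset_s:g} s leaves no frames for ROI {curve.roi_label!r}"
        )
    schedule = FrameSchedule(start=new_start[keep], duration=curve.schedule.duration[keep])
    return replace(curve, schedule=schedule, values=curve.values[keep])


def normalize_tac(
    raw_values_bq_per_ml: np.ndarray,
    roi_volume_ml: float,
    slice_thickness_mm: float,
    administered_activity_bq: float,
) -> np.ndarray:
    """Convert raw ROI concentration to activity per stem length per administered.

    ``out = raw * roi_volume / slice_thickness / administered_activity``:
    concentration times ROI volume gives activity in the ROI; dividing by the
    slice thickness spreads it per vertical mm of stem; dividing by the
    administered activity makes curves comparable across plants (units 1/mm).
    """
    if roi_volume_ml <= 0 or slice_thickness_mm <= 0 or administered_activity_bq <= 0:
        raise ValueError("volume, slice thickness and administered activity must be positive")
    raw = np.asarray(raw_values_bq_per_ml, dtype=float)
    return raw * roi_volume_ml / slice_thickness_mm / administered_activity_bq


def curves_to_tsv_string(curves: list[TimeActivityCurve]) -> str:
    """Render curves to the TAC TSV format in memory (used by the CLI)."""
    buf = io.StringIO()
    _curves_to_frame(list(curves)).to_csv(buf, sep="\t", index=False, float_format="%.17g")
    return buf.getvalue()
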