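"""Session data model and file I/O.

A :class:`TrackedSession` holds one fly's centroid trajectory (timestamps in
seconds, positions in mm after calibration) together with its metadata, and a
:class:`StimulusSchedule` holds the shadow-stimulus protocol (onset times and
the 2 s shadow duration).  All downstream analysis consumes these two types
only; nothing else in the package touches files.

Tracking CSVs follow the tracker's convention: columns ``frame``,
``timestamp_s``, ``x``, ``y`` with coordinates in pixels (converted here using
a mm-per-pixel calibration) or already in mm.  Rows with missing coordinates
are treated as tracking gaps: runs of up to ``max_gap_frames`` consecutive
missing frames are linearly interpolated, longer runs are recorded as gap
intervals so that overlapping trials can be invalidated downstream.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: nominal video frame rate of the tracker (frames per second)
FRAME_RATE = 100.0

#: tunnel footprint in mm (length along x, width along y)
DEFAULT_TUNNEL = (52.0, 5.0)

#: tracking gaps at most this many consecutive frames are interpolated
MAX_GAP_FRAMES = 3

#: tolerance (mm) for positions slightly outside the tunnel bounds
POSITION_TOLERANCE = 1.0


@dataclass
class TrackedSession:
    """One fly's calibrated centroid trajectory plus metadata.

    Parameters
    ----------
    fly_id : str
        Unique identifier of the animal.
    genotype : str
        Group label (e.g. ``"control"``, ``"parkin"``).
    age_days : int
        Age of the fly in days (>= 0).
    timestamps : ndarray, shape (n,)
        Seconds from session start, strictly increasing, nominal 0.01 s step.
    positions : ndarray, shape (n, 2)
        Centroid (x, y) in mm; x runs along the tunnel long axis with the
        origin at one tunnel end.
    calibration : float
        mm per pixel used to convert the raw coordinates (> 0).
    tunnel : tuple of float
        (length, width) of the tunnel in mm.
    gap_intervals : list of (float, float)
        Time intervals (s) during which tracking was lost for longer than the
        interpolation policy allows.
    meta : dict
        Arbitrary extra annotations (experiment id, sex, ...).
    """

    fly_id: str
    genotype: str
    age_days: int
    timestamps: np.ndarray
    positions: np.ndarray
    calibration: float = 1.0
    tunnel: tuple[float, float] = DEFAULT_TUNNEL
    gap_intervals: list[tuple[float, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.calibration <= 0:
            raise ParameterError("calibration must be > 0 mm/px")
        if self.age_days < 0:
            raise ParameterError("age_days must be >= 0")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise DataError("positions must have shape (n, 2)")
        if len(self.timestamps) != len(self.positions):
            raise DataError("timestamps and positions must have equal length")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise DataError(
                f"timestamps must be strictly increasing; first violation at row {row}"
            )
        finite = np.isfinite(self.positions).all(axis=1)
        if finite.any():
            pos = self.positions[finite]
            lo, hi = -POSITION_TOLERANCE, max(self.tunnel) + POSITION_TOLERANCE
            if pos.min() < lo or pos.max() > hi:
                raise DataError("positions fall outside tunnel bounds beyond tolerance")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Tracked span in seconds."""
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class StimulusSchedule:
    """Shadow-stimulus protocol: onset times and the shared shadow duration."""

    onsets: np.ndarray
    shadow_duration: float = 2.0
    session_length: float = 2400.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise DataError("onsets must be a 1-d array")
        if len(self.onsets) > 1 and np.any(np.diff(self.onsets) <= 0):
            raise DataError("stimulus onsets must be strictly ascending")
        if len(self.onsets) and self.onsets[-1] > self.session_length:
            warnings.warn(
                "stimulus onsets extend beyond the nominal session length",
                stacklevel=2,
            )

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def inter_trial_intervals(self, from_start: bool = True) -> np.ndarray:
        """Gaps between consecutive onsets; optionally including the gap from
        session start (t=0) to the first onset."""
        if self.n_trials == 0:
            return np.empty(0)
        if from_start:
            return np.diff(np.concatenate([[0.0], self.onsets]))
        return np.diff(self.onsets)


@dataclass
class SessionMeta:
    """Free-form key/value annotations for a session."""

    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict keys are unique by construction; accept (key, value) pairs too
        if not isinstance(self.annotations, dict):
            pairs = list(self.annotations)
            keys = [k for k, _ in pairs]
            if len(set(keys)) != len(keys):
                raise DataError("duplicate annotation keys")
            self.annotations = dict(pairs)


def _interpolate_gaps(
    timestamps: np.ndarray, xy: np.ndarray, max_gap: int = MAX_GAP_FRAMES
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Fill runs of <= ``max_gap`` missing frames by linear interpolation.

    Longer runs are interpolated too (so kinematics stay finite) but recorded
    as gap intervals which downstream code uses to invalidate trials.
    """
    missing = ~np.isfinite(xy).all(axis=1)
    gaps: list[tuple[float, float]] = []
    if not missing.any():
        return xy, gaps
    if missing.all():
        raise DataError("all rows have missing coordinates")
    idx = np.arange(len(xy))
    out = xy.copy()
    for k in range(2):
        good = ~missing
        out[:, k] = np.interp(idx, idx[good], xy[good, k])
    # locate runs of consecutive missing frames
    edges = np.flatnonzero(np.diff(np.concatenate([[0], missing.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > max_gap:
            gaps.append((float(timestamps[start]), float(timestamps[stop - 1])))
    return out, gaps


def read_tracking(
    path: str | Path,
    calibration: float = 1.0,
    tunnel: tuple[float, float] = DEFAULT_TUNNEL,
    unit: str = "px",
    fly_id: str | None = None,
    genotype: str = "unknown",
    age_days: int = 0,
) -> TrackedSession:
    """Read a tracker CSV (columns frame, timestamp_s, x, y) into a session.

    ``unit`` declares whether x/y are in pixels (converted by ``calibration``
    mm/px) or already in mm.  Missing coordinates become tracking gaps, not
    dropped rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise FormatError(f"{path.name}: tracking CSV must have x and y columns")
    if "timestamp_s" in cols:
        t = df[cols["timestamp_s"]].to_numpy(dtype=float)
    elif "frame" in cols:
        t = df[cols["frame"]].to_numpy(dtype=float) / FRAME_RATE
    else:
        raise FormatError(f"{path.name}: need a timestamp_s or frame column")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise DataError(f"{path.name}: non-monotonic timestamp at row {row}")
    xy = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    if unit == "px":
        xy = xy * calibration
    elif unit != "mm":
        raise ParameterError(f"unit must be 'px' or 'mm', got {unit!r}")
    xy, gaps = _interpolate_gaps(t, xy)
    if gaps:
        logger.info("%s: %d tracking gap(s) longer than %d frames",
                    path.name, len(gaps), MAX_GAP_FRAMES)
    return TrackedSession(
        fly_id=fly_id or path.stem,
        genotype=genotype,
        age_days=age_days,
        timestamps=t,
        positions=xy,
        calibration=calibration,
        tunnel=tunnel,
        gap_intervals=gaps,
    )


def write_tracking(session: TrackedSession, path: str | Path) -> Path:
    """Write a session back to the tracker CSV format (mm coordinates)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(session.n_frames),
            "timestamp_s": session.timestamps,
            "x": session.positions[:, 0],
            "y": session.positions[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")
    return path


def read_schedule(path: str | Path) -> StimulusSchedule:
    """Read a stimulus schedule from CSV (trial, onset_s, duration_s) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        onsets = np.asarray(payload["onset_s"], dtype=float)
        duration = float(payload.get("duration_s", 2.0))
        length = float(payload.get("session_length_s", 2400.0))
    else:
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "onset_s" not in cols:
            raise FormatError(f"{path.name}: schedule CSV must have an onset_s column")
        onsets = df[cols["onset_s"]].to_numpy(dtype=float)
        duration = (
            float(df[cols["duration_s"]].iloc[0]) if "duration_s" in cols and len(df)
            else 2.0
        )
        length = 2400.0
    if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
        raise DataError(f"{path.name}: onsets must be ascending")
    length = max(length, float(onsets[-1]) + duration) if len(onsets) else length
    return StimulusSchedule(onsets=onsets, shadow_duration=duration,
                            session_length=length)


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "trial": np.arange(schedule.n_trials),
            "onset_s": schedule.onsets,
            "duration_s": schedule.shadow_duration,
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")
    return path


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seeds: dict | list | int | None = None,
) -> list[Path]:
    """Write tidy result tables plus a JSON run manifest.

    One CSV per table (header-only when empty); the manifest records the
    configuration, seeds and package version so a run can be reproduced.
    Output is deterministic: identical inputs give byte-identical files.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.9f")
        written.append(p)
    manifest = {
        "software": "shadowtrial",
        "version": __version__,
        "config": config or {},
        "seeds": seeds,
        "tables": sorted(t.name for t in written),
    }
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written.append(mp)
    return written


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON analysis configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
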