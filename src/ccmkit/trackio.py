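"""Read, validate and write cell-track tables.

A *track* is one cell's time-ordered centroid positions within an imaging
field, as produced by segmentation + tracking pipelines.  Tracks are stored
as a flat table with columns ``track_id, frame, t, x, y`` (pixel units,
image convention: origin top-left, y increasing downward, frames 0-based)
plus per-field metadata: treatment condition, knockdown label, replicate,
field geometry and the frame interval in minutes.

Files are plain delimited text (comma by default, tab accepted) with
``#``-prefixed ``key: value`` metadata header lines.  Coordinates are
written with fixed 6-decimal precision so that write -> read round-trips
are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column order in track files
TRACK_COLUMNS = ("track_id", "frame", "t", "x", "y")

#: per-file metadata grouping columns recognised inside a table
GROUP_COLUMNS = ("field_id", "condition", "knockdown", "replicate")

# common tracker-export dialects, lowercased header -> canonical name
_COLUMN_ALIASES = {
    "track_id": "track_id", "track": "track_id", "id": "track_id",
    "cell_id": "track_id", "cell": "track_id", "particle": "track_id",
    "frame": "frame", "slice": "frame", "frame_number": "frame",
    "t": "t", "time": "t", "position_t": "t",
    "x": "x", "position_x": "x", "pos_x": "x", "x_px": "x",
    "y": "y", "position_y": "y", "pos_y": "y", "y_px": "y",
}

_MANDATORY = ("track_id", "frame", "x", "y")


@dataclass
class TrackSet:
    """Tracks from one imaging field under one experimental condition.

    Parameters
    ----------
    data
        DataFrame with at least ``track_id, frame, x, y``; ``t`` (minutes
        from T0) is derived from ``frame * frame_interval`` when absent.
    field_width, field_height
        Field extent in pixels; 0 means unknown (disables bounds checks
        and density-normalized metrics).
    frame_interval
        Minutes between consecutive frames (> 0).
    """

    data: pd.DataFrame
    field_id: str = "field0"
    condition: str = ""
    knockdown: str | None = None
    replicate: int = 1
    field_width: float = 0.0
    field_height: float = 0.0
    frame_interval: float = 30.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        df = self.data
        missing = [c for c in _MANDATORY if c not in df.columns]
        if missing:
            raise ValueError(f"track table missing required column(s): {missing}")
        df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
        if "t" not in df.columns:
            df = df.assign(t=df["frame"].to_numpy(dtype=float) * self.frame_interval)
        self.data = df[list(TRACK_COLUMNS)]

    # -- convenience accessors -------------------------------------------

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())

    def positions_at(self, frame: int) -> np.ndarray:
        """(n, 2) array of cell centroids observed at ``frame``."""
        sub = self.data[self.data["frame"] == frame]
        return sub[["x", "y"]].to_numpy(dtype=float)

    def counts_per_frame(self) -> pd.Series:
        return self.data.groupby("frame").size().sort_index()

    def with_data(self, data: pd.DataFrame) -> "TrackSet":
        return replace(self, data=data)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ValidationReport:
    """Report-only QC findings; validation never mutates the input."""

    out_of_bounds: list = field(default_factory=list)   # (track_id, frame)
    gaps: list = field(default_factory=list)            # (track_id, missing frame)
    singleton_tracks: list = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.out_of_bounds or self.gaps or self.singleton_tracks)


def _check_duplicates(df: pd.DataFrame, label: str) -> None:
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["track_id", "frame"]]
        raise ValueError(
            f"duplicated (track_id, frame) pair in {label}: "
            f"(track_id={first['track_id']}, frame={first['frame']})"
        )


def read_tracks(path, schema_map: dict | None = None) -> list[TrackSet]:
    """Read a delimited track table into one TrackSet per metadata group.

    ``schema_map`` renames nonstandard headers (original -> canonical);
    common tracker dialects (``position_x`` etc.) are recognised
    automatically.  Rows with non-finite coordinates are dropped and
    counted in the log.  Grouping columns (``field_id, condition,
    knockdown, replicate``) present in the table partition the rows; every
    input row lands in exactly one TrackSet.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    sep = ","
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
            elif line.strip():
                if "\t" in line:
                    sep = "\t"
                break

    df = pd.read_csv(path, comment="#", sep=sep)
    rename = {}
    schema_map = schema_map or {}
    for col in df.columns:
        if col in schema_map:
            rename[col] = schema_map[col]
        elif col.lower() in _COLUMN_ALIASES:
            rename[col] = _COLUMN_ALIASES[col.lower()]
    df = df.rename(columns=rename)

    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r} (after schema_map)")

    bad = ~(np.isfinite(df["x"]) & np.isfinite(df["y"]))
    if bad.any():
        log.warning("read_tracks(%s): dropped %d rows with non-finite coordinates",
                    path, int(bad.sum()))
        df = df[~bad]

    def _meta_kwargs(extra: dict) -> dict:
        kd = extra.get("knockdown", meta.get("knockdown", ""))
        if kd in ("", "None", None) or (isinstance(kd, float) and np.isnan(kd)):
            kd = None
        return dict(
            field_id=str(extra.get("field_id", meta.get("field_id", "field0"))),
            condition=str(extra.get("condition", meta.get("condition", ""))),
            knockdown=kd if kd is None else str(kd),
            replicate=int(extra.get("replicate", meta.get("replicate", 1))),
            field_width=float(meta.get("field_width", 0.0)),
            field_height=float(meta.get("field_height", 0.0)),
            frame_interval=float(meta.get("frame_interval", 30.0)),
        )

    group_cols = [c for c in GROUP_COLUMNS if c in df.columns]
    out: list[TrackSet] = []
    if group_cols:
        for key, sub in df.groupby(group_cols, dropna=False, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            extra = dict(zip(group_cols, key))
            sub = sub.drop(columns=group_cols)
            _check_duplicates(sub, f"{path} group {extra}")
            out.append(TrackSet(sub, **_meta_kwargs(extra)))
    else:
        _check_duplicates(df, str(path))
        out.append(TrackSet(df, **_meta_kwargs({})))
    return out


def write_tracks(ts: TrackSet, path) -> Path:
    """Write one TrackSet with '#' metadata headers; 6-decimal coordinates."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# field_id: {ts.field_id}\n")
        fh.write(f"# condition: {ts.condition}\n")
        fh.write(f"# knockdown: {'' if ts.knockdown is None else ts.knockdown}\n")
        fh.write(f"# replicate: {ts.replicate}\n")
        fh.write(f"# field_width: {ts.field_width}\n")
        fh.write(f"# field_height: {ts.field_height}\n")
        fh.write(f"# frame_interval: {ts.frame_interval}\n")
        fh.write(",".join(TRACK_COLUMNS) + "\n")
        for tid, frame, t, x, y in ts.data.itertuples(index=False):
            fh.write(f"{tid},{int(frame)},{t:.6f},{x:.6f},{y:.6f}\n")
    return path


def validate_tracks(ts: TrackSet) -> ValidationReport:
    """List out-of-bounds points, frame gaps and single-observation tracks."""
    report = ValidationReport()
    if ts.field_width > 0 and ts.field_height > 0:
        oob = (
            (ts.data["x"] < 0) | (ts.data["x"] > ts.field_width)
            | (ts.data["y"] < 0) | (ts.data["y"] > ts.field_height)
        )
        report.out_of_bounds = list(
            ts.data.loc[oob, ["track_id", "frame"]].itertuples(index=False, name=None)
        )
    for tid, sub in ts.data.groupby("track_id"):
        frames = sub["frame"].to_numpy()
        if len(frames) == 1:
            report.singleton_tracks.append(tid)
        missing = np.setdiff1d(np.arange(frames[0], frames[-1] + 1), frames)
        report.gaps.extend((tid, int(f)) for f in missing)
    return report
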