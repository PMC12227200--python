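"""Reading and writing fluorescence tables and result tables.

The interchange dialect is plain CSV: one mandatory header row of ROI
names, one row per frame, ``.`` as decimal separator.  Each recording is
one larva; the whole-brain signal is a designated column (default the
first) or the mean across columns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("none", "ptz_acute", "ptz_rebound")

#: decimal places kept when writing fluorescence/result tables
WRITE_DECIMALS = 9


class TraceParseError(ValueError):
    """A fluorescence table could not be parsed; names the offending cell."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = ""
        if row is not None or column is not None:
            loc = f" (row {row}, column {column!r})"
        super().__init__(message + loc)


@dataclass
class Recording:
    """Raw fluorescence of one larva, uniformly sampled.

    ``fluorescence`` is a (n_frames, n_rois) array; frame k occurs at
    ``t0_s + k / sampling_rate_hz``.  Invariants (finite, non-negative,
    at least two frames) are enforced at construction only.
    """

    larva_id: str
    group: str = "control"
    treatment: str = "none"
    sampling_rate_hz: float = 1.33
    fluorescence: np.ndarray = field(default_factory=lambda: np.zeros((2, 1)))
    roi_names: Sequence[str] = ()
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        if f.ndim == 1:
            f = f[:, None]
        if f.ndim != 2:
            raise ValueError("fluorescence must be 1-D or 2-D (frames x ROIs)")
        if f.shape[0] < 2:
            raise ValueError("a recording needs at least 2 frames")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence must be finite")
        if np.any(f < 0):
            raise ValueError("fluorescence must be non-negative")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        self.fluorescence = f
        if not self.roi_names:
            self.roi_names = tuple(f"roi{i}" for i in range(f.shape[1]))
        elif len(self.roi_names) != f.shape[1]:
            raise ValueError("roi_names length must match number of columns")
        else:
            self.roi_names = tuple(self.roi_names)

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.sampling_rate_hz

    def trace(self, roi: str | int = 0) -> np.ndarray:
        """Whole-brain signal: a named/indexed column, or the ROI mean."""
        if roi == "mean":
            return self.fluorescence.mean(axis=1)
        if isinstance(roi, str):
            try:
                roi = self.roi_names.index(roi)
            except ValueError:
                raise KeyError(f"no ROI named {roi!r}; have {self.roi_names}")
        return self.fluorescence[:, roi]


def read_recording(path: str | Path, metadata: Mapping | None = None) -> Recording:
    """Read a frame x ROI CSV into a :class:`Recording`.

    ``metadata`` may carry larva_id, group, treatment, sampling_rate_hz
    and t0_s; larva_id defaults to the file stem.
    """
    path = Path(path)
    meta = dict(metadata or {})
    try:
        df = pd.read_csv(path, header=0)
    except Exception as exc:  # malformed CSV structure
        raise TraceParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise TraceParseError(f"{path} holds no data rows")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise TraceParseError(
                f"non-numeric cell {df[col].iloc[r]!r} in {path}", row=r, column=str(col)
            )
        if vals.isna().any():
            r = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise TraceParseError(f"missing value in {path}", row=r, column=str(col))
        if (vals < 0).any():
            r = int(np.flatnonzero((vals < 0).to_numpy())[0])
            raise TraceParseError(
                f"negative fluorescence {vals.iloc[r]} in {path}", row=r, column=str(col)
            )
        df[col] = vals
    return Recording(
        larva_id=str(meta.pop("larva_id", path.stem)),
        fluorescence=df.to_numpy(dtype=float),
        roi_names=tuple(str(c) for c in df.columns),
        **meta,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write the frame x ROI table as CSV (header = ROI names)."""
    df = pd.DataFrame(rec.fluorescence, columns=list(rec.roi_names))
    df.to_csv(path, index=False, float_format=f"%.{WRITE_DECIMALS}g")


def _records_frame(items: Iterable, columns: Sequence[str]) -> pd.DataFrame:
    rows = []
    for it in items:
        d = dataclasses.asdict(it) if dataclasses.is_dataclass(it) else dict(it)
        rows.append({c: d.get(c) for c in columns})
    df = pd.DataFrame(rows, columns=list(columns))
    sort_cols = [c for c in ("larva_id", "onset_s") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    return df


EVENT_COLUMNS = (
    "larva_id", "onset_s", "offset_s", "peak_time_s", "amplitude_pct",
    "duration_s", "detect_threshold_pct", "truncated",
)
SEIZURE_COLUMNS = (
    "larva_id", "onset_s", "offset_s", "duration_s", "amplitude_pct",
    "peak_time_s", "align_time_s", "truncated",
)


def write_events_table(events: Iterable, path: str | Path) -> pd.DataFrame:
    """Write detected Ca2+ events as CSV, sorted by larva then onset."""
    df = _records_frame(events, EVENT_COLUMNS)
    df.to_csv(path, index=False)
    return df


def write_seizures_table(seizures: Iterable, path: str | Path) -> pd.DataFrame:
    """Write detected seizures as CSV, sorted by larva then onset."""
    df = _records_frame(seizures, SEIZURE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def write_summaries_table(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write per-larva summary rows (already tabular) as CSV."""
    df = summaries.sort_values("larva_id", kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False)
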