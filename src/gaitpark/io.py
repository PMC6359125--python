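"""Readers and writers for every on-disk representation the pipeline
touches.

Raw vGRF trials use the PhysioNet ``gaitpdb`` dialect: whitespace-
delimited numeric text, one sample per row, 19 columns by default
(time, 8 left-sensor forces, 8 right-sensor forces, left total, right
total).  Feature tables, stride-interval tables and exclusion-interval
lists are plain CSV with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    FEATURE_IDS,
    FEATURE_NAMES,
    NAME_TO_ID,
    ExclusionIntervals,
    FeatureTable,
    StrideIntervalFile,
    StrideTable,
    ValidationError,
    VGRFRecording,
)

__all__ = [
    "ColumnLayout",
    "GAITPDB_LAYOUT",
    "read_vgrf",
    "write_vgrf",
    "read_exclusion_intervals",
    "write_exclusion_intervals",
    "read_stride_intervals",
    "write_stride_intervals",
    "read_feature_table",
    "write_feature_table",
]


@dataclass(frozen=True)
class ColumnLayout:
    """Mapping from file columns to channels.

    ``None`` for ``time`` synthesizes a time base from ``fs``; ``None``
    for the total columns computes totals as per-foot sensor sums.
    """

    time: int | None = 0
    left_sensors: tuple[int, ...] = tuple(range(1, 9))
    right_sensors: tuple[int, ...] = tuple(range(9, 17))
    left_total: int | None = 17
    right_total: int | None = 18

    @property
    def n_columns(self) -> int:
        cols = [*self.left_sensors, *self.right_sensors]
        for c in (self.time, self.left_total, self.right_total):
            if c is not None:
                cols.append(c)
        return max(cols) + 1


#: The 19-column PhysioNet gaitpdb layout (default).
GAITPDB_LAYOUT = ColumnLayout()

#: 17-column variant without the two per-foot total columns.
NO_TOTALS_LAYOUT = ColumnLayout(left_total=None, right_total=None)


def _parse_numeric_rows(path: Path) -> np.ndarray:
    """Parse whitespace-delimited numeric text, rejecting (not dropping)
    malformed rows with the offending row index in the message."""
    rows: list[list[float]] = []
    ncols: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            fields = line.split()
            if not fields:
                continue
            try:
                row = [float(x) for x in fields]
            except ValueError as exc:
                raise ValidationError(f"{path}: non-numeric value in row {i}: {exc}") from None
            if ncols is None:
                ncols = len(row)
            elif len(row) != ncols:
                raise ValidationError(
                    f"{path}: row {i} has {len(row)} fields, expected {ncols}"
                )
            rows.append(row)
    if not rows:
        raise ValidationError(f"{path}: empty file")
    return np.asarray(rows, dtype=float)


def read_vgrf(
    path: str | Path,
    fs: float = 100.0,
    layout: ColumnLayout | None = None,
    subject_id: str | None = None,
    label: str = "healthy",
    meta: dict | None = None,
) -> VGRFRecording:
    """Read one raw vGRF trial.

    If the layout has no total columns, totals are computed as the
    per-foot sensor sums.  Negative forces are clipped to zero (vGRF is
    physically non-negative); the raw values are kept in
    ``meta['raw_negative_count']`` for audit.

    Parameters
    ----------
    path
        Whitespace-delimited numeric text file, one sample per row.
    fs
        Sampling rate in Hz, used to synthesize time when the layout has
        no time column (default 100 Hz, the gaitpdb rate).
    layout
        Column mapping; defaults to the 19-column gaitpdb layout, or the
        17-column no-totals variant when the file has 17 columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = _parse_numeric_rows(path)

    if layout is None:
        if data.shape[1] == GAITPDB_LAYOUT.n_columns:
            layout = GAITPDB_LAYOUT
        elif data.shape[1] == NO_TOTALS_LAYOUT.n_columns:
            layout = NO_TOTALS_LAYOUT
        else:
            raise ValidationError(
                f"{path}: {data.shape[1]} columns; expected 19 (gaitpdb) or 17 "
                f"(no totals) — pass an explicit layout"
            )
    if data.shape[1] < layout.n_columns:
        raise ValidationError(
            f"{path}: {data.shape[1]} columns, layout requires {layout.n_columns}"
        )

    n = data.shape[0]
    t = data[:, layout.time] if layout.time is not None else np.arange(n) / fs
    left = data[:, list(layout.left_sensors)]
    right = data[:, list(layout.right_sensors)]
    lt = data[:, layout.left_total] if layout.left_total is not None else left.sum(axis=1)
    rt = data[:, layout.right_total] if layout.right_total is not None else right.sum(axis=1)

    neg = int((left < 0).sum() + (right < 0).sum() + (lt < 0).sum() + (rt < 0).sum())
    left, right = np.clip(left, 0, None), np.clip(right, 0, None)
    lt, rt = np.clip(lt, 0, None), np.clip(rt, 0, None)

    dt = np.median(np.diff(t))
    if not np.isclose(dt, 1.0 / fs, rtol=0.01):
        raise ValidationError(
            f"{path}: median sampling interval {dt:.6g}s inconsistent with fs={fs}Hz"
        )

    meta = dict(meta or {})
    meta["raw_negative_count"] = neg
    return VGRFRecording(
        subject_id=subject_id or path.stem,
        label=label,
        fs=fs,
        t=t,
        left_sensors=left,
        right_sensors=right,
        left_total=lt,
        right_total=rt,
        meta=meta,
    )


def write_vgrf(rec: VGRFRecording, path: str | Path) -> None:
    """Write a recording in the 19-column gaitpdb dialect."""
    data = np.column_stack(
        [rec.t, rec.left_sensors, rec.right_sensors, rec.left_total, rec.right_total]
    )
    np.savetxt(path, data, fmt="%.6f", delimiter="\t")


def read_exclusion_intervals(path: str | Path) -> ExclusionIntervals:
    """Read a two-column CSV of (start_s, end_s) half-open intervals."""
    df = pd.read_csv(path)
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise ValidationError(f"{path}: exclusion file missing column {col!r}")
    return ExclusionIntervals(list(zip(df["start_s"].astype(float), df["end_s"].astype(float))))


def write_exclusion_intervals(ex: ExclusionIntervals, path: str | Path) -> None:
    pd.DataFrame(ex.intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)


_STRIDE_COLS = ["record_id", "subject_id", "label", "cycle",
                "left_stride_s", "left_swing_s", "right_stride_s", "right_swing_s"]


def write_stride_intervals(records: StrideIntervalFile | list[StrideTable], path: str | Path) -> None:
    """Write stride/swing interval series as long-form CSV (one cycle
    per row; repeat-length 17 digits preserve float64 exactly)."""
    tables = records.records if isinstance(records, StrideIntervalFile) else list(records)
    rows = []
    for st in tables:
        n = max(st.left_stride_s.size, st.right_stride_s.size)
        for i in range(n):
            rows.append({
                "record_id": st.record_id,
                "subject_id": st.subject_id,
                "label": st.label,
                "cycle": i,
                "left_stride_s": st.left_stride_s[i] if i < st.left_stride_s.size else np.nan,
                "left_swing_s": st.left_swing_s[i] if i < st.left_swing_s.size else np.nan,
                "right_stride_s": st.right_stride_s[i] if i < st.right_stride_s.size else np.nan,
                "right_swing_s": st.right_swing_s[i] if i < st.right_swing_s.size else np.nan,
            })
    pd.DataFrame(rows, columns=_STRIDE_COLS).to_csv(path, index=False, float_format="%.17g")


def read_stride_intervals(path: str | Path) -> StrideIntervalFile:
    """Read a long-form stride/swing interval CSV into per-record tables.

    Left/right series may differ in length by at most one cycle; every
    interval must be strictly positive.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"record_id", "left_stride_s", "left_swing_s", "right_stride_s", "right_swing_s"}
    missing = sorted(needed - set(df.columns))
    if missing:
        raise ValidationError(f"{path}: stride-interval table missing columns {missing}")
    records = []
    for rid, grp in df.groupby("record_id", sort=False):
        grp = grp.sort_values("cycle") if "cycle" in grp.columns else grp
        series = {}
        for col in ("left_stride_s", "left_swing_s", "right_stride_s", "right_swing_s"):
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if np.any(vals <= 0):
                raise ValidationError(f"{path}: non-positive interval in {col} of record {rid}")
            series[col] = vals
        if abs(series["left_stride_s"].size - series["right_stride_s"].size) > 1:
            raise ValidationError(
                f"{path}: record {rid} left/right series lengths differ by more than 1"
            )
        records.append(StrideTable(
            left_stride_s=series["left_stride_s"],
            left_swing_s=series["left_swing_s"],
            right_stride_s=series["right_stride_s"],
            right_swing_s=series["right_swing_s"],
            record_id=str(rid),
            subject_id=str(grp["subject_id"].iloc[0]) if "subject_id" in grp.columns else str(rid),
            label=str(grp["label"].iloc[0]) if "label" in grp.columns else None,
        ))
    return StrideIntervalFile(records=records)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV; feature columns are headed by both
    the reference id and the canonical name (``f3:cv_stride_time_left``)."""
    df = table.data.copy()
    df.columns = [f"{c}:{FEATURE_NAMES[c]}" if c in FEATURE_NAMES else c for c in df.columns]
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table CSV back to canonical column order.

    Feature columns may be headed by the reference id (``f3``), the
    canonical name, or the combined ``f3:cv_stride_time_left`` form, in
    any order on disk.  Unknown feature-like columns are an error.
    """
    df = pd.read_csv(path)
    import re

    rename = {}
    for c in df.columns:
        base = c.split(":", 1)[0]
        if re.fullmatch(r"f\d+", base):
            rename[c] = base
        elif base in ("record_id", "subject_id", "label"):
            rename[c] = base
        elif c.split(":", 1)[-1] in NAME_TO_ID:
            rename[c] = NAME_TO_ID[c.split(":", 1)[-1]]
        else:
            raise ValidationError(f"{path}: unknown feature column {c!r}")
    df = df.rename(columns=rename)
    df["record_id"] = df["record_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    return FeatureTable(df)
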