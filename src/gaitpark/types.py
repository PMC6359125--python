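"""Core containers shared across the gait-analysis pipeline.

The pipeline's common currencies are:

* :class:`VGRFRecording` — one walking trial of vertical ground-reaction
  force (vGRF) signals: 8 force sensors under each foot plus the two
  per-foot totals, sampled on a uniform time base (100 Hz in the
  PhysioNet ``gaitpdb`` layout).
* :class:`GaitEvents` — heel-strike (force onset) and toe-off (force
  offset) instants per foot, the output of segmentation.
* :class:`StrideTable` — per-gait-cycle durations (stride, swing,
  stance, double support) and the short/long-swing pairing from which
  all clinical features are computed.
* :class:`FeatureTable` — records x 19 named clinical features, the
  input to feature selection and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

LABELS = ("healthy", "PD", "ALS", "HD")

#: Canonical feature identifiers, in table order. f1-f9 are coefficients
#: of variation / asymmetry percentages, f10-f18 means (percent or
#: seconds), f19 the mean gait-asymmetry percentage.
FEATURE_IDS: tuple[str, ...] = tuple(f"f{i}" for i in range(1, 20))

#: Human-readable snake_case aliases for the 19 features.
FEATURE_NAMES: dict[str, str] = {
    "f1": "cv_swing_pct_left",
    "f2": "cv_swing_time_left",
    "f3": "cv_stride_time_left",
    "f4": "cv_swing_pct_right",
    "f5": "cv_swing_time_right",
    "f6": "cv_stride_time_right",
    "f7": "cv_short_swing",
    "f8": "cv_long_swing",
    "f9": "cv_gait_asymmetry",
    "f10": "mean_swing_pct_left",
    "f11": "mean_swing_time_left",
    "f12": "mean_stride_time_left",
    "f13": "mean_swing_pct_right",
    "f14": "mean_swing_time_right",
    "f15": "mean_stride_time_right",
    "f16": "mean_double_support_pct",
    "f17": "mean_short_swing",
    "f18": "mean_long_swing",
    "f19": "mean_gait_asymmetry",
}

NAME_TO_ID: dict[str, str] = {v: k for k, v in FEATURE_NAMES.items()}

import re as _re

_FEATURE_RE = _re.compile(r"^f(\d+)$")


def _ordered_feature_columns(columns) -> list[str]:
    """All ``f<N>`` columns in numeric order (canonical f1..f19 plus any
    extra synthetic feature columns)."""
    feats = [(int(m.group(1)), c) for c in columns if (m := _FEATURE_RE.match(str(c)))]
    return [c for _, c in sorted(feats)]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class SegmentationError(RuntimeError):
    """Raised when no usable gait can be extracted from a recording."""


@dataclass
class VGRFRecording:
    """One vGRF walking trial.

    Forces are in Newtons, time in seconds.  ``block`` labels contiguous
    runs of samples: after turn-segment excision a recording consists of
    several disjoint blocks and no computation may bridge a cut.
    """

    subject_id: str
    label: str
    fs: float
    t: np.ndarray
    left_sensors: np.ndarray   # (n, 8)
    right_sensors: np.ndarray  # (n, 8)
    left_total: np.ndarray
    right_total: np.ndarray
    block: np.ndarray | None = None  # int block index per sample
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left_sensors = np.atleast_2d(np.asarray(self.left_sensors, dtype=float))
        self.right_sensors = np.atleast_2d(np.asarray(self.right_sensors, dtype=float))
        self.left_total = np.asarray(self.left_total, dtype=float)
        self.right_total = np.asarray(self.right_total, dtype=float)
        if self.block is None:
            self.block = np.zeros(self.t.size, dtype=int)
        else:
            self.block = np.asarray(self.block, dtype=int)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs

    def block_slices(self) -> list[np.ndarray]:
        """Index arrays of the contiguous blocks, in time order."""
        out = []
        for b in np.unique(self.block):
            out.append(np.flatnonzero(self.block == b))
        return out

    def validate(self) -> None:
        n = self.t.size
        if n < 2:
            raise ValidationError("recording must contain at least 2 samples")
        for name in ("left_total", "right_total", "block"):
            if getattr(self, name).shape[0] != n:
                raise ValidationError(f"{name} length {getattr(self, name).shape[0]} != time length {n}")
        for name in ("left_sensors", "right_sensors"):
            arr = getattr(self, name)
            if arr.shape != (n, 8):
                raise ValidationError(f"{name} must have shape (n, 8), got {arr.shape}")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("time vector must be strictly increasing")
        for name in ("left_sensors", "right_sensors", "left_total", "right_total"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite force values in {name}")
        if np.any(self.left_total < 0) or np.any(self.right_total < 0):
            raise ValidationError("total forces must be non-negative (clip at ingestion)")

    def copy(self) -> "VGRFRecording":
        return replace(
            self,
            t=self.t.copy(),
            left_sensors=self.left_sensors.copy(),
            right_sensors=self.right_sensors.copy(),
            left_total=self.left_total.copy(),
            right_total=self.right_total.copy(),
            block=self.block.copy(),
            meta=dict(self.meta),
        )


@dataclass
class ExclusionIntervals:
    """Half-open ``[start, end)`` time intervals to excise (e.g. turns)."""

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if not s < e:
                raise ValidationError(f"exclusion interval ({s}, {e}) must have start < end")
        self.intervals = self._normalize(self.intervals)

    @staticmethod
    def _normalize(ivs: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
        """Sort and merge overlapping/adjacent intervals."""
        if not ivs:
            return []
        ivs = sorted((float(s), float(e)) for s, e in ivs)
        merged = [ivs[0]]
        for s, e in ivs[1:]:
            ps, pe = merged[-1]
            if s <= pe:
                merged[-1] = (ps, max(pe, e))
            else:
                merged.append((s, e))
        return merged


@dataclass
class GaitEvents:
    """Alternating force-onset (heel-strike) / force-offset (toe-off)
    instants per foot, tagged by contiguous block.

    Within each foot and block the sequence is hs, to, hs, to, ...
    starting with a heel strike (leading incomplete phases are dropped
    by the detector).
    """

    left_heel_strikes: np.ndarray
    left_toe_offs: np.ndarray
    right_heel_strikes: np.ndarray
    right_toe_offs: np.ndarray
    left_block: np.ndarray | None = None        # block id per left heel strike
    right_block: np.ndarray | None = None
    left_toe_block: np.ndarray | None = None    # block id per left toe-off
    right_toe_block: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("left_heel_strikes", "left_toe_offs", "right_heel_strikes", "right_toe_offs"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for side in ("left", "right"):
            if getattr(self, f"{side}_block") is None:
                setattr(self, f"{side}_block",
                        np.zeros(getattr(self, f"{side}_heel_strikes").size, dtype=int))
            if getattr(self, f"{side}_toe_block") is None:
                setattr(self, f"{side}_toe_block",
                        np.zeros(getattr(self, f"{side}_toe_offs").size, dtype=int))
            setattr(self, f"{side}_block", np.asarray(getattr(self, f"{side}_block"), dtype=int))
            setattr(self, f"{side}_toe_block",
                    np.asarray(getattr(self, f"{side}_toe_block"), dtype=int))

    def foot(self, side: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(heel_strikes, toe_offs, hs_block, toe_block) for one foot."""
        if side not in ("left", "right"):
            raise ValueError(f"unknown side {side!r}")
        return (getattr(self, f"{side}_heel_strikes"), getattr(self, f"{side}_toe_offs"),
                getattr(self, f"{side}_block"), getattr(self, f"{side}_toe_block"))


@dataclass
class StrideTable:
    """Per-cycle gait durations for one record.

    Per foot: stride time (heel-strike to next heel-strike of the same
    foot), swing time (toe-off to next heel-strike), stance time and
    swing percentage.  Per left-anchored cycle: double-support
    percentage and the short/long swing pair (ssw = smaller of the two
    feet's swing times in that cycle, lsw = larger, under the default
    per-cycle pairing rule).

    ``double_support_pct``, ``ssw_s`` and ``lsw_s`` may be ``None`` when
    the table was built from interval series that do not determine them.
    """

    left_stride_s: np.ndarray
    left_swing_s: np.ndarray
    right_stride_s: np.ndarray
    right_swing_s: np.ndarray
    left_stance_s: np.ndarray | None = None
    right_stance_s: np.ndarray | None = None
    double_support_pct: np.ndarray | None = None
    ssw_s: np.ndarray | None = None
    lsw_s: np.ndarray | None = None
    record_id: str = ""
    subject_id: str = ""
    label: str | None = None
    n_dropped_cycles: int = 0

    def __post_init__(self) -> None:
        for name in ("left_stride_s", "left_swing_s", "right_stride_s", "right_swing_s",
                     "left_stance_s", "right_stance_s", "double_support_pct", "ssw_s", "lsw_s"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        self.validate()
        if self.ssw_s is None and self.lsw_s is None:
            self._assign_short_long()

    def _assign_short_long(self) -> None:
        """Default short/long swing pairing: pair left cycle i with right
        cycle i (series aligned on overlapping strides by the caller) and
        take the per-cycle min/max."""
        n = min(self.left_swing_s.size, self.right_swing_s.size)
        if n == 0:
            self.ssw_s = np.empty(0)
            self.lsw_s = np.empty(0)
            return
        l, r = self.left_swing_s[:n], self.right_swing_s[:n]
        self.ssw_s = np.minimum(l, r)
        self.lsw_s = np.maximum(l, r)

    def validate(self) -> None:
        for side in ("left", "right"):
            stride = getattr(self, f"{side}_stride_s")
            swing = getattr(self, f"{side}_swing_s")
            if np.any(stride <= 0) or np.any(swing <= 0):
                raise ValidationError("stride and swing times must be positive")
            n = min(stride.size, swing.size)
            if np.any(swing[:n] >= stride[:n]):
                raise ValidationError("swing time must be strictly less than stride time")
        if self.double_support_pct is not None and self.double_support_pct.size:
            if np.any(self.double_support_pct < 0) or np.any(self.double_support_pct >= 100):
                raise ValidationError("double support percentage out of [0, 100)")
        if self.ssw_s is not None and self.lsw_s is not None and self.ssw_s.size:
            if np.any(self.ssw_s > self.lsw_s + 1e-12):
                raise ValidationError("short swing must not exceed long swing")

    @property
    def left_swing_pct(self) -> np.ndarray:
        n = min(self.left_swing_s.size, self.left_stride_s.size)
        return 100.0 * self.left_swing_s[:n] / self.left_stride_s[:n]

    @property
    def right_swing_pct(self) -> np.ndarray:
        n = min(self.right_swing_s.size, self.right_stride_s.size)
        return 100.0 * self.right_swing_s[:n] / self.right_stride_s[:n]

    @property
    def n_cycles(self) -> int:
        return min(self.left_stride_s.size, self.right_stride_s.size)


@dataclass
class StrideIntervalFile:
    """Per-record stride/swing interval series read from a delimited
    table, bypassing raw-signal segmentation."""

    records: list[StrideTable]


@dataclass
class FeatureTable:
    """Records x 19 clinical features plus label and subject key.

    Backed by a :class:`pandas.DataFrame` with columns ``record_id``,
    ``subject_id``, ``label`` and ``f1`` ... ``f19`` (NaN marks a
    flagged-missing feature value).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("record_id", "subject_id", "label") if c not in self.data.columns]
        if missing:
            raise ValidationError(f"feature table missing columns {missing}")
        feats = _ordered_feature_columns(self.data.columns)
        if not feats:
            raise ValidationError("feature table has no feature columns f1..f19")
        if self.data["record_id"].duplicated().any():
            raise ValidationError("duplicated record_id in feature table")
        # canonical column order
        self.data = self.data[["record_id", "subject_id", "label"] + feats].reset_index(drop=True)

    @property
    def feature_ids(self) -> list[str]:
        return _ordered_feature_columns(self.data.columns)

    def X(self, features: Sequence[str] | None = None) -> np.ndarray:
        cols = list(features) if features is not None else self.feature_ids
        return self.data[cols].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)
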