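"""Signal conditioning ahead of gait-cycle segmentation.

Three steps, mirroring standard practice for over-ground vGRF protocols:

1. trim a fixed margin (default 20 s) from both ends of the trial to
   discard gait initiation and termination effects;
2. excise listed exclusion intervals (turn-around segments of the
   walkway round trips); the surviving data are kept as separate
   contiguous blocks and never concatenated across a cut;
3. run a 10-point median filter over the two per-foot total-force
   channels to suppress swing-phase fluctuation spikes.

Turn intervals are supplied explicitly (they were identified manually in
the protocols this pipeline targets); :func:`propose_turn_intervals`
offers a stride-time-outlier heuristic that proposes candidate intervals
for review but is never applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import ExclusionIntervals, ValidationError, VGRFRecording

__all__ = [
    "PreprocessConfig",
    "trim_recording",
    "median_filter_totals",
    "preprocess",
    "propose_turn_intervals",
    "running_median",
]


@dataclass
class PreprocessConfig:
    trim_seconds: float = 20.0
    median_window: int = 10
    exclusion: ExclusionIntervals | None = None

    def __post_init__(self) -> None:
        if self.trim_seconds < 0:
            raise ValidationError("trim_seconds must be >= 0")
        if self.median_window < 1:
            raise ValidationError("median_window must be >= 1")


def trim_recording(rec: VGRFRecording, cfg: PreprocessConfig) -> VGRFRecording:
    """Drop the first and last ``trim_seconds`` and all exclusion
    intervals; surviving segments become separately indexed blocks."""
    if 2 * cfg.trim_seconds >= rec.duration:
        raise ValidationError(
            f"recording of {rec.duration:.1f}s too short to trim {cfg.trim_seconds}s per end"
        )
    t0 = rec.t[0]
    t_end = rec.t[-1] + 1.0 / rec.fs  # exclusive end of the sampled span
    keep = (rec.t >= t0 + cfg.trim_seconds) & (rec.t < t_end - cfg.trim_seconds)
    if cfg.exclusion is not None:
        for s, e in cfg.exclusion.intervals:
            keep &= ~((rec.t >= s) & (rec.t < e))
    if keep.sum() < 2:
        raise ValidationError("trimming/exclusion removed the entire recording")

    idx = np.flatnonzero(keep)
    t = rec.t[idx]
    # new block whenever a cut produced a gap in the time base
    gaps = np.diff(t) > 1.5 / rec.fs
    block = np.concatenate([[0], np.cumsum(gaps)]).astype(int)
    return replace(
        rec,
        t=t,
        left_sensors=rec.left_sensors[idx],
        right_sensors=rec.right_sensors[idx],
        left_total=rec.left_total[idx],
        right_total=rec.right_total[idx],
        block=block,
        meta=dict(rec.meta),
    )


def running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with left bias for even windows.

    A window of ``w`` covers offsets ``[-w//2, w - w//2 - 1]`` (for
    w=10: 5 samples before, 4 after); even counts yield the mean of the
    two middle order statistics; edges use shrinking windows.  Output
    length equals input length.
    """
    if window < 1:
        raise ValidationError("median window must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size
    if window > n:
        raise ValidationError(f"median window {window} exceeds series length {n}")
    if window == 1 or n == 0:
        return x.copy()
    lo_off = window // 2
    hi_off = window - lo_off - 1
    out = np.empty(n)
    # interior: full windows, vectorized
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(x, window)
        out[lo_off:n - hi_off] = np.median(sw, axis=1)
    # edges: shrinking windows
    for i in range(min(lo_off, n)):
        out[i] = np.median(x[0:i + hi_off + 1])
    for i in range(max(n - hi_off, 0), n):
        out[i] = np.median(x[i - lo_off:n])
    return out


def median_filter_totals(rec: VGRFRecording, window: int = 10) -> VGRFRecording:
    """Median-filter the two total-force channels, per contiguous block
    (never across an exclusion cut); sensor channels are untouched."""
    if window < 1:
        raise ValidationError("median window must be >= 1")
    lt, rt = rec.left_total.copy(), rec.right_total.copy()
    for idx in rec.block_slices():
        w = min(window, idx.size)
        lt[idx] = running_median(rec.left_total[idx], w)
        rt[idx] = running_median(rec.right_total[idx], w)
    return replace(rec, left_total=lt, right_total=rt,
                   t=rec.t.copy(), left_sensors=rec.left_sensors.copy(),
                   right_sensors=rec.right_sensors.copy(), block=rec.block.copy(),
                   meta=dict(rec.meta))


def preprocess(rec: VGRFRecording, cfg: PreprocessConfig | None = None) -> VGRFRecording:
    """Trim, excise exclusions and median-filter in one call."""
    cfg = cfg or PreprocessConfig()
    return median_filter_totals(trim_recording(rec, cfg), cfg.median_window)


def propose_turn_intervals(
    stride_onsets_s: np.ndarray,
    mad_factor: float = 3.0,
    pad_s: float = 0.5,
) -> ExclusionIntervals:
    """Propose candidate turn intervals from stride-time outliers.

    Strides whose duration deviates more than ``mad_factor`` median
    absolute deviations from the median stride are flagged; consecutive
    flagged strides are merged into one interval, padded by ``pad_s``.
    The result is a *proposal for review* — the pipeline never applies
    it without the caller passing it back explicitly as an exclusion.
    """
    onsets = np.asarray(stride_onsets_s, dtype=float)
    if onsets.size < 3:
        return ExclusionIntervals([])
    strides = np.diff(onsets)
    med = np.median(strides)
    mad = np.median(np.abs(strides - med))
    scale = 1.4826 * mad if mad > 0 else 1e-9
    flagged = np.abs(strides - med) > mad_factor * scale
    intervals: list[tuple[float, float]] = []
    i = 0
    while i < flagged.size:
        if flagged[i]:
            j = i
            while j + 1 < flagged.size and flagged[j + 1]:
                j += 1
            intervals.append((onsets[i] - pad_s, onsets[j + 1] + pad_s))
            i = j + 1
        else:
            i += 1
    return ExclusionIntervals(intervals)
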