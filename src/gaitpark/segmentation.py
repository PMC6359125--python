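"""Stance/swing phase detection and gait-cycle table construction.

Detection operates on the two median-filtered total-force channels: a
foot is in stance while its total force is at or above a threshold τ and
in swing below it.  The default τ is *relative* — 2% of the 95th
percentile of that foot's filtered total within the block — which makes
detection invariant to body weight; an absolute threshold in Newtons is
available.  Spurious micro-phases (force dropouts, residual swing
noise) shorter than ``min_phase_s`` are merged into their neighbours
before events are extracted.

A gait cycle runs from one heel strike (force onset) to the next of the
same foot.  Cycles are anchored on left-foot heel strikes; the right
cycle whose onset falls inside a left cycle is its pair for the
short/long-swing assignment and for double-support accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GaitEvents, SegmentationError, StrideIntervalFile, StrideTable, ValidationError, VGRFRecording

__all__ = [
    "SegmentationConfig",
    "detect_events",
    "build_stride_table",
    "segment",
    "stride_table_from_intervals",
]


@dataclass
class SegmentationConfig:
    threshold_mode: str = "relative"       # {"relative", "absolute"}
    relative_fraction: float = 0.02        # τ as fraction of the 95th force percentile
    absolute_newtons: float = 20.0         # τ in N when mode == "absolute"
    min_phase_s: float = 0.05              # phases shorter than this merge into a neighbour
    stride_bounds_s: tuple[float, float] | None = None  # optional physiologic filter
    short_long_mode: str = "per_cycle"     # {"per_cycle", "fixed_foot"}

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("relative", "absolute"):
            raise ValidationError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0 < self.relative_fraction < 0.5:
            raise ValidationError("relative_fraction must lie in (0, 0.5)")
        if self.min_phase_s < 0:
            raise ValidationError("min_phase_s must be >= 0")
        if self.short_long_mode not in ("per_cycle", "fixed_foot"):
            raise ValidationError(f"unknown short_long_mode {self.short_long_mode!r}")


def _runs(stance: np.ndarray) -> list[list]:
    """Run-length encode a boolean array as mutable [state, start, stop)."""
    change = np.flatnonzero(np.diff(stance.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [stance.size]])
    return [[bool(stance[a]), int(a), int(b)] for a, b in zip(starts, stops)]


def _merge_short_runs(runs: list[list], min_len: int) -> list[list]:
    """Flip interior runs shorter than ``min_len`` into their
    neighbours' state, shortest first, re-merging after each flip.
    Leading/trailing short runs are left; incomplete edge phases are
    dropped later anyway."""
    runs = [list(r) for r in runs]
    while True:
        interior = [(r[2] - r[1], i) for i, r in enumerate(runs[1:-1], start=1)]
        short = [(ln, i) for ln, i in interior if ln < min_len]
        if not short:
            return runs
        _, i = min(short)
        runs[i][0] = not runs[i][0]
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged


def _detect_foot(t: np.ndarray, force: np.ndarray, cfg: SegmentationConfig,
                 fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Heel-strike and toe-off times for one foot within one block.

    Returns (heel_strikes, toe_offs) with the sequence starting at the
    first complete heel strike and alternating hs, to, hs, to, ...
    """
    if cfg.threshold_mode == "relative":
        tau = cfg.relative_fraction * np.percentile(force, 95)
    else:
        tau = cfg.absolute_newtons
    stance = force >= tau
    if stance.all() or (~stance).all():
        return np.empty(0), np.empty(0)
    runs = _runs(stance)
    min_len = max(1, int(round(cfg.min_phase_s * fs)))
    runs = _merge_short_runs(runs, min_len)

    hs, to = [], []
    for state, start, _ in runs[1:]:  # transitions only (skip leading edge run)
        if state:
            hs.append(t[start])
        else:
            to.append(t[start])
    if not hs:
        return np.empty(0), np.empty(0)
    # start the sequence at the first heel strike; toe-offs before it
    # belong to the incomplete leading stance phase
    to = [x for x in to if x > hs[0]]
    # enforce alternation hs_i < to_i < hs_{i+1}; toe count <= hs count
    to = to[: len(hs)]
    return np.asarray(hs), np.asarray(to)


def detect_events(rec: VGRFRecording, cfg: SegmentationConfig | None = None) -> GaitEvents:
    """Detect per-foot heel-strike/toe-off events on the (filtered)
    total-force channels, independently per contiguous block.

    Raises ``SegmentationError`` when no threshold crossings exist on
    either foot ("no gait detected").
    """
    cfg = cfg or SegmentationConfig()
    sides = {"left": rec.left_total, "right": rec.right_total}
    out: dict[str, list] = {s: [[], [], [], []] for s in sides}
    for idx in rec.block_slices():
        block_id = int(rec.block[idx[0]])
        for side, force in sides.items():
            hs, to = _detect_foot(rec.t[idx], force[idx], cfg, rec.fs)
            out[side][0].extend(hs)
            out[side][1].extend(to)
            out[side][2].extend([block_id] * hs.size)
            out[side][3].extend([block_id] * to.size)
    if not out["left"][0] and not out["right"][0]:
        raise SegmentationError("no gait detected: total force never crosses the threshold")
    return GaitEvents(
        left_heel_strikes=out["left"][0],
        left_toe_offs=out["left"][1],
        right_heel_strikes=out["right"][0],
        right_toe_offs=out["right"][1],
        left_block=out["left"][2],
        right_block=out["right"][2],
        left_toe_block=out["left"][3],
        right_toe_block=out["right"][3],
    )


def build_stride_table(events: GaitEvents, cfg: SegmentationConfig | None = None,
                       record_id: str = "", subject_id: str = "",
                       label: str | None = None) -> StrideTable:
    """Build the per-cycle stride table from detected events.

    stride = heel-strike to next heel-strike of the same foot (within a
    block); stance = heel-strike to the toe-off inside the cycle; swing
    = that toe-off to the next heel-strike.  Double support per
    left-anchored cycle is the total time both feet are simultaneously
    in stance, as a percentage of that cycle's stride time, computed by
    exact interval intersection.
    """
    cfg = cfg or SegmentationConfig()
    per_foot: dict[str, dict] = {}
    for side in ("left", "right"):
        hs, to, blk, to_blk = events.foot(side)
        if hs.size < 2:
            raise SegmentationError(f"fewer than 2 heel strikes on the {side} foot")
        onsets, strides, swings, stances, blocks = [], [], [], [], []
        stance_ivs = []  # all stance intervals for double-support accounting
        for b in np.unique(blk):
            h = hs[blk == b]
            t_b = np.sort(to[to_blk == b]) if to.size else np.empty(0)
            for i in range(h.size - 1):
                inside = t_b[(t_b > h[i]) & (t_b < h[i + 1])]
                if inside.size != 1:
                    continue  # malformed cycle (missed or extra toe-off)
                t_off = float(inside[0])
                onsets.append(float(h[i]))
                strides.append(float(h[i + 1] - h[i]))
                stances.append(t_off - float(h[i]))
                swings.append(float(h[i + 1]) - t_off)
                blocks.append(int(b))
                stance_ivs.append((float(h[i]), t_off, int(b)))
            # trailing stance of the last heel strike (for DS overlap only)
            trailing = t_b[t_b > h[-1]]
            if trailing.size:
                stance_ivs.append((float(h[-1]), float(trailing[0]), int(b)))
        per_foot[side] = {
            "onset": np.asarray(onsets), "stride": np.asarray(strides),
            "swing": np.asarray(swings), "stance": np.asarray(stances),
            "block": np.asarray(blocks, dtype=int), "stance_ivs": stance_ivs,
        }

    n_dropped = 0
    if cfg.stride_bounds_s is not None:
        lo, hi = cfg.stride_bounds_s
        for side in ("left", "right"):
            f = per_foot[side]
            ok = (f["stride"] >= lo) & (f["stride"] <= hi)
            n_dropped += int((~ok).sum())
            for k in ("onset", "stride", "swing", "stance", "block"):
                f[k] = f[k][ok]

    L, R = per_foot["left"], per_foot["right"]
    if L["stride"].size == 0 or R["stride"].size == 0:
        raise SegmentationError("no complete gait cycles on one foot")

    # pair each left cycle with the right cycle whose onset falls inside it
    ssw, lsw, ds_pct = [], [], []
    for i in range(L["stride"].size):
        a, b = L["onset"][i], L["onset"][i] + L["stride"][i]
        blk = L["block"][i]
        j = np.flatnonzero((R["onset"] >= a) & (R["onset"] < b) & (R["block"] == blk))
        if j.size == 1:
            sw_l, sw_r = L["swing"][i], R["swing"][j[0]]
            ssw.append(min(sw_l, sw_r))
            lsw.append(max(sw_l, sw_r))
        # double support: overlap of left stance [a, a+stance) with all
        # right stance intervals, clipped to the cycle window
        ls_start, ls_end = a, a + L["stance"][i]
        overlap = 0.0
        for rs, re, rb in R["stance_ivs"]:
            if rb != blk:
                continue
            overlap += max(0.0, min(ls_end, re, b) - max(ls_start, rs, a))
        ds_pct.append(100.0 * overlap / L["stride"][i])

    ssw_a, lsw_a = np.asarray(ssw), np.asarray(lsw)
    if cfg.short_long_mode == "fixed_foot" and ssw_a.size:
        # assign the whole series to the foot with the smaller mean swing
        n = min(L["swing"].size, R["swing"].size)
        if np.mean(L["swing"]) <= np.mean(R["swing"]):
            ssw_a, lsw_a = L["swing"][:n], R["swing"][:n]
        else:
            ssw_a, lsw_a = R["swing"][:n], L["swing"][:n]

    return StrideTable(
        left_stride_s=L["stride"], left_swing_s=L["swing"],
        right_stride_s=R["stride"], right_swing_s=R["swing"],
        left_stance_s=L["stance"], right_stance_s=R["stance"],
        double_support_pct=np.asarray(ds_pct),
        ssw_s=ssw_a, lsw_s=lsw_a,
        record_id=record_id, subject_id=subject_id, label=label,
        n_dropped_cycles=n_dropped,
    )


def segment(rec: VGRFRecording, cfg: SegmentationConfig | None = None) -> StrideTable:
    """Detect events and build the stride table in one call."""
    cfg = cfg or SegmentationConfig()
    return build_stride_table(
        detect_events(rec, cfg), cfg,
        record_id=rec.subject_id, subject_id=rec.subject_id, label=rec.label,
    )


def stride_table_from_intervals(intervals: StrideIntervalFile) -> list[StrideTable]:
    """Stride tables built directly from interval series (bypassing
    segmentation).  Double support is not derivable from stride/swing
    intervals alone and stays absent; the dependent feature (mean double
    support %) is reported as missing downstream."""
    for st in intervals.records:
        st.validate()
    return intervals.records
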