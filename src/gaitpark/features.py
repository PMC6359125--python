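"""The 19 clinical gait features.

All features derive from per-cycle stride and swing durations:

* f1–f6: coefficients of variation (CV, in %) of swing percentage,
  swing time and stride time, for the left then the right foot;
* f7/f8: CV of the short-swing (SSW) and long-swing (LSW) series —
  per cycle, the smaller and larger of the two feet's swing times;
* f9: the CV gait-asymmetry, ``100·|ln(f7/f8)|``;
* f10–f15: means of the same six per-foot series (percent or seconds);
* f16: mean double-support time as % of stride;
* f17/f18: means of the SSW and LSW series (seconds);
* f19: mean gait asymmetry — the per-cycle ``100·|ln(ssw/lsw)|``
  averaged over cycles (a ratio-of-means variant is available).

CV uses the sample (n−1) standard deviation.  A feature whose inputs
are unavailable (e.g. double support when only interval series were
provided) or undefined (f9 with a zero CV) is flagged missing as NaN,
never silently zeroed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import FEATURE_IDS, FeatureTable, StrideTable, ValidationError

__all__ = [
    "coefficient_of_variation",
    "gait_asymmetry",
    "extract_features",
    "features_table",
]


def coefficient_of_variation(x: np.ndarray) -> float:
    """``100 · sd(x) / mean(x)`` with the sample (n−1) standard
    deviation; requires at least two values and a positive mean."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("CV requires at least 2 values")
    m = x.mean()
    if m <= 0:
        raise ValidationError("CV requires a positive mean")
    return float(100.0 * x.std(ddof=1) / m)


def gait_asymmetry(short: float, long: float) -> float:
    """``100 · |ln(short / long)|`` — symmetric log-ratio imbalance."""
    if short <= 0 or long <= 0:
        raise ValidationError("gait asymmetry requires positive swing times")
    return float(100.0 * abs(np.log(short / long)))


def extract_features(st: StrideTable, ga_mode: str = "mean_of_cycles") -> dict[str, float]:
    """Compute f1..f19 from a stride table.

    ``ga_mode`` selects the f19 definition: ``"mean_of_cycles"``
    (default) averages the per-cycle asymmetry ``100·|ln(ssw_i/lsw_i)|``;
    ``"ratio_of_means"`` computes ``100·|ln(mean ssw / mean lsw)|``.
    Missing or undefined features are NaN.
    """
    if ga_mode not in ("mean_of_cycles", "ratio_of_means"):
        raise ValidationError(f"unknown ga_mode {ga_mode!r}")
    for side in ("left", "right"):
        if getattr(st, f"{side}_stride_s").size < 2:
            raise ValidationError(f"need at least 2 cycles on the {side} foot")

    f: dict[str, float] = {k: float("nan") for k in FEATURE_IDS}

    f["f1"] = coefficient_of_variation(st.left_swing_pct)
    f["f2"] = coefficient_of_variation(st.left_swing_s)
    f["f3"] = coefficient_of_variation(st.left_stride_s)
    f["f4"] = coefficient_of_variation(st.right_swing_pct)
    f["f5"] = coefficient_of_variation(st.right_swing_s)
    f["f6"] = coefficient_of_variation(st.right_stride_s)

    f["f10"] = float(np.mean(st.left_swing_pct))
    f["f11"] = float(np.mean(st.left_swing_s))
    f["f12"] = float(np.mean(st.left_stride_s))
    f["f13"] = float(np.mean(st.right_swing_pct))
    f["f14"] = float(np.mean(st.right_swing_s))
    f["f15"] = float(np.mean(st.right_stride_s))

    if st.double_support_pct is not None and st.double_support_pct.size:
        f["f16"] = float(np.mean(st.double_support_pct))

    if st.ssw_s is not None and st.ssw_s.size >= 2:
        f["f7"] = coefficient_of_variation(st.ssw_s)
        f["f8"] = coefficient_of_variation(st.lsw_s)
        if f["f7"] > 0 and f["f8"] > 0:
            f["f9"] = 100.0 * abs(np.log(f["f7"] / f["f8"]))
        f["f17"] = float(np.mean(st.ssw_s))
        f["f18"] = float(np.mean(st.lsw_s))
        if ga_mode == "mean_of_cycles":
            f["f19"] = float(np.mean(
                [gait_asymmetry(s, l) for s, l in zip(st.ssw_s, st.lsw_s)]
            ))
        else:
            f["f19"] = gait_asymmetry(f["f17"], f["f18"])
    return f


def features_table(tables: list[StrideTable], ga_mode: str = "mean_of_cycles") -> FeatureTable:
    """One feature vector per stride table (one record per preprocessed
    walking trial, all retained blocks pooled)."""
    rows = []
    for i, st in enumerate(tables):
        row = extract_features(st, ga_mode=ga_mode)
        row["record_id"] = st.record_id or f"rec{i}"
        row["subject_id"] = st.subject_id or row["record_id"]
        row["label"] = st.label
        rows.append(row)
    df = pd.DataFrame(rows)
    return FeatureTable(df)
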