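"""Seeded synthetic gait cohorts with ground truth.

The generator produces both stride-interval tables and rendered raw
vGRF-like recordings so every pipeline stage can be validated closed
loop against known parameters:

* stride times are truncated-normal (mean ``mean_stride_s``, sd
  ``stride_cv_pct``·mean/100, truncated at ±4 sd and positive) —
  elevated stride/swing variability and left/right swing asymmetry are
  the gait signatures of the parkinsonian class this emulates;
* swing times are ``swing_fraction``·stride with per-foot
  multiplicative asymmetry offsets ``exp(±asymmetry_pct/200)`` (so the
  two feet's swing-time ratio is ``exp(-asymmetry_pct/100)`` and the
  log-asymmetry statistic recovers ``asymmetry_pct`` exactly when CVs
  are zero) plus multiplicative swing-CV noise;
* stance force is rendered as a double-peaked profile (heel-strike and
  push-off bumps at 25% / 75% of stance) scaled by body weight, with
  zero-mean swing-phase noise exercising the median filter, and
  optional standing pads and an irregular turn block with its true
  exclusion interval.

The class presets are illustrative test conditions — a "healthy-like"
regular gait and a "PD-like" gait with raised variability and
asymmetry — not claims about any study population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ExclusionIntervals, FeatureTable, StrideTable, ValidationError, VGRFRecording

__all__ = [
    "GaitClassParams",
    "HEALTHY_LIKE",
    "PD_LIKE",
    "simulate_strides",
    "render_vgrf",
    "simulate_feature_table",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GaitClassParams:
    """Statistical gait profile of one class of walkers."""

    mean_stride_s: float = 1.10
    swing_fraction: float = 0.38       # swing / stride, before asymmetry offsets
    stride_cv_pct: float = 2.0
    swing_cv_pct: float = 2.0
    asymmetry_pct: float = 2.0         # target 100·|ln(ssw/lsw)|
    body_weight_n: float = 800.0
    peak_positions: tuple[float, float] = (0.25, 0.75)   # as fractions of stance
    peak_amplitudes: tuple[float, float] = (1.10, 1.05)  # x body weight
    peak_width_frac: float = 0.13      # Gaussian sd as fraction of stance
    swing_noise_sd_n: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_stride_s <= 0:
            raise ValidationError("mean_stride_s must be positive")
        if not 0.2 < self.swing_fraction < 0.6:
            raise ValidationError("swing_fraction must lie in (0.2, 0.6)")
        if min(self.stride_cv_pct, self.swing_cv_pct, self.asymmetry_pct,
               self.swing_noise_sd_n) < 0:
            raise ValidationError("CVs, asymmetry and noise must be >= 0")
        hi = self.swing_fraction * np.exp(self.asymmetry_pct / 200.0)
        if hi >= 0.95:
            raise ValidationError("asymmetry offset pushes swing too close to stride")


HEALTHY_LIKE = GaitClassParams(mean_stride_s=1.10, stride_cv_pct=2.0,
                               swing_cv_pct=2.0, asymmetry_pct=2.0)
PD_LIKE = GaitClassParams(mean_stride_s=1.15, stride_cv_pct=5.0,
                          swing_cv_pct=5.0, asymmetry_pct=8.0)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated at ±4 sd and at zero."""
    if sd == 0:
        return np.full(n, mean)
    lo = max(mean - 4 * sd, 1e-9)
    hi = mean + 4 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_strides(
    params: GaitClassParams,
    n_cycles: int,
    seed: int = 0,
    record_id: str = "sim",
    label: str | None = None,
) -> StrideTable:
    """Draw a per-cycle stride table with known statistics.

    The left foot is the short-swing foot (offset ``exp(-a/200)``), the
    right the long-swing foot; with zero CVs the per-cycle swing ratio
    is exactly ``exp(-asymmetry_pct/100)``.  Event times for rendering
    are attached as ``meta`` arrays on the returned table.
    """
    if n_cycles < 2:
        raise ValidationError("need at least 2 cycles")
    rng = np.random.default_rng(seed)
    sd = params.stride_cv_pct * params.mean_stride_s / 100.0

    feet: dict[str, dict[str, np.ndarray]] = {}
    offsets = {"left": np.exp(-params.asymmetry_pct / 200.0),
               "right": np.exp(+params.asymmetry_pct / 200.0)}
    for side in ("left", "right"):
        strides = _truncated_normal(rng, params.mean_stride_s, sd, n_cycles)
        frac = params.swing_fraction * offsets[side]
        swing_sd = params.swing_cv_pct * frac / 100.0
        swings = _truncated_normal(rng, frac, swing_sd, n_cycles) * strides
        bad = swings >= strides
        for _ in range(100):
            if not bad.any():
                break
            swings[bad] = _truncated_normal(rng, frac, swing_sd, int(bad.sum())) * strides[bad]
            bad = swings >= strides
        if bad.any():
            raise ValidationError("infeasible parameters: swing >= stride persists")
        feet[side] = {"stride": strides, "swing": swings}

    # event times: left heel strikes at cumulative strides from 0,
    # right offset by half the mean stride
    lt = {"hs": np.concatenate([[0.0], np.cumsum(feet["left"]["stride"])])}
    rt = {"hs": params.mean_stride_s / 2.0 +
                np.concatenate([[0.0], np.cumsum(feet["right"]["stride"])])}
    lt["to"] = lt["hs"][1:] - feet["left"]["swing"]
    rt["to"] = rt["hs"][1:] - feet["right"]["swing"]

    st = StrideTable(
        left_stride_s=feet["left"]["stride"], left_swing_s=feet["left"]["swing"],
        right_stride_s=feet["right"]["stride"], right_swing_s=feet["right"]["swing"],
        left_stance_s=feet["left"]["stride"] - feet["left"]["swing"],
        right_stance_s=feet["right"]["stride"] - feet["right"]["swing"],
        record_id=record_id, subject_id=record_id, label=label,
    )
    # double support from exact event-interval intersection
    st.double_support_pct = _double_support(lt, rt, st.left_stride_s, st.left_stance_s)
    st.events = {"left_hs": lt["hs"], "left_to": lt["to"],
                 "right_hs": rt["hs"], "right_to": rt["to"]}
    return st


def _double_support(lt: dict, rt: dict, l_stride: np.ndarray, l_stance: np.ndarray) -> np.ndarray:
    """Per left cycle: overlap of left stance with right stance
    intervals, as % of stride."""
    right_stance = list(zip(rt["hs"][:-1], rt["to"]))
    ds = np.empty(l_stride.size)
    for i in range(l_stride.size):
        a = lt["hs"][i]
        ls_end = a + l_stance[i]
        b = a + l_stride[i]
        total = 0.0
        for rs, re in right_stance:
            re = min(re, b)
            total += max(0.0, min(ls_end, re) - max(a, rs))
        ds[i] = 100.0 * total / l_stride[i]
    return ds


def render_vgrf(
    st: StrideTable,
    params: GaitClassParams,
    fs: float = 100.0,
    seed: int = 0,
    pad_s: float = 0.0,
    turn: tuple[float, float] | None = None,
    profile: str = "double_peak",
) -> tuple[VGRFRecording, ExclusionIntervals]:
    """Render a stride table as a raw vGRF recording.

    Each stance interval carries the double-peaked force profile scaled
    by body weight (or a flat square profile with ``profile="square"``
    — segmentation must not depend on the stance shape); swing carries
    zero-mean Gaussian noise of sd ``swing_noise_sd_n`` clipped at zero.
    ``pad_s`` prepends/appends quiet standing (both feet loaded at half
    body weight); ``turn`` = (start_s, duration_s) overwrites that span
    with irregular half-loaded force, returning its true exclusion
    interval.  Ground-truth event times shift by ``pad_s``.
    """
    if fs < 50:
        raise ValidationError("rendering requires fs >= 50 Hz")
    ev = getattr(st, "events", None)
    if ev is None:
        raise ValidationError("stride table carries no event times (use simulate_strides)")
    rng = np.random.default_rng(seed)

    t_end = max(ev["left_hs"][-1], ev["right_hs"][-1]) + 2 * pad_s
    n = int(np.ceil(t_end * fs)) + 1
    t = np.arange(n) / fs
    totals = {"left": np.zeros(n), "right": np.zeros(n)}

    for side in ("left", "right"):
        hs = ev[f"{side}_hs"] + pad_s
        to = ev[f"{side}_to"] + pad_s
        for i in range(to.size):
            s0, s1 = hs[i], to[i]
            if (s1 - s0) * fs < 4:
                raise ValidationError("stance shorter than 4 samples at this fs")
            i0, i1 = int(np.ceil(s0 * fs)), int(np.floor((s1 - 1e-9) * fs)) + 1
            seg_t = t[i0:i1]
            if profile == "square":
                totals[side][i0:i1] = params.body_weight_n
            else:
                phase = (seg_t - s0) / (s1 - s0)
                w = params.peak_width_frac
                bump1 = params.peak_amplitudes[0] * np.exp(-0.5 * ((phase - params.peak_positions[0]) / w) ** 2)
                bump2 = params.peak_amplitudes[1] * np.exp(-0.5 * ((phase - params.peak_positions[1]) / w) ** 2)
                totals[side][i0:i1] = params.body_weight_n * (bump1 + bump2)
        if params.swing_noise_sd_n > 0:
            swing_mask = totals[side] == 0
            noise = rng.normal(0.0, params.swing_noise_sd_n, int(swing_mask.sum()))
            totals[side][swing_mask] = np.clip(noise, 0, None)

    if pad_s > 0:  # quiet standing at both ends
        pad_n = int(pad_s * fs)
        for side in ("left", "right"):
            totals[side][:pad_n] = params.body_weight_n / 2.0
            totals[side][n - pad_n:] = params.body_weight_n / 2.0

    exclusion = ExclusionIntervals([])
    if turn is not None:
        t0, dur = turn
        i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
        for side in ("left", "right"):
            irregular = params.body_weight_n / 2.0 * (
                1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t[i0:i1]) +
                rng.normal(0, 0.1, i1 - i0)
            )
            totals[side][i0:i1] = np.clip(irregular, 0, None)
        exclusion = ExclusionIntervals([(t0, t0 + dur)])

    # the 16 per-sensor channels are fixed fractions of each foot total
    frac = np.full(8, 1.0 / 8.0)
    rec = VGRFRecording(
        subject_id=st.record_id or "sim",
        label=st.label or "healthy",
        fs=fs,
        t=t,
        left_sensors=np.outer(totals["left"], frac),
        right_sensors=np.outer(totals["right"], frac),
        left_total=totals["left"],
        right_total=totals["right"],
        meta={"synthetic": True, "seed": seed, "pad_s": pad_s},
    )
    return rec, exclusion


def simulate_feature_table(
    class_specs: dict[str, dict],
    n_per_class: int,
    n_noise_features: int = 0,
    seed: int = 0,
    noise_feature_names: list[str] | None = None,
) -> FeatureTable:
    """Multivariate-normal feature tables with stated class effects.

    ``class_specs[label]`` maps feature ids to ``(mean, sd)``; features
    absent from a class spec default to N(0, 1).  ``n_noise_features``
    appends exchangeable N(0,1) features (named ``f<k>`` continuing the
    id sequence unless explicit names are given).  Deterministic given
    the seed.
    """
    import pandas as pd

    if len(class_specs) < 2:
        raise ValidationError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    informative = sorted({f for spec in class_specs.values() for f in spec})
    if noise_feature_names is None:
        used = {int(f[1:]) for f in informative if f.startswith("f")}
        start = max(used, default=0) + 1
        noise_feature_names = [f"f{start + i}" for i in range(n_noise_features)]
    rows = []
    rid = 0
    for label in sorted(class_specs):
        spec = class_specs[label]
        for _ in range(n_per_class):
            row = {"record_id": f"r{rid}", "subject_id": f"s{rid}", "label": label}
            for fid in informative:
                mean, sd = spec.get(fid, (0.0, 1.0))
                row[fid] = rng.normal(mean, sd)
            for fid in noise_feature_names:
                row[fid] = rng.normal(0.0, 1.0)
            rows.append(row)
            rid += 1
    return FeatureTable(pd.DataFrame(rows))


def simulate_cohort(
    n_per_class: int,
    n_cycles: int,
    seed: int = 0,
    params_by_label: dict[str, GaitClassParams] | None = None,
) -> list[StrideTable]:
    """A two-class cohort of stride tables (healthy-like vs PD-like by
    default), one record per subject, seeds derived from the master
    seed."""
    params_by_label = params_by_label or {"healthy": HEALTHY_LIKE, "PD": PD_LIKE}
    rng = np.random.default_rng(seed)
    tables = []
    for label in sorted(params_by_label):
        for i in range(n_per_class):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            tables.append(simulate_strides(
                params_by_label[label], n_cycles, seed=sub_seed,
                record_id=f"{label}_{i}", label=label,
            ))
    return tables
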