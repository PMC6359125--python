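"""Shared fixtures: analytically known gait signals and small tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gaitpark import FeatureTable, VGRFRecording


def square_wave_recording(
    stride_s: float = 1.1,
    stance_s: float = 0.7,
    offset_s: float = 0.55,
    n_cycles: int = 20,
    fs: float = 100.0,
    amplitude: float = 800.0,
    label: str = "healthy",
) -> VGRFRecording:
    """Two-footed square-wave vGRF: left stance starts at multiples of
    the stride, right offset by ``offset_s``.  All event times are exact
    sample instants when the parameters are multiples of 1/fs."""
    n = int(round((n_cycles * stride_s + offset_s) * fs)) + 1
    t = np.arange(n) / fs
    # integer-sample construction keeps edges exactly on the grid
    stride_n, stance_n = int(round(stride_s * fs)), int(round(stance_s * fs))
    offset_n = int(round(offset_s * fs))
    i = np.arange(n)
    left = np.where((i % stride_n) < stance_n, amplitude, 0.0)
    right = np.where(((i - offset_n) % stride_n) < stance_n, amplitude, 0.0)
    right[i < offset_n] = 0.0
    sensors_l = np.outer(left, np.full(8, 1 / 8))
    sensors_r = np.outer(right, np.full(8, 1 / 8))
    return VGRFRecording(
        subject_id="square", label=label, fs=fs, t=t,
        left_sensors=sensors_l, right_sensors=sensors_r,
        left_total=left, right_total=right,
    )


@pytest.fixture
def square_rec() -> VGRFRecording:
    return square_wave_recording()


def make_feature_table(n_per_class: int = 10, seed: int = 0,
                       signal: dict | None = None) -> FeatureTable:
    """Small two-class table of N(0,1) features f1..f19 with optional
    per-feature class-mean shifts ``signal={fid: delta}`` on class PD."""
    rng = np.random.default_rng(seed)
    rows = []
    for k, label in enumerate(["healthy", "PD"]):
        for i in range(n_per_class):
            row = {"record_id": f"{label}{i}", "subject_id": f"{label}{i}", "label": label}
            for j in range(1, 20):
                fid = f"f{j}"
                shift = (signal or {}).get(fid, 0.0) if label == "PD" else 0.0
                row[fid] = rng.normal(shift, 1.0)
            rows.append(row)
    return FeatureTable(pd.DataFrame(rows))
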