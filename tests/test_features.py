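"""The 19 clinical features against hand evaluations and an independent
brute-force oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitpark as gp
from gaitpark.types import StrideTable, ValidationError


# ---------------------------------------------------------------- oracle
def _sd(xs):
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def _cv(xs):
    return 100.0 * _sd(xs) / (sum(xs) / len(xs))


def _mean(xs):
    return sum(xs) / len(xs)


def brute_force_features(st: StrideTable) -> dict:
    """Feature-by-feature recomputation from the raw series using plain
    arithmetic, written independently of the library implementation."""
    nl = min(len(st.left_swing_s), len(st.left_stride_s))
    nr = min(len(st.right_swing_s), len(st.right_stride_s))
    lsp = [100.0 * st.left_swing_s[i] / st.left_stride_s[i] for i in range(nl)]
    rsp = [100.0 * st.right_swing_s[i] / st.right_stride_s[i] for i in range(nr)]
    out = {
        "f1": _cv(lsp), "f2": _cv(list(st.left_swing_s)), "f3": _cv(list(st.left_stride_s)),
        "f4": _cv(rsp), "f5": _cv(list(st.right_swing_s)), "f6": _cv(list(st.right_stride_s)),
        "f10": _mean(lsp), "f11": _mean(list(st.left_swing_s)),
        "f12": _mean(list(st.left_stride_s)),
        "f13": _mean(rsp), "f14": _mean(list(st.right_swing_s)),
        "f15": _mean(list(st.right_stride_s)),
    }
    out["f16"] = (_mean(list(st.double_support_pct))
                  if st.double_support_pct is not None and st.double_support_pct.size
                  else float("nan"))
    ssw, lsw = list(st.ssw_s), list(st.lsw_s)
    out["f7"], out["f8"] = _cv(ssw), _cv(lsw)
    out["f9"] = (100.0 * abs(math.log(out["f7"] / out["f8"]))
                 if out["f7"] > 0 and out["f8"] > 0 else float("nan"))
    out["f17"], out["f18"] = _mean(ssw), _mean(lsw)
    out["f19"] = _mean([100.0 * abs(math.log(s / l)) for s, l in zip(ssw, lsw)])
    return out


def random_stride_table(rng) -> StrideTable:
    n = int(rng.integers(3, 40))
    l_stride = rng.uniform(0.9, 1.4, n)
    r_stride = rng.uniform(0.9, 1.4, n)
    l_swing = l_stride * rng.uniform(0.25, 0.55, n)
    r_swing = r_stride * rng.uniform(0.25, 0.55, n)
    ds = rng.uniform(5, 40, n)
    return StrideTable(left_stride_s=l_stride, left_swing_s=l_swing,
                       right_stride_s=r_stride, right_swing_s=r_swing,
                       double_support_pct=ds)


# ----------------------------------------------------------------- tests
class TestCoefficientOfVariation:
    def test_zero_variance(self):
        assert gp.coefficient_of_variation([1.0, 1.0, 1.0]) == 0.0

    def test_hand_case(self):
        # sd = |1.2 - 1.0| / sqrt(2), mean = 1.1 -> 12.856%
        assert gp.coefficient_of_variation([1.0, 1.2]) == pytest.approx(12.8564869, abs=1e-3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100.0), seed=st.integers(0, 1000))
    def test_scale_invariance(self, c, seed):
        x = np.random.default_rng(seed).uniform(0.5, 2.0, 10)
        assert gp.coefficient_of_variation(c * x) == pytest.approx(
            gp.coefficient_of_variation(x), rel=1e-9)

    def test_contract_errors(self):
        with pytest.raises(ValidationError):
            gp.coefficient_of_variation([1.0])
        with pytest.raises(ValidationError):
            gp.coefficient_of_variation([-1.0, -2.0])


class TestGaitAsymmetry:
    def test_equal_swings_zero(self):
        assert gp.gait_asymmetry(0.4, 0.4) == 0.0

    def test_hand_case(self):
        assert gp.gait_asymmetry(0.38, 0.40) == pytest.approx(5.12933, abs=1e-3)

    def test_symmetry(self):
        assert gp.gait_asymmetry(0.3, 0.5) == gp.gait_asymmetry(0.5, 0.3)

    def test_positive_inputs_required(self):
        with pytest.raises(ValidationError):
            gp.gait_asymmetry(0.0, 0.4)


class TestExtractFeatures:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            stl = random_stride_table(rng)
            got = gp.extract_features(stl)
            want = brute_force_features(stl)
            for fid in gp.FEATURE_IDS:
                if math.isnan(want[fid]):
                    assert math.isnan(got[fid]), fid
                else:
                    assert got[fid] == pytest.approx(want[fid], rel=1e-9), fid

    def test_periodic_gait_zero_variability_limit(self):
        stl = StrideTable(
            left_stride_s=np.full(10, 1.1), left_swing_s=np.full(10, 0.4),
            right_stride_s=np.full(10, 1.1), right_swing_s=np.full(10, 0.4),
        )
        f = gp.extract_features(stl)
        for fid in ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8"):
            assert f[fid] == 0.0
        assert math.isnan(f["f9"])  # 0/0 flagged missing
        assert f["f19"] == 0.0
        assert f["f10"] == f["f13"] == pytest.approx(100 * 0.4 / 1.1)

    def test_two_cycle_left_stride_cv(self):
        stl = StrideTable(
            left_stride_s=np.array([1.0, 1.2]), left_swing_s=np.array([0.4, 0.4]),
            right_stride_s=np.array([1.1, 1.1]), right_swing_s=np.array([0.4, 0.4]),
        )
        assert gp.extract_features(stl)["f3"] == pytest.approx(12.8564869, abs=1e-3)

    def test_foot_swap_permutes_features(self):
        rng = np.random.default_rng(5)
        stl = random_stride_table(rng)
        swapped = StrideTable(
            left_stride_s=stl.right_stride_s, left_swing_s=stl.right_swing_s,
            right_stride_s=stl.left_stride_s, right_swing_s=stl.left_swing_s,
            double_support_pct=stl.double_support_pct,
        )
        a, b = gp.extract_features(stl), gp.extract_features(swapped)
        for x, y in [("f1", "f4"), ("f2", "f5"), ("f3", "f6"),
                     ("f10", "f13"), ("f11", "f14"), ("f12", "f15")]:
            assert a[x] == pytest.approx(b[y], rel=1e-9)
            assert a[y] == pytest.approx(b[x], rel=1e-9)
        for fid in ("f7", "f8", "f9", "f16", "f17", "f18", "f19"):
            assert a[fid] == pytest.approx(b[fid], rel=1e-9)

    def test_time_rescaling(self):
        rng = np.random.default_rng(6)
        stl = random_stride_table(rng)
        c = 1.37
        scaled = StrideTable(
            left_stride_s=c * stl.left_stride_s, left_swing_s=c * stl.left_swing_s,
            right_stride_s=c * stl.right_stride_s, right_swing_s=c * stl.right_swing_s,
            double_support_pct=stl.double_support_pct,
        )
        a, b = gp.extract_features(stl), gp.extract_features(scaled)
        for fid in ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8", "f9",
                    "f10", "f13", "f16", "f19"):
            assert b[fid] == pytest.approx(a[fid], rel=1e-9)
        for fid in ("f11", "f12", "f14", "f15", "f17", "f18"):
            assert b[fid] == pytest.approx(c * a[fid], rel=1e-9)

    def test_needs_two_cycles(self):
        stl = StrideTable(
            left_stride_s=np.array([1.0]), left_swing_s=np.array([0.4]),
            right_stride_s=np.array([1.0, 1.0]), right_swing_s=np.array([0.4, 0.4]),
        )
        with pytest.raises(ValidationError):
            gp.extract_features(stl)

    def test_generator_recovers_target_cv(self):
        """Stride CV 4%, 200 cycles: the estimate lies inside the
        sampling-error band (CV se ~ cv/sqrt(2n) ~ 0.2pp; band +/-1.2pp)."""
        params = gp.GaitClassParams(stride_cv_pct=4.0, swing_cv_pct=2.0)
        stl = gp.simulate_strides(params, 200, seed=17)
        f3 = gp.extract_features(stl)["f3"]
        assert 2.8 <= f3 <= 5.2

    def test_parameter_recovery_over_cohorts(self):
        """Mean absolute error of mean-stride and stride-CV estimates
        over 100 seeded synthetic records at 200 cycles."""
        params = gp.GaitClassParams(mean_stride_s=1.1, stride_cv_pct=4.0)
        err_mean, err_cv = [], []
        for seed in range(100):
            stl = gp.simulate_strides(params, 200, seed=seed)
            f = gp.extract_features(stl)
            err_mean.append(abs(f["f12"] - 1.1))
            err_cv.append(abs(f["f3"] - 4.0))
        assert np.mean(err_mean) < 2 / 100.0   # < 2 sample periods at 100 Hz
        assert np.mean(err_cv) < 1.0           # < 1 percentage point


class TestFeaturesTable:
    def test_one_row_per_record(self):
        tables = [gp.simulate_strides(gp.HEALTHY_LIKE, 20, seed=s,
                                      record_id=f"r{s}", label="healthy")
                  for s in range(4)]
        ft = gp.features_table(tables)
        assert len(ft) == 4
        assert ft.feature_ids == list(gp.FEATURE_IDS)

    def test_ratio_of_means_mode(self):
        stl = gp.simulate_strides(gp.PD_LIKE, 50, seed=2)
        a = gp.extract_features(stl, ga_mode="mean_of_cycles")
        b = gp.extract_features(stl, ga_mode="ratio_of_means")
        assert b["f19"] == pytest.approx(
            100 * abs(math.log(a["f17"] / a["f18"])), rel=1e-9)
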