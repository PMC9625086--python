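"""Temporal trajectory classes and the CD28 enhancement ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costimsplice.temporal import (
    classify_temporal,
    classify_temporal_table,
    costim_ratio,
    costim_ratio_table,
    crosstab_enhanced_temporal,
    enhanced_fraction,
)
from costimsplice.types import TemporalClass


class TestClassifyTemporal:
    def test_fourfold_drop_is_transient(self):
        tc = classify_temporal("e", 0.20, 0.05, True, False)
        assert tc.temporal_class is TemporalClass.EARLY_TRANSIENT

    def test_mild_drop_is_sustained(self):
        tc = classify_temporal("e", 0.20, 0.15, True, True)
        assert tc.temporal_class is TemporalClass.EARLY_SUSTAINED

    def test_late_only_significance(self):
        tc = classify_temporal("e", 0.0, 0.30, False, True)
        assert tc.temporal_class is TemporalClass.LATE

    def test_neither_timepoint_significant_rejected(self):
        with pytest.raises(ValueError):
            classify_temporal("e", 0.0, 0.0, False, False)

    def test_partition_over_table(self):
        calls = pd.DataFrame(
            {
                "event_id": ["a", "a", "b", "b", "c", "c", "d", "d"],
                "condition": "CD3CD28",
                "timepoint": [8, 48] * 4,
                "significant": [True, True, True, False, False, True, False, False],
                "mean_dpsi": [0.2, 0.15, 0.2, 0.04, 0.01, 0.3, 0.0, 0.0],
            }
        )
        out = classify_temporal_table(calls)
        # d is significant nowhere and must be absent; others get one class each
        assert set(out["event_id"]) == {"a", "b", "c"}
        assert len(out) == 3
        assert dict(zip(out["event_id"], out["temporal_class"])) == {
            "a": "EARLY_SUSTAINED",
            "b": "EARLY_TRANSIENT",
            "c": "LATE",
        }

    def test_sig48_restriction(self):
        calls = pd.DataFrame(
            {
                "event_id": ["a", "a", "b", "b"],
                "condition": "CD3CD28",
                "timepoint": [8, 48, 8, 48],
                "significant": [True, False, True, True],
                "mean_dpsi": [0.2, 0.02, 0.2, 0.18],
            }
        )
        assert set(classify_temporal_table(calls, input_set="sig_48h")["event_id"]) == {"b"}
        assert set(classify_temporal_table(calls, input_set="union")["event_id"]) == {"a", "b"}


class TestCostimRatio:
    def test_floor_rescues_small_denominator(self):
        r = costim_ratio("e", 8, 0.005, 0.03)
        assert r.dpsi_cd3_floored == pytest.approx(0.01)
        assert r.ratio == pytest.approx(3.0)
        assert r.enhanced

    def test_ratio_two_boundary_not_enhanced(self):
        r = costim_ratio("e", 8, 0.10, 0.20)
        assert r.ratio == pytest.approx(2.0)
        assert not r.enhanced

    def test_equal_effects_ratio_one(self):
        r = costim_ratio("e", 8, 0.15, 0.15)
        assert r.ratio == pytest.approx(1.0)
        assert not r.enhanced

    def test_sign_conflict_never_enhanced(self):
        r = costim_ratio("e", 8, -0.10, 0.30)
        assert r.sign_conflict
        assert not r.enhanced

    def test_negative_concordant_effects_can_be_enhanced(self):
        r = costim_ratio("e", 8, -0.05, -0.20)
        assert r.ratio == pytest.approx(4.0)
        assert r.enhanced

    def test_continuity_at_floor(self):
        eps = 1e-9
        lo = costim_ratio("e", 8, 0.01 - eps, 0.05).ratio
        hi = costim_ratio("e", 8, 0.01 + eps, 0.05).ratio
        assert lo == pytest.approx(hi, abs=1e-5)

    @given(d328=st.floats(-0.8, 0.8), d3=st.floats(-0.8, 0.8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_costimulated_dpsi(self, d3, d328):
        step = 0.05
        r1 = costim_ratio("e", 8, d3, d328).ratio
        r2 = costim_ratio("e", 8, d3, d328 + step).ratio
        if d3 != 0 or d328 > 0:  # fixed denominator sign
            sign = np.sign(d3) if d3 != 0 else 1.0
            if sign > 0:
                assert r2 >= r1
            else:
                assert r2 <= r1

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            costim_ratio("e", 8, float("nan"), 0.1)


class TestEnhancedFraction:
    def test_fraction_arithmetic(self):
        ratios = [costim_ratio(f"e{i}", 8, 0.05, 0.25) for i in range(24)]
        ratios += [costim_ratio(f"n{i}", 8, 0.2, 0.2) for i in range(76)]
        assert enhanced_fraction(ratios) == pytest.approx(0.24)

    def test_none_enhanced(self):
        ratios = [costim_ratio(f"e{i}", 8, 0.2, 0.2) for i in range(5)]
        assert enhanced_fraction(ratios) == 0.0

    def test_table_denominator_is_significant_set(self):
        calls = pd.DataFrame(
            {
                "event_id": ["a", "a", "b", "b", "c", "c"],
                "condition": ["CD3", "CD3CD28"] * 3,
                "timepoint": 8,
                "significant": [False, True, True, True, False, False],
                "mean_dpsi": [0.02, 0.25, 0.2, 0.22, 0.01, 0.05],
            }
        )
        rt = costim_ratio_table(calls, 8)
        assert set(rt["event_id"]) == {"a", "b"}  # c not significant under CD3CD28
        assert bool(rt.set_index("event_id").loc["a", "enhanced"]) is True
        assert bool(rt.set_index("event_id").loc["b", "enhanced"]) is False


class TestCrosstab:
    def _temporal(self, mapping):
        return pd.DataFrame(
            {
                "event_id": list(mapping),
                "temporal_class": list(mapping.values()),
                "dpsi_8h": 0.2,
                "dpsi_48h": 0.1,
                "sig_8h": True,
                "sig_48h": True,
            }
        )

    def test_modal_class(self):
        t = self._temporal({"a": "EARLY_TRANSIENT", "b": "EARLY_TRANSIENT", "c": "LATE"})
        out = crosstab_enhanced_temporal({"a", "b"}, {"c"}, t)
        assert out["modal_class"]["enhanced_8h"] == "EARLY_TRANSIENT"
        assert out["modal_class"]["enhanced_48h"] == "LATE"

    def test_empty_sets_all_zero(self):
        t = self._temporal({"a": "LATE"})
        out = crosstab_enhanced_temporal(set(), set(), t)
        assert all(v == 0 for d in out["counts"].values() for v in d.values())
        assert out["modal_class"]["enhanced_8h"] is None

    def test_counts_match_enumeration(self):
        rng = np.random.default_rng(5)
        classes = ["EARLY_TRANSIENT", "EARLY_SUSTAINED", "LATE"]
        mapping = {f"e{i}": classes[rng.integers(3)] for i in range(200)}
        t = self._temporal(mapping)
        e8 = {f"e{i}" for i in range(0, 200, 3)}
        out = crosstab_enhanced_temporal(e8, set(), t)
        for c in classes:
            brute = sum(1 for e in e8 if mapping[e] == c)
            assert out["counts"]["enhanced_8h"][c] == brute
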