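"""Significance rules, concordance statistics and expression-side analyses."""

import numpy as np
import pytest

from costimsplice.calls import (
    baseline_psi_summary,
    call_de_genes,
    call_significant,
    call_significant_table,
    cd28_enhanced_expression,
    donor_correlation,
    donor_overlap,
    splicing_expression_overlap,
    summarize_event_types,
)
from costimsplice.types import DpsiEstimate, EventAnnotation, EventType

import pandas as pd


def dpsi_set(dpsis, probs):
    return [
        DpsiEstimate("e1", f"d{i+1}", "CD3", 8, d, p)
        for i, (d, p) in enumerate(zip(dpsis, probs))
    ]


class TestCallSignificant:
    @pytest.mark.parametrize(
        "dpsis, probs, n_pass, significant",
        [
            ([0.15, 0.12, 0.03], [0.97, 0.96, 0.50], 2, True),
            ([0.15, 0.08, 0.03], [0.97, 0.90, 0.40], 1, False),
            ([-0.12, -0.14, -0.11], [0.96, 0.98, 0.97], 3, True),  # both directions
        ],
    )
    def test_two_of_three_rule(self, dpsis, probs, n_pass, significant):
        call = call_significant(dpsi_set(dpsis, probs))
        assert call.n_donors_pass == n_pass
        assert call.significant is significant
        assert call.mean_dpsi == pytest.approx(np.mean(dpsis))

    def test_duplicate_donor_rejected(self):
        records = dpsi_set([0.2, 0.2], [0.99, 0.99])
        records[1].donor = records[0].donor
        with pytest.raises(ValueError):
            call_significant(records)

    def test_min_donors_applies_to_donors_present(self):
        call = call_significant(dpsi_set([0.2, 0.2], [0.99, 0.99]), min_donors=2)
        assert call.significant

    def test_table_path_matches_scalar_rule(self):
        df = pd.DataFrame(
            {
                "event_id": ["e1"] * 3 + ["e2"] * 3,
                "donor": ["d1", "d2", "d3"] * 2,
                "condition": "CD3",
                "timepoint": 8,
                "dpsi_hat": [0.15, 0.12, 0.03, 0.15, 0.08, 0.03],
                "prob_exceeds": [0.97, 0.96, 0.50, 0.97, 0.90, 0.40],
            }
        )
        out = call_significant_table(df).set_index("event_id")
        assert bool(out.loc["e1", "significant"]) is True
        assert bool(out.loc["e2", "significant"]) is False


class TestDonorConcordance:
    def test_perfect_and_inverse_correlation(self):
        assert donor_correlation([0.1, 0.2, 0.3], [0.2, 0.4, 0.6]) == pytest.approx(1.0)
        x = np.array([0.1, 0.2, 0.3])
        assert donor_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0.1, 0.3, 0.2, 0.4])
        # independent manual computation of covariance / (sx sy)
        manual = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert manual == pytest.approx(0.80)
        assert donor_correlation(x, y) == pytest.approx(0.80)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(30), rng.random(30)
        r = donor_correlation(x, y)
        assert donor_correlation(y, x) == pytest.approx(r)
        assert donor_correlation(3 * x + 1, 0.5 * y - 2) == pytest.approx(r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            donor_correlation([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])

    def test_overlap_set_arithmetic(self):
        ov = donor_overlap({"A": {1, 2}, "B": {2, 3}})
        assert ov["intersection"][("A", "B")] == 1
        assert ov["union"][("A", "B")] == 3

    def test_overlap_identical_sets(self):
        ov = donor_overlap({"A": {1, 2, 3}, "B": {1, 2, 3}})
        assert ov["intersection"][("A", "B")] == ov["union"][("A", "B")] == 3

    def test_overlap_matches_enumeration(self):
        rng = np.random.default_rng(1)
        sets = {
            d: set(rng.choice(1000, 100, replace=False).tolist()) for d in "ABC"
        }
        ov = donor_overlap(sets)
        brute = sum(1 for x in range(1000) if all(x in sets[d] for d in "ABC"))
        assert ov["intersection"][("A", "B", "C")] == brute


class TestBaselinePsi:
    def test_identical_vectors_d_zero(self):
        v = np.linspace(0.1, 0.9, 50)
        assert baseline_psi_summary(v, v)["ks_statistic"] == pytest.approx(0.0)

    def test_disjoint_supports_d_one(self):
        s = baseline_psi_summary(np.zeros(20), np.ones(20))
        assert s["ks_statistic"] == pytest.approx(1.0)

    def test_shifted_uniform_matches_ecdf_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.random(10_000)
        b = np.clip(a + 0.2, 0, 1)
        d = baseline_psi_summary(a, b)["ks_statistic"]
        grid = np.linspace(0, 1, 2001)
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
        assert d == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)), abs=0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            baseline_psi_summary(np.array([1.2]), np.array([0.5]))


class TestEventTypes:
    def _ann(self, eid, etype):
        return EventAnnotation(eid, f"g_{eid}", etype, "chr1", 100, 200, "+")

    def test_thirty_percent_complex(self):
        anns = {f"c{i}": self._ann(f"c{i}", EventType.CASSETTE) for i in range(7)}
        anns.update({f"x{i}": self._ann(f"x{i}", EventType.COMPLEX) for i in range(3)})
        s = summarize_event_types(set(anns), anns)
        assert s["proportions"]["COMPLEX"] == pytest.approx(0.30)

    def test_single_type_and_sum_to_one(self):
        anns = {f"c{i}": self._ann(f"c{i}", EventType.ALT5SS) for i in range(5)}
        s = summarize_event_types(set(anns), anns)
        assert s["proportions"]["ALT5SS"] == 1.0
        assert sum(s["proportions"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_large_composition_matches_tally(self):
        rng = np.random.default_rng(3)
        types = list(EventType)
        anns = {}
        tally = {t.value: 0 for t in types}
        for i in range(1000):
            t = types[rng.integers(len(types))]
            anns[f"e{i}"] = self._ann(f"e{i}", t)
            tally[t.value] += 1
        s = summarize_event_types(set(anns), anns)
        assert s["counts"] == tally

    def test_unannotated_event_rejected(self):
        with pytest.raises(KeyError):
            summarize_event_types({"missing"}, {})


class TestExpression:
    def _expr(self, values):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(values))],
                "condition": "CD3",
                "timepoint": 48,
                "log2fc": values,
            }
        )

    def test_threshold_is_strict_and_magnitude_based(self):
        genes = call_de_genes(self._expr([1.6, 1.5, -2.0, 0.3]))
        assert genes == {"g0", "g2"}

    def test_overlap_statistics(self):
        assert splicing_expression_overlap({"a"}, {"b"})["jaccard"] == 0.0
        assert splicing_expression_overlap({"a", "b"}, {"a", "b"})["jaccard"] == 1.0
        rng = np.random.default_rng(4)
        a = set(rng.choice(100, 30, replace=False).tolist())
        b = set(rng.choice(100, 30, replace=False).tolist())
        s = splicing_expression_overlap(a, b)
        assert s["intersection"] == sum(1 for x in range(100) if x in a and x in b)

    def test_enhancement_ratio_is_inclusive(self):
        assert cd28_enhanced_expression({"g": 4.0}, {"g": 2.0}) == {"g"}
        assert cd28_enhanced_expression({"g": 3.0}, {"g": 2.0}) == set()

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            cd28_enhanced_expression({"g": -1.0}, {"g": 2.0})
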