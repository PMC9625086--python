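"""Ground-truth generator: planted classes, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from costimsplice import (
    SimulationConfig,
    simulate_counts,
    simulate_expression,
    simulate_genome,
    simulate_truth,
)
from costimsplice.simulate import reverse_complement, truth_table
from costimsplice.types import EventClass, EventTruth, TemporalClass


class TestSimulateTruth:
    def test_all_null_events_have_constant_psi(self):
        cfg = SimulationConfig(
            n_events=100, seed=1, class_proportions={EventClass.NULL: 1.0}
        )
        truth = simulate_truth(cfg)
        assert len(truth) == 100
        for ev in truth:
            vals = set(ev.true_psi.values())
            assert len(vals) == 1

    def test_enhanced_events_obey_ratio_relation(self):
        cfg = SimulationConfig(
            n_events=200, seed=2,
            class_proportions={EventClass.CD28_ENHANCED: 1.0},
        )
        for ev in simulate_truth(cfg):
            assert ev.true_ratio > 2
            base = ev.true_psi[("UNSTIM", 8)]
            # at the peak timepoint of its trajectory
            tp = 8 if ev.temporal_class_true is not TemporalClass.LATE else 48
            d3 = ev.true_psi[("CD3", tp)] - base
            d328 = ev.true_psi[("CD3CD28", tp)] - base
            assert d328 == pytest.approx(ev.true_ratio * d3, rel=1e-9)
            assert abs(d328) >= 0.10

    def test_temporal_profiles_realized(self):
        cfg = SimulationConfig(
            n_events=300, seed=3,
            class_proportions={EventClass.CD3_ONLY: 1.0},
        )
        for ev in simulate_truth(cfg):
            base = ev.true_psi[("UNSTIM", 8)]
            d8 = abs(ev.true_psi[("CD3CD28", 8)] - base)
            d48 = abs(ev.true_psi[("CD3CD28", 48)] - base)
            if ev.temporal_class_true is TemporalClass.EARLY_TRANSIENT:
                assert d8 >= 0.10 and d48 < d8 / 2
            elif ev.temporal_class_true is TemporalClass.EARLY_SUSTAINED:
                assert d8 >= 0.10 and d48 >= d8 / 2
            else:
                assert d8 == pytest.approx(0.0) and d48 >= 0.10

    def test_psi_stays_in_unit_interval(self):
        truth = simulate_truth(SimulationConfig(n_events=400, seed=4))
        for ev in truth:
            for v in ev.true_psi.values():
                assert 0.0 <= v <= 1.0

    def test_bad_proportions_rejected(self):
        cfg = SimulationConfig(class_proportions={EventClass.NULL: 0.5})
        with pytest.raises(ValueError):
            simulate_truth(cfg)

    def test_determinism(self):
        cfg = SimulationConfig(n_events=50, seed=1)
        t1 = truth_table(simulate_truth(cfg))
        t2 = truth_table(simulate_truth(SimulationConfig(n_events=50, seed=1)))
        pd.testing.assert_frame_equal(t1, t2)


class TestSimulateCounts:
    def test_determinism_and_shared_event_ids(self, small_sim):
        cfg, truth, counts = small_sim
        counts2 = simulate_counts(truth, cfg)
        pd.testing.assert_frame_equal(counts, counts2)
        assert set(counts["event_id"]) == {ev.event_id for ev in truth}
        # one record per event x donor x condition x timepoint
        assert len(counts) == cfg.n_events * cfg.n_donors * 4 * 2

    def test_calibration_at_high_depth(self):
        cfg = SimulationConfig(
            n_events=200, seed=5, mean_depth=1e5, donor_sd=0.0, overdispersion=0.0,
            class_proportions={EventClass.NULL: 1.0},
        )
        truth = simulate_truth(cfg)
        counts = simulate_counts(truth, cfg)
        psi_true = {ev.event_id: ev.true_psi[("UNSTIM", 8)] for ev in truth}
        inc_eff = (counts["inc_junc1"] + counts["inc_junc2"]) / 2
        emp = inc_eff / (inc_eff + counts["exc_junc"])
        err = np.abs(emp - counts["event_id"].map(psi_true))
        assert np.mean(err < 0.01) >= 0.99

    def test_zero_psi_gives_zero_inclusion(self):
        cfg = SimulationConfig(n_events=1, n_donors=2, seed=6)
        psi = {(c, t): 0.0 for c in cfg.conditions for t in cfg.timepoints}
        truth = [EventTruth("ev0", EventClass.NULL, TemporalClass.NONE, psi, None)]
        counts = simulate_counts(truth, cfg)
        assert (counts["inc_junc1"] == 0).all()
        assert (counts["inc_junc2"] == 0).all()

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts([], SimulationConfig())


class TestSimulateGenome:
    def test_planted_motif_present_in_enhanced_flank(self, genome_sim):
        cfg, truth, genome, ann = genome_sim
        enhanced = [ev for ev in truth if ev.event_class is EventClass.CD28_ENHANCED]
        assert enhanced, "fixture should contain enhanced events"
        assert all(ev.motif_planted for ev in enhanced)
        assert not any(
            ev.motif_planted for ev in truth if ev.event_class is not EventClass.CD28_ENHANCED
        )

    def test_determinism(self, genome_sim):
        cfg, truth, genome, ann = genome_sim
        truth2 = simulate_truth(SimulationConfig(n_events=120, seed=7))
        genome2, ann2 = simulate_genome(truth2, "TGCATG", 1.0, 0.0, cfg)
        assert genome == genome2
        pd.testing.assert_frame_equal(ann, ann2)

    def test_minus_strand_written_reverse_complemented(self, genome_sim):
        cfg, truth, genome, ann = genome_sim
        minus = ann[ann["strand"] == "-"]
        plus = ann[ann["strand"] == "+"]
        assert len(minus) > 20 and len(plus) > 20  # roughly half each

    def test_background_motif_rate_matches_uniform_expectation(self):
        # no planting: occurrences per window follow the (W-L+1)/4^L expectation
        cfg = SimulationConfig(n_events=400, seed=8)
        truth = simulate_truth(cfg)
        genome, ann = simulate_genome(truth, "TGCATG", 0.0, 0.0, cfg)
        L = 6
        count = 0
        n_windows = 0
        for r in ann.itertuples(index=False):
            seq = genome[r.chrom]
            if r.strand == "+":
                win = seq[r.end + 7 : r.end + 250]
            else:
                win = reverse_complement(seq[r.start - 250 : r.start - 7])
            count += win.count("TGCATG")
            n_windows += 1
        expected = n_windows * (243 - L + 1) * 0.25**L
        assert count == pytest.approx(expected, abs=4 * np.sqrt(expected) + 1)

    def test_short_motif_rejected(self, genome_sim):
        cfg, truth, _, _ = genome_sim
        with pytest.raises(ValueError):
            simulate_genome(truth, "ACG", 1.0, 0.0, cfg)

    def test_short_intron_rejected(self):
        cfg = SimulationConfig(n_events=5, seed=9, intron_length=100)
        truth = simulate_truth(cfg)
        with pytest.raises(ValueError):
            simulate_genome(truth, "TGCATG", 0.0, 0.0, cfg)


class TestSimulateExpression:
    def test_planted_enhanced_rbps_exactly_recoverable(self):
        expr = simulate_expression(seed=10)
        sub3 = expr[(expr["condition"] == "CD3")]
        sub328 = expr[(expr["condition"] == "CD3CD28")]
        fc3 = dict(zip(sub3["gene_id"], 2.0 ** sub3["log2fc"]))
        fc328 = dict(zip(sub328["gene_id"], 2.0 ** sub328["log2fc"]))
        truth_set = set(sub3.loc[sub3["true_cd28_enhanced_rbp"] == 1, "gene_id"])
        from costimsplice import cd28_enhanced_expression

        rbp_flags = dict(zip(sub3["gene_id"], sub3["is_rbp"].astype(bool)))
        found = cd28_enhanced_expression(fc328, fc3, rbp_flags=rbp_flags)
        assert found == truth_set
        assert len(found) == 49
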