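"""Planted-truth recovery checks: the package validating itself.

Each function builds a synthetic experiment with known ground truth, runs
the corresponding analysis stage from scratch, and returns the measured
recovery statistic. These are the quantitative claims the package makes
about its own behaviour; the test suite and the reproduction script both
call them.
"""

from __future__ import annotations

import numpy as np

from . import calls as calls_mod
from . import motifs as motifs_mod
from . import temporal as temporal_mod
from .pipeline import quantify
from .psi import prob_dpsi_exceeds
from .simulate import SimulationConfig, simulate_counts, simulate_genome, simulate_truth
from .types import EventClass, SequenceWindow, TemporalClass


def posterior_calibration(seed: int = 0, n_oracle: int = 1_000_000) -> dict:
    """Max |QMC - Monte-Carlo-oracle| deviation of the exceedance probability.

    Twelve count configurations: read depths {1, 10, 100, 1000} crossed
    with stimulated PSI {0.05, 0.5, 0.95}; the unstimulated arm sits at
    PSI 0.5 with the same depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    devs = []
    for depth in (1, 10, 100, 1000):
        for psi in (0.05, 0.5, 0.95):
            inc = round(depth * psi)
            a1, b1 = 0.5 + inc, 0.5 + depth - inc
            a2, b2 = 0.5 + depth / 2, 0.5 + depth / 2
            p = prob_dpsi_exceeds(a1, b1, a2, b2, threshold=0.10, seed=seed)
            s = rng.beta(a1, b1, n_oracle)
            u = rng.beta(a2, b2, n_oracle)
            oracle = float(np.mean(np.abs(s - u) >= 0.10))
            devs.append(abs(p - oracle))
    return {"max_abs_deviation": float(max(devs)), "n": len(devs)}


def _quantify_subset(counts, conditions, timepoints, seed, n_draws=2000):
    sub = counts[
        counts["condition"].isin(list(conditions) + ["UNSTIM"])
        & counts["timepoint"].isin(timepoints)
    ]
    return quantify(sub, n_draws=n_draws, seed=seed)


def null_calibration(seed: int = 0, n_events: int = 1000, depth: float = 100) -> dict:
    """False-positive rate of the 2-of-3 rule on a pure-null experiment."""
    cfg = SimulationConfig(
        n_events=n_events, seed=seed, mean_depth=depth,
        class_proportions={EventClass.NULL: 1.0},
    )
    counts = simulate_counts(simulate_truth(cfg), cfg)
    q = _quantify_subset(counts, ["CD3CD28"], [8], seed)
    dpsi = q.dropna(subset=["dpsi"]).rename(columns={"dpsi": "dpsi_hat"})
    calls = calls_mod.call_significant_table(dpsi)
    return {"significant_fraction": float(calls["significant"].mean()), "n": n_events}


def power_recovery(seed: int = 0, n_events: int = 600, depth: float = 100) -> dict:
    """Sensitivity of the 2-of-3 rule for events planted at |dPSI| = 0.25."""
    cfg = SimulationConfig(
        n_events=n_events, seed=seed, mean_depth=depth,
        effect_min=0.25, effect_max=0.25,
        class_proportions={EventClass.CD3_ONLY: 1.0},
        temporal_proportions={TemporalClass.EARLY_SUSTAINED: 1.0},
        sustained_retention=1.0,
    )
    counts = simulate_counts(simulate_truth(cfg), cfg)
    q = _quantify_subset(counts, ["CD3"], [8], seed)
    dpsi = q.dropna(subset=["dpsi"]).rename(columns={"dpsi": "dpsi_hat"})
    calls = calls_mod.call_significant_table(dpsi)
    return {"sensitivity": float(calls["significant"].mean()), "n": n_events}


def enhanced_recovery(seed: int = 0, n_events: int = 800, depth: float = 100) -> dict:
    """Recovery of planted CD28-enhanced events (true ratio in [3, 5])
    against CD3-only events (true ratio 1) by the floored ratio > 2 rule."""
    cfg = SimulationConfig(
        n_events=n_events, seed=seed, mean_depth=depth,
        class_proportions={
            EventClass.CD3_ONLY: 0.5, EventClass.CD28_ENHANCED: 0.5,
        },
        temporal_proportions={TemporalClass.EARLY_SUSTAINED: 1.0},
    )
    truth = simulate_truth(cfg)
    counts = simulate_counts(truth, cfg)
    q = _quantify_subset(counts, ["CD3", "CD3CD28"], [8], seed)
    dpsi = q.dropna(subset=["dpsi"]).rename(columns={"dpsi": "dpsi_hat"})
    calls = calls_mod.call_significant_table(dpsi)
    ratios = temporal_mod.costim_ratio_table(calls, 8).set_index("event_id")
    cls = {ev.event_id: ev.event_class for ev in truth}
    enh = [e for e in ratios.index if cls[e] is EventClass.CD28_ENHANCED]
    cd3 = [e for e in ratios.index if cls[e] is EventClass.CD3_ONLY]
    sens = float(ratios.loc[enh, "enhanced"].mean()) if enh else float("nan")
    spec = float(1.0 - ratios.loc[cd3, "enhanced"].mean()) if cd3 else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "n_enhanced_in_set": len(enh),
        "n_cd3_only_in_set": len(cd3),
        "n": n_events,
    }


def temporal_recovery(
    seed: int = 0, n_events: int = 500, depth: float = 300, donor_sd: float = 0.1
) -> dict:
    """Accuracy of trajectory classification on planted trajectories."""
    cfg = SimulationConfig(
        n_events=n_events, seed=seed, mean_depth=depth, donor_sd=donor_sd,
        class_proportions={EventClass.CD3_ONLY: 1.0},
    )
    truth = simulate_truth(cfg)
    counts = simulate_counts(truth, cfg)
    q = _quantify_subset(counts, ["CD3CD28"], [8, 48], seed)
    dpsi = q.dropna(subset=["dpsi"]).rename(columns={"dpsi": "dpsi_hat"})
    calls = calls_mod.call_significant_table(dpsi)
    classed = temporal_mod.classify_temporal_table(calls)
    true_cls = {ev.event_id: ev.temporal_class_true.value for ev in truth}
    if len(classed) == 0:
        return {"accuracy": float("nan"), "n_classified": 0, "n": n_events}
    correct = [
        int(true_cls[r.event_id] == r.temporal_class)
        for r in classed.itertuples(index=False)
    ]
    return {
        "accuracy": float(np.mean(correct)),
        "n_classified": len(classed),
        "n": n_events,
    }


def make_windows(
    rng: np.random.Generator,
    n: int,
    motif: str | None = None,
    motif_fraction: float = 0.0,
    prefix: str = "w",
) -> list[SequenceWindow]:
    """Random-sequence windows (220/120/243 nt) with optional motif planting."""
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        up = "".join(rng.choice(bases, 220))
        ex = "".join(rng.choice(bases, 120))
        dn = "".join(rng.choice(bases, 243))
        if motif is not None and rng.random() < motif_fraction:
            pos = int(rng.integers(0, 243 - len(motif)))
            dn = dn[:pos] + motif + dn[pos + len(motif):]
        out.append(SequenceWindow(f"{prefix}{i}", up, ex, dn, False))
    return out


def motif_recovery(
    seed: int = 0,
    motif: str = "TGCATG",
    n_fg: int = 200,
    n_bg: int = 800,
    fg_fraction: float = 0.4,
    bg_fraction: float = 0.05,
    n_permutations: int = 100,
) -> dict:
    """Planted-motif enrichment recovery and the label-permutation null."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 102]))
    fg = make_windows(rng, n_fg, motif, fg_fraction, prefix="f")
    bg = make_windows(rng, n_bg, motif, bg_fraction, prefix="b")
    res = motifs_mod.kmer_enrichment(fg, bg)
    row = res[res["kmer"] == motif]
    perm_frac = motifs_mod.permutation_null(
        fg, bg, n_permutations=n_permutations, seed=seed
    )
    return {
        "planted_motif_significant": bool(row["significant"].iloc[0]) if len(row) else False,
        "planted_motif_e_value": float(row["e_value"].iloc[0]) if len(row) else float("inf"),
        "planted_motif_ratio": float(row["enrichment_ratio"].iloc[0]) if len(row) else 0.0,
        "permutation_positive_fraction": float(perm_frac),
        "n": n_fg + n_bg,
    }


def strand_invariance(seed: int = 0, n_events: int = 100) -> dict:
    """Mismatch count after reverse-complementing the genome and flipping strands."""
    from .pipeline import _annotation_records
    from .simulate import reverse_complement

    cfg = SimulationConfig(n_events=n_events, seed=seed)
    truth = simulate_truth(cfg)
    genome, ann = simulate_genome(truth, "TGCATG", 0.5, 0.05, cfg)
    flipped_genome = {c: reverse_complement(s) for c, s in genome.items()}
    ann_records = _annotation_records(ann)
    from .types import EventType

    mismatches = 0
    n_checked = 0
    for eid, a in ann_records.items():
        if a.event_type is not EventType.CASSETTE:
            continue
        n_checked += 1
        n = len(genome[a.chrom])
        w1 = motifs_mod.extract_windows(a, genome)
        a2 = type(a)(
            event_id=a.event_id, gene_id=a.gene_id, event_type=a.event_type,
            chrom=a.chrom, exon_start=n - a.exon_end, exon_end=n - a.exon_start,
            strand="-" if a.strand == "+" else "+",
        )
        w2 = motifs_mod.extract_windows(a2, flipped_genome)
        if (w1.upstream_seq, w1.exon_seq, w1.downstream_seq) != (
            w2.upstream_seq, w2.exon_seq, w2.downstream_seq,
        ):
            mismatches += 1
    return {"mismatches": mismatches, "n": n_checked}


def determinism_check(seed: int = 0, n_events: int = 60, tmp_dir: str | None = None) -> dict:
    """Byte-identity of two end-to-end runs with the same seed."""
    import tempfile
    from pathlib import Path

    from .config import PipelineConfig
    from .pipeline import run_pipeline

    with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
        blobs = []
        for sub in ("a", "b"):
            cfg = PipelineConfig(seed=seed, output_dir=str(Path(td) / sub))
            run_pipeline(cfg, sim_config=SimulationConfig(n_events=n_events, seed=seed))
            blobs.append((Path(td) / sub / "report.json").read_bytes())
    return {"identical": blobs[0] == blobs[1], "n": n_events}
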