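"""End-to-end orchestration: simulate/ingest -> quantify -> call ->
classify -> ratio -> enrich -> report.

Every source of randomness derives from the single pipeline seed; a rerun
with the same configuration produces byte-identical output files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls as calls_mod
from . import io as io_mod
from . import motifs as motifs_mod
from . import temporal as temporal_mod
from .config import PipelineConfig
from .psi import prob_dpsi_exceeds_bulk
from .simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_expression,
    simulate_genome,
    simulate_truth,
    truth_table,
)
from .types import STIM_CONDITIONS, EventAnnotation, EventType

logger = logging.getLogger("costimsplice")


def quantify(
    counts: pd.DataFrame,
    prior_strength: float = 0.5,
    dpsi_threshold: float = 0.10,
    n_draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample PSI posteriors and per-donor dPSI against UNSTIM.

    Returns one row per (event, donor, condition, timepoint) with columns
    psi, alpha, beta and, for stimulated arms, dpsi and prob_exceeds
    (all fraction scale).
    """
    df = counts.copy()
    inc_eff = (df["inc_junc1"] + df["inc_junc2"]) / 2.0
    df["alpha"] = prior_strength + inc_eff
    df["beta"] = prior_strength + df["exc_junc"]
    df["psi"] = df["alpha"] / (df["alpha"] + df["beta"])

    unstim = df[df["condition"] == "UNSTIM"][
        ["event_id", "donor", "timepoint", "psi", "alpha", "beta"]
    ].rename(columns={"psi": "psi_u", "alpha": "alpha_u", "beta": "beta_u"})
    stim = df[df["condition"] != "UNSTIM"]
    merged = stim.merge(unstim, on=["event_id", "donor", "timepoint"], how="left")
    if merged["psi_u"].isna().any():
        missing = merged.loc[merged["psi_u"].isna(), "event_id"].unique()
        raise ValueError(f"missing UNSTIM pairing for events {missing[:5]}")
    merged = merged.sort_values(
        ["event_id", "donor", "condition", "timepoint"], ignore_index=True
    )
    merged["dpsi"] = merged["psi"] - merged["psi_u"]
    merged["prob_exceeds"] = prob_dpsi_exceeds_bulk(
        merged["alpha"].to_numpy(),
        merged["beta"].to_numpy(),
        merged["alpha_u"].to_numpy(),
        merged["beta_u"].to_numpy(),
        threshold=dpsi_threshold,
        n_draws=n_draws,
        seed=np.random.SeedSequence([seed, 11]),
    )
    out = df.merge(
        merged[["event_id", "donor", "condition", "timepoint", "dpsi", "prob_exceeds"]],
        on=["event_id", "donor", "condition", "timepoint"],
        how="left",
    )
    return out.sort_values(
        ["event_id", "donor", "condition", "timepoint"], ignore_index=True
    )


def _donor_concordance(dpsi: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Pairwise Pearson r of per-donor dPSI over significant events, plus
    the per-donor significant-set overlaps, per condition/timepoint."""
    out: dict[str, dict] = {"pearson": {}, "overlap": {}}
    for (cond, tp), sub in dpsi.dropna(subset=["dpsi"]).groupby(
        ["condition", "timepoint"], observed=True
    ):
        key = f"{cond}_{tp}h"
        sig_ids = set(
            calls.loc[
                (calls["condition"] == cond)
                & (calls["timepoint"] == tp)
                & calls["significant"],
                "event_id",
            ]
        )
        if len(sig_ids) < 3:
            continue
        wide = sub[sub["event_id"].isin(sig_ids)].pivot_table(
            index="event_id", columns="donor", values="dpsi"
        )
        donors = sorted(wide.columns)
        pear = {}
        for i, a in enumerate(donors):
            for b in donors[i + 1:]:
                pair = wide[[a, b]].dropna()
                if len(pair) >= 3 and pair[a].std() > 0 and pair[b].std() > 0:
                    pear[f"{a}:{b}"] = calls_mod.donor_correlation(
                        pair[a].to_numpy(), pair[b].to_numpy()
                    )
        out["pearson"][key] = pear
        # per-donor significant sets (single-donor rule) for the Venn-style overlap
        per_donor_sets = {}
        thr_pass = sub[(sub["dpsi"].abs() > 0.10) & (sub["prob_exceeds"] > 0.95)]
        for d in donors:
            per_donor_sets[d] = set(thr_pass.loc[thr_pass["donor"] == d, "event_id"])
        ov = calls_mod.donor_overlap(per_donor_sets)
        out["overlap"][key] = {
            "intersection": {"&".join(k): v for k, v in ov["intersection"].items()},
            "union": {"|".join(k): v for k, v in ov["union"].items()},
        }
    return out


def _annotation_records(ann: pd.DataFrame) -> dict[str, EventAnnotation]:
    return {
        r.name: EventAnnotation(
            event_id=r.name,
            gene_id=getattr(r, "gene_id", r.name),
            event_type=EventType(r.event_type),
            chrom=r.chrom,
            exon_start=int(r.start),
            exon_end=int(r.end),
            strand=r.strand,
        )
        for r in ann.itertuples(index=False)
    }


def run_pipeline(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    genome: dict[str, str] | None = None,
    expression: pd.DataFrame | None = None,
    rbp_table: dict[str, list[str]] | None = None,
    sim_config: SimulationConfig | None = None,
    motif: str = "TGCATG",
    planted_fraction_fg: float = 0.4,
    planted_fraction_bg: float = 0.05,
    write_outputs: bool = True,
) -> dict:
    """Execute the full analysis and return the report dict.

    When ``counts`` is None a synthetic experiment is generated from
    ``sim_config`` (defaults derived from the pipeline seed), including a
    genome with a planted motif and an expression table. Outputs are
    written under ``config.output_dir`` unless ``write_outputs=False``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    stage = "simulate"
    try:
        if counts is None:
            sc = sim_config or SimulationConfig(seed=config.seed)
            logger.info("simulating %d events, %d donors, seed %d", sc.n_events, sc.n_donors, sc.seed)
            truth = simulate_truth(sc)
            counts = simulate_counts(truth, sc)
            genome, annotations = simulate_genome(
                truth, motif, planted_fraction_fg, planted_fraction_bg, sc,
                flank=config.flank,
                donor_exclusion=config.donor_exclusion,
                acceptor_exclusion=config.acceptor_exclusion,
            )
            if expression is None:
                expression = simulate_expression(seed=sc.seed)
            if write_outputs:
                io_mod.write_junction_counts(counts, outdir / "junction_counts.tsv")
                truth_table(truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
                io_mod.write_fasta(genome, outdir / "genome.fasta")
                io_mod.write_annotations(annotations, outdir / "annotations.tsv")
                expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)

        stage = "quantify"
        logger.info(
            "quantify: prior=%.2f dpsi_threshold=%.2f n_draws=%d",
            config.prior_strength, config.dpsi_threshold, config.n_draws,
        )
        psi = quantify(
            counts,
            prior_strength=config.prior_strength,
            dpsi_threshold=config.dpsi_threshold,
            n_draws=config.n_draws,
            seed=config.seed,
        )
        dpsi = psi[psi["condition"] != "UNSTIM"].rename(columns={"dpsi": "dpsi_hat"})

        stage = "call"
        logger.info(
            "call: prob_threshold=%.2f min_donors=%d", config.prob_threshold, config.min_donors
        )
        n_donors_present = counts["donor"].nunique()
        if config.min_donors > n_donors_present:
            logger.warning(
                "min_donors=%d exceeds donors present (%d): no event can be significant",
                config.min_donors, n_donors_present,
            )
        calls = calls_mod.call_significant_table(
            dpsi,
            dpsi_threshold=config.dpsi_threshold,
            prob_threshold=config.prob_threshold,
            min_donors=config.min_donors,
        )
        sig_counts = {
            f"{cond}_{tp}h": int(
                calls[
                    (calls["condition"] == cond)
                    & (calls["timepoint"] == tp)
                    & calls["significant"]
                ].shape[0]
            )
            for cond in STIM_CONDITIONS
            for tp in (8, 48)
        }
        concordance = _donor_concordance(
            dpsi.rename(columns={"dpsi_hat": "dpsi"}), calls
        )

        stage = "classify"
        temporal = temporal_mod.classify_temporal_table(
            calls,
            condition="CD3CD28",
            input_set=config.temporal_input_set,
            fold_drop_threshold=config.fold_drop_threshold,
        )
        temporal_counts = temporal["temporal_class"].value_counts().to_dict()

        stage = "ratio"
        ratios = {}
        enhanced_fraction = {}
        ratio_histograms = {}
        for tp in (8, 48):
            rt = temporal_mod.costim_ratio_table(
                calls, tp, floor=config.ratio_floor, ratio_threshold=config.ratio_threshold
            )
            ratios[tp] = rt
            if len(rt):
                enhanced_fraction[f"{tp}h"] = float(rt["enhanced"].mean())
                bins = [-np.inf, -2, -1, 0, 1, 2, 3, 5, 10, np.inf]
                hist, _ = np.histogram(rt["ratio"], bins=bins)
                ratio_histograms[f"{tp}h"] = {
                    "bin_edges": [str(b) for b in bins],
                    "counts": hist.tolist(),
                }
            else:
                enhanced_fraction[f"{tp}h"] = 0.0
        # alternative denominator (CD3-significant events), reported alongside
        enhanced_fraction_cd3_denom = {}
        for tp in (8, 48):
            rt = temporal_mod.costim_ratio_table(
                calls, tp, floor=config.ratio_floor,
                ratio_threshold=config.ratio_threshold, denominator_set="CD3",
            )
            enhanced_fraction_cd3_denom[f"{tp}h"] = (
                float(rt["enhanced"].mean()) if len(rt) else 0.0
            )
        crosstab = temporal_mod.crosstab_enhanced_temporal(
            set(ratios[8].loc[ratios[8]["enhanced"], "event_id"]),
            set(ratios[48].loc[ratios[48]["enhanced"], "event_id"]),
            temporal,
        )

        stage = "baseline"
        unstim_psi = (
            psi[(psi["condition"] == "UNSTIM") & (psi["timepoint"] == 8)]
            .groupby("event_id", observed=True)["psi"]
            .mean()
        )
        sig_any = set(calls.loc[calls["significant"], "event_id"])
        baseline = None
        if sig_any:
            baseline = calls_mod.baseline_psi_summary(
                unstim_psi[unstim_psi.index.isin(sig_any)].to_numpy(),
                unstim_psi.to_numpy(),
            )

        stage = "annotate"
        event_types = None
        spliced_genes = None
        if annotations is not None:
            event_types = calls_mod.summarize_event_types(sig_any, annotations)
            gene_of = dict(zip(annotations["name"], annotations["gene_id"]))
            spliced_genes = {gene_of[e] for e in sig_any if e in gene_of}

        stage = "expression"
        expr_report = None
        if expression is not None:
            de_sets = {}
            for cond in ("CD3", "CD3CD28"):
                sub = expression[
                    (expression["condition"] == cond) & (expression["timepoint"] == 48)
                ]
                if len(sub):
                    de_sets[cond] = calls_mod.call_de_genes(sub, config.log2fc_threshold)
            expr_report = {"n_de_genes_48h": {c: len(s) for c, s in de_sets.items()}}
            if spliced_genes is not None and "CD3CD28" in de_sets:
                expr_report["splicing_expression_overlap"] = (
                    calls_mod.splicing_expression_overlap(spliced_genes, de_sets["CD3CD28"])
                )
            sub3 = expression[
                (expression["condition"] == "CD3") & (expression["timepoint"] == 48)
            ]
            sub328 = expression[
                (expression["condition"] == "CD3CD28") & (expression["timepoint"] == 48)
            ]
            if len(sub3) and len(sub328):
                fc3 = {g: 2.0**v for g, v in zip(sub3["gene_id"], sub3["log2fc"])}
                fc328 = {g: 2.0**v for g, v in zip(sub328["gene_id"], sub328["log2fc"])}
                rbp_flags = {
                    g: bool(f) for g, f in zip(sub3["gene_id"], sub3["is_rbp"])
                }
                enhanced_rbps = calls_mod.cd28_enhanced_expression(
                    fc328, fc3, rbp_flags=rbp_flags
                )
                expr_report["n_cd28_enhanced_rbps"] = len(enhanced_rbps)

        stage = "enrich"
        motif_report = None
        enrichment = None
        if genome is not None and annotations is not None:
            ann_records = _annotation_records(annotations)
            cassette = {
                eid for eid, a in ann_records.items()
                if a.event_type is EventType.CASSETTE
            }
            fg_ids = sorted(
                set(ratios[48].loc[ratios[48]["enhanced"], "event_id"]) & cassette
            )
            bg_ids = sorted(
                (set(ratios[48]["event_id"]) - set(fg_ids)) & cassette
            )
            if len(fg_ids) >= 2 and bg_ids:
                fg_w = [
                    motifs_mod.extract_windows(
                        ann_records[e], genome, config.flank,
                        config.donor_exclusion, config.acceptor_exclusion,
                    )
                    for e in fg_ids
                ]
                bg_w = [
                    motifs_mod.extract_windows(
                        ann_records[e], genome, config.flank,
                        config.donor_exclusion, config.acceptor_exclusion,
                    )
                    for e in bg_ids
                ]
                logger.info(
                    "enrich: %d fg vs %d bg windows, k=%d..%d, E<%g ratio>%g",
                    len(fg_w), len(bg_w), config.k_min, config.k_max,
                    config.e_value_cutoff, config.enrichment_ratio_cutoff,
                )
                enrichment = motifs_mod.kmer_enrichment(
                    fg_w, bg_w, config.k_min, config.k_max,
                    config.e_value_cutoff, config.enrichment_ratio_cutoff,
                )
                sig_kmers = enrichment.loc[enrichment["significant"], "kmer"].tolist()
                motif_report = {
                    "n_kmers_tested": int(len(enrichment)),
                    "n_significant": len(sig_kmers),
                    "top_significant_kmers": sig_kmers[:20],
                }
                if rbp_table:
                    motif_report["rbp_matches"] = motifs_mod.match_rbp_motifs(
                        sig_kmers[:50], rbp_table
                    )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "thresholds": {
            "dpsi_threshold": config.dpsi_threshold,
            "prob_threshold": config.prob_threshold,
            "min_donors": config.min_donors,
            "ratio_floor": config.ratio_floor,
            "ratio_threshold": config.ratio_threshold,
            "fold_drop_threshold": config.fold_drop_threshold,
            "e_value_cutoff": config.e_value_cutoff,
            "enrichment_ratio_cutoff": config.enrichment_ratio_cutoff,
            "log2fc_threshold": config.log2fc_threshold,
            "seed": config.seed,
        },
        "significant_event_counts": sig_counts,
        "donor_concordance": concordance,
        "temporal_class_counts": temporal_counts,
        "enhanced_fraction": enhanced_fraction,
        "enhanced_fraction_cd3_denominator": enhanced_fraction_cd3_denom,
        "ratio_histograms": ratio_histograms,
        "enhanced_temporal_crosstab": crosstab,
        "baseline_psi": baseline,
        "event_type_summary": event_types,
        "expression": expr_report,
        "motif_enrichment": motif_report,
    }

    if write_outputs:
        out_cols = ["event_id", "donor", "condition", "timepoint", "psi", "dpsi", "prob_exceeds"]
        io_mod.write_psi_table(psi[out_cols], outdir / "psi_dpsi.tsv")
        io_mod.write_calls_table(calls, outdir / "significance_calls.tsv")
        temporal.to_csv(outdir / "temporal_classes.tsv", sep="\t", index=False)
        for tp in (8, 48):
            ratios[tp].to_csv(outdir / f"costim_ratios_{tp}h.tsv", sep="\t", index=False)
        if enrichment is not None:
            enrichment.head(5000).to_csv(outdir / "kmer_enrichment.tsv", sep="\t", index=False)
        io_mod.write_report(report, outdir / "report.json")
    return report
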