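"""Synthetic junction-count experiments with planted ground truth.

Emulates the structure of a paired stimulation time-course in primary CD4+
T cells: three donors, four stimulation arms (unstimulated, anti-CD28,
anti-CD3, anti-CD3/CD28) and two timepoints (8 h, 48 h), with splice
junction read counts per event and sample.

Planted event classes
---------------------
NULL
    PSI identical across all arms and timepoints (pure noise events).
CD3_ONLY
    A TCR-driven dPSI of the same size under CD3 and CD3/CD28
    (enhancement ratio 1); no effect under CD28 alone.
CD28_ENHANCED
    dPSI under CD3/CD28 equals ``true_ratio`` (> 2) times the CD3 dPSI,
    with the costimulated effect at least 0.10 so it is callable.

Every regulated event additionally carries a temporal trajectory:
Early/Transient (full effect at 8 h decaying to less than half by 48 h),
Early/Sustained (effect at 8 h retained at 48 h) or Late (effect only at
48 h).

Counts are generated hierarchically: a per-(donor, event) effect on the
logit-PSI scale models donor variability; total junction depth is Poisson;
inclusion evidence is beta-binomial (``overdispersion`` rho in [0, 1),
rho = 0 recovering the binomial). An included fragment spans both flanking
junctions of a cassette exon, so inclusion evidence I contributes 2I
junction observations split evenly (binomially) between the two inclusion
junctions — each inclusion junction then carries the full inclusion
evidence on average, matching the junction-averaging PSI estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    CONDITIONS,
    TIMEPOINTS,
    EventClass,
    EventTruth,
    EventType,
    TemporalClass,
)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic experiment.

    Defaults mirror the experimental design being emulated (3 donors,
    4 arms, 8/48 h) with a read depth of 100 junction reads per event and
    sample, mild overdispersion and moderate donor variability.
    """

    n_events: int = 1000
    n_donors: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    timepoints: tuple[int, ...] = TIMEPOINTS
    class_proportions: dict[EventClass, float] = field(
        default_factory=lambda: {
            EventClass.NULL: 0.70,
            EventClass.CD3_ONLY: 0.20,
            EventClass.CD28_ENHANCED: 0.10,
        }
    )
    temporal_proportions: dict[TemporalClass, float] = field(
        default_factory=lambda: {
            TemporalClass.EARLY_TRANSIENT: 0.2,
            TemporalClass.EARLY_SUSTAINED: 0.3,
            TemporalClass.LATE: 0.5,
        }
    )
    # Mixture on (0,1) for unstimulated PSI: weight on a mid-range
    # Beta(mid_a, mid_b) component, remainder Beta(tail_a, tail_b).
    baseline_psi_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "mid_weight": 0.7,
            "mid_a": 6.0,
            "mid_b": 6.0,
            "tail_a": 1.2,
            "tail_b": 1.2,
        }
    )
    donor_sd: float = 0.15
    mean_depth: float = 100.0
    overdispersion: float = 0.01  # beta-binomial rho; 0 = binomial
    # effect-size ranges (fraction scale) for regulated events
    effect_min: float = 0.12
    effect_max: float = 0.35
    ratio_min: float = 3.0
    ratio_max: float = 5.0
    transient_decay: float = 0.2  # 48 h effect as fraction of 8 h (transient)
    sustained_retention: float = 0.85  # 48 h effect as fraction of 8 h (sustained)
    event_type_proportions: dict[EventType, float] = field(
        default_factory=lambda: {
            EventType.CASSETTE: 0.55,
            EventType.ALT5SS: 0.08,
            EventType.ALT3SS: 0.05,
            EventType.INTRON_RETENTION: 0.02,
            EventType.COMPLEX: 0.30,
        }
    )
    intron_length: int = 400
    exon_length: int = 120
    flank_exon_length: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0 or self.n_donors <= 0:
            raise ValueError("n_events and n_donors must be positive")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if abs(sum(self.temporal_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("temporal_proportions must sum to 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.overdispersion < 1):
            raise ValueError("overdispersion must be in [0, 1)")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be non-negative")


def _draw_baseline_psi(rng: np.random.Generator, params: dict[str, float]) -> float:
    if rng.random() < params["mid_weight"]:
        return float(rng.beta(params["mid_a"], params["mid_b"]))
    return float(rng.beta(params["tail_a"], params["tail_b"]))


def _temporal_profile(cls: TemporalClass, config: SimulationConfig) -> dict[int, float]:
    if cls is TemporalClass.EARLY_TRANSIENT:
        return {8: 1.0, 48: config.transient_decay}
    if cls is TemporalClass.EARLY_SUSTAINED:
        return {8: 1.0, 48: config.sustained_retention}
    return {8: 0.0, 48: 1.0}  # LATE


def simulate_truth(config: SimulationConfig) -> list[EventTruth]:
    """Draw per-event ground truth (class, trajectory, PSI surface).

    Event classes follow ``class_proportions``; CD28-enhanced events have
    dPSI(CD3/CD28) = true_ratio x dPSI(CD3) with |dPSI(CD3/CD28)| >= 0.10.
    Effect signs are chosen toward whichever PSI bound leaves room, so the
    full PSI surface stays inside (0, 1) without clipping that would
    distort the planted ratio.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    classes = sorted(config.class_proportions, key=lambda c: c.value)
    class_p = np.array([config.class_proportions[c] for c in classes])
    tclasses = sorted(config.temporal_proportions, key=lambda c: c.value)
    temporal_p = np.array([config.temporal_proportions[c] for c in tclasses])

    truth: list[EventTruth] = []
    width = len(str(max(config.n_events - 1, 1)))
    for i in range(config.n_events):
        event_id = f"ev{i:0{width}d}"
        event_class = classes[rng.choice(len(classes), p=class_p)]
        baseline = _draw_baseline_psi(rng, config.baseline_psi_distribution)

        if event_class is EventClass.NULL:
            psi = {
                (cond, tp): baseline
                for cond in config.conditions
                for tp in config.timepoints
            }
            truth.append(
                EventTruth(event_id, event_class, TemporalClass.NONE, psi, None)
            )
            continue

        temporal = tclasses[rng.choice(len(tclasses), p=temporal_p)]
        profile = _temporal_profile(temporal, config)
        peak = float(rng.uniform(config.effect_min, config.effect_max))
        if event_class is EventClass.CD28_ENHANCED:
            ratio = float(rng.uniform(config.ratio_min, config.ratio_max))
            peak = max(peak, 0.10)
            effect = {"CD28": 0.0, "CD3": peak / ratio, "CD3CD28": peak}
        else:
            ratio = 1.0
            effect = {"CD28": 0.0, "CD3": peak, "CD3CD28": peak}

        sign = 1.0 if rng.random() < 0.5 else -1.0
        # keep baseline + sign*peak inside (0.02, 0.98); flip if out of room
        margin = 0.02
        if sign > 0 and baseline + peak > 1 - margin:
            sign = -1.0
        if sign < 0 and baseline - peak < margin:
            sign = 1.0
            if baseline + peak > 1 - margin:
                baseline = 0.5
        psi = {}
        for cond in config.conditions:
            for tp in config.timepoints:
                if cond == "UNSTIM":
                    psi[(cond, tp)] = baseline
                else:
                    psi[(cond, tp)] = baseline + sign * effect[cond] * profile[tp]
        truth.append(EventTruth(event_id, event_class, temporal, psi, ratio))
    return truth


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial draws; rho = 0 is exactly binomial; p in {0,1} stays exact."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n)
    if rho == 0:
        return rng.binomial(n, p)
    conc = (1.0 - rho) / rho
    a = np.clip(p * conc, 1e-12, None)
    b = np.clip((1.0 - p) * conc, 1e-12, None)
    q = rng.beta(a, b)
    q = np.where(p == 0.0, 0.0, np.where(p == 1.0, 1.0, q))
    return rng.binomial(n, q)


def simulate_counts(truth: list[EventTruth], config: SimulationConfig) -> pd.DataFrame:
    """Generate the junction-count table (one row per event x sample).

    Columns: event_id, donor, condition, timepoint, inc_junc1, inc_junc2,
    exc_junc. The per-(donor, event) effect is additive on the logit-PSI
    scale with standard deviation ``donor_sd``; boundary PSI values 0 and 1
    are preserved exactly.
    """
    if not truth:
        raise ValueError("truth must be nonempty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    donors = [f"donor{d + 1}" for d in range(config.n_donors)]
    n_ev = len(truth)

    # donor-by-event baseline shift on the logit scale
    delta = rng.normal(0.0, config.donor_sd, size=(config.n_donors, n_ev))

    rows = []
    for cond in config.conditions:
        for tp in config.timepoints:
            psi_true = np.array([ev.true_psi[(cond, tp)] for ev in truth])
            boundary = (psi_true <= 0.0) | (psi_true >= 1.0)
            logit = np.log(
                np.clip(psi_true, 1e-9, 1 - 1e-9)
                / (1 - np.clip(psi_true, 1e-9, 1 - 1e-9))
            )
            for di, donor in enumerate(donors):
                p = 1.0 / (1.0 + np.exp(-(logit + delta[di])))
                p = np.where(boundary, psi_true, p)
                depth = rng.poisson(config.mean_depth, size=n_ev)
                inc = _beta_binomial(rng, depth, p, config.overdispersion)
                exc = depth - inc
                inc1 = rng.binomial(2 * inc, 0.5)
                inc2 = 2 * inc - inc1
                rows.append(
                    pd.DataFrame(
                        {
                            "event_id": [ev.event_id for ev in truth],
                            "donor": donor,
                            "condition": cond,
                            "timepoint": tp,
                            "inc_junc1": inc1,
                            "inc_junc2": inc2,
                            "exc_junc": exc,
                        }
                    )
                )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["event_id", "donor", "condition", "timepoint"], ignore_index=True
    )


def truth_table(truth: list[EventTruth]) -> pd.DataFrame:
    """Flatten EventTruth records into a TSV-ready table (percent scale PSI)."""
    rows = []
    for ev in truth:
        row = {
            "event_id": ev.event_id,
            "event_class": ev.event_class.value,
            "temporal_class_true": ev.temporal_class_true.value,
            "true_ratio": "" if ev.true_ratio is None else f"{ev.true_ratio:.6g}",
            "motif_planted": int(ev.motif_planted),
        }
        for (cond, tp), v in ev.true_psi.items():
            row[f"psi_{cond}_{tp}h"] = round(100.0 * v, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_genome(
    truth: list[EventTruth],
    motif: str,
    planted_fraction_fg: float,
    planted_fraction_bg: float,
    config: SimulationConfig,
    flank: int = 250,
    donor_exclusion: int = 7,
    acceptor_exclusion: int = 30,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build one cassette-exon locus per event, planting ``motif`` in flanks.

    Each locus is its own contig laid out (in transcript orientation) as
    upstream exon / intron / cassette exon / intron / downstream exon.
    The motif is inserted into the analysable part of the downstream
    intronic window — between the 7 bp donor-site exclusion and the 250 bp
    flank limit — for a ``planted_fraction_fg`` share of CD28-enhanced
    events and a ``planted_fraction_bg`` share of all others. Roughly half
    of the loci are written reverse-complemented with strand '-'.

    Mutates ``EventTruth.motif_planted`` in place to record planting.
    Returns (genome dict chrom -> sequence, annotation DataFrame with
    0-based half-open coordinates on the written genome).
    """
    motif = motif.upper()
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    if not (0 <= planted_fraction_fg <= 1 and 0 <= planted_fraction_bg <= 1):
        raise ValueError("planted fractions must be in [0, 1]")
    if config.intron_length < flank:
        raise ValueError(
            f"intron_length {config.intron_length} too short to host {flank} bp windows"
        )
    if config.intron_length < 300:
        raise ValueError("flanking introns must be >= 300 bp")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    etypes = sorted(config.event_type_proportions, key=lambda t: t.value)
    etype_p = np.array([config.event_type_proportions[t] for t in etypes])

    genome: dict[str, str] = {}
    rows = []
    bases = np.array(list("ACGT"))
    for ev in truth:
        exon_len = config.exon_length
        fl = config.flank_exon_length
        il = config.intron_length
        total = 2 * fl + 2 * il + exon_len
        seq = rng.choice(bases, size=total)
        exon_start = fl + il
        exon_end = exon_start + exon_len

        frac = (
            planted_fraction_fg
            if ev.event_class is EventClass.CD28_ENHANCED
            else planted_fraction_bg
        )
        planted = bool(rng.random() < frac)
        if planted:
            lo = exon_end + donor_exclusion
            hi = exon_end + flank - len(motif)
            pos = int(rng.integers(lo, hi + 1))
            seq[pos : pos + len(motif)] = list(motif)
        ev.motif_planted = planted

        design = "".join(seq)
        minus = bool(rng.random() < 0.5)
        chrom = f"contig_{ev.event_id}"
        if minus:
            genome[chrom] = reverse_complement(design)
            s, e = total - exon_end, total - exon_start
            up_s, up_e = total - fl, total
            dn_s, dn_e = 0, fl
            strand = "-"
        else:
            genome[chrom] = design
            s, e = exon_start, exon_end
            up_s, up_e = 0, fl
            dn_s, dn_e = total - fl, total
            strand = "+"
        etype = etypes[rng.choice(len(etypes), p=etype_p)]
        rows.append(
            {
                "chrom": chrom,
                "start": s,
                "end": e,
                "name": ev.event_id,
                "score": 0,
                "strand": strand,
                "gene_id": f"gene_{ev.event_id}",
                "event_type": etype.value,
                "upstream_exon_start": up_s,
                "upstream_exon_end": up_e,
                "downstream_exon_start": dn_s,
                "downstream_exon_end": dn_e,
            }
        )
    return genome, pd.DataFrame(rows)


def simulate_expression(
    n_genes: int = 2000,
    n_rbps: int = 300,
    n_de: int = 400,
    n_cd28_enhanced_rbps: int = 49,
    timepoint: int = 48,
    log2fc_sd: float = 0.4,
    de_log2fc: float = 2.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-expression fold-change table with planted DE and enhanced RBPs.

    One row per gene x stimulated condition for ``timepoint``; columns
    gene_id, condition, timepoint, log2fc, is_rbp, plus the planted truth
    columns true_de and true_cd28_enhanced_rbp. CD28-enhanced RBPs receive
    a CD3/CD28 linear fold change at least twice their CD3 fold change.
    """
    if n_cd28_enhanced_rbps > n_rbps or n_rbps > n_genes:
        raise ValueError("need n_cd28_enhanced_rbps <= n_rbps <= n_genes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    is_rbp = np.zeros(n_genes, dtype=bool)
    is_rbp[:n_rbps] = True
    enhanced_rbp = np.zeros(n_genes, dtype=bool)
    enh_idx = rng.choice(n_rbps, size=n_cd28_enhanced_rbps, replace=False)
    enhanced_rbp[enh_idx] = True
    de = np.zeros(n_genes, dtype=bool)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de[de_idx] = True

    rows = []
    base = rng.normal(0.0, log2fc_sd, size=n_genes)
    base = np.where(de, np.sign(rng.random(n_genes) - 0.5) * de_log2fc, base)
    lfc_by_cond = {
        cond: base + rng.normal(0.0, 0.05, size=n_genes)
        for cond in ("CD28", "CD3", "CD3CD28")
    }
    # planted enhanced RBPs get at least a twofold linear boost over their
    # realized CD3 fold change, so the planted set is exactly recoverable
    lfc_by_cond["CD3CD28"] = np.where(
        enhanced_rbp,
        lfc_by_cond["CD3"] + 1.0 + rng.uniform(0, 0.5, n_genes),
        lfc_by_cond["CD3CD28"],
    )
    for cond in ("CD28", "CD3", "CD3CD28"):
        lfc = lfc_by_cond[cond]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "condition": cond,
                    "timepoint": timepoint,
                    "log2fc": np.round(lfc, 6),
                    "is_rbp": is_rbp.astype(int),
                    "true_de": de.astype(int),
                    "true_cd28_enhanced_rbp": enhanced_rbp.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
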