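"""Shared domain types for the costimulation splicing pipeline.

Conditions follow the four-arm stimulation design of primary CD4+ T cell
experiments: unstimulated control, anti-CD28 alone, anti-CD3 alone (TCR
engagement) and anti-CD3/CD28 (costimulation), each sampled at an early
(8 h) and a late (48 h) timepoint.

All PSI (percent spliced-in) values are stored internally on the fraction
scale [0, 1]; file formats use percent (see :mod:`costimsplice.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


CONDITIONS = ("UNSTIM", "CD28", "CD3", "CD3CD28")
STIM_CONDITIONS = ("CD28", "CD3", "CD3CD28")
TIMEPOINTS = (8, 48)


class EventClass(str, enum.Enum):
    """Planted ground-truth class of a simulated splicing event."""

    NULL = "NULL"
    CD3_ONLY = "CD3_ONLY"
    CD28_ENHANCED = "CD28_ENHANCED"


class TemporalClass(str, enum.Enum):
    """Trajectory of a regulated event between the 8 h and 48 h timepoints."""

    EARLY_TRANSIENT = "EARLY_TRANSIENT"
    EARLY_SUSTAINED = "EARLY_SUSTAINED"
    LATE = "LATE"
    NONE = "NONE"


class EventType(str, enum.Enum):
    """Structural category of a local splicing variation."""

    CASSETTE = "CASSETTE"
    ALT5SS = "ALT5SS"
    ALT3SS = "ALT3SS"
    INTRON_RETENTION = "INTRON_RETENTION"
    COMPLEX = "COMPLEX"


@dataclass
class JunctionCountRecord:
    """Raw junction read counts for one event in one sample.

    A cassette exon has two inclusion junctions (upstream-exon/cassette and
    cassette/downstream-exon) and one exclusion junction.
    """

    event_id: str
    donor: str
    condition: str
    timepoint: int
    inclusion_counts: list[int]
    exclusion_counts: list[int]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if not self.inclusion_counts and not self.exclusion_counts:
            raise ValueError("at least one junction count list must be nonempty")
        for c in list(self.inclusion_counts) + list(self.exclusion_counts):
            if c < 0 or int(c) != c:
                raise ValueError(f"junction counts must be non-negative integers, got {c}")


@dataclass
class PsiEstimate:
    """Beta-posterior summary of PSI for one event/sample.

    ``alpha`` and ``beta`` are the parameters of the posterior
    Beta(alpha, beta) on effective (junction-averaged) counts, and
    ``psi_hat`` is its mean.
    """

    event_id: str
    donor: str
    condition: str
    timepoint: int
    psi_hat: float
    alpha: float
    beta: float
    low_coverage: bool = False


@dataclass
class DpsiEstimate:
    """dPSI (stimulated PSI minus unstimulated PSI) for one donor/timepoint.

    ``prob_exceeds`` is the posterior probability that |dPSI| is at least
    the configured threshold, under independent beta posteriors for the
    stimulated and unstimulated arms.
    """

    event_id: str
    donor: str
    condition: str  # stimulated arm
    timepoint: int
    dpsi_hat: float
    prob_exceeds: float


@dataclass
class SignificanceCall:
    """Per-event decision from the >=min_donors-of-n reproducibility rule."""

    event_id: str
    condition: str
    timepoint: int
    per_donor_pass: dict[str, bool]
    n_donors_pass: int
    significant: bool
    mean_dpsi: float


@dataclass
class EventAnnotation:
    """Genomic annotation of one splicing event (0-based half-open)."""

    event_id: str
    gene_id: str
    event_type: EventType
    chrom: str
    exon_start: int
    exon_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.exon_start >= self.exon_end:
            raise ValueError("exon_start must be < exon_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class ExpressionRecord:
    gene_id: str
    condition: str
    timepoint: int
    log2fc: float
    is_rbp: bool = False


@dataclass
class TemporalClassification:
    event_id: str
    temporal_class: TemporalClass
    dpsi_8h: float
    dpsi_48h: float
    sig_8h: bool
    sig_48h: bool


@dataclass
class CostimRatio:
    """CD3/CD28-over-CD3 dPSI enhancement ratio with the 1% denominator floor."""

    event_id: str
    timepoint: int
    dpsi_cd3: float
    dpsi_cd3cd28: float
    dpsi_cd3_floored: float
    ratio: float
    enhanced: bool
    sign_conflict: bool


@dataclass
class SequenceWindow:
    """Flanking-intron and exon sequences for one cassette event.

    Sequences are reported 5'->3' in transcript orientation; minus-strand
    loci are reverse-complemented at extraction time.
    """

    event_id: str
    upstream_seq: str
    exon_seq: str
    downstream_seq: str
    strand_applied: bool
    truncated: bool = False


@dataclass
class MotifEnrichment:
    kmer: str
    fg_windows_with: int
    fg_total: int
    bg_windows_with: int
    bg_total: int
    enrichment_ratio: float
    p_value: float
    e_value: float
    significant: bool


@dataclass
class EventTruth:
    """Ground truth for one simulated event, enabling recovery tests."""

    event_id: str
    event_class: EventClass
    temporal_class_true: TemporalClass
    true_psi: dict[tuple[str, int], float]
    true_ratio: Optional[float]
    motif_planted: bool = False
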