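"""Significance calls, donor concordance and expression-side analyses.

The reproducibility rule mirrors standard practice for donor-replicated
splicing screens: a splicing event is significant for a given stimulation
arm and timepoint when, in at least ``min_donors`` of the donors assayed,
the dPSI point estimate exceeds 10% in magnitude *and* the posterior
probability that |dPSI| >= 10% exceeds 0.95. The magnitude convention
(|dPSI|, both directions count) is used throughout, since biologically
meaningful events include both increased inclusion and increased skipping.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import DpsiEstimate, EventAnnotation, EventType, SignificanceCall

DEFAULT_LOG2FC_THRESHOLD = 1.5


def call_significant(
    dpsi_records: list[DpsiEstimate],
    dpsi_threshold: float = 0.10,
    prob_threshold: float = 0.95,
    min_donors: int = 2,
    magnitude: bool = True,
) -> SignificanceCall:
    """Apply the per-donor threshold rule and the >=min_donors vote.

    ``magnitude=False`` switches to a one-sided (increase-only) reading of
    the dPSI cutoff.
    """
    if not dpsi_records:
        raise ValueError("need at least one donor record")
    key = {(r.event_id, r.condition, r.timepoint) for r in dpsi_records}
    if len(key) != 1:
        raise ValueError(f"records span multiple event/condition/timepoint keys: {key}")
    donors = [r.donor for r in dpsi_records]
    if len(set(donors)) != len(donors):
        raise ValueError("duplicate donor records")
    per_donor = {}
    for r in dpsi_records:
        effect = abs(r.dpsi_hat) if magnitude else r.dpsi_hat
        per_donor[r.donor] = bool(effect > dpsi_threshold and r.prob_exceeds > prob_threshold)
    n_pass = sum(per_donor.values())
    event_id, condition, timepoint = next(iter(key))
    return SignificanceCall(
        event_id=event_id,
        condition=condition,
        timepoint=timepoint,
        per_donor_pass=per_donor,
        n_donors_pass=n_pass,
        significant=n_pass >= min_donors,
        mean_dpsi=float(np.mean([r.dpsi_hat for r in dpsi_records])),
    )


def call_significant_table(
    dpsi: pd.DataFrame,
    dpsi_threshold: float = 0.10,
    prob_threshold: float = 0.95,
    min_donors: int = 2,
    magnitude: bool = True,
) -> pd.DataFrame:
    """Vectorised significance calls over a dPSI table.

    ``dpsi`` needs columns event_id, donor, condition, timepoint,
    dpsi_hat, prob_exceeds (fraction scale). Returns one row per
    event/condition/timepoint with n_donors_pass, significant, mean_dpsi.
    """
    if dpsi.duplicated(["event_id", "donor", "condition", "timepoint"]).any():
        raise ValueError("duplicate donor records in dPSI table")
    effect = dpsi["dpsi_hat"].abs() if magnitude else dpsi["dpsi_hat"]
    passed = (effect > dpsi_threshold) & (dpsi["prob_exceeds"] > prob_threshold)
    g = dpsi.assign(_pass=passed).groupby(
        ["event_id", "condition", "timepoint"], sort=True, observed=True
    )
    out = g.agg(
        n_donors_pass=("_pass", "sum"),
        n_donors=("_pass", "size"),
        mean_dpsi=("dpsi_hat", "mean"),
    ).reset_index()
    out["significant"] = out["n_donors_pass"] >= min_donors
    return out


def donor_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two donors' dPSI vectors over shared events."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 shared events")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def donor_overlap(sets: dict[str, set]) -> dict[str, dict[tuple[str, ...], int]]:
    """Intersection and union sizes for every subset of >=1 donors."""
    if len(sets) < 2:
        raise ValueError("need at least 2 donor sets")
    donors = sorted(sets)
    inter: dict[tuple[str, ...], int] = {}
    union: dict[tuple[str, ...], int] = {}
    for r in range(1, len(donors) + 1):
        for combo in combinations(donors, r):
            inter[combo] = len(set.intersection(*(set(sets[d]) for d in combo)))
            union[combo] = len(set.union(*(set(sets[d]) for d in combo)))
    return {"intersection": inter, "union": union}


def baseline_psi_summary(
    unstim_psi_significant: np.ndarray, unstim_psi_all: np.ndarray
) -> dict:
    """Compare baseline (unstimulated) PSI of regulated events vs all events.

    An unbiased baseline distribution (small KS D) indicates that
    regulated events are not preselected for skewed starting PSI.
    Returns deciles of both distributions and the two-sample KS statistic.
    """
    sig = np.asarray(unstim_psi_significant, dtype=float)
    allv = np.asarray(unstim_psi_all, dtype=float)
    if sig.size == 0 or allv.size == 0:
        raise ValueError("both PSI vectors must be nonempty")
    for v in (sig, allv):
        if np.any((v < 0) | (v > 1)):
            raise ValueError("PSI values must lie in [0, 1]")
    qs = np.arange(0.1, 1.0, 0.1)
    ks = stats.ks_2samp(sig, allv, method="asymp")
    return {
        "deciles_significant": np.quantile(sig, qs).tolist(),
        "deciles_all": np.quantile(allv, qs).tolist(),
        "ks_statistic": float(ks.statistic),
    }


def summarize_event_types(
    significant_event_ids: set[str], annotations: dict[str, EventAnnotation] | pd.DataFrame
) -> dict[str, dict]:
    """Counts and proportions of event types among significant events."""
    if isinstance(annotations, pd.DataFrame):
        ann_map = dict(zip(annotations["name"], annotations["event_type"]))
    else:
        ann_map = {eid: a.event_type.value for eid, a in annotations.items()}
    missing = set(significant_event_ids) - set(ann_map)
    if missing:
        raise KeyError(f"unannotated significant events: {sorted(missing)[:5]}...")
    counts: dict[str, int] = {t.value: 0 for t in EventType}
    for eid in significant_event_ids:
        counts[ann_map[eid]] += 1
    total = max(sum(counts.values()), 1)
    props = {t: c / total for t, c in counts.items()}
    return {"counts": counts, "proportions": props}


def call_de_genes(
    expr: pd.DataFrame, log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD
) -> set[str]:
    """Genes with |log2FC| strictly above the threshold (direction-agnostic)."""
    if expr.duplicated(["gene_id", "condition", "timepoint"]).any():
        raise ValueError("expected one record per gene/condition/timepoint")
    if not np.isfinite(expr["log2fc"]).all():
        raise ValueError("log2fc values must be finite")
    hits = expr.loc[expr["log2fc"].abs() > log2fc_threshold, "gene_id"]
    return set(hits)


def splicing_expression_overlap(spliced_genes: set, de_genes: set) -> dict[str, float]:
    """Exact overlap statistics between splicing-regulated and DE gene sets."""
    a, b = set(spliced_genes), set(de_genes)
    inter = len(a & b)
    union = len(a | b)
    return {
        "intersection": inter,
        "splicing_only": len(a - b),
        "expression_only": len(b - a),
        "jaccard": inter / union if union else 0.0,
    }


def cd28_enhanced_expression(
    fc_cd3cd28: dict[str, float],
    fc_cd3: dict[str, float],
    ratio_threshold: float = 2.0,
    rbp_flags: dict[str, bool] | None = None,
) -> set[str]:
    """Genes expressed at least ``ratio_threshold`` times as highly under
    CD3/CD28 costimulation as under CD3 alone (linear fold changes,
    inclusive >=). Restricted to RBP-encoding genes when ``rbp_flags`` is
    given.
    """
    enhanced = set()
    for gene in set(fc_cd3cd28) & set(fc_cd3):
        fc28, fc3 = fc_cd3cd28[gene], fc_cd3[gene]
        if fc28 <= 0 or fc3 <= 0:
            raise ValueError(f"fold changes must be positive (gene {gene})")
        if fc28 / fc3 >= ratio_threshold:
            enhanced.add(gene)
    if rbp_flags is not None:
        enhanced &= {g for g, flag in rbp_flags.items() if flag}
    return enhanced
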