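"""Temporal trajectory classes and the CD28 enhancement ratio.

Trajectory classes partition regulated events by their behaviour between
8 h and 48 h of stimulation:

* Early/Transient — significant at 8 h, |dPSI| drops by more than
  ``fold_drop_threshold``-fold by 48 h;
* Early/Sustained — significant at 8 h, no more than a
  ``fold_drop_threshold``-fold drop;
* Late — all remaining (48 h-significant) events.

The enhancement ratio contrasts costimulated and TCR-only splicing change:
ratio = dPSI(CD3/CD28) / dPSI(CD3), with CD3 denominators below 1% in
magnitude floored to 1% so near-zero TCR-only changes cannot blow the
ratio up. Events with a ratio strictly greater than 2 (and concordant
signs) are CD28-enhanced.
"""

from __future__ import annotations

import math

import pandas as pd

from .types import CostimRatio, TemporalClass, TemporalClassification

DEFAULT_FLOOR = 0.01
DEFAULT_RATIO_THRESHOLD = 2.0
DEFAULT_FOLD_DROP = 2.0


def classify_temporal(
    event_id: str,
    dpsi_8h: float,
    dpsi_48h: float,
    sig_8h: bool,
    sig_48h: bool,
    fold_drop_threshold: float = DEFAULT_FOLD_DROP,
) -> TemporalClassification:
    """Assign exactly one trajectory class to a regulated event.

    Raises if the event is significant at neither timepoint (it then has
    no trajectory to classify).
    """
    if not (sig_8h or sig_48h):
        raise ValueError(f"event {event_id} significant at neither timepoint")
    if sig_8h and abs(dpsi_48h) < abs(dpsi_8h) / fold_drop_threshold:
        cls = TemporalClass.EARLY_TRANSIENT
    elif sig_8h:
        cls = TemporalClass.EARLY_SUSTAINED
    else:
        cls = TemporalClass.LATE
    return TemporalClassification(event_id, cls, dpsi_8h, dpsi_48h, sig_8h, sig_48h)


def classify_temporal_table(
    calls: pd.DataFrame,
    condition: str = "CD3CD28",
    input_set: str = "union",
    fold_drop_threshold: float = DEFAULT_FOLD_DROP,
) -> pd.DataFrame:
    """Classify every event significant at 8 h or 48 h for ``condition``.

    ``calls`` is a significance-call table (columns event_id, condition,
    timepoint, significant, mean_dpsi). ``input_set`` selects the events
    classified: "union" (significant at either timepoint, the default) or
    "sig_48h" (restricted to 48 h-significant events).
    """
    if input_set not in ("union", "sig_48h"):
        raise ValueError("input_set must be 'union' or 'sig_48h'")
    sub = calls[calls["condition"] == condition]
    wide = sub.pivot_table(
        index="event_id",
        columns="timepoint",
        values=["significant", "mean_dpsi"],
        aggfunc="first",
    )
    sig8 = wide.get(("significant", 8), pd.Series(False, index=wide.index)).fillna(False).astype(bool)
    sig48 = wide.get(("significant", 48), pd.Series(False, index=wide.index)).fillna(False).astype(bool)
    d8 = wide.get(("mean_dpsi", 8), pd.Series(0.0, index=wide.index)).fillna(0.0)
    d48 = wide.get(("mean_dpsi", 48), pd.Series(0.0, index=wide.index)).fillna(0.0)
    keep = sig48 if input_set == "sig_48h" else (sig8 | sig48)
    rows = []
    for eid in wide.index[keep]:
        tc = classify_temporal(
            eid, float(d8[eid]), float(d48[eid]), bool(sig8[eid]), bool(sig48[eid]),
            fold_drop_threshold,
        )
        rows.append(
            {
                "event_id": eid,
                "temporal_class": tc.temporal_class.value,
                "dpsi_8h": tc.dpsi_8h,
                "dpsi_48h": tc.dpsi_48h,
                "sig_8h": tc.sig_8h,
                "sig_48h": tc.sig_48h,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "temporal_class", "dpsi_8h", "dpsi_48h", "sig_8h", "sig_48h"],
    )


def costim_ratio(
    event_id: str,
    timepoint: int,
    dpsi_cd3: float,
    dpsi_cd3cd28: float,
    floor: float = DEFAULT_FLOOR,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> CostimRatio:
    """Enhancement ratio with the 1% denominator floor.

    The floored denominator keeps the sign of the CD3 dPSI (taking the
    sign of the costimulated dPSI when the CD3 dPSI is exactly zero), so
    concordant effects give positive ratios. Opposite-sign effects with
    both magnitudes above the floor are flagged ``sign_conflict`` and are
    never called enhanced.
    """
    if not (math.isfinite(dpsi_cd3) and math.isfinite(dpsi_cd3cd28)):
        raise ValueError("dPSI values must be finite")
    if dpsi_cd3 != 0.0:
        sign = math.copysign(1.0, dpsi_cd3)
    elif dpsi_cd3cd28 != 0.0:
        sign = math.copysign(1.0, dpsi_cd3cd28)
    else:
        sign = 1.0
    denom = sign * max(abs(dpsi_cd3), floor)
    ratio = dpsi_cd3cd28 / denom
    sign_conflict = (
        dpsi_cd3 * dpsi_cd3cd28 < 0
        and abs(dpsi_cd3) > floor
        and abs(dpsi_cd3cd28) > floor
    )
    enhanced = (ratio > ratio_threshold) and not sign_conflict
    return CostimRatio(
        event_id=event_id,
        timepoint=timepoint,
        dpsi_cd3=dpsi_cd3,
        dpsi_cd3cd28=dpsi_cd3cd28,
        dpsi_cd3_floored=denom,
        ratio=ratio,
        enhanced=enhanced,
        sign_conflict=sign_conflict,
    )


def costim_ratio_table(
    calls: pd.DataFrame,
    timepoint: int,
    floor: float = DEFAULT_FLOOR,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    denominator_set: str = "CD3CD28",
) -> pd.DataFrame:
    """Ratios for all events significant under ``denominator_set`` at ``timepoint``.

    Donor-mean dPSI values from the significance-call table feed the
    per-event ratio. ``denominator_set`` names the condition whose
    significant events define the analysis set ("CD3CD28" or "CD3").
    """
    sub = calls[calls["timepoint"] == timepoint]
    sig_ids = set(
        sub.loc[(sub["condition"] == denominator_set) & sub["significant"], "event_id"]
    )
    d3 = sub[sub["condition"] == "CD3"].set_index("event_id")["mean_dpsi"]
    d328 = sub[sub["condition"] == "CD3CD28"].set_index("event_id")["mean_dpsi"]
    rows = []
    for eid in sorted(sig_ids):
        r = costim_ratio(
            eid,
            timepoint,
            float(d3.get(eid, 0.0)),
            float(d328.get(eid, 0.0)),
            floor,
            ratio_threshold,
        )
        rows.append(
            {
                "event_id": eid,
                "timepoint": timepoint,
                "dpsi_cd3": r.dpsi_cd3,
                "dpsi_cd3cd28": r.dpsi_cd3cd28,
                "dpsi_cd3_floored": r.dpsi_cd3_floored,
                "ratio": r.ratio,
                "enhanced": r.enhanced,
                "sign_conflict": r.sign_conflict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "timepoint", "dpsi_cd3", "dpsi_cd3cd28",
            "dpsi_cd3_floored", "ratio", "enhanced", "sign_conflict",
        ],
    )


def enhanced_fraction(ratios: list[CostimRatio] | pd.DataFrame) -> float:
    """Fraction of the timepoint's analysis set called CD28-enhanced."""
    if isinstance(ratios, pd.DataFrame):
        if len(ratios) == 0:
            raise ValueError("empty ratio table")
        return float(ratios["enhanced"].mean())
    if not ratios:
        raise ValueError("empty ratio list")
    return sum(r.enhanced for r in ratios) / len(ratios)


def crosstab_enhanced_temporal(
    enhanced_8h: set[str],
    enhanced_48h: set[str],
    temporal: pd.DataFrame,
) -> dict:
    """Cross-tabulate enhancement timepoint against temporal class.

    Returns the full contingency counts plus the modal temporal class of
    each enhancement set (None when the set has no classified events).
    """
    cls = dict(zip(temporal["event_id"], temporal["temporal_class"]))
    classes = [c.value for c in TemporalClass if c is not TemporalClass.NONE]
    table = {
        "enhanced_8h": {c: 0 for c in classes},
        "enhanced_48h": {c: 0 for c in classes},
    }
    for name, ids in (("enhanced_8h", enhanced_8h), ("enhanced_48h", enhanced_48h)):
        for eid in ids:
            if eid in cls:
                table[name][cls[eid]] += 1
    modal = {}
    for name in table:
        counts = table[name]
        total = sum(counts.values())
        modal[name] = max(counts, key=lambda c: counts[c]) if total else None
    return {"counts": table, "modal_class": modal}
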