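"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 TSV with a header row. PSI and dPSI values are stored
in files on the percent scale with 4 decimal places (human-readable and
matching the ">10% dPSI" convention); every internal computation uses the
fraction scale. The converters here are the only place scaling occurs.

Annotations use BED-derived 0-based half-open coordinates; sequences use
FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CONDITIONS, TIMEPOINTS, JunctionCountRecord, SequenceWindow

JUNCTION_COLUMNS = [
    "event_id", "donor", "condition", "timepoint", "inc_junc1", "inc_junc2", "exc_junc",
]


def percent(fraction_values):
    """Fraction -> percent."""
    return np.asarray(fraction_values, dtype=float) * 100.0


def fraction(percent_values):
    """Percent -> fraction."""
    return np.asarray(percent_values, dtype=float) / 100.0


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a junction-count TSV.

    Raises ValueError naming the offending line for missing columns,
    negative counts, or unknown condition/timepoint labels.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        if row.condition not in CONDITIONS:
            raise ValueError(f"{path}:{i}: unknown condition {row.condition!r}")
        if row.timepoint not in TIMEPOINTS:
            raise ValueError(f"{path}:{i}: unknown timepoint {row.timepoint!r}")
        for col in ("inc_junc1", "inc_junc2", "exc_junc"):
            v = getattr(row, col)
            if not (np.isreal(v) and float(v) == int(v) and int(v) >= 0):
                raise ValueError(f"{path}:{i}: {col} must be a non-negative integer, got {v!r}")
    for col in ("inc_junc1", "inc_junc2", "exc_junc", "timepoint"):
        df[col] = df[col].astype(int)
    return df


def write_junction_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=JUNCTION_COLUMNS)


def junction_records(df: pd.DataFrame) -> list[JunctionCountRecord]:
    """Convert a junction-count table to typed records."""
    return [
        JunctionCountRecord(
            event_id=r.event_id,
            donor=r.donor,
            condition=r.condition,
            timepoint=int(r.timepoint),
            inclusion_counts=[int(r.inc_junc1), int(r.inc_junc2)],
            exclusion_counts=[int(r.exc_junc)],
        )
        for r in df.itertuples(index=False)
    ]


def write_psi_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a PSI/dPSI table, converting fraction columns to percent."""
    out = df.copy()
    for col in ("psi", "dpsi"):
        if col in out.columns:
            out[col] = np.round(percent(out[col]), 4)
    if "prob_exceeds" in out.columns:
        out["prob_exceeds"] = np.round(out["prob_exceeds"], 4)
    out.to_csv(path, sep="\t", index=False)


def read_psi_table(path: str | Path) -> pd.DataFrame:
    """Read a PSI/dPSI table back to the internal fraction scale."""
    df = pd.read_csv(path, sep="\t")
    for col in ("psi", "dpsi"):
        if col in df.columns:
            df[col] = fraction(df[col])
    return df


def write_calls_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["mean_dpsi"] = np.round(percent(out["mean_dpsi"]), 4)
    out["significant"] = out["significant"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_calls_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["mean_dpsi"] = fraction(df["mean_dpsi"])
    df["significant"] = df["significant"].astype(bool)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "name", "score", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {missing}")
    return df


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_windows_fasta(windows: list[SequenceWindow], path: str | Path) -> None:
    """Windows as FASTA, one record per region, header event_id|region."""
    records = []
    for w in windows:
        for region, seq in (
            ("upstream", w.upstream_seq),
            ("exon", w.exon_seq),
            ("downstream", w.downstream_seq),
        ):
            records.append(SeqRecord(Seq(seq), id=f"{w.event_id}|{region}", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "condition", "timepoint", "log2fc"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression column(s) {missing}")
    if "is_rbp" not in df.columns:
        df["is_rbp"] = 0
    return df


def read_rbp_table(path: str | Path) -> dict[str, list[str]]:
    """RBP motif table: TSV with columns rbp_name, consensus (one per row)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("rbp_name", "consensus"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    table: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        table.setdefault(r.rbp_name, []).append(str(r.consensus).upper())
    return table


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, rounded floats, trailing newline."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
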