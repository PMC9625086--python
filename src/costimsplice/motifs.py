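"""Flanking-intron sequence windows and k-mer enrichment.

Around each alternative cassette exon, the analysable sequence is the exon
itself plus up to 250 nt of each flanking intron, minus short exclusion
zones at the exon's own splice sites: 30 nt on the acceptor (3' splice
site, intron upstream in transcript orientation) side and 7 nt on the
donor (5' splice site, downstream intron) side, where near-invariant
splicing signals would otherwise dominate any enrichment. Windows are
reported 5'->3' on the transcript; minus-strand loci are
reverse-complemented. Coordinates are 0-based half-open.

Motif discovery is an exact k-mer presence/absence test: for every k-mer
(k between ``k_min`` and ``k_max``) present in at least two foreground
windows, a one-sided hypergeometric tail p-value on windows-with-motif
counts, a foreground/background rate ratio, and a Bonferroni-style
E-value (p times the number of k-mers tested). A k-mer is significant
when E < 0.05 and the enrichment ratio exceeds 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import reverse_complement
from .types import EventAnnotation, EventType, SequenceWindow

DEFAULT_FLANK = 250
DEFAULT_DONOR_EXCLUSION = 7
DEFAULT_ACCEPTOR_EXCLUSION = 30

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_BASES = "ACGT"


def _clamp(lo: int, hi: int, length: int) -> tuple[int, int, bool]:
    clo, chi = max(lo, 0), min(hi, length)
    if chi < clo:
        clo = chi = max(min(lo, length), 0)
    return clo, chi, (clo != lo or chi != hi)


def extract_windows(
    annotation: EventAnnotation,
    genome: dict[str, str],
    flank: int = DEFAULT_FLANK,
    donor_exclusion: int = DEFAULT_DONOR_EXCLUSION,
    acceptor_exclusion: int = DEFAULT_ACCEPTOR_EXCLUSION,
) -> SequenceWindow:
    """Extract the upstream-intron, exon and downstream-intron windows.

    In transcript orientation the upstream window covers the ``flank`` nt
    preceding the exon minus the ``acceptor_exclusion`` nt adjacent to the
    exon's 3' splice site; the downstream window covers the ``flank`` nt
    following the exon minus the ``donor_exclusion`` nt adjacent to the 5'
    splice site. Windows truncated by contig boundaries are flagged.
    """
    if annotation.event_type is not EventType.CASSETTE:
        raise ValueError(
            f"unsupported event type {annotation.event_type.value}: windows are "
            "defined for cassette exons only"
        )
    if annotation.chrom not in genome:
        raise KeyError(f"chrom {annotation.chrom!r} not in genome")
    seq = genome[annotation.chrom].upper()
    n = len(seq)
    s, e = annotation.exon_start, annotation.exon_end
    if s < 0 or e > n:
        raise IndexError(f"event {annotation.event_id} coordinates outside contig")

    if annotation.strand == "+":
        up_lo, up_hi = s - flank, s - acceptor_exclusion
        dn_lo, dn_hi = e + donor_exclusion, e + flank
        (a, b, t1), (c, d, t2) = _clamp(up_lo, up_hi, n), _clamp(dn_lo, dn_hi, n)
        upstream, downstream = seq[a:b], seq[c:d]
        exon = seq[s:e]
    else:
        # transcript-upstream intron lies genomically to the right
        up_lo, up_hi = e + acceptor_exclusion, e + flank
        dn_lo, dn_hi = s - flank, s - donor_exclusion
        (a, b, t1), (c, d, t2) = _clamp(up_lo, up_hi, n), _clamp(dn_lo, dn_hi, n)
        upstream = reverse_complement(seq[a:b])
        downstream = reverse_complement(seq[c:d])
        exon = reverse_complement(seq[s:e])
    return SequenceWindow(
        event_id=annotation.event_id,
        upstream_seq=upstream,
        exon_seq=exon,
        downstream_seq=downstream,
        strand_applied=(annotation.strand == "-"),
        truncated=t1 or t2,
    )


def _window_text(w: SequenceWindow) -> str:
    # the separator blocks k-mers from spanning region boundaries
    return f"{w.upstream_seq}#{w.exon_seq}#{w.downstream_seq}"


def _kmer_offsets(k_min: int, k_max: int) -> dict[int, int]:
    offsets, total = {}, 0
    for k in range(k_min, k_max + 1):
        offsets[k] = total
        total += 4**k
    offsets[-1] = total  # sentinel: total row count
    return offsets


def _presence_matrix(
    windows: list[SequenceWindow], k_min: int, k_max: int
) -> tuple[np.ndarray, dict[int, int]]:
    """Boolean (k-mer code x window) presence matrix over all window text."""
    offsets = _kmer_offsets(k_min, k_max)
    m = np.zeros((offsets[-1], len(windows)), dtype=np.uint8)
    for wi, w in enumerate(windows):
        b = _BASE_CODE[np.frombuffer(_window_text(w).encode("ascii"), dtype=np.uint8)]
        invalid = (b < 0).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(invalid)])
        for k in range(k_min, k_max + 1):
            if b.size < k:
                continue
            code = np.zeros(b.size - k + 1, dtype=np.int64)
            for j in range(k):
                code = code * 4 + b[j : b.size - k + 1 + j]
            ok = (cs[k:] - cs[:-k]) == 0
            if ok.any():
                m[np.unique(code[ok]) + offsets[k], wi] = 1
    return m, offsets


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _enrichment_stats(
    fg_with: np.ndarray,
    bg_with: np.ndarray,
    fg_total: int,
    bg_total: int,
    min_fg: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Tested indices, enrichment ratios and hypergeometric tail p-values."""
    tested = fg_with >= min_fg
    n_tested = int(tested.sum())
    idx = np.flatnonzero(tested)
    fw = fg_with[idx].astype(float)
    bw = bg_with[idx].astype(float)
    fg_rate = fw / fg_total
    bg_rate = np.where(bw == 0, 0.5, bw) / bg_total  # half-count pseudocount
    ratio = fg_rate / bg_rate
    p = stats.hypergeom.sf(fw - 1, fg_total + bg_total, fw + bw, fg_total)
    return idx, ratio, p, n_tested


def _enrichment_frame(
    fg_with: np.ndarray,
    bg_with: np.ndarray,
    fg_total: int,
    bg_total: int,
    offsets: dict[int, int],
    k_min: int,
    k_max: int,
    e_value_cutoff: float,
    ratio_cutoff: float,
    min_fg: int = 2,
) -> pd.DataFrame:
    idx, ratio, p, n_tested = _enrichment_stats(fg_with, bg_with, fg_total, bg_total, min_fg)
    e = p * n_tested
    sig = (e < e_value_cutoff) & (ratio > ratio_cutoff)

    ks = np.empty(idx.size, dtype=np.int64)
    for k in range(k_min, k_max + 1):
        lo, hi = offsets[k], offsets[k] + 4**k
        ks[(idx >= lo) & (idx < hi)] = k
    kmers = [_decode(int(i - offsets[k]), int(k)) for i, k in zip(idx, ks)]
    out = pd.DataFrame(
        {
            "kmer": kmers,
            "fg_windows_with": fg_with[idx],
            "fg_total": fg_total,
            "bg_windows_with": bg_with[idx],
            "bg_total": bg_total,
            "enrichment_ratio": ratio,
            "p_value": p,
            "e_value": e,
            "significant": sig,
        }
    )
    return out.sort_values(["e_value", "kmer"], ignore_index=True)


def kmer_enrichment(
    fg: list[SequenceWindow],
    bg: list[SequenceWindow],
    k_min: int = 5,
    k_max: int = 8,
    e_value_cutoff: float = 0.05,
    ratio_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Exact k-mer enrichment of foreground vs background windows.

    Returns one row per k-mer present in >= 2 foreground windows, sorted
    by E-value, with columns matching
    :class:`~costimsplice.types.MotifEnrichment`.
    """
    if not fg:
        raise ValueError("foreground window set is empty")
    if not bg:
        raise ValueError("background window set is empty")
    if {w.event_id for w in fg} & {w.event_id for w in bg}:
        raise ValueError("foreground and background share event_ids")
    m, offsets = _presence_matrix(list(fg) + list(bg), k_min, k_max)
    fg_with = m[:, : len(fg)].sum(axis=1).astype(np.int64)
    bg_with = m[:, len(fg):].sum(axis=1).astype(np.int64)
    return _enrichment_frame(
        fg_with, bg_with, len(fg), len(bg), offsets, k_min, k_max,
        e_value_cutoff, ratio_cutoff,
    )


def permutation_null(
    fg: list[SequenceWindow],
    bg: list[SequenceWindow],
    n_permutations: int = 100,
    k_min: int = 5,
    k_max: int = 8,
    e_value_cutoff: float = 0.05,
    ratio_cutoff: float = 2.0,
    seed: int = 0,
) -> float:
    """Fraction of label permutations yielding any significant k-mer.

    Shuffles the foreground/background labels while keeping set sizes, and
    reruns the enrichment decision on each permutation. A well-calibrated
    test yields a small fraction (<= the E-value cutoff's nominal level).
    """
    rng = np.random.default_rng(seed)
    windows = list(fg) + list(bg)
    m, offsets = _presence_matrix(windows, k_min, k_max)
    n_fg, n_all = len(fg), len(windows)
    totals = m.sum(axis=1).astype(np.int64)
    hits = 0
    mf = m.astype(np.float32)
    perm = np.zeros((n_all, n_permutations), dtype=np.float32)
    for p in range(n_permutations):
        idx = rng.permutation(n_all)[:n_fg]
        perm[idx, p] = 1.0
    fg_counts = np.rint(mf @ perm).astype(np.int64)  # kmers x permutations
    for p in range(n_permutations):
        fg_with = fg_counts[:, p]
        bg_with = totals - fg_with
        # decision only: hypergeometric tail needed just for ratio-passing rows
        tested = fg_with >= 2
        n_tested = int(tested.sum())
        idx = np.flatnonzero(tested)
        fw = fg_with[idx].astype(float)
        bw = bg_with[idx].astype(float)
        ratio = (fw / n_fg) / (np.where(bw == 0, 0.5, bw) / (n_all - n_fg))
        cand = ratio > ratio_cutoff
        if cand.any():
            pv = stats.hypergeom.sf(
                fw[cand] - 1, n_all, fw[cand] + bw[cand], n_fg
            )
            if np.any(pv * n_tested < e_value_cutoff):
                hits += 1
    return hits / n_permutations


def _compatible(kmer: str, consensus: str) -> bool:
    """True when the shorter string fits inside the longer at some offset
    with every aligned position compatible under IUPAC degeneracy."""
    short, long_ = (kmer, consensus) if len(kmer) <= len(consensus) else (consensus, kmer)
    short_is_kmer = len(kmer) <= len(consensus)
    for off in range(len(long_) - len(short) + 1):
        ok = True
        for i, sc in enumerate(short):
            lc = long_[off + i]
            base, cons = (sc, lc) if short_is_kmer else (lc, sc)
            if base not in IUPAC[cons]:
                ok = False
                break
        if ok:
            return True
    return False


def match_rbp_motifs(
    enriched_kmers: list[str], rbp_table: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Map each enriched k-mer to RBPs whose IUPAC consensus it matches."""
    for rbp, consensi in rbp_table.items():
        for cons in consensi:
            bad = set(cons.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in {rbp} consensus")
    out: dict[str, list[str]] = {}
    for kmer in enriched_kmers:
        matches = sorted(
            rbp
            for rbp, consensi in rbp_table.items()
            if any(_compatible(kmer.upper(), c.upper()) for c in consensi)
        )
        if matches:
            out[kmer] = matches
    return out
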