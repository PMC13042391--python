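"""Sequence- and interval-level SV annotation.

Covers degenerate-motif scanning (e.g. the CTCF recognition sequence
CCGCGNGGNGGCAG) on both strands, ChIP-seq peak support for motif hits,
motif containment within deletions, and transposable-element association of
deletions.  Overlap fractions are computed against interval unions so
overlapping repeat annotations are never double-counted and fractions stay
<= 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .records import CallSet, Peak, SVRecord, sv_id
from .simulate import reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a degenerate motif.

    ``matched_seq`` is the motif-oriented sequence: for minus-strand hits it
    is the reverse complement of the genomic slice ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    matched_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.end - self.start != len(self.matched_seq):
            raise ValueError("hit interval must span the motif length")


def motif_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif to an overlap-aware lookahead regex."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


def reverse_complement_motif(motif: str) -> str:
    motif = motif.upper()
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif")
    return motif.translate(_IUPAC_COMPLEMENT)[::-1]


def scan_motif(sequences: Mapping[str, str], motif: str) -> list[MotifHit]:
    """All exact occurrences of an IUPAC motif on both strands.

    Overlapping hits are all reported; output is ordered by
    (chrom, start, strand).
    """
    fwd = motif_regex(motif)
    rev = motif_regex(reverse_complement_motif(motif))
    hits: list[MotifHit] = []
    m = len(motif)
    for chrom in sequences:
        seq = sequences[chrom].upper()
        for match in fwd.finditer(seq):
            s = match.start()
            hits.append(MotifHit(chrom, s, s + m, "+", match.group(1)))
        for match in rev.finditer(seq):
            s = match.start()
            hits.append(MotifHit(chrom, s, s + m, "-",
                                 reverse_complement(match.group(1))))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def _passing_peak_trees(peaks: Iterable[Peak], min_signal: float,
                        min_nlq: float) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        # signal threshold is inclusive, q-value threshold strict
        if p.signal_value >= min_signal and p.neg_log10_q > min_nlq:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def peak_support(sites: Sequence[MotifHit], peaks: Iterable[Peak],
                 min_overlap_frac: float = 0.5, min_signal: float = 50.0,
                 min_nlq: float = 3.0) -> list[tuple[bool, int]]:
    """Per-site (supported, supporting-peak count) under peak-quality filters.

    A site is supported iff at least ``min_overlap_frac`` of its length
    (inclusive) overlaps a single surviving peak; the count tallies all such
    peaks across datasets.
    """
    trees = _passing_peak_trees(peaks, min_signal, min_nlq)
    out: list[tuple[bool, int]] = []
    for site in sites:
        length = site.end - site.start
        count = 0
        for iv in trees.get(site.chrom, IntervalTree()).overlap(site.start, site.end):
            overlap = min(site.end, iv.end) - max(site.start, iv.begin)
            # ratio comparison keeps the inclusive boundary exact in floats
            if length > 0 and overlap / length >= min_overlap_frac:
                count += 1
        out.append((count > 0, count))
    return out


def dels_with_motif(dels: CallSet | Sequence[SVRecord],
                    hits: Sequence[MotifHit]) -> dict[str, int]:
    """Count motif hits fully contained in each deletion span.

    Containment, not overlap: a hit straddling a boundary does not count.
    Returns ``{sv_id: contained-hit count}`` for every DEL.
    """
    records = list(dels.records if isinstance(dels, CallSet) else dels)
    trees: dict[str, IntervalTree] = {}
    for h in hits:
        trees.setdefault(h.chrom, IntervalTree()).addi(h.start, h.end, h)
    counts: dict[str, int] = {}
    for rec in records:
        if rec.svtype != "DEL":
            continue
        n = 0
        for iv in trees.get(rec.chrom, IntervalTree()).overlap(rec.start, rec.end):
            if iv.begin >= rec.start and iv.end <= rec.end:
                n += 1
        counts[sv_id(rec)] = n
    return counts


def _union_overlap(span: tuple[int, int], intervals: Iterable[tuple[int, int]]) -> int:
    """Length of ((union of intervals) intersect span)."""
    clipped = sorted((max(s, span[0]), min(e, span[1]))
                     for s, e in intervals if e > span[0] and s < span[1])
    total = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def te_association(dels: CallSet | Sequence[SVRecord],
                   te_intervals: Sequence[tuple], min_frac: float = 0.6
                   ) -> tuple[dict[str, bool], float]:
    """Flag deletions with >= ``min_frac`` of their span in TE intervals.

    TE intervals may overlap each other; overlapped bases are computed on
    the interval union.  Returns per-DEL flags and the dataset-level
    associated fraction.
    """
    records = [r for r in (dels.records if isinstance(dels, CallSet) else dels)
               if r.svtype == "DEL"]
    trees: dict[str, IntervalTree] = {}
    for te in te_intervals:
        chrom, start, end = te[0], int(te[1]), int(te[2])
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    flags: dict[str, bool] = {}
    n_assoc = 0
    for rec in records:
        ivs = [(iv.begin, iv.end)
               for iv in trees.get(rec.chrom, IntervalTree()).overlap(rec.start, rec.end)]
        covered = _union_overlap((rec.start, rec.end), ivs)
        # ratio comparison keeps the inclusive boundary exact in floats
        flag = rec.svlen > 0 and covered / rec.svlen >= min_frac
        flags[sv_id(rec)] = flag
        n_assoc += flag
    fraction = n_assoc / len(records) if records else 0.0
    return flags, fraction
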