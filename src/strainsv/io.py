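"""Readers/writers for the standard formats the pipeline touches.

VCF is handled through :mod:`pysam`, FASTA through Biopython.  All
coordinates are converted to the internal 0-based half-open convention on
read and back to the native dialect on write (see :mod:`strainsv.records`).

VCF dialect: symbolic ALTs (``<DEL>``, ``<INV>``, ``<DUP>``, ``<INS>``) carry
SVTYPE/SVLEN/END in INFO with POS pointing at the first affected base;
insertions with a known sequence are written with an explicit padded ALT.
Both dialects are accepted on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    UNVALIDATED,
    VALIDATION_STATES,
    CallSet,
    Peak,
    SmallVariantRecord,
    SVRecord,
    ValidationScore,
)

log = logging.getLogger(__name__)

_SYMBOLIC = {"<DEL>": "DEL", "<INS>": "INS", "<INV>": "INV", "<DUP>": "DUP",
             "<DUP:TANDEM>": "DUP"}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{chrom: uppercase sequence}`` map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED / narrowPeak

def read_bed(path: str | Path) -> list[tuple]:
    """Read a BED3+ file -> list of ``(chrom, start, end, *extras)`` tuples.

    Coordinates are BED-native (0-based half-open), which is also the
    internal convention.  Malformed lines raise with their line number.
    """
    out: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            out.append((fields[0], start, end, *fields[3:]))
    return out


def write_bed(intervals: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    signalValue is column 7, qValue (-log10) column 9.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            try:
                peaks.append(Peak(chrom=f[0], start=int(f[1]), end=int(f[2]),
                                  name=f[3], strand=f[5],
                                  signal_value=float(f[6]), neg_log10_q=float(f[8])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t{p.strand}\t"
                     f"{p.signal_value:g}\t-1\t{p.neg_log10_q:g}\t-1\n")


# ---------------------------------------------------------------------------
# SV VCF

def _genotype_str(gt: tuple) -> str:
    if gt is None or all(a is None for a in gt):
        return "./."
    return "/".join("." if a is None else str(a) for a in gt)


def _genotype_tuple(genotype: str) -> tuple:
    alleles = genotype.replace("|", "/").split("/")
    return tuple(None if a == "." else int(a) for a in alleles)


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value


def read_sv_vcf(path: str | Path, caller: str = "", sample: str = "") -> CallSet:
    """Read one caller's SV calls for one sample into a :class:`CallSet`.

    Records whose coordinates/length cannot be determined (no SVLEN, no
    sequence ALT and no END) are skipped and counted in the provenance.
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    sample_key = sample if sample in vcf_samples else (vcf_samples[0] if vcf_samples else None)
    records: list[SVRecord] = []
    skipped = 0
    for rec in vf:
        for alt in rec.alts or ():
            try:
                parsed = _parse_variant(rec, alt, sample_key, caller, sample)
            except ValueError as exc:
                log.warning("skipping record at %s:%s: %s", rec.chrom, rec.pos, exc)
                skipped += 1
                continue
            if parsed is not None:
                records.append(parsed)
    vf.close()
    cs = CallSet(caller, sample, records,
                 [f"read {Path(path).name}: {len(records)} records, {skipped} skipped"])
    return cs


def _parse_variant(rec, alt: str, sample_key, caller: str, sample: str) -> Optional[SVRecord]:
    info = rec.info
    svtype = _scalar(info.get("SVTYPE")) if "SVTYPE" in info else None
    symbolic = alt.startswith("<")
    if svtype is None:
        if symbolic:
            svtype = _SYMBOLIC.get(alt)
            if svtype is None:
                raise ValueError(f"unknown symbolic ALT {alt}")
        else:
            svtype = "INS" if len(alt) > len(rec.ref) else "DEL"
    if symbolic and alt in _SYMBOLIC and _SYMBOLIC[alt] != svtype:
        svtype = _SYMBOLIC[alt]

    svlen = abs(int(_scalar(info["SVLEN"]))) if "SVLEN" in info else None
    alt_seq = None
    pos0 = rec.start  # 0-based POS-1
    if svtype == "BND":
        start = pos0
        end = pos0
        svlen = 0
    elif not symbolic:
        # explicit padded alleles: affected bases begin after the shared prefix
        if svtype == "INS":
            if not alt.startswith(rec.ref):
                raise ValueError("unpadded explicit INS allele")
            alt_seq = alt[len(rec.ref):]
            if svlen is None:
                svlen = len(alt_seq)
            start = pos0 + len(rec.ref)
            end = start
        else:
            if svlen is None:
                svlen = abs(len(rec.ref) - len(alt))
            start = pos0 + len(alt)
            end = start + svlen
    else:
        if svtype == "INS":
            if svlen is None:
                raise ValueError("symbolic INS without SVLEN")
            start = pos0
            end = start
        else:
            if svlen is None:
                end = rec.stop
                svlen = end - pos0
                if svlen <= 0:
                    raise ValueError("record lacks SVLEN, sequence ALT and END")
            start = pos0
            end = start + svlen

    genotype, dp, gq = "./.", None, None
    if sample_key is not None:
        fmt = rec.samples[sample_key]
        if "GT" in fmt:
            genotype = _genotype_str(fmt.get("GT"))
        dp = fmt.get("DP") if "DP" in fmt else None
        gq = fmt.get("GQ") if "GQ" in fmt else None
    support = int(_scalar(info["SUPPORT"])) if "SUPPORT" in info else None
    filters = list(rec.filter)
    filter_status = filters[0] if filters else "."
    validation = _scalar(info.get("VALSTATE")) if "VALSTATE" in info else UNVALIDATED
    if validation not in VALIDATION_STATES:
        validation = UNVALIDATED
    return SVRecord(chrom=rec.chrom, start=start, end=end, svtype=svtype,
                    svlen=int(svlen), alt_seq=alt_seq, genotype=genotype,
                    qual=rec.qual, support=support,
                    dp=None if dp is None else int(dp),
                    gq=None if gq is None else int(gq),
                    filter_status=filter_status, sample=sample, caller=caller,
                    validation=validation)


def _sv_header(callset: CallSet, contig_lengths: Mapping[str, int] | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">')
    header.add_line('##INFO=<ID=VALSTATE,Number=1,Type=String,Description="Validation state">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    contigs = sorted({r.chrom for r in callset.records})
    lengths = contig_lengths or {}
    for chrom in contigs:
        if chrom in lengths:
            header.add_line(f"##contig=<ID={chrom},length={lengths[chrom]}>")
        else:
            header.add_line(f"##contig=<ID={chrom}>")
    for status in sorted({r.filter_status for r in callset.records}):
        if status not in ("PASS", "."):
            header.add_line(f'##FILTER=<ID={status},Description="caller filter">')
    header.add_sample(callset.sample or "SAMPLE")
    return header


def write_sv_vcf(callset: CallSet, path: str | Path,
                 contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a CallSet as a sorted single-sample VCF.

    Symbolic ALTs are emitted except for insertions with a known sequence,
    which get explicit padded alleles.  DEL SVLEN is written negative,
    mirroring common caller output.
    """
    header = _sv_header(callset, contig_lengths)
    vf = pysam.VariantFile(str(path), "w", header=header)
    sample = callset.sample or "SAMPLE"
    for r in callset.records:  # already sorted by CallSet invariant
        if r.svtype == "INS" and r.alt_seq is not None:
            pos0 = max(r.start - 1, 0)
            alleles = ("N", "N" + r.alt_seq)
            stop = pos0 + 1
        elif r.svtype == "INS":
            pos0 = r.start
            alleles = ("N", "<INS>")
            stop = pos0 + 1
        else:
            pos0 = r.start
            alleles = ("N", f"<{r.svtype}>")
            stop = r.end if r.end > r.start else pos0 + 1
        rec = vf.new_record(contig=r.chrom, start=pos0, stop=stop, alleles=alleles)
        rec.info["SVTYPE"] = r.svtype
        rec.info["SVLEN"] = -r.svlen if r.svtype == "DEL" else r.svlen
        if r.support is not None:
            rec.info["SUPPORT"] = r.support
        if r.validation != UNVALIDATED:
            rec.info["VALSTATE"] = r.validation
        if r.qual is not None:
            rec.qual = r.qual
        if r.filter_status != ".":
            rec.filter.add(r.filter_status)
        fmt = rec.samples[sample]
        fmt["GT"] = _genotype_tuple(r.genotype)
        if r.dp is not None:
            fmt["DP"] = r.dp
        if r.gq is not None:
            fmt["GQ"] = r.gq
        vf.write(rec)
    vf.close()


# ---------------------------------------------------------------------------
# small-variant VCF

def read_small_variant_vcf(path: str | Path, sample: str = "") -> list[SmallVariantRecord]:
    """Read SNP/INDEL calls for one sample (first sample column by default)."""
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    sample_key = sample if sample in vcf_samples else (vcf_samples[0] if vcf_samples else None)
    out = []
    for rec in vf:
        genotype, dp, gq = "./.", None, None
        if sample_key is not None:
            fmt = rec.samples[sample_key]
            if "GT" in fmt:
                genotype = _genotype_str(fmt.get("GT"))
            dp = fmt.get("DP") if "DP" in fmt else None
            gq = fmt.get("GQ") if "GQ" in fmt else None
        filters = list(rec.filter)
        out.append(SmallVariantRecord(
            chrom=rec.chrom, pos=rec.start, ref_allele=rec.ref,
            alt_alleles=list(rec.alts or ()), genotype=genotype, qual=rec.qual,
            dp=None if dp is None else int(dp),
            gq=None if gq is None else int(gq),
            filter_status=filters[0] if filters else ".", sample=sample))
    vf.close()
    return out


# ---------------------------------------------------------------------------
# validation-score tables

def read_validation_scores(path: str | Path) -> list[ValidationScore]:
    """Read a TSV of ``id  gs  qs  assessable`` rows (header optional)."""
    scores = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("record_id"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            assessable = f[3].strip().lower() in ("1", "true", "yes")
            gs = float(f[1]) if f[1] not in (".", "", "NA") else None
            qs = float(f[2]) if f[2] not in (".", "", "NA") else None
            scores.append(ValidationScore(f[0], gs, qs, assessable))
    return scores


def write_validation_scores(scores: Iterable[ValidationScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tgs\tqs\tassessable\n")
        for s in scores:
            gs = "." if s.gs is None else f"{s.gs:g}"
            qs = "." if s.qs is None else f"{s.qs:g}"
            fh.write(f"{s.record_id}\t{gs}\t{qs}\t{int(s.assessable)}\n")
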