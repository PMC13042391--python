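"""Core domain types for the structural-variant toolkit.

Coordinate convention
---------------------
All intervals are stored 0-based, half-open ``[start, end)``.  VCF input and
output converts from/to 1-based inclusive coordinates at the boundary; BED is
already 0-based half-open.  Under this convention ``end - start == svlen`` for
DEL/INV/DUP records.  An insertion's reference footprint is a point, so INS
records carry ``end == start`` and their length lives entirely in ``svlen``
(and ``alt_seq`` when the inserted sequence is known).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

SV_TYPES = frozenset({"DEL", "INS", "INV", "DUP", "BND"})
SIM_SV_TYPES = ("DEL", "INS", "INV", "DUP")

# validation states for read-based validation (GS/QS thresholding)
UNVALIDATED = "unvalidated"
VALIDATED = "validated"
FAILED = "failed"
NOT_ASSESSABLE = "not_assessable"
VALIDATION_STATES = frozenset({UNVALIDATED, VALIDATED, FAILED, NOT_ASSESSABLE})


@dataclass
class SVRecord:
    """One structural-variant call.

    ``start``/``end`` are internal 0-based half-open coordinates.  ``svlen``
    is a non-negative magnitude (negative DEL lengths from caller VCFs are
    normalised on read).  Missing numeric annotations are ``None``, never 0.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    alt_seq: Optional[str] = None
    genotype: str = "./."
    qual: Optional[float] = None
    support: Optional[int] = None
    dp: Optional[int] = None
    gq: Optional[int] = None
    filter_status: str = "PASS"
    sample: str = ""
    caller: str = ""
    validation: str = UNVALIDATED

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.validation not in VALIDATION_STATES:
            raise ValueError(f"unknown validation state {self.validation!r}")
        if self.end < self.start:
            raise ValueError(
                f"end < start for {self.chrom}:{self.start}-{self.end}"
            )
        if self.svlen < 0:
            raise ValueError("svlen must be a non-negative magnitude")
        if self.svtype in ("DEL", "INV", "DUP") and self.end - self.start != self.svlen:
            raise ValueError(
                f"{self.svtype} span {self.end - self.start} != svlen {self.svlen}"
            )
        if self.svtype == "INS":
            if self.end != self.start:
                raise ValueError("INS records must have end == start")
            if self.alt_seq is not None and len(self.alt_seq) != self.svlen:
                raise ValueError("INS svlen must equal len(alt_seq)")

    @property
    def interval(self) -> tuple[int, int]:
        """Reference footprint for overlap math; 1 bp for insertions."""
        if self.svtype == "INS":
            return (self.start, self.start + 1)
        return (self.start, self.end)

    def copy(self, **changes) -> "SVRecord":
        return replace(self, **changes)


@dataclass
class SmallVariantRecord:
    """A SNP or INDEL call (single sample)."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_alleles: list[str]
    genotype: str = "./."
    qual: Optional[float] = None
    dp: Optional[int] = None
    gq: Optional[int] = None
    filter_status: str = "PASS"
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.ref_allele or not all(self.alt_alleles):
            raise ValueError("alleles must be non-empty strings")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def is_snp(self) -> bool:
        return self.is_biallelic and len(self.ref_allele) == 1 and len(self.alt_alleles[0]) == 1


def _sort_key(rec: SVRecord) -> tuple:
    return (rec.chrom, rec.start, rec.end, rec.svtype, rec.svlen, rec.caller)


@dataclass
class CallSet:
    """A named, sorted collection of SVRecords from one caller on one sample."""

    name: str
    sample: str
    records: list[SVRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.sample and rec.sample != self.sample:
                raise ValueError(
                    f"record sample {rec.sample!r} != callset sample {self.sample!r}"
                )
        self.records = sorted(self.records, key=_sort_key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def of_type(self, svtype: str) -> list[SVRecord]:
        return [r for r in self.records if r.svtype == svtype]

    def with_records(self, records: Iterable[SVRecord], note: str | None = None) -> "CallSet":
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return CallSet(self.name, self.sample, list(records), prov)


@dataclass(frozen=True)
class SizeBinning:
    """Size-bin edges: small = [small_min, small_max] bp, large above (capped
    at large_max by the QC filter, not by the binning itself)."""

    small_min: int = 50
    small_max: int = 1000
    large_max: int = 500_000

    def __post_init__(self) -> None:
        if not (self.small_min < self.small_max < self.large_max):
            raise ValueError("require small_min < small_max < large_max")

    def bin_of(self, svlen: int) -> str:
        return "small" if svlen <= self.small_max else "large"


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak (ENCODE narrowPeak row)."""

    chrom: str
    start: int
    end: int
    signal_value: float
    neg_log10_q: float
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")
        if self.signal_value < 0:
            raise ValueError("signalValue must be >= 0")


@dataclass(frozen=True)
class ValidationScore:
    """Read-based validation statistics (GS/QS) for one SV, keyed by sv_id."""

    record_id: str
    gs: Optional[float]
    qs: Optional[float]
    assessable: bool = True

    def __post_init__(self) -> None:
        if self.assessable:
            for v in (self.gs, self.qs):
                if v is None or not (-1.0 <= v <= 1.0):
                    raise ValueError("assessable scores must lie in [-1, 1]")


def sv_id(record: SVRecord) -> str:
    """Variant identifier ``chromosome-start-SVtype-SVlength``.

    The start is the 1-based (VCF display) position, e.g.
    ``chr1-3101582-DEL-357``.
    """
    return f"{record.chrom}-{record.start + 1}-{record.svtype}-{record.svlen}"


def parse_sv_id(identifier: str) -> tuple[str, int, str, int]:
    """Invert :func:`sv_id` -> (chrom, start0, svtype, svlen)."""
    parts = identifier.rsplit("-", 3)
    if len(parts) != 4 or parts[2] not in SV_TYPES:
        raise ValueError(f"malformed SV id {identifier!r}")
    chrom, pos1, svtype, svlen = parts
    return chrom, int(pos1) - 1, svtype, int(svlen)
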