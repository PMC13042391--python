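"""Truth-set simulation and a parametric caller-error model.

``plan_svs`` plants non-overlapping SVs of one type into a reference,
``apply_svs`` edits the sequence accordingly, and ``corrupt_calls``
perturbs a truth set the way an imperfect caller would (missed calls,
breakpoint jitter, false positives, DUP-as-INS relabelling), so the
evaluation harness can be exercised without running any external caller.

Simulation is haploid: inbred strains are homozygous, so every truth
genotype is "1/1".
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import CallSet, SVRecord, SIM_SV_TYPES

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimPlan:
    """Parameters for planting one batch of SVs of a single type."""

    n_svs: int
    svtype: str
    size_min: int = 50
    size_max: int = 1000
    seed: int = 0
    min_gap: int = 100

    def __post_init__(self) -> None:
        if self.svtype not in SIM_SV_TYPES:
            raise ValueError(f"cannot simulate SVTYPE {self.svtype!r}")
        if self.n_svs < 1:
            raise ValueError("n_svs must be >= 1")
        if self.size_min < 50:
            raise ValueError("size_min must be >= 50 (SV definition)")
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")
        if self.size_max > 500_000:
            raise ValueError("size_max above the 500 kb pipeline bound")


@dataclass(frozen=True)
class CallerErrorModel:
    """Call-level corruption parameters standing in for a real caller.

    miss_rate: probability a truth SV is dropped.
    fp_rate: expected false calls per Mb of genome.
    jitter_sd: Gaussian breakpoint noise (bp).
    len_jitter_sd: Gaussian length noise (bp).
    mistype_rate: probability a DUP is emitted as an INS.
    """

    miss_rate: float = 0.0
    fp_rate: float = 0.0
    jitter_sd: float = 0.0
    len_jitter_sd: float = 0.0
    mistype_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.miss_rate, self.mistype_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for sd in (self.jitter_sd, self.len_jitter_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


class PlacementError(RuntimeError):
    """Raised when the genome is too dense to place the requested SVs."""

    def __init__(self, placed: int, requested: int):
        super().__init__(f"placed only {placed} of {requested} SVs before the "
                         f"retry budget was exhausted")
        self.placed = placed
        self.requested = requested


def _occupied_conflict(occ: list[tuple[int, int]], start: int, end: int, gap: int) -> bool:
    """Check [start, end) against a sorted list of occupied intervals."""
    i = bisect_left(occ, (start, end))
    if i < len(occ) and occ[i][0] < end + gap:
        return True
    if i > 0 and occ[i - 1][1] + gap > start:
        return True
    return False


def plan_svs(reference: Mapping[str, str], plan: SimPlan, sample: str = "sim",
             avoid: Sequence[SVRecord] = (), max_retries: int | None = None) -> CallSet:
    """Plant ``plan.n_svs`` SVs of one type at uniform-random positions.

    Placements are mutually non-overlapping with pairwise reference gaps of
    at least ``plan.min_gap`` and never cross a chromosome end; the result is
    deterministic given ``plan.seed``.  ``avoid`` lists intervals already
    claimed (e.g. by an earlier plan of a different type), so mixed-type
    truth sets stay non-overlapping.
    """
    rng = np.random.default_rng(plan.seed)
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    for c, L in zip(chroms, lengths):
        if L <= plan.size_max + 2 * plan.min_gap:
            raise ValueError(f"chromosome {c} too short for size_max={plan.size_max}")
    weights = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for rec in avoid:
        lo, hi = rec.interval
        insort(occupied.setdefault(rec.chrom, []), (lo, hi))

    budget = max_retries if max_retries is not None else 10 * plan.n_svs
    records: list[SVRecord] = []
    attempts = 0
    while len(records) < plan.n_svs:
        if attempts > budget + plan.n_svs:
            raise PlacementError(len(records), plan.n_svs)
        attempts += 1
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        size = int(rng.integers(plan.size_min, plan.size_max + 1))
        footprint = 1 if plan.svtype == "INS" else size
        hi_start = len(reference[chrom]) - footprint - plan.min_gap
        lo_start = plan.min_gap
        if hi_start <= lo_start:
            continue
        start = int(rng.integers(lo_start, hi_start))
        if _occupied_conflict(occupied[chrom], start, start + footprint, plan.min_gap):
            continue
        insort(occupied[chrom], (start, start + footprint))
        if plan.svtype == "INS":
            rec = SVRecord(chrom=chrom, start=start, end=start, svtype="INS",
                           svlen=size, alt_seq=random_sequence(size, rng),
                           genotype="1/1", sample=sample, caller="truth")
        else:
            rec = SVRecord(chrom=chrom, start=start, end=start + size,
                           svtype=plan.svtype, svlen=size, genotype="1/1",
                           sample=sample, caller="truth")
        records.append(rec)
    return CallSet("truth", sample, records,
                   [f"plan_svs {plan.svtype} n={plan.n_svs} seed={plan.seed}"])


class CoordinateMap:
    """Reference -> mutated coordinate conversion outside edited spans."""

    def __init__(self, events: Mapping[str, list[tuple[int, int, int]]]):
        # events[chrom]: sorted (ref_start, ref_end, delta) per edit
        self._events = {c: sorted(v) for c, v in events.items()}

    def to_mutated(self, chrom: str, pos: int) -> int:
        offset = 0
        for ref_start, ref_end, delta in self._events.get(chrom, ()):
            if pos >= ref_end:
                offset += delta
            elif pos >= ref_start:
                raise ValueError(f"{chrom}:{pos} lies inside an edited span")
            else:
                break
        return pos + offset


def apply_svs(reference: Mapping[str, str], truth: CallSet) -> tuple[dict[str, str], CoordinateMap]:
    """Edit the reference according to a non-overlapping truth set.

    DEL removes the span; INS inserts ``alt_seq`` at the point; INV
    reverse-complements the span in place; DUP appends one extra tandem copy
    immediately after the span.
    """
    by_chrom: dict[str, list[SVRecord]] = {}
    for rec in truth:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    mutated: dict[str, str] = {}
    events: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, seq in reference.items():
        recs = sorted(by_chrom.get(chrom, []), key=lambda r: r.interval)
        prev = None
        for rec in recs:
            if prev is not None and rec.interval[0] < prev.interval[1]:
                raise ValueError(
                    f"overlapping truth records {prev.chrom}:{prev.start} and "
                    f"{rec.chrom}:{rec.start}")
            prev = rec
        parts: list[str] = []
        cursor = 0
        ev: list[tuple[int, int, int]] = []
        for rec in recs:
            parts.append(seq[cursor:rec.start])
            span = seq[rec.start:rec.end]
            if rec.svtype == "DEL":
                ev.append((rec.start, rec.end, -rec.svlen))
            elif rec.svtype == "INS":
                if rec.alt_seq is None:
                    raise ValueError(f"INS at {chrom}:{rec.start} lacks alt_seq")
                parts.append(rec.alt_seq)
                ev.append((rec.start, rec.start, rec.svlen))
            elif rec.svtype == "INV":
                parts.append(reverse_complement(span))
                ev.append((rec.start, rec.end, 0))
            elif rec.svtype == "DUP":
                parts.append(span + span)
                ev.append((rec.start, rec.end, rec.svlen))
            else:
                raise ValueError(f"cannot apply SVTYPE {rec.svtype}")
            cursor = rec.end
        parts.append(seq[cursor:])
        mutated[chrom] = "".join(parts)
        events[chrom] = ev
    return mutated, CoordinateMap(events)


def corrupt_calls(truth: CallSet, model: CallerErrorModel, genome_size: int,
                  chrom_lengths: Mapping[str, int] | None = None,
                  caller: str | None = None) -> CallSet:
    """Corrupt a truth set with a caller-error model (deterministic per seed).

    Each truth record is dropped with ``miss_rate``; survivors get Gaussian
    breakpoint/length jitter; Poisson(fp_rate * genome_size/1e6) false calls
    of the same type are added at random positions; DUPs are relabelled INS
    with ``mistype_rate``.
    """
    rng = np.random.default_rng(model.seed)
    if caller is None:
        caller = truth.name
    if chrom_lengths is None:
        chroms = sorted({r.chrom for r in truth.records}) or ["chr1"]
        chrom_lengths = {c: genome_size // len(chroms) for c in chroms}
    chroms = sorted(chrom_lengths)
    records: list[SVRecord] = []
    for rec in truth.records:
        if rng.random() < model.miss_rate:
            continue
        svtype = rec.svtype
        if svtype == "DUP" and rng.random() < model.mistype_rate:
            svtype = "INS"
        start = rec.start
        svlen = rec.svlen
        if model.jitter_sd > 0 or model.len_jitter_sd > 0:
            if model.jitter_sd > 0:
                start += int(round(rng.normal(0.0, model.jitter_sd)))
            if model.len_jitter_sd > 0:
                svlen += int(round(rng.normal(0.0, model.len_jitter_sd)))
            svlen = max(svlen, 1)
            clen = chrom_lengths.get(rec.chrom, genome_size)
            footprint = 0 if svtype == "INS" else svlen
            start = min(max(start, 0), max(clen - footprint - 1, 0))
        end = start if svtype == "INS" else start + svlen
        alt_seq = None
        if svtype == "INS" and rec.alt_seq is not None and len(rec.alt_seq) == svlen:
            alt_seq = rec.alt_seq
        records.append(rec.copy(start=start, end=end, svtype=svtype, svlen=svlen,
                                alt_seq=alt_seq, caller=caller))
    n_fp = int(rng.poisson(model.fp_rate * genome_size / 1e6))
    truth_types = sorted({r.svtype for r in truth.records}) or ["DEL"]
    lens = [r.svlen for r in truth.records] or [100]
    lo_len, hi_len = min(lens), max(lens)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(n_fp):
        svtype = truth_types[int(rng.integers(len(truth_types)))]
        svlen = int(rng.integers(lo_len, hi_len + 1))
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        footprint = 0 if svtype == "INS" else svlen
        hi = max(chrom_lengths[chrom] - footprint - 1, 1)
        start = int(rng.integers(0, hi))
        end = start if svtype == "INS" else start + svlen
        alt_seq = random_sequence(svlen, rng) if svtype == "INS" else None
        records.append(SVRecord(chrom=chrom, start=start, end=end, svtype=svtype,
                                svlen=svlen, alt_seq=alt_seq, genotype="1/1",
                                sample=truth.sample, caller=caller,
                                support=int(rng.integers(5, 40)),
                                dp=int(rng.integers(10, 60)),
                                gq=int(rng.integers(30, 99)),
                                qual=float(rng.integers(31, 100))))
    return CallSet(caller, truth.sample, records,
                   truth.provenance + [f"corrupt_calls seed={model.seed}"])
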