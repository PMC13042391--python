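"""Seeded fixture-bundle generator.

Builds, from one integer seed, everything the pipeline consumes: a toy
two-chromosome genome (with degenerate CTCF-motif realisations embedded,
some inside deletion spans), per-strain truth sets, three corrupted
per-caller call sets per strain with distinct error models, validation
score tables, a TE annotation BED, a ChIP-seq narrowPeak file, the truth
presence/absence matrix with one planted case-strain-unique 1641 bp
deletion, and a binary phenotype table.  Byte-identical given the same
seed.

The error models emulate the behaviour seen when real callers are
benchmarked: every caller misses a few percent of true SVs, jitters
breakpoints by a handful of bases and emits sporadic false positives; the
two heuristic callers additionally emit duplications as insertions, which
is why duplications are routed through a validation-gated single-caller
rule downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as svio
from .records import CallSet, SVRecord, ValidationScore, sv_id
from .simulate import (
    CallerErrorModel,
    SimPlan,
    corrupt_calls,
    plan_svs,
    random_sequence,
)

CALLERS = ("cue", "sniffles2", "sawfish")

#: distinct per-caller corruption behaviour (rates chosen to resemble the
#: high-recall regime real long-read callers show on deletions/insertions)
ERROR_MODELS: dict[str, CallerErrorModel] = {
    "cue": CallerErrorModel(miss_rate=0.04, fp_rate=0.4, jitter_sd=6.0,
                            len_jitter_sd=4.0, mistype_rate=0.0),
    "sniffles2": CallerErrorModel(miss_rate=0.08, fp_rate=0.8, jitter_sd=10.0,
                                  len_jitter_sd=6.0, mistype_rate=1.0),
    "sawfish": CallerErrorModel(miss_rate=0.06, fp_rate=0.6, jitter_sd=8.0,
                                len_jitter_sd=5.0, mistype_rate=1.0),
}

CTCF_MOTIF = "CCGCGNGGNGGCAG"
PLANTED_DEL_LEN = 1641


@dataclasses.dataclass
class FixtureBundle:
    """Paths and metadata of one generated bundle."""

    root: Path
    seed: int
    genome_size: int
    strains: list[str]
    case_strain: str
    callers: tuple[str, ...]
    planted_id: str

    @property
    def genome_path(self) -> Path:
        return self.root / "genome.fa"

    def truth_vcf(self, strain: str) -> Path:
        return self.root / "truth" / f"{strain}.truth.vcf"

    def calls_vcf(self, strain: str, caller: str) -> Path:
        return self.root / "calls" / f"{strain}.{caller}.vcf"

    def scores_tsv(self, strain: str, caller: str) -> Path:
        return self.root / "scores" / f"{strain}.{caller}.scores.tsv"

    @property
    def matrix_path(self) -> Path:
        return self.root / "matrix.tsv"

    @property
    def phenotype_path(self) -> Path:
        return self.root / "phenotype.tsv"

    @property
    def te_path(self) -> Path:
        return self.root / "te.bed"

    @property
    def peaks_path(self) -> Path:
        return self.root / "peaks.narrowPeak"

    @classmethod
    def load(cls, root: str | Path) -> "FixtureBundle":
        root = Path(root)
        meta: dict[str, str] = {}
        with open(root / "manifest.tsv") as fh:
            for line in fh:
                key, _, value = line.rstrip("\n").partition("\t")
                meta[key] = value
        return cls(root=root, seed=int(meta["seed"]),
                   genome_size=int(meta["genome_size"]),
                   strains=meta["strains"].split(","),
                   case_strain=meta["case_strain"],
                   callers=tuple(meta["callers"].split(",")),
                   planted_id=meta["planted_id"])


def _motif_realization(rng: np.random.Generator) -> str:
    return "".join(ch if ch != "N" else "ACGT"[rng.integers(4)] for ch in CTCF_MOTIF)


def _derived_seed(seed: int, *indices: int) -> int:
    x = seed & 0x7FFFFFFF
    for idx in indices:
        x = (x * 1_000_003 + idx * 8191 + 17) % (2**31)
    return x


def make_fixtures(seed: int, genome_size: int = 1_000_000, n_strains: int = 35,
                  out_dir: str | Path = "fixtures", overwrite: bool = False) -> FixtureBundle:
    """Write a complete deterministic fixture bundle under ``out_dir``."""
    if genome_size < 1_000_000:
        raise ValueError("genome_size must be >= 1 Mb for the default plans")
    root = Path(out_dir)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"{root} exists; pass overwrite=True to replace it")
    for sub in ("", "truth", "calls", "scores"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(_derived_seed(seed, 0))
    len1 = int(genome_size * 0.7)
    genome = {"chr1": random_sequence(len1, rng),
              "chr2": random_sequence(genome_size - len1, rng)}
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    strains = [f"STR{i + 1:02d}" for i in range(n_strains)]
    case_strain = strains[0]

    # ---- shared SV pool -------------------------------------------------
    pool: list[SVRecord] = []

    def extend(plan: SimPlan) -> list[SVRecord]:
        cs = plan_svs(genome, plan, sample="pool", avoid=pool)
        pool.extend(cs.records)
        return cs.records

    small_dels = extend(SimPlan(40, "DEL", 50, 1000, seed=_derived_seed(seed, 1)))
    large_dels = extend(SimPlan(8, "DEL", 1200, 5000, seed=_derived_seed(seed, 2)))
    planted = extend(SimPlan(1, "DEL", PLANTED_DEL_LEN, PLANTED_DEL_LEN,
                             seed=_derived_seed(seed, 3)))[0]
    small_ins = extend(SimPlan(30, "INS", 50, 1000, seed=_derived_seed(seed, 4)))
    invs = extend(SimPlan(8, "INV", 60, 2000, seed=_derived_seed(seed, 5)))
    dups = extend(SimPlan(10, "DUP", 60, 2000, seed=_derived_seed(seed, 6)))

    # ---- embed motif realisations --------------------------------------
    motif_rng = np.random.default_rng(_derived_seed(seed, 7))
    occupied = sorted((r.chrom, *r.interval) for r in pool)

    def place_motif(chrom: str, start: int) -> None:
        seq = genome[chrom]
        genome[chrom] = seq[:start] + _motif_realization(motif_rng) + seq[start + len(CTCF_MOTIF):]

    motif_positions: list[tuple[str, int]] = []
    inside_dels = [r for r in (small_dels + large_dels) if r.svlen >= 200][:12]
    for rec in inside_dels:
        pos = rec.start + int(motif_rng.integers(20, rec.svlen - len(CTCF_MOTIF) - 20))
        place_motif(rec.chrom, pos)
        motif_positions.append((rec.chrom, pos))
    placed = 0
    while placed < 20:
        chrom = "chr1" if motif_rng.random() < 0.7 else "chr2"
        pos = int(motif_rng.integers(100, chrom_lengths[chrom] - 100))
        span = (chrom, pos, pos + len(CTCF_MOTIF))
        if any(c == chrom and s < span[2] and e > span[1] for c, s, e in occupied):
            continue
        place_motif(chrom, pos)
        motif_positions.append(span[:2])
        placed += 1
    svio.write_fasta(genome, root / "genome.fa")

    # ---- presence assignment -------------------------------------------
    pres_rng = np.random.default_rng(_derived_seed(seed, 8))
    presence: dict[str, set[str]] = {}
    non_case = strains[1:]
    for rec in pool:
        rid = sv_id(rec)
        if rec is planted:
            presence[rid] = {case_strain}
        elif rec.svtype in ("INV", "DUP"):
            k = int(min(5 + pres_rng.geometric(0.3), n_strains))
            presence[rid] = set(pres_rng.choice(strains, size=k, replace=False))
        else:
            k = int(min(pres_rng.geometric(0.5), n_strains))
            if k == 1:
                # strain-unique background SVs never land on the case strain,
                # keeping the planted deletion the only case-unique variant
                presence[rid] = {non_case[int(pres_rng.integers(len(non_case)))]}
            else:
                presence[rid] = set(pres_rng.choice(strains, size=k, replace=False))

    planted_id = sv_id(planted)
    impact = {rid: ("high" if rid == planted_id else "modifier") for rid in presence}

    # truth matrix + phenotype
    ordered_ids = [sv_id(r) for r in sorted(pool, key=lambda r: (r.chrom, r.start))]
    with open(root / "matrix.tsv", "w") as fh:
        fh.write("sv_id\t" + "\t".join(strains) + "\timpact\n")
        for rid in ordered_ids:
            row = "\t".join("1" if s in presence[rid] else "0" for s in strains)
            fh.write(f"{rid}\t{row}\t{impact[rid]}\n")
    with open(root / "phenotype.tsv", "w") as fh:
        fh.write("strain\tphenotype\n")
        for s in strains:
            fh.write(f"{s}\t{int(s == case_strain)}\n")

    # ---- per-strain truth + corrupted caller calls ----------------------
    truth_by_rec = sorted(pool, key=lambda r: (r.chrom, r.start))
    for si, strain in enumerate(strains):
        truth_records = [r.copy(sample=strain) for r in truth_by_rec
                         if strain in presence[sv_id(r)]]
        truth = CallSet("truth", strain, truth_records)
        svio.write_sv_vcf(truth, root / "truth" / f"{strain}.truth.vcf",
                          contig_lengths=chrom_lengths)
        for ci, caller in enumerate(CALLERS):
            model = dataclasses.replace(ERROR_MODELS[caller],
                                        seed=_derived_seed(seed, 10 + si, ci))
            calls = corrupt_calls(truth, model, genome_size,
                                  chrom_lengths=chrom_lengths, caller=caller)
            qrng = np.random.default_rng(_derived_seed(seed, 100 + si, ci))
            dressed = []
            for rec in calls.records:
                qual = 10.0 if qrng.random() < 0.05 else float(qrng.integers(35, 95))
                dressed.append(rec.copy(qual=qual,
                                        support=int(qrng.integers(6, 30)),
                                        dp=int(qrng.integers(12, 50)),
                                        gq=int(qrng.integers(35, 95))))
            calls = CallSet(caller, strain, dressed, calls.provenance)
            svio.write_sv_vcf(calls, root / "calls" / f"{strain}.{caller}.vcf",
                              contig_lengths=chrom_lengths)
            _write_scores(calls, truth, root / "scores" / f"{strain}.{caller}.scores.tsv",
                          np.random.default_rng(_derived_seed(seed, 200 + si, ci)))

    # ---- TE annotations -------------------------------------------------
    te_rng = np.random.default_rng(_derived_seed(seed, 9))
    te_intervals: list[tuple[str, int, int, str]] = []
    all_dels = sorted(small_dels + large_dels + [planted], key=lambda r: (r.chrom, r.start))
    for i, rec in enumerate(all_dels):
        if te_rng.random() < 0.5:  # about half the DELs become TE-associated
            cover = int(np.ceil(0.6 * rec.svlen)) + int(te_rng.integers(0, rec.svlen // 4 + 1))
            cover = min(cover, rec.svlen)
            off = int(te_rng.integers(0, rec.svlen - cover + 1))
            te_intervals.append((rec.chrom, rec.start + off, rec.start + off + cover,
                                 f"TE{i}"))
    for j in range(40):  # background repeats away from deletions
        chrom = "chr1" if te_rng.random() < 0.7 else "chr2"
        length = int(te_rng.integers(100, 1500))
        start = int(te_rng.integers(0, chrom_lengths[chrom] - length))
        te_intervals.append((chrom, start, start + length, f"BG{j}"))
    te_intervals.sort()
    svio.write_bed(te_intervals, root / "te.bed")

    # ---- ChIP-seq peaks over roughly half the motif sites ---------------
    peak_rng = np.random.default_rng(_derived_seed(seed, 11))
    peaks = []
    for k, (chrom, pos) in enumerate(sorted(motif_positions)):
        if peak_rng.random() < 0.55:
            pad = int(peak_rng.integers(30, 150))
            signal = float(peak_rng.integers(50, 300))
            nlq = float(peak_rng.uniform(3.1, 30.0))
        else:  # weak peak failing the signal/q filters
            pad = int(peak_rng.integers(10, 40))
            signal = float(peak_rng.uniform(5.0, 49.9))
            nlq = float(peak_rng.uniform(0.5, 3.0))
        from .records import Peak
        peaks.append(Peak(chrom=chrom, start=max(pos - pad, 0),
                          end=pos + len(CTCF_MOTIF) + pad,
                          signal_value=round(signal, 1), neg_log10_q=round(nlq, 2),
                          name=f"peak{k}", strand="."))
    svio.write_narrowpeak(sorted(peaks, key=lambda p: (p.chrom, p.start)),
                          root / "peaks.narrowPeak")

    with open(root / "manifest.tsv", "w") as fh:
        fh.write(f"seed\t{seed}\n")
        fh.write(f"genome_size\t{genome_size}\n")
        fh.write(f"strains\t{','.join(strains)}\n")
        fh.write(f"case_strain\t{case_strain}\n")
        fh.write(f"callers\t{','.join(CALLERS)}\n")
        fh.write(f"planted_id\t{planted_id}\n")

    return FixtureBundle(root=root, seed=seed, genome_size=genome_size,
                         strains=strains, case_strain=case_strain,
                         callers=CALLERS, planted_id=planted_id)


def _write_scores(calls: CallSet, truth: CallSet, path: Path,
                  rng: np.random.Generator) -> None:
    """Emit GS/QS validation scores for DUP/INV calls.

    Calls near a true variant mostly validate; false positives mostly fail
    or cannot be assessed — mimicking how a read-based validator behaves.
    """
    from .matching import MatchProfile, records_match

    near = MatchProfile("score", 200, 200, 200, require_same_type=False)
    truth_recs = [r for r in truth.records if r.svtype in ("DUP", "INV")]
    scores: list[ValidationScore] = []
    seen: set[str] = set()
    for rec in calls.records:
        if rec.svtype not in ("DUP", "INV"):
            continue
        rid = sv_id(rec)
        if rid in seen:
            continue
        seen.add(rid)
        is_true = any(records_match(rec, t, near) for t in truth_recs)
        roll = rng.random()
        if is_true:
            if roll < 0.85:
                scores.append(ValidationScore(rid, round(float(rng.uniform(0.2, 0.8)), 3),
                                              round(float(rng.uniform(0.12, 0.6)), 3), True))
            elif roll < 0.95:
                scores.append(ValidationScore(rid, round(float(rng.uniform(-0.5, 0.1)), 3),
                                              round(float(rng.uniform(-0.5, 0.05)), 3), True))
            else:
                scores.append(ValidationScore(rid, None, None, False))
        else:
            if roll < 0.7:
                scores.append(ValidationScore(rid, round(float(rng.uniform(-0.6, 0.1)), 3),
                                              round(float(rng.uniform(-0.6, 0.05)), 3), True))
            else:
                scores.append(ValidationScore(rid, None, None, False))
    svio.write_validation_scores(scores, path)
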