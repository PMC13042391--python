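"""End-to-end orchestration: filter -> validate -> cluster -> route ->
annotate -> compare/associate, driven by a flat key/value config.

Every stage logs machine-parsable input/output record counts to stderr;
results only ever go to files under ``out_dir``.  The run is fully
deterministic: re-running with an identical config produces byte-identical
outputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import io as svio
from .annotate import dels_with_motif, peak_support, scan_motif, te_association
from .compare import GenotypeMatrix, build_genotype_matrix, perfect_association_scan, sharing_spectrum
from .consensus import (
    DEFAULT_ROUTING,
    MERGE_PROFILE,
    cluster_calls,
    dup_within_ins,
    group_table,
    route_and_select,
)
from .filters import CALLER_SV_RULES, SVRules, apply_validation, drop_report, filter_svs
from .fixtures import CTCF_MOTIF, FixtureBundle
from .matching import COMPARISON_PROFILE, MatchProfile
from .records import CallSet, SizeBinning, sv_id

log = logging.getLogger("strainsv.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Flat run configuration; every field maps to one config-file key."""

    bundle_dir: str = "fixtures"
    out_dir: str = "pipeline_out"
    gs_min: float = 0.15
    qs_min: float = 0.1
    merge_max_dist: int = 1000
    comparison_max_dist: int = 50
    dup_ins_tolerance: int = 1000
    te_min_frac: float = 0.6
    peak_min_overlap_frac: float = 0.5
    peak_min_signal: float = 50.0
    peak_min_nlq: float = 3.0
    motif: str = CTCF_MOTIF
    exclude_callers: str = ""  # comma-separated caller names to drop

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        values = parse_flat_config(path)
        known = {f.name: f.type for f in dc_fields(cls)}
        unknown = set(values) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        casts = {f.name: type(getattr(cls, f.name)) for f in dc_fields(cls)}
        return cls(**{k: casts[k](v) for k, v in values.items()})


def parse_flat_config(path: str | Path) -> dict[str, str]:
    """Parse ``key = value`` lines; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def _stage(stage: str, strain: str, n_in: int, n_out: int) -> None:
    log.info("stage=%s strain=%s in=%d out=%d dropped=%d",
             stage, strain, n_in, n_out, n_in - n_out)


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Run the full per-strain pipeline on a fixture bundle.

    Returns a summary dict and writes per-strain final VCFs plus group,
    annotation, matrix, spectrum and association reports under ``out_dir``.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    bundle = FixtureBundle.load(config.bundle_dir)
    out = Path(config.out_dir)
    (out / "final").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(parents=True, exist_ok=True)

    missing = [str(p) for p in [bundle.genome_path, bundle.phenotype_path,
                                bundle.te_path, bundle.peaks_path]
               if not p.exists()]
    excluded = {c for c in config.exclude_callers.split(",") if c}
    callers = [c for c in bundle.callers if c not in excluded]
    for strain in bundle.strains:
        for caller in callers:
            if not bundle.calls_vcf(strain, caller).exists():
                missing.append(str(bundle.calls_vcf(strain, caller)))
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing[:5]}")

    genome = svio.read_fasta(bundle.genome_path)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    binning = SizeBinning()
    merge_profile = MatchProfile("merge", config.merge_max_dist,
                                 config.merge_max_dist, 10**9)
    comparison_profile = MatchProfile("comparison", config.comparison_max_dist,
                                      config.comparison_max_dist,
                                      config.comparison_max_dist)

    final: dict[str, CallSet] = {}
    drop_rows: list[tuple[str, str, str, str]] = []
    group_rows: list[dict] = []
    dup_flag_rows: list[tuple[str, str, bool]] = []
    for strain in bundle.strains:
        filtered: list[CallSet] = []
        for caller in callers:
            calls = svio.read_sv_vcf(bundle.calls_vcf(strain, caller),
                                     caller=caller, sample=strain)
            kept, dropped = filter_svs(calls, CALLER_SV_RULES.get(caller, SVRules()))
            _stage("filter", f"{strain}/{caller}", len(calls), len(kept))
            drop_rows += [(strain, caller, rid, reason)
                          for rid, reason in drop_report(dropped)]
            scores_path = bundle.scores_tsv(strain, caller)
            if scores_path.exists():
                kept = apply_validation(kept, svio.read_validation_scores(scores_path),
                                        gs_min=config.gs_min, qs_min=config.qs_min)
            filtered.append(kept)
        groups = cluster_calls(filtered, merge_profile)
        _stage("cluster", strain, sum(len(cs) for cs in filtered), len(groups))
        strain_final = route_and_select(groups, DEFAULT_ROUTING, binning, sample=strain)
        _stage("route", strain, len(groups), len(strain_final))
        for row in group_table(groups, DEFAULT_ROUTING, binning):
            row["strain"] = strain
            group_rows.append(row)
        for rid, flag in dup_within_ins(strain_final, config.dup_ins_tolerance).items():
            dup_flag_rows.append((strain, rid, flag))
        svio.write_sv_vcf(strain_final, out / "final" / f"{strain}.vcf",
                          contig_lengths=chrom_lengths)
        final[strain] = strain_final

    pd.DataFrame(drop_rows, columns=["strain", "caller", "sv_id", "reason"]).to_csv(
        out / "reports" / "dropped.tsv", sep="\t", index=False)
    pd.DataFrame(group_rows).to_csv(out / "reports" / "groups.tsv", sep="\t", index=False)
    pd.DataFrame(dup_flag_rows, columns=["strain", "sv_id", "within_ins"]).to_csv(
        out / "reports" / "dup_within_ins.tsv", sep="\t", index=False)

    # ---- annotation ------------------------------------------------------
    hits = scan_motif(genome, config.motif)
    peaks = svio.read_narrowpeak(bundle.peaks_path)
    support = peak_support(hits, peaks, config.peak_min_overlap_frac,
                           config.peak_min_signal, config.peak_min_nlq)
    with open(out / "reports" / "motif_sites.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tmatched_seq\tsupported\tn_peaks\n")
        for h, (sup, n) in zip(hits, support):
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.matched_seq}"
                     f"\t{int(sup)}\t{n}\n")

    te = svio.read_bed(bundle.te_path)
    annot_rows = []
    for strain in bundle.strains:
        dels = [r for r in final[strain].records if r.svtype == "DEL"]
        motif_counts = dels_with_motif(dels, hits)
        te_flags, te_frac = te_association(dels, te, config.te_min_frac)
        for rec in dels:
            rid = sv_id(rec)
            annot_rows.append({"strain": strain, "sv_id": rid,
                               "motif_count": motif_counts.get(rid, 0),
                               "te_associated": int(te_flags.get(rid, False))})
        _stage("annotate", strain, len(dels), len(dels))
    pd.DataFrame(annot_rows).to_csv(out / "reports" / "del_annotations.tsv",
                                    sep="\t", index=False)

    # ---- cross-strain matrix, spectrum, association ----------------------
    matrix = build_genotype_matrix(final, comparison_profile)
    matrix.to_tsv(out / "reports" / "matrix.tsv")
    spectrum, strain_unique, no_carrier = sharing_spectrum(matrix)
    with open(out / "reports" / "spectrum.tsv", "w") as fh:
        fh.write("n_strains\tn_svs\n")
        for k in sorted(spectrum):
            fh.write(f"{k}\t{spectrum[k]}\n")
    strain_unique.to_csv(out / "reports" / "strain_unique.tsv", sep="\t",
                         header=["n_unique_svs"], index_label="strain")
    pheno = pd.read_csv(bundle.phenotype_path, sep="\t", index_col=0)["phenotype"]
    assoc_hits = perfect_association_scan(matrix, pheno)
    with open(out / "reports" / "association_hits.txt", "w") as fh:
        for rid in assoc_hits:
            fh.write(rid + "\n")

    with open(out / "run_manifest.tsv", "w") as fh:
        for f in dc_fields(PipelineConfig):
            fh.write(f"{f.name}\t{getattr(config, f.name)}\n")
        fh.write(f"bundle_seed\t{bundle.seed}\n")
        fh.write(f"n_strains\t{len(bundle.strains)}\n")
        fh.write(f"callers\t{','.join(callers)}\n")

    summary = {
        "n_strains": len(bundle.strains),
        "final_counts": {s: len(cs) for s, cs in final.items()},
        "type_totals": _type_totals(final),
        "n_matrix_svs": len(matrix.sv_ids),
        "spectrum": spectrum,
        "no_carrier": no_carrier,
        "association_hits": assoc_hits,
        "out_dir": str(out),
    }
    return summary


def _type_totals(final: Mapping[str, CallSet]) -> dict[str, int]:
    totals: dict[str, int] = {}
    for cs in final.values():
        for rec in cs.records:
            totals[rec.svtype] = totals.get(rec.svtype, 0) + 1
    return totals
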