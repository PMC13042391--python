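"""Hard-filtering rules for small variants and SVs, plus GS/QS validation
thresholding.

Small variants keep QUAL >= 30 (records "below 30" are excluded) while SVs
require QUAL > 30 — the two rule sets are deliberately asymmetric, and
genotype handling also differs: small-variant filtering keeps only
homozygous-alternate "1/1" calls, whereas SV filtering only removes "0/0".

Each dropped record is tagged with the first failing rule, using a fixed
rule order (chromosome, filter, svtype, svlen, qual, support, dp, gq, gt),
so drop reports are reproducible.  A rule whose threshold is ``None`` is
disabled — this is how callers that lack a field (e.g. no QUAL) opt out of
the corresponding criterion.  An enabled rule applied to a record missing
the field drops the record with that rule's reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional, Sequence

from .records import (
    FAILED,
    NOT_ASSESSABLE,
    UNVALIDATED,
    VALIDATED,
    CallSet,
    SmallVariantRecord,
    SVRecord,
    ValidationScore,
    sv_id,
)

# autosomes chr1..chr19 plus chrX
DEFAULT_CHROMOSOMES = frozenset({f"chr{i}" for i in range(1, 20)} | {"chrX"})


def _check_known_keys(cls, config: dict) -> dict:
    known = {f.name for f in dc_fields(cls)}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown rule name(s) in config: {sorted(unknown)}")
    return config


@dataclass(frozen=True)
class SmallVariantRules:
    """Hard filters for SNPs/INDELs; ``None`` disables a rule."""

    chromosomes: Optional[frozenset[str]] = DEFAULT_CHROMOSOMES
    require_pass: bool = True
    min_qual: Optional[float] = 30.0     # kept iff QUAL >= min_qual
    min_dp: Optional[int] = 10
    min_gq: Optional[int] = 30
    genotype: Optional[str] = "1/1"
    biallelic_only: bool = True

    @classmethod
    def from_config(cls, config: dict) -> "SmallVariantRules":
        return cls(**_check_known_keys(cls, config))


@dataclass(frozen=True)
class SVRules:
    """Hard filters for SV calls; ``None`` disables a rule."""

    chromosomes: Optional[frozenset[str]] = DEFAULT_CHROMOSOMES
    require_pass: bool = True
    exclude_svtypes: frozenset[str] = frozenset({"BND"})
    min_svlen: Optional[int] = 50
    max_svlen: Optional[int] = 500_000
    min_qual: Optional[float] = 30.0     # kept iff QUAL > min_qual (strict)
    min_support: Optional[int] = None
    min_dp: Optional[int] = None
    min_gq: Optional[int] = None
    exclude_genotypes: frozenset[str] = frozenset({"0/0"})

    @classmethod
    def from_config(cls, config: dict) -> "SVRules":
        return cls(**_check_known_keys(cls, config))


#: per-caller presets mirroring which criteria apply to which tool
#: (read-support for the one caller that reports it, depth for the one that
#: lacks QUAL, genotype quality where the field exists)
CALLER_SV_RULES: dict[str, SVRules] = {
    "cue": SVRules(),
    "sniffles2": SVRules(min_support=5, min_gq=30),
    "sawfish": SVRules(min_gq=30),
    "pbsv": SVRules(min_qual=None, min_dp=10),
    "dipcall": SVRules(),
}


def _fail_if_missing(value, threshold, ok) -> bool:
    """True when an enabled rule fails (missing field counts as failing)."""
    if threshold is None:
        return False
    if value is None:
        return True
    return not ok(value, threshold)


def _small_variant_reason(rec: SmallVariantRecord, rules: SmallVariantRules) -> Optional[str]:
    if rules.chromosomes is not None and rec.chrom not in rules.chromosomes:
        return "chromosome"
    if rules.require_pass and rec.filter_status != "PASS":
        return "filter"
    if _fail_if_missing(rec.qual, rules.min_qual, lambda v, t: v >= t):
        return "qual"
    if _fail_if_missing(rec.dp, rules.min_dp, lambda v, t: v >= t):
        return "dp"
    if _fail_if_missing(rec.gq, rules.min_gq, lambda v, t: v >= t):
        return "gq"
    if rules.genotype is not None and rec.genotype != rules.genotype:
        return "gt"
    if rules.biallelic_only and not rec.is_biallelic:
        return "biallelic"
    return None


def filter_small_variants(
    records: Sequence[SmallVariantRecord], rules: SmallVariantRules | dict | None = None
) -> tuple[list[SmallVariantRecord], list[tuple[SmallVariantRecord, str]]]:
    """Split records into (kept, dropped-with-reason), order preserved."""
    if rules is None:
        rules = SmallVariantRules()
    elif isinstance(rules, dict):
        rules = SmallVariantRules.from_config(rules)
    kept, dropped = [], []
    for rec in records:
        reason = _small_variant_reason(rec, rules)
        if reason is None:
            kept.append(rec)
        else:
            dropped.append((rec, reason))
    return kept, dropped


def _sv_reason(rec: SVRecord, rules: SVRules) -> Optional[str]:
    if rules.chromosomes is not None and rec.chrom not in rules.chromosomes:
        return "chromosome"
    if rules.require_pass and rec.filter_status != "PASS":
        return "filter"
    if rec.svtype in rules.exclude_svtypes:
        return "svtype"
    if rules.min_svlen is not None and rec.svlen < rules.min_svlen:
        return "svlen"
    if rules.max_svlen is not None and rec.svlen > rules.max_svlen:
        return "svlen"
    if _fail_if_missing(rec.qual, rules.min_qual, lambda v, t: v > t):
        return "qual"
    if _fail_if_missing(rec.support, rules.min_support, lambda v, t: v >= t):
        return "support"
    if _fail_if_missing(rec.dp, rules.min_dp, lambda v, t: v >= t):
        return "dp"
    if _fail_if_missing(rec.gq, rules.min_gq, lambda v, t: v >= t):
        return "gq"
    if rec.genotype in rules.exclude_genotypes:
        return "gt"
    return None


def filter_svs(
    callset: CallSet, rules: SVRules | dict | None = None
) -> tuple[CallSet, list[tuple[SVRecord, str]]]:
    """Apply SV hard filters; returns (kept CallSet, dropped-with-reason)."""
    if rules is None:
        rules = CALLER_SV_RULES.get(callset.name, SVRules())
    elif isinstance(rules, dict):
        rules = SVRules.from_config(rules)
    kept, dropped = [], []
    for rec in callset.records:
        reason = _sv_reason(rec, rules)
        if reason is None:
            kept.append(rec)
        else:
            dropped.append((rec, reason))
    return callset.with_records(kept, f"filter_svs: kept {len(kept)}, dropped {len(dropped)}"), dropped


def drop_report(dropped: Iterable[tuple[SVRecord, str]]) -> list[tuple[str, str]]:
    """(sv_id, reason) rows for a TSV drop report."""
    return [(sv_id(rec), reason) for rec, reason in dropped]


def apply_validation(callset: CallSet, scores: Iterable[ValidationScore],
                     gs_min: float = 0.15, qs_min: float = 0.1) -> CallSet:
    """Set per-record validation state from GS/QS scores (inclusive bounds).

    A record is ``validated`` iff its score is assessable and GS >= gs_min
    and QS >= qs_min; ``failed`` if assessable but below either bound;
    ``not_assessable`` when the validator could not score it; records
    without any score stay ``unvalidated``.
    """
    by_id: dict[str, ValidationScore] = {}
    for s in scores:
        if s.record_id in by_id:
            raise ValueError(f"duplicate validation score id {s.record_id!r}")
        by_id[s.record_id] = s
    out = []
    for rec in callset.records:
        score = by_id.get(sv_id(rec))
        if score is None:
            out.append(rec.copy(validation=UNVALIDATED))
        elif not score.assessable:
            out.append(rec.copy(validation=NOT_ASSESSABLE))
        elif score.gs >= gs_min and score.qs >= qs_min:
            out.append(rec.copy(validation=VALIDATED))
        else:
            out.append(rec.copy(validation=FAILED))
    return callset.with_records(out, f"apply_validation gs>={gs_min} qs>={qs_min}")
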