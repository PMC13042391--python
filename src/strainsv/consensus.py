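"""Multi-caller consensus: clustering one strain's calls across callers and
routing each cluster through a type/size-specific acceptance rule.

Routing mirrors the production rules of the pipeline this toolkit models:
deletions (both sizes) need >=2 of the alignment-based caller trio; small
insertions need both of the two callers that detect them reliably; large
insertions come from the single assembly-based caller and must pass
read-based validation; inversions and duplications are accepted from any of
their designated callers only when validated (the validation flag also
stands in for manual inspection of inversions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .matching import MatchProfile, records_match
from .records import VALIDATED, CallSet, SizeBinning, SVRecord, sv_id

#: merge tolerance used to link calls across callers: 1 kb on both
#: breakpoints, same type required, no length constraint
MERGE_PROFILE = MatchProfile("merge", 1000, 1000, 10**9)


@dataclass
class ConsensusGroup:
    """One cluster of same-variant calls across callers."""

    members: list[SVRecord]
    callers: frozenset[str]
    representative: SVRecord
    route: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a consensus group needs >= 1 member")

    @property
    def svtype(self) -> str:
        return self.representative.svtype

    @property
    def validated(self) -> bool:
        return any(m.validation == VALIDATED for m in self.members)


def _representative(members: Sequence[SVRecord]) -> SVRecord:
    """Member with median start; ties broken by caller name then position."""
    ordered = sorted(members, key=lambda m: (m.start, m.caller, m.end))
    lower_median = ordered[(len(ordered) - 1) // 2]
    candidates = [m for m in members if m.start == lower_median.start]
    return min(candidates, key=lambda m: (m.caller, m.end, m.svlen))


def cluster_calls(callsets: Sequence[CallSet],
                  merge_profile: MatchProfile = MERGE_PROFILE) -> list[ConsensusGroup]:
    """Connected components of the records_match graph across callers.

    All callsets must belong to one strain.  Within-caller duplicates may
    share a group but count once toward caller support.  Output order is
    deterministic (by representative position).
    """
    samples = {cs.sample for cs in callsets}
    if len(samples) > 1:
        raise ValueError(f"mixed strains in cluster_calls: {sorted(samples)}")
    records: list[SVRecord] = [r for cs in callsets for r in cs.records]
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.caller))
    parent = list(range(len(records)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    # sorted sweep: only pairs within the start tolerance are examined
    for i, a in enumerate(records):
        for j in range(i + 1, len(records)):
            b = records[j]
            if b.chrom != a.chrom or b.start - a.start >= merge_profile.max_start_diff:
                break
            if records_match(a, b, merge_profile):
                union(i, j)
    groups: dict[int, list[SVRecord]] = {}
    for idx in range(len(records)):
        groups.setdefault(find(idx), []).append(records[idx])
    out = []
    for _, members in sorted(groups.items()):
        rep = _representative(members)
        out.append(ConsensusGroup(members=members,
                                  callers=frozenset(m.caller for m in members),
                                  representative=rep))
    out.sort(key=lambda g: (g.representative.chrom, g.representative.start,
                            g.representative.svtype, g.representative.svlen))
    return out


@dataclass(frozen=True)
class RouteRule:
    """Acceptance rule for one (svtype, size-bin) stratum."""

    callers: frozenset[str]
    min_support: int = 1
    require_validation: bool = False

    def accepts(self, group: ConsensusGroup) -> bool:
        support = len(group.callers & self.callers)
        if support < self.min_support:
            return False
        if self.require_validation and not group.validated:
            return False
        return True


DEL_TRIO = frozenset({"cue", "sniffles2", "sawfish"})

#: default routing table keyed by (svtype, size_bin)
DEFAULT_ROUTING: dict[tuple[str, str], RouteRule] = {
    ("DEL", "small"): RouteRule(DEL_TRIO, min_support=2),
    ("DEL", "large"): RouteRule(DEL_TRIO, min_support=2),
    ("INS", "small"): RouteRule(frozenset({"sniffles2", "sawfish"}), min_support=2),
    ("INS", "large"): RouteRule(frozenset({"dipcall"}), min_support=1,
                                require_validation=True),
    ("INV", "small"): RouteRule(frozenset({"cue", "sniffles2", "pbsv"}), min_support=1,
                                require_validation=True),
    ("INV", "large"): RouteRule(frozenset({"cue", "sniffles2", "pbsv"}), min_support=1,
                                require_validation=True),
    ("DUP", "small"): RouteRule(frozenset({"cue", "pbsv"}), min_support=1,
                                require_validation=True),
    ("DUP", "large"): RouteRule(frozenset({"cue", "pbsv"}), min_support=1,
                                require_validation=True),
}


def route_and_select(groups: Sequence[ConsensusGroup],
                     routing: Mapping[tuple[str, str], RouteRule] | None = None,
                     binning: SizeBinning | None = None,
                     sample: str = "") -> CallSet:
    """Apply the routing table; kept records are group representatives."""
    if routing is None:
        routing = DEFAULT_ROUTING
    if binning is None:
        binning = SizeBinning()
    kept = []
    for group in groups:
        rep = group.representative
        key = (rep.svtype, binning.bin_of(rep.svlen))
        rule = routing.get(key)
        if rule is None:
            raise ValueError(f"no routing rule for stratum {key}")
        group.route = f"{key[0]}:{key[1]}"
        if rule.accepts(group):
            validation = VALIDATED if group.validated else rep.validation
            kept.append(rep.copy(caller="consensus", validation=validation))
    if not sample and groups:
        sample = groups[0].representative.sample
    return CallSet("consensus", sample, kept,
                   [f"route_and_select: kept {len(kept)} of {len(groups)} groups"])


def group_table(groups: Sequence[ConsensusGroup],
                routing: Mapping[tuple[str, str], RouteRule] | None = None,
                binning: SizeBinning | None = None) -> list[dict]:
    """Tabular view of groups (group id, members, callers, route, decision)."""
    if routing is None:
        routing = DEFAULT_ROUTING
    if binning is None:
        binning = SizeBinning()
    rows = []
    for n, group in enumerate(groups):
        rep = group.representative
        key = (rep.svtype, binning.bin_of(rep.svlen))
        rule = routing.get(key)
        rows.append({
            "group": n,
            "representative": sv_id(rep),
            "members": ",".join(sorted(sv_id(m) + "@" + m.caller for m in group.members)),
            "callers": ",".join(sorted(group.callers)),
            "route": f"{key[0]}:{key[1]}",
            "kept": bool(rule is not None and rule.accepts(group)),
        })
    return rows


def dup_within_ins(final: CallSet | Sequence[SVRecord], tolerance: int = 1000) -> dict[str, bool]:
    """Flag DUPs whose both breakpoints lie near a single INS position.

    A DUP is flagged "within-INS" iff there is one INS record such that both
    the DUP start and end are within ``tolerance`` bp (inclusive) of that
    insertion's point of insertion.
    """
    records = list(final.records if isinstance(final, CallSet) else final)
    ins_positions = [(r.chrom, r.start) for r in records if r.svtype == "INS"]
    flags: dict[str, bool] = {}
    for rec in records:
        if rec.svtype != "DUP":
            continue
        flags[sv_id(rec)] = any(
            chrom == rec.chrom
            and abs(rec.start - pos) <= tolerance
            and abs(rec.end - pos) <= tolerance
            for chrom, pos in ins_positions)
    return flags
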