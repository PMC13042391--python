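"""Tolerance-based SV matching and precision/recall/F1 evaluation.

Two records represent the same variant when their start positions, end
positions and lengths each differ by strictly less than the profile's
tolerances and their types are compatible.  Call-to-truth assignment is a
maximum-cardinality one-to-one bipartite matching; ties among maximum
matchings are broken by the smallest total breakpoint distance, which is
obtained by solving a min-cost assignment with a big-M penalty on non-edges
(decomposed into connected components so only candidate pairs are ever
enumerated).  Evaluation stratifies TP/FP/FN by SV type and size bin, the
truth record defining the stratum of each matched pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .records import CallSet, SizeBinning, SVRecord


@dataclass(frozen=True)
class MatchProfile:
    """Tolerances defining when two SV records are the same variant.

    All offset comparisons are strict (< tolerance).  ``typeignore_ins_dup``
    additionally treats INS and DUP as compatible, modelling callers that
    emit duplications as insertions.
    """

    name: str = "default"
    max_start_diff: int = 500
    max_end_diff: int = 500
    max_len_diff: int = 500
    require_same_type: bool = True
    typeignore_ins_dup: bool = False

    def __post_init__(self) -> None:
        if min(self.max_start_diff, self.max_end_diff, self.max_len_diff) < 0:
            raise ValueError("tolerances must be >= 0")


#: three evaluation presets plus the 50 bp cross-dataset comparison rule
DEFAULT_PROFILE = MatchProfile("default", 500, 500, 500)
STRINGENT_PROFILE = MatchProfile("stringent", 100, 100, 50)
RELAXED_PROFILE = MatchProfile("relaxed", 1000, 1000, 1000)
COMPARISON_PROFILE = MatchProfile("comparison", 50, 50, 50)

PROFILES = {p.name: p for p in
            (DEFAULT_PROFILE, STRINGENT_PROFILE, RELAXED_PROFILE, COMPARISON_PROFILE)}


def _types_compatible(a: str, b: str, profile: MatchProfile) -> bool:
    if not profile.require_same_type:
        return True
    if a == b:
        return True
    return profile.typeignore_ins_dup and {a, b} == {"INS", "DUP"}


def records_match(a: SVRecord, b: SVRecord, profile: MatchProfile) -> bool:
    """True iff ``a`` and ``b`` represent the same variant under ``profile``."""
    if a.chrom != b.chrom:
        return False
    if not _types_compatible(a.svtype, b.svtype, profile):
        return False
    if abs(a.start - b.start) >= profile.max_start_diff:
        return False
    # an insertion's end is its insertion point, so the end comparison for
    # any pair involving an INS reduces to the start comparison
    if a.svtype == "INS" or b.svtype == "INS":
        d_end = abs(a.start - b.start)
    else:
        d_end = abs(a.end - b.end)
    if d_end >= profile.max_end_diff:
        return False
    return abs(a.svlen - b.svlen) < profile.max_len_diff


def _pair_distance(a: SVRecord, b: SVRecord) -> int:
    if a.svtype == "INS" or b.svtype == "INS":
        return 2 * abs(a.start - b.start)
    return abs(a.start - b.start) + abs(a.end - b.end)


def _candidate_edges(calls: Sequence[SVRecord], truth: Sequence[SVRecord],
                     profile: MatchProfile) -> list[tuple[int, int, int]]:
    """(call_idx, truth_idx, distance) for all matching pairs.

    A sorted sweep over start positions keeps this near-linear when records
    are spread out; only pairs within the start tolerance are tested.
    """
    edges = []
    order_t = sorted(range(len(truth)), key=lambda j: (truth[j].chrom, truth[j].start))
    order_c = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].start))
    lo = 0
    for i in order_c:
        c = calls[i]
        while lo < len(order_t):
            t = truth[order_t[lo]]
            if (t.chrom, t.start + profile.max_start_diff) < (c.chrom, c.start):
                lo += 1
            else:
                break
        k = lo
        while k < len(order_t):
            j = order_t[k]
            t = truth[j]
            if (t.chrom, t.start - profile.max_start_diff) > (c.chrom, c.start):
                break
            if records_match(c, t, profile):
                edges.append((i, j, _pair_distance(c, t)))
            k += 1
    return edges


def _components(edges: list[tuple[int, int, int]]) -> list[list[tuple[int, int, int]]]:
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, j, _ in edges:
        for node in (("c", i), ("t", j)):
            parent.setdefault(node, node)
        union(("c", i), ("t", j))
    groups: dict[tuple[str, int], list[tuple[int, int, int]]] = {}
    for e in edges:
        groups.setdefault(find(("c", e[0])), []).append(e)
    return [groups[k] for k in sorted(groups)]


def match_sets(calls: CallSet | Sequence[SVRecord], truth: CallSet | Sequence[SVRecord],
               profile: MatchProfile) -> list[tuple[int, int]]:
    """Maximum one-to-one matching; returns (call_index, truth_index) pairs.

    Indices refer to the (sorted) order of the input sets.  Deterministic:
    among maximum matchings the one with the smallest total breakpoint
    distance is returned, ties broken by lexicographic record order.
    """
    calls_r = list(calls.records if isinstance(calls, CallSet) else calls)
    truth_r = list(truth.records if isinstance(truth, CallSet) else truth)
    edges = _candidate_edges(calls_r, truth_r, profile)
    pairs: list[tuple[int, int]] = []
    for comp in _components(edges):
        ci = sorted({i for i, _, _ in comp})
        tj = sorted({j for _, j, _ in comp})
        cmap = {i: a for a, i in enumerate(ci)}
        tmap = {j: b for b, j in enumerate(tj)}
        # big-M penalty: any real edge set beats any solution using a non-edge
        big_m = float(sum(d for _, _, d in comp) + len(comp) + 1)
        cost = np.full((len(ci), len(tj)), big_m)
        for i, j, d in comp:
            cost[cmap[i], tmap[j]] = float(d)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < big_m:
                pairs.append((ci[r], tj[c]))
    return sorted(pairs)


@dataclass
class EvalResult:
    """TP/FP/FN counts and derived metrics for one (type, size-bin) stratum."""

    svtype: str
    size_bin: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def stratum(self) -> str:
        return f"{self.svtype}:{self.size_bin}"


def evaluate(calls: CallSet | Sequence[SVRecord], truth: CallSet | Sequence[SVRecord],
             profile: MatchProfile, binning: SizeBinning | None = None) -> list[EvalResult]:
    """Score calls against truth per (svtype, size-bin) stratum.

    tp = matched pairs (stratum from the truth record), fp = unmatched
    calls (own stratum), fn = unmatched truth; a pooled ``overall`` row is
    appended last.
    """
    if binning is None:
        binning = SizeBinning()
    calls_r = list(calls.records if isinstance(calls, CallSet) else calls)
    truth_r = list(truth.records if isinstance(truth, CallSet) else truth)
    pairs = match_sets(calls_r, truth_r, profile)
    matched_c = {i for i, _ in pairs}
    matched_t = {j for _, j in pairs}
    strata: dict[tuple[str, str], list[int]] = {}

    def bump(key: tuple[str, str], slot: int) -> None:
        strata.setdefault(key, [0, 0, 0])[slot] += 1

    for _, j in pairs:
        t = truth_r[j]
        bump((t.svtype, binning.bin_of(t.svlen)), 0)
    for i, c in enumerate(calls_r):
        if i not in matched_c:
            bump((c.svtype, binning.bin_of(c.svlen)), 1)
    for j, t in enumerate(truth_r):
        if j not in matched_t:
            bump((t.svtype, binning.bin_of(t.svlen)), 2)

    results = [EvalResult(sv, b, *counts) for (sv, b), counts in sorted(strata.items())]
    results.append(EvalResult("overall", "all", len(pairs),
                              len(calls_r) - len(pairs), len(truth_r) - len(pairs)))
    return results


def sweep_profiles(calls, truth, profiles: Sequence[MatchProfile],
                   binning: SizeBinning | None = None) -> dict[str, list[EvalResult]]:
    """Evaluate under several tolerance profiles; strata ordered identically."""
    if not profiles:
        raise ValueError("need at least one profile")
    out: dict[str, list[EvalResult]] = {}
    all_strata: list[tuple[str, str]] = []
    per_profile = {}
    for profile in profiles:
        res = evaluate(calls, truth, profile, binning)
        per_profile[profile.name] = {(r.svtype, r.size_bin): r for r in res}
        for r in res:
            if (r.svtype, r.size_bin) not in all_strata:
                all_strata.append((r.svtype, r.size_bin))
    all_strata.sort(key=lambda s: (s == ("overall", "all"), s))
    for profile in profiles:
        rows = per_profile[profile.name]
        out[profile.name] = [rows.get((sv, b), EvalResult(sv, b, 0, 0, 0))
                             for sv, b in all_strata]
    return out


def evaluation_table(results: dict[str, list[EvalResult]]):
    """Flatten a sweep into a tidy DataFrame (rows: stratum x profile)."""
    import pandas as pd

    rows = []
    for profile, res in results.items():
        for r in res:
            rows.append({"profile": profile, "svtype": r.svtype, "size_bin": r.size_bin,
                         "tp": r.tp, "fp": r.fp, "fn": r.fn,
                         "precision": r.precision, "recall": r.recall, "f1": r.f1})
    return pd.DataFrame(rows)
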