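"""Cross-dataset comparison, strain-sharing summaries and the
perfect-association scan.

Two SV datasets are compared per type with the 50 bp tolerance rule (both
breakpoints and the length must differ by strictly less than 50 bp), using
one-to-one matching so Venn totals are never double-counted.  The
presence/absence :class:`GenotypeMatrix` supports sharing spectra
(how many strains carry each SV) and a scan for SVs whose carrier pattern
equals a binary phenotype exactly — the zero-discordance pattern a
qualitative-trait scan calls "effect size 1, p-value 0".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .matching import COMPARISON_PROFILE, MatchProfile, match_sets, records_match
from .records import CallSet, SVRecord, sv_id


@dataclass
class ComparisonReport:
    """Shared/unique counts and ids for a two-dataset comparison."""

    shared: int
    unique_a: int
    unique_b: int
    shared_ids: list[tuple[str, str]] = field(default_factory=list)
    unique_a_ids: list[str] = field(default_factory=list)
    unique_b_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shared + self.unique_a < 0 or self.shared + self.unique_b < 0:
            raise ValueError("negative counts")

    @property
    def total_a(self) -> int:
        return self.shared + self.unique_a

    @property
    def total_b(self) -> int:
        return self.shared + self.unique_b


def compare_sv_datasets(a: CallSet | Sequence[SVRecord], b: CallSet | Sequence[SVRecord],
                        profile: MatchProfile = COMPARISON_PROFILE) -> ComparisonReport:
    """Tolerance-based comparison, each SV type analysed separately.

    shared = size of the maximum one-to-one matching under the profile
    (strict <50 bp rule by default); an SV in A certifies at most one SV in
    B as shared.
    """
    a_recs = list(a.records if isinstance(a, CallSet) else a)
    b_recs = list(b.records if isinstance(b, CallSet) else b)
    shared_ids: list[tuple[str, str]] = []
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    types = sorted({r.svtype for r in a_recs} | {r.svtype for r in b_recs})
    for svtype in types:
        ia = [i for i, r in enumerate(a_recs) if r.svtype == svtype]
        ib = [j for j, r in enumerate(b_recs) if r.svtype == svtype]
        pairs = match_sets([a_recs[i] for i in ia], [b_recs[j] for j in ib], profile)
        for pi, pj in pairs:
            matched_a.add(ia[pi])
            matched_b.add(ib[pj])
            shared_ids.append((sv_id(a_recs[ia[pi]]), sv_id(b_recs[ib[pj]])))
    unique_a_ids = [sv_id(r) for i, r in enumerate(a_recs) if i not in matched_a]
    unique_b_ids = [sv_id(r) for j, r in enumerate(b_recs) if j not in matched_b]
    return ComparisonReport(shared=len(shared_ids), unique_a=len(unique_a_ids),
                            unique_b=len(unique_b_ids), shared_ids=sorted(shared_ids),
                            unique_a_ids=sorted(unique_a_ids),
                            unique_b_ids=sorted(unique_b_ids))


def compare_by_id(a: Sequence[str], b: Sequence[str]) -> ComparisonReport:
    """Exact id-based comparison (set intersection / differences)."""
    for name, ids in (("a", a), ("b", b)):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate id in dataset {name}: {x!r}")
            seen.add(x)
    sa, sb = set(a), set(b)
    shared = sorted(sa & sb)
    ua = sorted(sa - sb)
    ub = sorted(sb - sa)
    return ComparisonReport(shared=len(shared), unique_a=len(ua), unique_b=len(ub),
                            shared_ids=[(x, x) for x in shared],
                            unique_a_ids=ua, unique_b_ids=ub)


class GenotypeMatrix:
    """SV-by-strain presence/absence matrix with optional impact labels."""

    def __init__(self, presence: pd.DataFrame, impact: pd.Series | None = None):
        if not presence.isin([0, 1]).all().all():
            raise ValueError("presence entries must be 0/1")
        self.presence = presence.astype(np.int8)
        if impact is not None:
            impact = impact.reindex(presence.index)
        self.impact = impact

    @property
    def sv_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def strains(self) -> list[str]:
        return list(self.presence.columns)

    @classmethod
    def from_arrays(cls, sv_ids: Sequence[str], strains: Sequence[str],
                    presence, impact: Mapping[str, str] | None = None) -> "GenotypeMatrix":
        df = pd.DataFrame(np.asarray(presence), index=list(sv_ids), columns=list(strains))
        series = pd.Series(impact) if impact is not None else None
        return cls(df, series)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        impact = None
        if "impact" in df.columns:
            impact = df.pop("impact")
        return cls(df, impact)

    def to_tsv(self, path: str | Path) -> None:
        df = self.presence.copy()
        if self.impact is not None:
            df["impact"] = self.impact
        df.to_csv(path, sep="\t", index_label="sv_id")


def sharing_spectrum(matrix: GenotypeMatrix) -> tuple[dict[int, int], pd.Series, int]:
    """Allele-sharing summary.

    Returns ``(spectrum, strain_unique, no_carrier)`` where ``spectrum[k]``
    counts SVs carried by exactly k >= 1 strains, ``strain_unique`` tallies
    per strain the SVs it alone carries, and ``no_carrier`` counts all-zero
    rows (excluded from the spectrum).
    """
    row_sums = matrix.presence.sum(axis=1)
    spectrum = {int(k): int(n) for k, n in row_sums.value_counts().items() if k >= 1}
    unique_rows = matrix.presence.loc[row_sums == 1]
    strain_unique = unique_rows.sum(axis=0).astype(int)
    return spectrum, strain_unique, int((row_sums == 0).sum())


def perfect_association_scan(matrix: GenotypeMatrix, phenotype,
                             impact_filter: str | None = None,
                             include_complement: bool = False) -> list[str]:
    """SVs whose presence pattern equals the binary phenotype exactly.

    ``phenotype`` maps every strain to 0/1 (a pandas Series, dict or array
    aligned with the matrix's strain order).  Zero discordant strains is the
    "genetic effect size 1, association p-value 0" pattern.  Optionally also
    reports complement (protective-allele) patterns, and can be restricted
    to SVs with a given impact label.
    """
    if isinstance(phenotype, (pd.Series, dict)):
        pheno = pd.Series(phenotype).reindex(matrix.strains)
        if pheno.isna().any():
            missing = [s for s in matrix.strains if s not in dict(phenotype)]
            raise ValueError(f"phenotype missing strains: {missing}")
    else:
        pheno = pd.Series(list(phenotype), index=matrix.strains)
    if len(pheno) != len(matrix.strains):
        raise ValueError("phenotype length != number of strains")
    vec = pheno.astype(int).to_numpy()
    if vec.sum() == 0:
        warnings.warn("phenotype has no positive strains; scan is empty")
        return []
    pres = matrix.presence.to_numpy()
    hit = (pres == vec).all(axis=1)
    if include_complement:
        hit |= (pres == (1 - vec)).all(axis=1)
    ids = [sv for sv, h in zip(matrix.sv_ids, hit) if h]
    if impact_filter is not None:
        if matrix.impact is None:
            raise ValueError("matrix carries no impact labels")
        ids = [sv for sv in ids if matrix.impact.get(sv) == impact_filter]
    return ids


def build_genotype_matrix(callsets: Mapping[str, CallSet],
                          profile: MatchProfile = COMPARISON_PROFILE,
                          impact: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Cluster final per-strain calls across strains into a presence matrix.

    Records from all strains are linked with :func:`records_match` under the
    comparison profile; each connected component becomes one matrix row,
    identified by the sv_id of its earliest member, with presence 1 for
    every strain contributing a member.
    """
    strains = sorted(callsets)
    tagged: list[tuple[str, SVRecord]] = []
    for strain in strains:
        for rec in callsets[strain].records:
            tagged.append((strain, rec))
    tagged.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end, t[0]))
    parent = list(range(len(tagged)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (_, a) in enumerate(tagged):
        for j in range(i + 1, len(tagged)):
            b = tagged[j][1]
            if b.chrom != a.chrom or b.start - a.start >= profile.max_start_diff:
                break
            if records_match(a, b, profile):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[int]] = {}
    for idx in range(len(tagged)):
        clusters.setdefault(find(idx), []).append(idx)
    sv_ids, rows = [], []
    for root in sorted(clusters):
        members = clusters[root]
        rep_strain, rep = tagged[min(members)]
        row_id = sv_id(rep)
        carriers = {tagged[m][0] for m in members}
        sv_ids.append(row_id)
        rows.append([1 if s in carriers else 0 for s in strains])
    return GenotypeMatrix.from_arrays(sv_ids, strains, np.array(rows, dtype=np.int8),
                                      impact=impact)
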