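import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strainsv as sv
from strainsv.annotate import IUPAC, motif_regex, reverse_complement_motif
from strainsv.simulate import random_sequence, reverse_complement

CTCF = "CCGCGNGGNGGCAG"


def naive_scan(seq: str, motif: str):
    """Sliding-window oracle over both strands."""
    def matches(window: str, pattern: str) -> bool:
        return len(window) == len(pattern) and all(
            b in IUPAC[p] for b, p in zip(window, pattern))

    hits = []
    rc = reverse_complement_motif(motif)
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i:i + len(motif)]
        if matches(window, motif):
            hits.append((i, "+"))
        if matches(window, rc):
            hits.append((i, "-"))
    return sorted(hits)


class TestScanMotif:
    def test_single_plus_strand_occurrence(self):
        seq = "T" * 50 + "CCGCGAGGTGGCAG" + "T" * 50
        hits = sv.scan_motif({"chr1": seq}, CTCF)
        assert [(h.start, h.strand) for h in hits] == [(50, "+")]
        assert hits[0].matched_seq == "CCGCGAGGTGGCAG"

    def test_minus_strand_occurrence(self):
        realization = "CCGCGAGGTGGCAG"
        seq = "T" * 30 + reverse_complement(realization) + "T" * 30
        hits = sv.scan_motif({"chr1": seq}, CTCF)
        assert [(h.start, h.strand) for h in hits] == [(30, "-")]
        assert hits[0].matched_seq == realization

    def test_invalid_iupac_character(self):
        with pytest.raises(ValueError, match="IUPAC"):
            sv.scan_motif({"chr1": "ACGT"}, "ACGZ")

    def test_overlapping_hits_all_reported(self):
        # AA in a poly-A run occurs at every offset
        hits = sv.scan_motif({"chr1": "AAAA"}, "AA")
        plus = [h.start for h in hits if h.strand == "+"]
        assert plus == [0, 1, 2]

    def test_equals_sliding_window_oracle_fuzzed(self):
        rng = np.random.default_rng(71)
        for trial in range(100):
            seq = random_sequence(300, rng)
            # plant a forward or reverse realization half the time
            if trial % 2 == 0:
                real = "".join(c if c != "N" else "ACGT"[rng.integers(4)]
                               for c in CTCF)
                if trial % 4 == 0:
                    real = reverse_complement(real)
                pos = int(rng.integers(0, len(seq) - len(real)))
                seq = seq[:pos] + real + seq[pos + len(real):]
            got = [(h.start, h.strand) for h in sv.scan_motif({"c": seq}, CTCF)]
            assert got == naive_scan(seq, CTCF)

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=120))
    def test_strand_symmetry(self, seq):
        fwd = {(h.start, h.strand) for h in sv.scan_motif({"c": seq}, "CANNTG")}
        L = len(seq)
        swapped = {(L - h.end, "+" if h.strand == "-" else "-")
                   for h in sv.scan_motif({"c": reverse_complement(seq)}, "CANNTG")}
        assert fwd == swapped


class TestPeakSupport:
    def site(self, start=100, length=14, chrom="chr1"):
        return sv.MotifHit(chrom, start, start + length, "+", "A" * length)

    def peak(self, start, end, signal=100.0, nlq=5.0, chrom="chr1"):
        return sv.Peak(chrom, start, end, signal, nlq)

    def test_half_overlap_is_inclusive(self):
        site = self.site(100, 14)
        peak = self.peak(107, 300)  # covers exactly 7 of 14 bp
        assert sv.peak_support([site], [peak]) == [(True, 1)]
        barely_less = self.peak(108, 300)  # 6 of 14
        assert sv.peak_support([site], [barely_less]) == [(False, 0)]

    def test_signal_threshold_inclusive_q_strict(self):
        site = self.site()
        assert sv.peak_support([site], [self.peak(0, 500, signal=49.9)]) == [(False, 0)]
        assert sv.peak_support([site], [self.peak(0, 500, signal=50.0)]) == [(True, 1)]
        assert sv.peak_support([site], [self.peak(0, 500, nlq=3.0)]) == [(False, 0)]
        assert sv.peak_support([site], [self.peak(0, 500, nlq=3.01)]) == [(True, 1)]

    def test_counts_equal_quadratic_oracle(self):
        rng = np.random.default_rng(72)
        sites = [self.site(int(rng.integers(0, 5000)), 14) for _ in range(40)]
        peaks = [self.peak(int(s), int(s) + int(rng.integers(10, 400)),
                           signal=float(rng.integers(10, 200)),
                           nlq=float(rng.uniform(0, 10)))
                 for s in rng.integers(0, 5000, 60)]
        got = sv.peak_support(sites, peaks)
        for site, (supported, count) in zip(sites, got):
            want = 0
            for p in peaks:
                if p.signal_value >= 50 and p.neg_log10_q > 3:
                    ov = min(site.end, p.end) - max(site.start, p.start)
                    if ov / (site.end - site.start) >= 0.5:
                        want += 1
            assert count == want and supported == (want > 0)

    def test_monotone_in_overlap_threshold(self):
        rng = np.random.default_rng(73)
        sites = [self.site(int(rng.integers(0, 3000)), 14) for _ in range(30)]
        peaks = [self.peak(int(s), int(s) + 50) for s in rng.integers(0, 3000, 40)]
        counts = [sum(s for s, _ in sv.peak_support(sites, peaks, min_overlap_frac=f))
                  for f in (0.1, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestDelsWithMotif:
    def make_del(self, start, length):
        return sv.SVRecord(chrom="chr1", start=start, end=start + length,
                           svtype="DEL", svlen=length)

    def hit(self, start):
        return sv.MotifHit("chr1", start, start + 14, "+", "A" * 14)

    def test_contained_motif_counts(self):
        counts = sv.dels_with_motif([self.make_del(1000, 200)], [self.hit(1100)])
        assert list(counts.values()) == [1]

    def test_straddling_motif_does_not_count(self):
        counts = sv.dels_with_motif([self.make_del(1000, 200)], [self.hit(995)])
        assert list(counts.values()) == [0]
        counts = sv.dels_with_motif([self.make_del(1000, 200)], [self.hit(1190)])
        assert list(counts.values()) == [0]

    def test_counts_equal_brute_force(self):
        rng = np.random.default_rng(74)
        dels = [self.make_del(int(s), int(rng.integers(50, 500)))
                for s in rng.integers(0, 20_000, 30)]
        hits = [self.hit(int(s)) for s in rng.integers(0, 20_000, 80)]
        counts = sv.dels_with_motif(dels, hits)
        for d in dels:
            want = sum(1 for h in hits if h.start >= d.start and h.end <= d.end)
            assert counts[sv.sv_id(d)] == want


class TestTeAssociation:
    def make_del(self, start, length):
        return sv.SVRecord(chrom="chr1", start=start, end=start + length,
                           svtype="DEL", svlen=length)

    def test_sixty_percent_boundary_inclusive(self):
        d = self.make_del(1000, 100)
        flags, frac = sv.te_association([d], [("chr1", 1000, 1060)])
        assert flags[sv.sv_id(d)] is True and frac == 1.0
        flags, _ = sv.te_association([d], [("chr1", 1000, 1059)])
        assert flags[sv.sv_id(d)] is False

    def test_no_overlap_not_associated(self):
        d = self.make_del(1000, 100)
        flags, frac = sv.te_association([d], [("chr1", 5000, 6000)])
        assert flags[sv.sv_id(d)] is False and frac == 0.0

    def test_union_not_sum_of_overlapping_tes(self):
        d = self.make_del(1000, 100)
        tes = [("chr1", 1000, 1045), ("chr1", 1015, 1060)]  # union 60, sum 90
        flags, _ = sv.te_association(d_list := [d], tes)
        assert flags[sv.sv_id(d)] is True
        tes_less = [("chr1", 1000, 1040), ("chr1", 1015, 1055)]  # union 55
        flags, _ = sv.te_association(d_list, tes_less)
        assert flags[sv.sv_id(d)] is False

    def test_equals_quadratic_union_oracle(self):
        rng = np.random.default_rng(75)
        dels = [self.make_del(int(s), int(rng.integers(50, 400)))
                for s in rng.integers(0, 30_000, 25)]
        tes = [("chr1", int(s), int(s) + int(rng.integers(20, 600)))
               for s in rng.integers(0, 30_000, 50)]
        flags, frac = sv.te_association(dels, tes)
        n_true = 0
        for d in dels:
            covered = sum(1 for pos in range(d.start, d.end)
                          if any(t[1] <= pos < t[2] for t in tes))
            want = covered / d.svlen >= 0.6
            assert flags[sv.sv_id(d)] == want
            n_true += want
        assert frac == n_true / len(dels)

    def test_monotone_in_fraction_threshold(self):
        rng = np.random.default_rng(76)
        dels = [self.make_del(int(s), int(rng.integers(50, 400)))
                for s in rng.integers(0, 30_000, 25)]
        tes = [("chr1", int(s), int(s) + int(rng.integers(20, 600)))
               for s in rng.integers(0, 30_000, 50)]
        counts = [sum(sv.te_association(dels, tes, min_frac=f)[0].values())
                  for f in (0.2, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)
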