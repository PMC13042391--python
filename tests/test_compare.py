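import numpy as np
import pandas as pd
import pytest

import strainsv as sv
from conftest import random_records


def del_rec(start, length=200, svtype="DEL", chrom="chr1"):
    end = start if svtype == "INS" else start + length
    return sv.SVRecord(chrom=chrom, start=start, end=end, svtype=svtype, svlen=length)


class TestCompareSvDatasets:
    def test_identical_datasets_fully_shared(self):
        recs = [del_rec(s) for s in range(1000, 50_000, 5000)]
        rep = sv.compare_sv_datasets(recs, [r.copy() for r in recs])
        assert (rep.shared, rep.unique_a, rep.unique_b) == (len(recs), 0, 0)

    def test_strict_50bp_boundary(self):
        a = [del_rec(1000)]
        assert sv.compare_sv_datasets(a, [del_rec(1049)]).shared == 1
        assert sv.compare_sv_datasets(a, [del_rec(1050)]).shared == 0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(61)
        a = random_records(rng, 25, span=20_000)
        b = random_records(rng, 30, span=20_000)
        fwd = sv.compare_sv_datasets(a, b)
        rev = sv.compare_sv_datasets(b, a)
        assert fwd.shared == rev.shared
        assert (fwd.unique_a, fwd.unique_b) == (rev.unique_b, rev.unique_a)

    def test_types_compared_separately(self):
        a = [del_rec(1000, svtype="DEL")]
        b = [del_rec(1000, svtype="INV")]
        assert sv.compare_sv_datasets(a, b).shared == 0

    def test_planted_overlap_fraction_recovered(self):
        rng = np.random.default_rng(62)
        shared = [del_rec(int(s), length=int(L)) for s, L in
                  zip(range(10_000, 10_000 + 60 * 4000, 4000),
                      rng.integers(50, 400, 60))]
        only_a = [del_rec(s) for s in range(500_000, 500_000 + 20 * 4000, 4000)]
        only_b = [del_rec(s) for s in range(900_000, 900_000 + 20 * 4000, 4000)]
        a = shared + only_a
        b = [r.copy(start=r.start + 5, end=r.end + 5) for r in shared] + only_b
        rep = sv.compare_sv_datasets(a, b)
        assert (rep.shared, rep.unique_a, rep.unique_b) == (60, 20, 20)
        assert rep.shared + rep.unique_a == len(a)
        assert rep.shared + rep.unique_b == len(b)


class TestCompareById:
    def test_set_semantics(self):
        rep = sv.compare_by_id(["a", "b", "c"], ["b", "c", "d"])
        assert (rep.shared, rep.unique_a, rep.unique_b) == (2, 1, 1)
        assert rep.unique_a_ids == ["a"] and rep.unique_b_ids == ["d"]

    def test_disjoint_and_identical(self):
        assert sv.compare_by_id(["x"], ["y"]).shared == 0
        assert sv.compare_by_id(["x", "y"], ["y", "x"]).shared == 2

    def test_duplicate_id_reported(self):
        with pytest.raises(ValueError, match="dup1"):
            sv.compare_by_id(["dup1", "dup1"], ["b"])

    def test_matches_brute_force_set_ops(self):
        rng = np.random.default_rng(63)
        universe = [f"chr1-{i}-DEL-100" for i in range(200)]
        for _ in range(20):
            a = list(rng.choice(universe, size=int(rng.integers(0, 80)), replace=False))
            b = list(rng.choice(universe, size=int(rng.integers(0, 80)), replace=False))
            rep = sv.compare_by_id(a, b)
            assert rep.shared == len(set(a) & set(b))
            assert rep.unique_a == len(set(a) - set(b))


class TestSharingSpectrum:
    def test_single_sv_three_carriers(self):
        m = sv.GenotypeMatrix.from_arrays(["sv1"], ["s1", "s2", "s3", "s4"],
                                          [[1, 1, 1, 0]])
        spectrum, unique, no_carrier = sv.sharing_spectrum(m)
        assert spectrum == {3: 1} and no_carrier == 0
        assert unique.sum() == 0

    def test_all_zero_row_counted_separately(self):
        m = sv.GenotypeMatrix.from_arrays(["sv1", "sv2"], ["s1", "s2"],
                                          [[0, 0], [1, 0]])
        spectrum, unique, no_carrier = sv.sharing_spectrum(m)
        assert spectrum == {1: 1} and no_carrier == 1
        assert unique["s1"] == 1

    def test_matches_brute_force_row_sums(self):
        rng = np.random.default_rng(64)
        pres = rng.integers(0, 2, size=(120, 12))
        ids = [f"sv{i}" for i in range(120)]
        strains = [f"st{j}" for j in range(12)]
        m = sv.GenotypeMatrix.from_arrays(ids, strains, pres)
        spectrum, unique, no_carrier = sv.sharing_spectrum(m)
        sums = pres.sum(axis=1)
        for k in range(1, 13):
            assert spectrum.get(k, 0) == int((sums == k).sum())
        assert no_carrier == int((sums == 0).sum())
        # mass balance
        assert sum(spectrum.values()) + no_carrier == 120
        for j, s in enumerate(strains):
            assert unique[s] == int(((sums == 1) & (pres[:, j] == 1)).sum())


class TestPerfectAssociationScan:
    def make_matrix(self):
        strains = [f"st{j}" for j in range(35)]
        pres = np.zeros((4, 35), dtype=int)
        pres[0, 0] = 1                      # case-unique
        pres[1, :] = 1                      # universal
        pres[2, 1] = 1                      # unique to a control strain
        pres[3, [0, 5]] = 1                 # case + one control
        ids = ["hit", "universal", "control_unique", "near_miss"]
        impact = {"hit": "high", "universal": "modifier",
                  "control_unique": "high", "near_miss": "high"}
        return sv.GenotypeMatrix.from_arrays(ids, strains, pres, impact), strains

    def test_exact_pattern_recovered(self):
        m, strains = self.make_matrix()
        pheno = pd.Series([1] + [0] * 34, index=strains)
        assert sv.perfect_association_scan(m, pheno) == ["hit"]
        assert sv.perfect_association_scan(m, pheno, impact_filter="high") == ["hit"]

    def test_empty_phenotype_warns_and_is_empty(self):
        m, strains = self.make_matrix()
        with pytest.warns(UserWarning):
            hits = sv.perfect_association_scan(m, pd.Series(0, index=strains))
        assert hits == []

    def test_complement_flag(self):
        m, strains = self.make_matrix()
        pheno = pd.Series([0] * 35, index=strains)
        pheno.iloc[1:] = 0
        pheno = pd.Series([0 if j == 1 else 1 for j in range(35)], index=strains)
        hits = sv.perfect_association_scan(m, pheno, include_complement=True)
        assert hits == ["control_unique"]

    def test_invariant_under_strain_permutation(self):
        m, strains = self.make_matrix()
        pheno = pd.Series([1] + [0] * 34, index=strains)
        rng = np.random.default_rng(65)
        perm = list(rng.permutation(35))
        m2 = sv.GenotypeMatrix(m.presence.iloc[:, perm], m.impact)
        assert sv.perfect_association_scan(m2, pheno[m2.strains]) == ["hit"]

    def test_matches_brute_force_row_comparison(self):
        rng = np.random.default_rng(66)
        pres = rng.integers(0, 2, size=(100, 10))
        ids = [f"sv{i}" for i in range(100)]
        strains = [f"st{j}" for j in range(10)]
        m = sv.GenotypeMatrix.from_arrays(ids, strains, pres)
        pheno = pd.Series(rng.integers(0, 2, size=10), index=strains)
        if pheno.sum() == 0:
            pheno.iloc[0] = 1
        hits = sv.perfect_association_scan(m, pheno)
        want = [ids[i] for i in range(100)
                if (pres[i] == pheno.to_numpy()).all()]
        assert hits == want

    def test_missing_strain_rejected(self):
        m, strains = self.make_matrix()
        with pytest.raises(ValueError, match="length|missing"):
            sv.perfect_association_scan(m, pd.Series([1, 0], index=strains[:2]))


class TestGenotypeMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        m = sv.GenotypeMatrix.from_arrays(
            ["sv1", "sv2"], ["s1", "s2"], [[1, 0], [0, 1]],
            impact={"sv1": "high", "sv2": "modifier"})
        m.to_tsv(tmp_path / "m.tsv")
        back = sv.GenotypeMatrix.from_tsv(tmp_path / "m.tsv")
        assert back.presence.equals(m.presence)
        assert list(back.impact) == ["high", "modifier"]

    def test_non_binary_entries_rejected(self):
        with pytest.raises(ValueError):
            sv.GenotypeMatrix.from_arrays(["sv1"], ["s1"], [[2]])


def test_build_genotype_matrix_links_strains():
    recs = {
        "s1": sv.CallSet("consensus", "s1",
                         [del_rec(1000).copy(sample="s1"),
                          del_rec(50_000).copy(sample="s1")]),
        "s2": sv.CallSet("consensus", "s2",
                         [del_rec(1010, length=210).copy(sample="s2")]),
    }
    m = sv.build_genotype_matrix(recs)
    assert m.strains == ["s1", "s2"]
    rows = {rid: list(m.presence.loc[rid]) for rid in m.sv_ids}
    assert rows["chr1-1001-DEL-200"] == [1, 1]
    assert rows["chr1-50001-DEL-200"] == [1, 0]
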