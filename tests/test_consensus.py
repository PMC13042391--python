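import numpy as np
import pytest

import strainsv as sv
from strainsv.consensus import DEFAULT_ROUTING, MERGE_PROFILE, RouteRule, group_table
from strainsv.records import VALIDATED, FAILED, NOT_ASSESSABLE


def rec(start, length=200, svtype="DEL", caller="cue", sample="s1",
        validation="unvalidated", chrom="chr1"):
    end = start if svtype == "INS" else start + length
    return sv.SVRecord(chrom=chrom, start=start, end=end, svtype=svtype,
                       svlen=length, genotype="1/1", sample=sample,
                       caller=caller, validation=validation)


def callsets(*groups_of_records, sample="s1"):
    by_caller = {}
    for r in [r for grp in groups_of_records for r in grp]:
        by_caller.setdefault(r.caller, []).append(r)
    return [sv.CallSet(c, sample, rs) for c, rs in sorted(by_caller.items())]


class TestClusterCalls:
    def test_identical_call_three_callers_one_group(self):
        recs = [rec(5000, caller=c) for c in ("cue", "sniffles2", "sawfish")]
        groups = sv.cluster_calls(callsets(recs))
        assert len(groups) == 1
        assert groups[0].callers == {"cue", "sniffles2", "sawfish"}

    def test_distant_calls_stay_separate(self):
        groups = sv.cluster_calls(callsets([rec(1000), rec(3000, caller="sniffles2")]))
        assert len(groups) == 2

    def test_mixed_strains_rejected(self):
        a = sv.CallSet("cue", "s1", [rec(1000)])
        b = sv.CallSet("sniffles2", "s2", [rec(1000, caller="sniffles2", sample="s2")])
        with pytest.raises(ValueError, match="mixed strains"):
            sv.cluster_calls([a, b])

    def test_components_equal_transitive_closure_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            recs = []
            for caller in ("cue", "sniffles2", "sawfish"):
                for _ in range(int(rng.integers(1, 7))):
                    recs.append(rec(int(rng.integers(0, 8000)),
                                    length=int(rng.integers(50, 400)),
                                    caller=caller))
            groups = sv.cluster_calls(callsets(recs))
            # brute-force transitive closure over the records_match graph
            n = len(recs)
            adj = [[sv.records_match(recs[i], recs[j], MERGE_PROFILE)
                    for j in range(n)] for i in range(n)]
            labels = list(range(n))
            changed = True
            while changed:
                changed = False
                for i in range(n):
                    for j in range(n):
                        if adj[i][j] and labels[j] != labels[i]:
                            lo = min(labels[i], labels[j])
                            labels[i] = labels[j] = lo
                            changed = True
            assert len(groups) == len(set(labels))

    def test_within_caller_duplicates_count_once(self):
        recs = [rec(5000), rec(5010), rec(5005, caller="sniffles2")]
        groups = sv.cluster_calls(callsets(recs))
        assert len(groups) == 1
        assert groups[0].callers == {"cue", "sniffles2"}

    def test_representative_is_median_member(self):
        recs = [rec(5000, caller="cue"), rec(5100, caller="sniffles2"),
                rec(5200, caller="sawfish")]
        groups = sv.cluster_calls(callsets(recs))
        assert groups[0].representative.start == 5100


class TestRouting:
    def test_two_of_three_rule_for_deletions(self):
        seen_by_two = [rec(1000, caller="cue"), rec(1000, caller="sniffles2")]
        seen_by_one = [rec(9000, caller="sawfish")]
        groups = sv.cluster_calls(callsets(seen_by_two, seen_by_one))
        final = sv.route_and_select(groups)
        assert [r.start for r in final.records] == [1000]

    def test_large_ins_needs_assembly_caller_and_validation(self):
        ok = rec(1000, length=5000, svtype="INS", caller="dipcall",
                 validation=VALIDATED)
        not_assessed = rec(9000, length=5000, svtype="INS", caller="dipcall",
                           validation=NOT_ASSESSABLE)
        wrong_caller = rec(20_000, length=5000, svtype="INS", caller="sniffles2",
                           validation=VALIDATED)
        groups = sv.cluster_calls(callsets([ok], [not_assessed], [wrong_caller]))
        final = sv.route_and_select(groups)
        assert [r.start for r in final.records] == [1000]

    def test_validation_gate_for_inv_and_dup(self):
        kept = [rec(1000, svtype="INV", caller="cue", validation=VALIDATED),
                rec(5000, svtype="DUP", caller="pbsv", validation=VALIDATED)]
        dropped = [rec(9000, svtype="INV", caller="cue", validation=FAILED),
                   rec(13_000, svtype="DUP", caller="pbsv")]
        groups = sv.cluster_calls(callsets(kept, dropped))
        final = sv.route_and_select(groups)
        assert sorted(r.start for r in final.records) == [1000, 5000]

    def test_no_loss_when_everything_supported_and_validated(self):
        starts = range(1000, 20_000, 2000)
        recs = []
        for s in starts:
            for c in ("cue", "sniffles2", "sawfish"):
                recs.append(rec(s, caller=c, validation=VALIDATED))
        groups = sv.cluster_calls(callsets(recs))
        final = sv.route_and_select(groups)
        assert len(final) == len(groups) == len(list(starts))

    def test_unknown_svtype_stratum_rejected(self):
        groups = sv.cluster_calls(callsets([rec(1000)]))
        with pytest.raises(ValueError, match="no routing rule"):
            sv.route_and_select(groups, routing={})

    def test_removing_a_caller_never_increases_two_support_groups(self):
        rng = np.random.default_rng(55)
        recs = []
        for caller in ("cue", "sniffles2", "sawfish"):
            for _ in range(25):
                recs.append(rec(int(rng.integers(0, 100_000)), caller=caller))
        all_sets = callsets(recs)
        full = sv.route_and_select(sv.cluster_calls(all_sets))
        for drop in range(3):
            reduced = [cs for i, cs in enumerate(all_sets) if i != drop]
            partial = sv.route_and_select(sv.cluster_calls(reduced))
            assert len(partial) <= len(full)

    def test_final_set_restabilises_as_singletons(self):
        recs = [rec(s, caller=c) for s in (1000, 40_000, 80_000)
                for c in ("cue", "sniffles2")]
        final = sv.route_and_select(sv.cluster_calls(callsets(recs)))
        regrouped = sv.cluster_calls([final.with_records(
            [r.copy(caller="consensus") for r in final.records])])
        assert all(len(g.members) == 1 for g in regrouped)

    def test_group_table_accounts_for_every_group(self):
        recs = [rec(1000, caller="cue"), rec(1000, caller="sniffles2"),
                rec(50_000, caller="sawfish")]
        groups = sv.cluster_calls(callsets(recs))
        rows = group_table(groups)
        assert len(rows) == len(groups)
        assert sum(r["kept"] for r in rows) == 1


class TestDupWithinIns:
    def test_flagged_when_both_ends_near_insertion(self):
        dup = rec(1000, length=100, svtype="DUP")
        ins = rec(1050, length=300, svtype="INS")
        flags = sv.dup_within_ins([dup, ins], tolerance=500)
        assert flags == {sv.sv_id(dup): True}

    def test_no_insertions_no_flags(self):
        dup = rec(1000, length=100, svtype="DUP")
        assert sv.dup_within_ins([dup], tolerance=500) == {sv.sv_id(dup): False}

    def test_far_end_prevents_flag(self):
        dup = rec(1000, length=5000, svtype="DUP")
        ins = rec(1100, length=50, svtype="INS")
        assert sv.dup_within_ins([dup, ins], tolerance=500) == {sv.sv_id(dup): False}

    def test_flag_count_monotone_in_tolerance(self):
        rng = np.random.default_rng(77)
        recs = [rec(int(rng.integers(0, 50_000)),
                    length=int(rng.integers(50, 800)),
                    svtype=("DUP" if rng.random() < 0.5 else "INS"))
                for _ in range(60)]
        counts = []
        for tol in (10, 100, 1000, 10_000):
            flags = sv.dup_within_ins(recs, tolerance=tol)
            counts.append(sum(flags.values()))
        assert counts == sorted(counts)
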