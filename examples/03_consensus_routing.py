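"""Merge three callers' calls for one strain and route them to a final set.

Deletions need two of the designated caller trio; duplications need a
designated caller plus read-based validation.  The example also flags a
duplication that sits inside a called insertion.
"""

import strainsv as sv
from strainsv.records import VALIDATED


def rec(start, svtype="DEL", caller="cue", length=300, validation="unvalidated"):
    end = start if svtype == "INS" else start + length
    return sv.SVRecord(chrom="chr1", start=start, end=end, svtype=svtype,
                       svlen=length, genotype="1/1", sample="STR01",
                       caller=caller, validation=validation)


callsets = [
    sv.CallSet("cue", "STR01", [
        rec(10_000), rec(50_000),
        rec(90_000, svtype="DUP", validation=VALIDATED)]),
    sv.CallSet("sniffles2", "STR01", [
        rec(10_004, caller="sniffles2"),   # same deletion, 4 bp off
        rec(90_020, svtype="INS", caller="sniffles2")]),  # DUP emitted as INS
    sv.CallSet("sawfish", "STR01", [
        rec(10_002, caller="sawfish"),
        rec(90_010, svtype="INS", caller="sawfish")]),
]

groups = sv.cluster_calls(callsets)
final = sv.route_and_select(groups)
print(f"{sum(len(c) for c in callsets)} calls -> {len(groups)} groups "
      f"-> {len(final)} kept")
for r in final.records:
    print(f"  kept {sv.sv_id(r)}")
flags = sv.dup_within_ins(final, tolerance=1000)
print("dup-within-INS flags:", flags)
# The 10 kb deletion is kept (3 callers agree); the 50 kb one is dropped
# (single caller).  The validated duplication survives the DUP route, and
# the two INS relabellings survive the small-INS route -- the within-INS
# flag then marks the duplication as living inside that insertion call.
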