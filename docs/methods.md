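# Methods

## Coordinate and record model

All interval arithmetic uses 0-based, half-open coordinates; VCF I/O
converts to/from 1-based inclusive positions at the boundary and BED is
consumed natively.  Under this convention `end − start == svlen` for
DEL/INV/DUP.  An insertion's reference footprint is a point (`end ==
start`); for overlap computations it is treated as 1 bp.  SVLEN is stored as
a non-negative magnitude — the negative deletion lengths many callers emit
are normalised on read — because the variant identifier format
(`chrom-start-type-length`, with a 1-based start) uses positive lengths.
BND records are parsed but carry no length; they exist only to be removed by
the SV filters.  Missing numeric annotations are represented as `None`,
never 0, so "the caller does not report this field" is distinguishable from
"the field is zero".

## Matching and evaluation

Two records represent the same variant when they share a chromosome, their
types are compatible, and |Δstart|, |Δend| and |Δlen| are each *strictly*
below the profile's tolerances.  Strict inequality follows the comparison
rule's wording ("differ by less than 50 bp"); the 50/50/50 `comparison`
profile is used for cross-dataset work.  Because an insertion's end equals
its start, the end-offset check for any pair involving an INS reduces to the
start-offset check — without this, a duplication relabelled as an insertion
by a caller could never match under the type-ignoring mode, which exists
precisely for that failure.

Three evaluation presets ship as `default` (500/500/500 bp), `stringent`
(100/100/50) and `relaxed` (1000/1000/1000).  These numeric settings are
this package's own documented defaults — chosen to bracket common practice
in long-read SV benchmarking — and are fully overridable; nothing downstream
depends on their exact values, and the evaluation sweep exists exactly to
show how results move across them.

Call-to-truth assignment is a maximum-cardinality one-to-one bipartite
matching, so the TP count is well defined rather than an artefact of greedy
ordering.  Candidate pairs are enumerated with a sorted sweep over start
positions (only pairs within the start tolerance are inspected), the
candidate graph is split into connected components, and each component is
solved with `scipy.optimize.linear_sum_assignment` on a cost matrix whose
real edges cost |Δstart| + |Δend| and whose non-edges carry a big-M penalty
exceeding the total real cost.  This yields, deterministically, the maximum
matching with the smallest total breakpoint distance.  An exhaustive
enumeration oracle in the test-suite confirms optimality on random instances
with ≤8 records per side.

Each matched pair is assigned to the (type, size-bin) stratum of its *truth*
record — the truth defines the experiment — while unmatched calls use their
own length.  Size bins default to small = 50–1000 bp and large above
(simulation plans cap at 100 kb in examples; the hard filter caps at
500 kb).  Degenerate denominators yield 0 (empty calls ⇒ P = R = F1 = 0).

## Simulation

Truth sets are haploid with genotype "1/1" throughout: inbred strains are
homozygous, and the small-variant filter's genotype rule assumes exactly
that.  Planted SVs are mutually non-overlapping with a configurable minimum
reference gap (default 100 bp) and never cross a chromosome end; placement
is uniform at random (chromosomes weighted by length) with rejection
sampling capped at 10·n retries before a placement error reports how many
were placed.  Whether real simulated SVs may abut or nest is not specified
anywhere authoritative; non-overlap keeps sequence editing and the length
ledger exact.

Sequence editing: DEL removes the span, INS inserts its (seeded,
uniform-random) sequence at the point, INV reverse-complements the span in
place, DUP appends one extra tandem copy — the minimal duplication model,
since no copy number is specified by the protocol this emulates.  Two exact
invariants follow and are tested: `len(mutated) = len(ref) − ΣDEL + ΣINS +
ΣDUP`, and applying the same INV set twice restores the sequence
byte-for-byte.  A coordinate map converts reference to mutated coordinates
outside edited spans and refuses positions inside one.

The caller-error model operates at the *call* level: each truth record is
dropped with `miss_rate`, survivors receive Gaussian breakpoint and length
jitter (rounded, clamped to the chromosome), Poisson(`fp_rate` ·
genome_Mb) false calls of the truth's types are scattered uniformly, and
DUPs are relabelled INS with `mistype_rate`.  Read-level simulation and
alignment are deliberately not reproduced; the model emulates the *effect*
of an imperfect caller on a call set, which is what the evaluation and
consensus machinery consume.  Consequences: error processes are independent
per record (no locus-specific hardness, no repeat-context correlation), all
callers see the same truth, and validation scores are synthetic.  Passing
tests therefore demonstrate the correctness of the harness arithmetic and
routing logic under known error rates — not caller performance on real
sequencing data.

## Filters

Rule order is fixed (chromosome, FILTER, svtype, svlen, QUAL, SUPPORT, DP,
GQ, genotype) and each dropped record carries the *first* failing rule, so
drop reports are reproducible.  The two rule sets are deliberately
asymmetric, exactly as specified by the protocol being modelled: small
variants exclude QUAL *below* 30 (keep ≥ 30) while SVs require QUAL
*greater than* 30; small variants keep only genotype "1/1" while SV
filtering removes only "0/0".  A rule with a `None` threshold is disabled —
per-caller presets use this for tools that lack a field (no QUAL rule for
the depth-filtered caller; SUPPORT only where reported).  When a rule *is*
enabled and a record lacks the field, the record is dropped with that rule's
reason: an unverifiable quality claim is treated as a failed one.
Validation thresholding is inclusive (GS ≥ 0.15 and QS ≥ 0.1 ⇒ validated);
assessable-but-below ⇒ failed; non-assessable ⇒ not_assessable; unscored
records stay unvalidated.

## Consensus

Clustering links records across callers by the match predicate under a
merge profile of 1 kb on both breakpoints, same type required, no length
constraint — the conventional default of widely used SV-merging tools, since
the exact merge parameters of the modelled pipeline are unpublished;
configurable.  Groups are connected components; within-caller duplicates
share a group but count once toward caller support.  The representative is
the member with the median start (lower median; ties broken by caller name),
giving a deterministic, central breakpoint.

Routing, per (type, size-bin): deletions ≥2 of {cue, sniffles2, sawfish};
small insertions both of {sniffles2, sawfish}; large insertions {dipcall}
plus validation; inversions any of {cue, sniffles2, pbsv} plus validation;
duplications {cue, pbsv} plus validation.  The validation gate also stands
in for the manual visual review inversions receive in practice — a
repository cannot look at read pileups, so the flag is the programmatic
equivalent.  A group counts as validated when any member passed validation.
The duplication-within-insertion check flags a DUP when both its breakpoints
lie within a tolerance (default 1 kb) of a single insertion's point of
insertion; since an insertion's reference footprint is a point, "within"
can only mean proximity, and the tolerance is explicit for that reason.

## Comparison, sharing and association

Cross-dataset comparison runs per SV type under the strict <50 bp rule with
one-to-one matching, so an SV in one dataset certifies at most one SV in the
other as shared and Venn totals never double-count.  Type equality is
enforced by default (the DUP/INS type-ignoring mode is available as a
flag).  SNP-style comparison is exact set intersection over canonical id
strings; duplicate ids are an error naming the offender.

The genotype matrix is binary SV × strain presence.  The sharing spectrum
counts SVs by carrier number k ≥ 1; all-zero rows are excluded and reported
separately.  The perfect-association scan returns SVs whose presence row
equals the phenotype vector exactly — the zero-discordance pattern ("effect
size 1, p-value 0") — optionally extended to complement rows (protective
alleles) behind a flag that is off by default, because the scan's purpose is
variants present only in affected strains.  Cross-strain matrix
construction from per-strain final call sets links records with the
comparison profile and uses each cluster's earliest member's id as the row
id.

## Annotation

Motif scanning compiles the full IUPAC alphabet to a lookahead regex (so
overlapping occurrences are all reported) and scans the forward sequence
with both the motif and its reverse-complement pattern; minus-strand hits
store the motif-oriented sequence.  Peak support keeps peaks with signal ≥
50 (inclusive) and −log10 q > 3 (strict), both per the thresholds' wording,
and a site is supported when ≥50% of its length overlaps a single surviving
peak.  TE association computes overlapped bases on the *union* of TE
intervals clipped to the deletion span — repeat annotations overlap each
other, and a fraction must stay ≤ 1 — with the ≥60% boundary inclusive.
Fraction comparisons are done in ratio form (`covered/len ≥ frac`) so
inclusive boundaries are exact in floating point.

## Fixture bundle and problem sizes

The default bundle models a 35-strain panel on a 1 Mb two-chromosome toy
genome: a pool of 97 SVs (40 small + 8 large deletions, 30 small
insertions, 8 inversions, 10 duplications, plus one planted 1641 bp
deletion carried only by the case strain).  Deletion/insertion carrier
counts follow a geometric distribution concentrated on 1–3 strains,
mirroring the sharing spectra seen in real panels; inversions and
duplications are shared more broadly so every route receives traffic.
Strain-unique background SVs are assigned only to non-case strains, making
the planted deletion the case strain's only unique variant — that is the
construction the association-recovery checks rely on.  Per-caller error
models differ (miss 4–8%, jitter 6–10 bp, 0.4–0.8 FP/Mb) and the two
heuristic callers relabel duplications as insertions, which exercises both
the validation-gated duplication route and the within-insertion flag.
Validation scores validate ~85% of calls near a true DUP/INV and fail or
decline to assess most false positives.

Test and acceptance runs use a 20 Mb single-chromosome genome with 1000 SVs
per type for the conservation and parameter-recovery checks, and 200
random ≤8×8 instances for the matching oracle; these sizes keep each check
in seconds while leaving the binomial error bars (3 SDs at n = 1000 ≈
±0.038 on recall) tight enough to detect real defects.

## Known limitations

- Call-level corruption cannot expose alignment- or assembly-specific
  failure modes; conclusions about real callers require real call sets.
- Haploid truth only; heterozygous and mosaic SVs are out of scope.
- No nested or overlapping SV generation.
- Sequence-similarity and genotype-aware matching are not implemented;
  matching is purely positional.
- The genome-build liftOver step real annotation work needs is out of
  scope; all fixtures live on one build.
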