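# strainsv

Structural-variant (SV) simulation, benchmarking, multi-caller consensus and
strain-association analysis for inbred-strain panels.

## The problem

Building an SV database across dozens of inbred mouse strains from long-read
sequencing requires a chain of computational decisions that are easy to get
subtly wrong: when do two SV calls from different tools represent the *same*
variant, how should calls from several imperfect callers be combined into one
trustworthy per-strain call set, which hard filters remove unreliable calls,
and how can a case-unique variant be pinned to a binary phenotype across a
strain panel.  `strainsv` implements that chain as a tested, reusable Python
library:

- **Truth-set simulation** — plant non-overlapping DEL/INS/INV/DUP of
  controlled size into a reference (`plan_svs`, `apply_svs`) and corrupt the
  truth with a parametric caller-error model (`corrupt_calls`: miss rate,
  false calls per Mb, Gaussian breakpoint/length jitter, DUP→INS
  relabelling), so the whole evaluation harness is testable without running
  any external caller.
- **Tolerance-based matching & evaluation** — two records match when
  |Δstart|, |Δend| and |Δlen| are each strictly below the profile's
  tolerances and the types are compatible.  Call-to-truth assignment is a
  *maximum-cardinality one-to-one bipartite matching* (min total breakpoint
  distance among maxima), from which precision `TP/(TP+FP)`, recall
  `TP/(TP+FN)` and `F1 = 2PR/(P+R)` are reported per SV type and size bin
  (small 50–1000 bp, large above).
- **Hard filters** — small variants: autosomes+chrX, FILTER=PASS, QUAL ≥ 30,
  DP ≥ 10, GQ ≥ 30, genotype 1/1, biallelic only; SVs: QUAL > 30 (where the
  caller provides it), per-caller SUPPORT/DP/GQ rules, 50 bp ≤ SVLEN ≤
  500 kb, no BND, no 0/0.  Every dropped record carries the first failing
  rule.
- **Validation thresholding** — read-based validation scores accept a call
  at GS ≥ 0.15 and QS ≥ 0.1 (inclusive).
- **Consensus routing** — calls from multiple callers on one strain are
  clustered (1 kb tolerance, same type) and each cluster is routed by
  type/size: deletions need ≥2 of the designated trio, small insertions both
  of their two reliable callers, large insertions the assembly-based caller
  plus validation, inversions and duplications a designated caller plus
  validation.  Duplications sitting inside a called insertion are flagged.
- **Dataset comparison & association** — cross-dataset sharing under the
  strict <50 bp rule (per type, one-to-one), exact id-based SNP comparison,
  allele-sharing spectra, per-strain strain-unique counts, and a
  perfect-association scan returning SVs whose presence/absence row equals a
  binary phenotype exactly (zero discordant strains).
- **Annotation** — IUPAC motif scanning on both strands (e.g. the CTCF
  recognition sequence `CCGCGNGGNGGCAG`), ChIP-seq peak support (≥50%
  overlap with peaks of signal ≥ 50 and −log10 q > 3), motif containment in
  deletions, and transposable-element association (≥60% of the deletion span
  covered by the TE interval union).

A seeded fixture generator (`make_fixtures`) emits everything the pipeline
consumes — toy genome, per-strain truth VCFs, three corrupted per-caller
call sets per strain, validation scores, TE BED, narrowPeak file, genotype
matrix with a planted case-unique 1641 bp deletion, phenotype table — so no
external data is ever needed.

## Worked example

`examples/05_association_scan.py` builds the 35-strain fixture bundle and
scans for SVs perfectly associated with the phenotype:

```
strains sharing an SV -> number of SVs:
  1: 43
  2: 16
  3: 11
  4: 7
  5: 1
strain-unique SVs in STR01: 1
perfect-association hits: ['chr1-389172-DEL-1641']
planted deletion:         chr1-389172-DEL-1641
```

Most SV alleles are shared by only 1–3 strains (the head of the sharing
spectrum), the case strain carries exactly one strain-unique SV, and the
scan returns exactly the planted 1641 bp deletion — the only presence row
with zero discordance against the phenotype.  Running the full pipeline
(`examples/07_full_pipeline.py`) recovers the same deletion from the
*corrupted caller calls* after filtering, consensus routing and cross-strain
matrix construction:

```
final SV totals by type: {'DEL': 93, 'INV': 61, 'INS': 81, 'DUP': 61}
SVs in cross-strain matrix: 97
association hits: ['chr1-389159-DEL-1643']
planted deletion:  chr1-389172-DEL-1641
```

The hit's coordinates differ from the truth by a few bases because it is the
consensus representative of breakpoint-jittered calls — well inside the
50 bp comparison tolerance.

The `strainsv` console script exposes the same operations as subcommands
(`fixtures`, `simulate`, `corrupt`, `filter`, `evaluate`, `merge`,
`compare`, `assoc`, `annotate`, `run`); each example script in `examples/`
demonstrates one capability from Python.

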