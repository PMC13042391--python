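"""Motif scanning, ChIP-peak support and TE association of deletions.

Scans a small sequence for the degenerate CTCF recognition sequence
CCGCGNGGNGGCAG on both strands, checks which hits are supported by a
qualifying ChIP-seq peak (>=50% overlap, signal >=50, -log10 q > 3), and
flags a deletion that removes >=60% TE sequence.
"""

import strainsv as sv
from strainsv.fixtures import CTCF_MOTIF
from strainsv.simulate import random_sequence, reverse_complement

import numpy as np

rng = np.random.default_rng(4)
seq = random_sequence(2000, rng)
site_fwd = "CCGCGAGGTGGCAG"                     # one realisation of the motif
seq = seq[:500] + site_fwd + seq[514:]
seq = seq[:1200] + reverse_complement(site_fwd) + seq[1214:]
genome = {"chr1": seq}

hits = sv.scan_motif(genome, CTCF_MOTIF)
print(f"{len(hits)} motif hits:")
for h in hits:
    print(f"  {h.chrom}:{h.start}-{h.end} strand={h.strand} seq={h.matched_seq}")

peaks = [sv.Peak("chr1", 450, 600, signal_value=80.0, neg_log10_q=6.0),
         sv.Peak("chr1", 1150, 1300, signal_value=49.9, neg_log10_q=6.0)]
for h, (supported, n) in zip(hits, sv.peak_support(hits, peaks)):
    print(f"  {h.chrom}:{h.start} supported={supported} peaks={n}")

deletion = sv.SVRecord(chrom="chr1", start=480, end=580, svtype="DEL", svlen=100)
contained = sv.dels_with_motif([deletion], hits)
te_flags, frac = sv.te_association([deletion], [("chr1", 480, 545)])
print(f"motifs inside deletion: {contained}")
print(f"TE-associated: {te_flags} (dataset fraction {frac:.2f})")
# Both strands are found; only the forward site is peak-supported because
# the second peak's signal (49.9) misses the inclusive >=50 cutoff.  The
# deletion contains the forward motif and 65% of it is TE sequence, so it
# counts as TE-associated.
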