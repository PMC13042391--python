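"""Plant a truth set, corrupt it with a caller-error model, and benchmark.

Plants 1000 small deletions into a 5 Mb toy genome, simulates a caller that
misses 20% of them, adds one false call per Mb and jitters breakpoints by
10 bp, then scores the calls under three tolerance profiles.
"""

import numpy as np

import strainsv as sv
from strainsv.simulate import random_sequence

genome = {"chr1": random_sequence(5_000_000, np.random.default_rng(0))}

truth = sv.plan_svs(genome, sv.SimPlan(n_svs=1000, svtype="DEL",
                                       size_min=50, size_max=1000, seed=1))
model = sv.CallerErrorModel(miss_rate=0.2, fp_rate=1.0, jitter_sd=10.0, seed=2)
calls = sv.corrupt_calls(truth, model, genome_size=5_000_000)

sweep = sv.sweep_profiles(calls, truth,
                          [sv.STRINGENT_PROFILE, sv.DEFAULT_PROFILE,
                           sv.RELAXED_PROFILE])
print("profile     P       R       F1")
for name, results in sweep.items():
    overall = results[-1]
    print(f"{name:<10}  {overall.precision:.3f}   {overall.recall:.3f}   "
          f"{overall.f1:.3f}")
# Recall sits near 1 - miss_rate = 0.8; precision is diluted only by the
# ~5 false calls the error model scattered over 5 Mb.  With 10 bp jitter all
# three tolerance profiles agree, mirroring how robust tolerance-based
# benchmarking is to the exact breakpoint-stringency setting.
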