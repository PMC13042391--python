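import numpy as np
import pytest

import strainsv as sv
from strainsv.simulate import random_sequence


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(424242)
    return {"chr1": random_sequence(300_000, rng),
            "chr2": random_sequence(120_000, rng)}


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default fixture bundle: 35 strains, 1 Mb toy genome, seed 11."""
    out = tmp_path_factory.mktemp("bundle") / "fixtures"
    return sv.make_fixtures(seed=11, out_dir=out)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline") / "out"
    config = sv.PipelineConfig(bundle_dir=str(bundle.root), out_dir=str(out))
    summary = sv.run_pipeline(config)
    return config, summary


def brute_force_max_matching(calls, truth, profile) -> int:
    """Exhaustive maximum-cardinality one-to-one matching (oracle)."""
    edges = [[j for j, t in enumerate(truth) if sv.records_match(c, t, profile)]
             for c in calls]

    best = 0

    def extend(i: int, used: frozenset, size: int) -> None:
        nonlocal best
        if size + (len(calls) - i) <= best:
            return
        if i == len(calls):
            best = max(best, size)
            return
        extend(i + 1, used, size)
        for j in edges[i]:
            if j not in used:
                extend(i + 1, used | {j}, size + 1)

    extend(0, frozenset(), 0)
    return best


def random_records(rng, n, chrom="chr1", span=2000, svtype="DEL", max_len=400):
    """Dense random SVs for small matching instances."""
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(50, max_len))
        if svtype == "INS":
            out.append(sv.SVRecord(chrom=chrom, start=start, end=start,
                                   svtype="INS", svlen=length))
        else:
            out.append(sv.SVRecord(chrom=chrom, start=start, end=start + length,
                                   svtype=svtype, svlen=length))
    return out
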