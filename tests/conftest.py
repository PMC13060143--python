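import numpy as np
import pandas as pd
import pytest

from regscreen.core import FragmentSet, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_genome():
    from regscreen.simulate import simulate_genome

    return simulate_genome(20_000, gc=0.45, seed=3)


@pytest.fixture
def toy_fragments():
    rows = [
        ("chr1", 100, 400, "a", "rep1"),
        ("chr1", 150, 500, "a", "rep1"),
        ("chr1", 300, 450, "b", "rep1"),
        ("chr2", 0, 200, "b", "rep1"),
    ]
    return FragmentSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "replicate"])
    )


@pytest.fixture
def toy_library():
    rng = np.random.default_rng(0)
    protos = []
    while len(protos) < 200:
        p = "".join(rng.choice(list("ACGT"), size=20))
        if p not in protos:
            protos.append(p)
    return pd.DataFrame(
        {
            "protospacer": protos,
            "region_id": [f"region{i // 10}" for i in range(200)],
        }
    )


def interval(chrom="chr1", start=0, end=100, strand="."):
    return GenomicInterval(chrom, start, end, strand)
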