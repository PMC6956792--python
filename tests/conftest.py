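import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ppcoal as pc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def symmetric4():
    return pc.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def reference_tree():
    return pc.reference_species_tree(100_000.0)


@pytest.fixture
def two_species_matrix():
    """4+4 haploids, 3 loci: fixed difference, shared polymorphism, private."""
    sm = pc.SampleMap(
        {f"A_{i}": "A" for i in range(4)} | {f"B_{i}": "B" for i in range(4)}
    )
    geno = np.array(
        [
            [1, 1, 0],
            [1, 0, 0],
            [1, 1, 1],
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 0],
            [0, 1, 0],
            [0, 0, 0],
        ],
        dtype=np.int8,
    )
    inds = [f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)]
    return pc.SNPMatrix(geno, inds, sm)


def random_ultrametric_tree(labels, rng):
    """Random coalescent-style rooted ultrametric tree over ``labels``."""
    heights = {lab: 0.0 for lab in labels}
    newick = {lab: lab for lab in labels}
    height = 0.0
    live = list(labels)
    while len(live) > 1:
        height += float(rng.exponential(1.0)) + 1e-3
        i, j = sorted(rng.choice(len(live), size=2, replace=False))
        a, b = live[i], live[j]
        la = height - heights[a]
        lb = height - heights[b]
        merged = f"({newick[a]}:{la!r},{newick[b]}:{lb!r})"
        key = a + b
        newick[key] = merged
        heights[key] = height
        live = [x for k, x in enumerate(live) if k not in (i, j)] + [key]
    return pc.parse_newick(newick[live[0]] + ";")
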