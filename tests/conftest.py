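import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

import splicewalk as sw


@pytest.fixture
def toy_multigraph():
    """Two lncRNAs and two AS genes with all three layer types."""
    nodes = [
        sw.NodeMeta("L1", "lncRNA"),
        sw.NodeMeta("L2", "lncRNA"),
        sw.NodeMeta("G1", "AS_gene"),
        sw.NodeMeta("G2", "AS_gene"),
    ]
    layers = [
        sw.Layer("coexpression", {("G1", "L1"): 1.0, ("G2", "L2"): 1.0}),
        sw.Layer("epigenetic", {("G1", "L1"): 1.0}),
        sw.Layer("ppi", {("G1", "G2"): 1.0}),
    ]
    return sw.build_multigraph(layers, nodes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_transcript_pair(rng, n_exons=None):
    """A random exon structure (and a copy) for identity-type tests."""
    n = int(n_exons or rng.integers(1, 8))
    starts = np.cumsum(rng.integers(50, 300, size=2 * n))
    exons = tuple(
        ("chr1", int(starts[2 * i]), int(starts[2 * i + 1])) for i in range(n)
    )
    strand = "+" if rng.random() < 0.5 else "-"
    return sw.IsoformAnnotation("iso", "g", strand, exons)
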