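import numpy as np
import pytest

from hgbench.dyngraph import (
    ConceptNode,
    EdgeObservation,
    build_dynamic_graph,
)
from hgbench.synthdata import (
    SynthConfig,
    generate_citation_graph,
    generate_dynamic_graph,
)


def make_nodes(*ids, semantic_type="T0", dim=None, rng=None):
    out = []
    for i, nid in enumerate(ids):
        feats = None
        if dim is not None:
            vec = rng.normal(size=dim) if rng is not None else np.arange(dim) + i
            feats = tuple(float(x) for x in vec)
        out.append(ConceptNode(nid, semantic_type, feats))
    return out


@pytest.fixture
def toy_graph():
    """Path a-b-c growing over three years with repeat mentions."""
    nodes = make_nodes("a", "b", "c", "d")
    obs = [
        EdgeObservation("a", "b", 2010, "d1"),
        EdgeObservation("b", "c", 2011, "d2"),
        EdgeObservation("a", "b", 2012, "d3"),
        EdgeObservation("a", "c", 2012, "d4"),
    ]
    return build_dynamic_graph(obs, nodes)


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic world shared by tests that only need plausible data."""
    cfg = SynthConfig(
        n_nodes=200,
        n_types=3,
        type_proportions=(0.5, 0.3, 0.2),
        years=(2000, 2005),
        edges_per_year=60,
        feature_dim=8,
        seed=7,
    )
    graph, catalysts = generate_dynamic_graph(cfg)
    citations = generate_citation_graph(graph, cfg, catalysts)
    return cfg, graph, catalysts, citations
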