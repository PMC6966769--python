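import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from coregnet.config import PipelineConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def toy_cycle_graph():
    """A small TF graph with three directed cycles: one 2-cycle plus two
    larger cycles sharing a two-arc path, so that exactly two arc removals
    (one from the 2-cycle, one from the shared path) break every cycle."""
    g = nx.DiGraph()
    for n in "XYPQRS":
        g.add_node(n, kind="tf")
    g.add_edges_from(
        [("X", "Y"), ("Y", "X"),
         ("P", "Q"), ("Q", "R"), ("R", "P"), ("R", "S"), ("S", "P")]
    )
    return g


def random_weighted_digraph(seed, n_lo=4, n_hi=9, p_edge=0.3, w_hi=9):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p_edge:
                g.add_edge(u, v, weight=int(rng.integers(1, w_hi)))
    return g
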