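import itertools

import networkx as nx
import numpy as np
import pytest

from mitofln import canonical_pair, make_gold_standard, make_world
from mitofln.netcore import GoldStandardPairs


def all_pairs(genes):
    return [canonical_pair(a, b) for a, b in itertools.combinations(sorted(genes), 2)]


def random_weighted_graph(n=20, p=0.3, seed=0):
    """Connected-ish ER graph with positive random weights."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    relabel = {i: f"N{i:03d}" for i in g.nodes}
    g = nx.relabel_nodes(g, relabel)
    for a, b in g.edges:
        g[a][b]["weight"] = float(rng.lognormal(0.0, 0.5))
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


@pytest.fixture
def small_world():
    return make_world(n_mito=30, n_nonmito=10, n_pathways=5,
                      pathway_size_range=(3, 6), seed=11)


@pytest.fixture
def small_gold(small_world):
    return make_gold_standard(small_world)


def gold_from_pathways(pathways):
    """Brute-force gold standard oracle: double loop over annotated genes."""
    membership = {}
    for pid, members in pathways.items():
        for m in members:
            membership.setdefault(m, set()).add(pid)
    genes = sorted(membership)
    pos, neg = set(), set()
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if membership[a] & membership[b]:
                pos.add(canonical_pair(a, b))
            else:
                neg.add(canonical_pair(a, b))
    return GoldStandardPairs(frozenset(pos), frozenset(neg))
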