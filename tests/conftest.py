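"""Shared fixtures: canonical toy graphs and a seeded synthetic world."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netcoherence import GeneSet, build_world
from netcoherence.types import DegreeTable


def make_table(pairs, set_id="t"):
    """DegreeTable from [(k_int, k_ext), ...] with synthetic gene names."""
    rows = [(f"g{i}", ki, ke) for i, (ki, ke) in enumerate(pairs)]
    return DegreeTable(set_id=set_id, table=pd.DataFrame(rows, columns=["gene", "k_int", "k_ext"]))


@pytest.fixture
def ring10():
    return nx.relabel_nodes(nx.cycle_graph(10), {i: f"R{i}" for i in range(10)})


@pytest.fixture
def k10():
    return nx.relabel_nodes(nx.complete_graph(10), {i: f"K{i}" for i in range(10)})


@pytest.fixture
def k20():
    return nx.relabel_nodes(nx.complete_graph(20), {i: f"L{i}" for i in range(20)})


@pytest.fixture(scope="session")
def world1():
    """Default desk-scale synthetic world, fixed seed, shared read-only."""
    return build_world(seed=1)


def brute_force_degrees(graph: nx.Graph, genes: set[str]) -> dict[str, tuple[int, int]]:
    """Independent k_int/k_ext oracle: explicit edge enumeration."""
    members = {g for g in genes if g in graph}
    out = {}
    for g in members:
        k_int = sum(
            1 for u, v in graph.edges if (u == g and v in members) or (v == g and u in members)
        )
        k_ext = sum(
            1 for u, v in graph.edges if (u == g and v not in members) or (v == g and u not in members)
        )
        out[g] = (k_int, k_ext)
    return out


def set_partitions(items):
    """All partitions of a list (Bell-number many; keep len(items) <= 8)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1 :]
        yield [[first]] + partition


def brute_force_modularity(graph: nx.Graph) -> float:
    """Exhaustive maximum modularity over all node partitions."""
    best = -np.inf
    for partition in set_partitions(list(graph.nodes)):
        q = nx.community.modularity(graph, [set(b) for b in partition])
        best = max(best, q)
    return best


def geneset(set_id, genes, category="test"):
    return GeneSet(set_id, category, frozenset(genes))
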