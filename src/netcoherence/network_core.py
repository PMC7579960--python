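"""Global interactome construction and internal/external degree tables.

The interactome is a simple undirected :class:`networkx.Graph` over gene
symbols. For a phenotype gene set S, each member gene g present in the
network gets an internal degree k_int(g) (neighbors inside S) and an
external degree k_ext(g) (neighbors outside S); by construction
k_int + k_ext equals g's global degree. Eligibility filters reject sets
with too few non-zero interacting genes or with no internal-degree
variation, which would make the slope fit meaningless.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .types import DegreeTable, EdgeRecord, EligibilityReport, GeneSet

logger = logging.getLogger(__name__)

#: Paper-default minimum count of genes with at least one in-set interaction.
DEFAULT_MIN_NONZERO = 10


def build_global_network(edges: Iterable[EdgeRecord]) -> nx.Graph:
    """Build the global PPI graph from an edge list.

    Self-loops and duplicate undirected edges collapse silently; the node
    set is the union of edge endpoints. An empty edge list is an error —
    a degree universe with no interactions is meaningless.
    """
    graph = nx.Graph()
    for rec in edges:
        if rec.gene_a != rec.gene_b:
            graph.add_edge(rec.gene_a, rec.gene_b)
    if graph.number_of_edges() == 0:
        raise ValueError("cannot build a global network from an empty edge list")
    return graph


def compute_degrees(network: nx.Graph, gene_set: GeneSet) -> DegreeTable:
    """Internal/external degree table of ``gene_set`` within ``network``.

    Genes of the set absent from the network (no PPI annotation) are
    dropped with a logged count. Genes with k_int = 0 but k_ext > 0 are
    kept: they contribute external-degree information.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    members = frozenset(gene_set.genes) & frozenset(network.nodes)
    n_dropped = len(gene_set.genes) - len(members)
    if n_dropped:
        logger.debug("%s: %d/%d genes have no PPI annotation", gene_set.set_id, n_dropped, len(gene_set.genes))
    rows = []
    for gene in sorted(members):
        neighbors = set(network[gene])
        k_int = len(neighbors & members)
        rows.append((gene, k_int, len(neighbors) - k_int))
    table = pd.DataFrame(rows, columns=["gene", "k_int", "k_ext"])
    return DegreeTable(set_id=gene_set.set_id, table=table, n_dropped=n_dropped)


def assess_eligibility(table: DegreeTable, min_nonzero: int = DEFAULT_MIN_NONZERO) -> EligibilityReport:
    """Apply the pre-fit filters.

    A set is ineligible when fewer than ``min_nonzero`` genes have
    k_int >= 1, or when every retained gene shares one identical internal
    degree (no internal degree distribution, so no slope can be fit).
    """
    n_nonzero = table.n_nonzero
    if n_nonzero < min_nonzero:
        reason = "too_few_nonzero"
    elif table.table["k_int"].nunique() <= 1:
        reason = "degenerate_internal_degrees"
    else:
        reason = "ok"
    return EligibilityReport(
        n_in_network=table.n_in_network,
        n_nonzero=n_nonzero,
        eligible=reason == "ok",
        reason=reason,
    )


def adjacency_index(network: nx.Graph) -> dict[str, frozenset[str]]:
    """Precomputed node -> neighbor-set map for fast repeated degree
    computation over many gene sets (reference panels, permutations)."""
    return {node: frozenset(network[node]) for node in network.nodes}


def degrees_from_index(
    index: dict[str, frozenset[str]], genes: Iterable[str], set_id: str = ""
) -> DegreeTable:
    """Degree table computed against a prebuilt :func:`adjacency_index`.

    Same contract as :func:`compute_degrees`; avoids re-touching the graph
    for every one of thousands of random sets.
    """
    genes = frozenset(genes)
    members = genes & index.keys()
    rows = []
    for gene in sorted(members):
        neighbors = index[gene]
        k_int = len(neighbors & members)
        rows.append((gene, k_int, len(neighbors) - k_int))
    table = pd.DataFrame(rows, columns=["gene", "k_int", "k_ext"])
    return DegreeTable(set_id=set_id, table=table, n_dropped=len(genes) - len(members))
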