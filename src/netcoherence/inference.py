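"""Permutation significance of coherence, and greedy modularity.

The permutation null mimics the observed phenotype's footprint: repeated
uniform gene draws of the phenotype's size g are harvested for their
non-zero interacting genes (genes with at least one edge inside the draw)
until at least n such genes accumulate; the combined set is scored with the
same degree-table + through-origin-slope machinery as the phenotype. With
the default ``coherent`` tail, small p means the observed slope is smaller
(more coherent) than the assembled-random slopes. The estimator is add-one
smoothed, p = (count + 1) / (n_perm + 1), so p is never exactly zero.

Modularity of the internal subnetwork is computed with greedy agglomerative
(Clauset-Newman-Moore) modularity maximization, for comparing coherence
against the classic community-structure score.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np

from .errors import AssemblyError, DegenerateSlopeError, ModularityError
from .network_core import adjacency_index, degrees_from_index
from .slope import fit_origin_slope
from .types import GeneSet, ModularityResult, PermutationResult

DEFAULT_N_PERM = 10_000
DEFAULT_MAX_DRAWS = 10_000


def _harvest_nonzero(index: dict[str, frozenset[str]], draw: frozenset[str]) -> set[str]:
    """Genes of ``draw`` with >= 1 interaction inside ``draw``."""
    return {g for g in draw if index.get(g, frozenset()) & draw}


def assemble_random_network(
    network_or_index: nx.Graph | dict[str, frozenset[str]],
    g: int,
    n_required: int,
    rng: np.random.Generator,
    max_draws: int = DEFAULT_MAX_DRAWS,
) -> GeneSet:
    """Assemble one size-matched random network for the permutation null.

    Uniform gene sets of size ``g`` are drawn repeatedly; from each draw
    the non-zero interacting genes are harvested and accumulated
    (deduplicated) until at least ``n_required`` of them are collected.
    Raises :class:`AssemblyError` when ``max_draws`` draws do not suffice.
    """
    index = network_or_index if isinstance(network_or_index, dict) else adjacency_index(network_or_index)
    nodes = sorted(index)
    if g > len(nodes):
        raise ValueError(f"draw size {g} exceeds network size {len(nodes)}")
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    collected: set[str] = set()
    for _ in range(max_draws):
        draw = frozenset(rng.choice(nodes, size=g, replace=False).tolist())
        collected |= _harvest_nonzero(index, draw)
        if len(collected) >= n_required:
            return GeneSet("random_assembly", "random", frozenset(collected))
    raise AssemblyError(
        f"collected {len(collected)}/{n_required} non-zero interacting genes after {max_draws} draws of size {g}"
    )


def permutation_test(
    beta_obs: float,
    network: nx.Graph,
    g: int,
    n_required: int,
    n_perm: int = DEFAULT_N_PERM,
    rng: Optional[np.random.Generator] = None,
    tail: str = "coherent",
    seed: Optional[int] = None,
    keep_slopes: bool = False,
    max_draws: int = DEFAULT_MAX_DRAWS,
    index: Optional[dict[str, frozenset[str]]] = None,
) -> PermutationResult:
    """Permutation test of an observed slope against assembled random networks.

    ``tail='coherent'`` (default) counts random slopes <= beta_obs, so a
    small p indicates a smaller-than-random slope, i.e. greater-than-random
    coherence. ``tail='paper'`` counts random slopes > beta_obs, the
    literal published indicator direction, kept for audit. Either way
    p = (count + 1) / (n_perm + 1).
    """
    if tail not in ("coherent", "paper"):
        raise ValueError(f"unknown tail {tail!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if index is None:
        index = adjacency_index(network)

    slopes: list[float] = []
    redraw_cap = 100 * n_perm
    attempts = 0
    while len(slopes) < n_perm:
        if attempts >= redraw_cap:
            raise AssemblyError(f"exceeded {redraw_cap} assembly attempts for {n_perm} permutations")
        attempts += 1
        assembled = assemble_random_network(index, g, n_required, rng, max_draws=max_draws)
        try:
            fit = fit_origin_slope(degrees_from_index(index, assembled.genes, "random_assembly"))
        except DegenerateSlopeError:
            continue  # cannot happen once n_required >= 1 genes interact, but guard anyway
        slopes.append(fit.beta)

    arr = np.asarray(slopes)
    if tail == "coherent":
        count = int(np.sum(arr <= beta_obs))
    else:
        count = int(np.sum(arr > beta_obs))
    return PermutationResult(
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        n_exceeding=count,
        tail=tail,
        seed=seed,
        random_slopes=tuple(slopes) if keep_slopes else None,
    )


def greedy_modularity(network: nx.Graph, gene_set: GeneSet) -> ModularityResult:
    """Greedy (Clauset-Newman-Moore) modularity of the internal subnetwork.

    The induced subgraph on the set's in-network genes (internal edges
    only) is partitioned by greedy agglomerative modularity maximization;
    the partition's modularity Q is returned. An edgeless subgraph has no
    defined modularity.
    """
    members = frozenset(gene_set.genes) & frozenset(network.nodes)
    sub = network.subgraph(members)
    if sub.number_of_edges() == 0:
        raise ModularityError(f"{gene_set.set_id}: internal subnetwork has no edges")
    communities = nx.community.greedy_modularity_communities(sub)
    q = nx.community.modularity(sub, communities)
    return ModularityResult(q=float(q), n_communities=len(communities))
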