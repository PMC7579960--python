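"""Synthetic interactomes with planted modules of known coherence.

Real inputs to the pipeline are a global PPI database, high-coherence
pathway collections, and GWAS-style phenotype gene lists. This module
emulates all three: a random background graph (Erdos-Renyi, or preferential
attachment for PPI-like heavy-tailed degrees), reference collections of
planted dense modules, and phenotype sets at controlled coherence levels
(``high``/``medium``: planted modules with decreasing internal density;
``random``: uniform draws from the background, i.e. no planted structure).

Planted-module genes are fresh nodes added on top of the background and
kept disjoint across modules, so each set's ground-truth coherence level is
uncontaminated. Worlds serialize to exactly the dialects the readers parse
(STRING-style links file, GMT collections, phenotype TSV) plus a JSON
manifest of ground-truth parameters.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .types import GeneSet, SyntheticWorld
from . import io_formats

GENE_FMT = "G%06d"

#: Desk-scale defaults: a 2000-gene background at ER density 0.005 (mean
#: degree ~10, the order of a thresholded PPI network), 3 collections x 10
#: reference modules of sizes 20-80 at internal density 0.6, and paired
#: phenotypes per coherence level spanning sizes 20-100.
DEFAULT_WORLD = dict(
    n_genes=2000,
    model="erdos_renyi",
    density_param=0.005,
    n_collections=3,
    modules_per_collection=10,
    module_size_range=(20, 80),
    module_p_in=0.6,
    phenotype_sizes={"high": (40, 80), "medium": (30, 60), "random": (25, 100)},
    phenotype_p_in={"high": 0.8, "medium": 0.3},
)


def _fresh_labels(network: nx.Graph, count: int) -> list[str]:
    start = network.number_of_nodes()
    return [GENE_FMT % i for i in range(start, start + count)]


def generate_background(
    n_genes: int,
    model: str = "erdos_renyi",
    density_param: float = 0.005,
    seed: Optional[int] = None,
) -> nx.Graph:
    """Generate the background interactome over genes ``G000000..``.

    ``erdos_renyi`` wires each pair independently with probability
    ``density_param``; ``powerlaw`` grows a Barabasi-Albert preferential
    attachment graph with ``int(density_param)`` edges per new node,
    mimicking the heavy-tailed degree distributions of real PPI networks.
    """
    if n_genes < 100:
        raise ValueError("background needs at least 100 genes")
    if model == "erdos_renyi":
        graph = nx.fast_gnp_random_graph(n_genes, density_param, seed=seed)
    elif model == "powerlaw":
        graph = nx.barabasi_albert_graph(n_genes, max(int(density_param), 1), seed=seed)
    else:
        raise ValueError(f"unknown background model {model!r}")
    if graph.number_of_edges() == 0:
        raise ValueError("background parameters yield an empty edge set")
    return nx.relabel_nodes(graph, {i: GENE_FMT % i for i in range(n_genes)})


def plant_module(
    network: nx.Graph,
    size: int,
    p_in: float,
    p_out: float,
    rng: np.random.Generator,
) -> GeneSet:
    """Plant a dense module on previously edgeless genes.

    ``size`` fresh genes (the lexicographically first degree-0 nodes;
    an error if the network has too few) are wired internally with per-pair probability ``p_in`` and externally
    to uniform edge-bearing outside genes with per-pair probability
    ``p_out``. With p_in = 1 and p_out = 0 this is an exact clique with no
    outside edges — the maximal-coherence construction.
    """
    if not 0 < p_in <= 1:
        raise ValueError("p_in must be in (0, 1]")
    if size > network.number_of_nodes():
        raise ValueError(f"module size {size} exceeds node count {network.number_of_nodes()}")
    free = sorted(n for n, d in network.degree() if d == 0)
    if len(free) < size:
        raise ValueError(f"insufficient unused genes: need {size}, have {len(free)}")
    members = free[:size]
    for a, b in itertools.combinations(members, 2):
        if rng.random() < p_in:
            network.add_edge(a, b)
    if p_out > 0:
        member_set = set(members)
        outside = sorted(n for n, d in network.degree() if d > 0 and n not in member_set)
        for m in members:
            k = rng.binomial(len(outside), p_out) if outside else 0
            if k:
                partners = rng.choice(outside, size=k, replace=False)
                for p in partners:
                    network.add_edge(m, p)
    return GeneSet("module", "planted", frozenset(members))


def build_world(
    seed: int,
    n_genes: int = DEFAULT_WORLD["n_genes"],
    model: str = DEFAULT_WORLD["model"],
    density_param: float = DEFAULT_WORLD["density_param"],
    n_collections: int = DEFAULT_WORLD["n_collections"],
    modules_per_collection: int = DEFAULT_WORLD["modules_per_collection"],
    module_size_range: tuple[int, int] = DEFAULT_WORLD["module_size_range"],
    module_p_in: float = DEFAULT_WORLD["module_p_in"],
    module_p_out: Optional[float] = None,
    phenotype_sizes: Optional[dict[str, Sequence[int]]] = None,
    phenotype_p_in: Optional[dict[str, float]] = None,
) -> SyntheticWorld:
    """Generate a full synthetic world: background + planted collections +
    phenotypes at ``high``/``medium``/``random`` coherence levels.

    Planted sets get fresh disjoint genes on top of the ``n_genes``
    background; external attachment defaults to the background density so
    module genes look background-typical from outside. ``random``-level
    phenotypes are uniform draws of background genes. Degree-0 genes are
    pruned at the end: the interactome contains edge-bearing genes only.
    """
    if phenotype_sizes is None:
        phenotype_sizes = {k: list(v) for k, v in DEFAULT_WORLD["phenotype_sizes"].items()}
    if phenotype_p_in is None:
        phenotype_p_in = dict(DEFAULT_WORLD["phenotype_p_in"])
    if module_p_out is None:
        module_p_out = density_param if model == "erdos_renyi" else 0.005

    ss = np.random.SeedSequence(seed)
    bg_seed, plant_seed, pheno_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    network = generate_background(n_genes, model, density_param, seed=bg_seed)

    plant_rng = np.random.default_rng(plant_seed)
    module_sizes = [
        int(s)
        for s in plant_rng.integers(
            module_size_range[0], module_size_range[1] + 1, size=n_collections * modules_per_collection
        )
    ]
    planted_sizes = sum(module_sizes) + sum(
        s for lvl, sizes in phenotype_sizes.items() if lvl != "random" for s in sizes
    )
    network.add_nodes_from(_fresh_labels(network, planted_sizes))

    collections: dict[str, list[GeneSet]] = {}
    size_iter = iter(module_sizes)
    for c in range(n_collections):
        name = f"collection_{chr(ord('a') + c)}"
        sets = []
        for m in range(modules_per_collection):
            module = plant_module(network, next(size_iter), module_p_in, module_p_out, plant_rng)
            sets.append(GeneSet(f"{name}_set{m:02d}", name, module.genes))
        collections[name] = sets

    pheno_rng = np.random.default_rng(pheno_seed)
    # random-level phenotypes are uniform draws from the edge-bearing
    # interactome (planted modules included), matching the definition of
    # the random reference sets they should be indistinguishable from
    edge_bearing = sorted(n for n, d in network.degree() if d > 0)
    phenotypes: list[tuple[GeneSet, str]] = []
    for level in sorted(phenotype_sizes):
        for j, size in enumerate(phenotype_sizes[level]):
            set_id = f"pheno_{level}_{j}"
            if level == "random":
                genes = frozenset(
                    pheno_rng.choice(edge_bearing, size=size, replace=False).tolist()
                )
            else:
                module = plant_module(network, size, phenotype_p_in[level], module_p_out, pheno_rng)
                genes = module.genes
            phenotypes.append((GeneSet(set_id, level, genes), level))

    network.remove_nodes_from([n for n, d in network.degree() if d == 0])
    params = dict(
        n_genes=n_genes,
        model=model,
        density_param=density_param,
        n_collections=n_collections,
        modules_per_collection=modules_per_collection,
        module_size_range=list(module_size_range),
        module_p_in=module_p_in,
        module_p_out=module_p_out,
        phenotype_sizes={k: list(v) for k, v in phenotype_sizes.items()},
        phenotype_p_in=dict(phenotype_p_in),
    )
    return SyntheticWorld(
        network=network,
        reference_collections=collections,
        phenotypes=phenotypes,
        seed=seed,
        params=params,
    )


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Serialize a world as on-disk fixtures in the reader dialects.

    Writes ``ppi_links.txt`` (STRING-style; scores drawn uniformly in
    501-1000 from the world seed, so the default score filter keeps every
    edge), one GMT per reference collection, ``phenotypes.tsv``, and
    ``manifest.json`` with the ground-truth parameters. Returns the paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rng = np.random.default_rng(np.random.SeedSequence((world.seed, 0xC0DE)))
    edges = sorted(tuple(sorted(e)) for e in world.network.edges)
    links = directory / "ppi_links.txt"
    with open(links, "w", encoding="utf-8") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for (a, b), score in zip(edges, rng.integers(501, 1001, size=len(edges))):
            fh.write(f"{a} {b} {int(score)}\n")
    paths["links"] = links

    for name, sets in world.reference_collections.items():
        gmt = directory / f"{name}.gmt"
        io_formats.write_gmt(sets, gmt)
        paths[name] = gmt

    pheno = directory / "phenotypes.tsv"
    with open(pheno, "w", encoding="utf-8") as fh:
        fh.write("DISEASE/TRAIT\tCATEGORY\tMAPPED_GENE\n")
        for gs, level in world.phenotypes:
            fh.write(f"{gs.set_id}\t{level}\t{', '.join(sorted(gs.genes))}\n")
    paths["phenotypes"] = pheno

    manifest = directory / "manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "seed": world.seed,
                "params": world.params,
                "n_nodes": world.network.number_of_nodes(),
                "n_edges": world.network.number_of_edges(),
                "phenotype_levels": {gs.set_id: level for gs, level in world.phenotypes},
            },
            indent=2,
            sort_keys=True,
        )
    )
    paths["manifest"] = manifest
    return paths
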