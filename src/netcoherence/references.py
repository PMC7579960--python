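"""Size-matched reference panels and min-max normalization of slopes.

Raw through-origin slopes depend strongly on network size, so they are not
comparable across phenotypes. For a query of effective size g we build a
panel of size-matched anchors: high-coherence reference networks (pathway
style collections; their median slope is beta_min) and random gene sets
drawn from the interactome (median slope beta_max). The normalized
coherence of a slope beta is

    coherence = (beta - beta_max) / (beta_min - beta_max),

which is 0 at the random anchor, 1 at the pathway anchor, and deliberately
NOT clamped: sets more coherent than the median pathway exceed 1.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import DegenerateSlopeError, PanelError
from .network_core import adjacency_index, degrees_from_index
from .slope import fit_origin_slope
from .types import GeneSet, ReferencePanel, SlopeFit

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOM = 1000
DEFAULT_PER_COLLECTION = 10


def sample_random_geneset(pool: Sequence[str] | frozenset[str], size: int, rng: np.random.Generator) -> GeneSet:
    """Uniform sample of ``size`` genes without replacement from ``pool``.

    The pool is sorted before sampling so draws are reproducible for a
    given seed regardless of set iteration order.
    """
    pool = sorted(pool)
    if size > len(pool):
        raise ValueError(f"cannot sample {size} genes from a pool of {len(pool)}")
    genes = rng.choice(pool, size=size, replace=False)
    return GeneSet("random", "random", frozenset(genes.tolist()))


def effective_size(gene_set: GeneSet, network: nx.Graph) -> int:
    """Count of set genes present in the network (PPI-annotated genes)."""
    return sum(1 for g in gene_set.genes if g in network)


def select_size_matched_reference(
    collections: Mapping[str, Sequence[GeneSet]],
    network: nx.Graph,
    target_size: int,
    per_collection: int = DEFAULT_PER_COLLECTION,
) -> list[GeneSet]:
    """Pick, per collection, the ``per_collection`` sets whose effective
    size is nearest ``target_size`` (ties by set_id, lexicographic).

    A collection smaller than ``per_collection`` contributes all its sets
    with a warning. The default 10 sets from each of 3 collections gives
    the 30-network high-coherence reference.
    """
    chosen: list[GeneSet] = []
    for name in sorted(collections):
        sets = collections[name]
        if not sets:
            raise PanelError(f"reference collection {name!r} is empty")
        ranked = sorted(sets, key=lambda gs: (abs(effective_size(gs, network) - target_size), gs.set_id))
        if len(ranked) < per_collection:
            logger.warning(
                "collection %s has %d sets (< %d requested); using all", name, len(ranked), per_collection
            )
        picked = ranked[:per_collection]
        worst = max((effective_size(gs, network) for gs in picked), default=target_size)
        best = min((effective_size(gs, network) for gs in picked), default=target_size)
        if target_size and (worst > 1.25 * target_size or best < 0.75 * target_size):
            logger.info(
                "collection %s: size-matched sets span [%d, %d] for target %d (> 25%% deviation)",
                name, best, worst, target_size,
            )
        chosen.extend(picked)
    return chosen


def build_reference_panel(
    network: nx.Graph,
    collections: Mapping[str, Sequence[GeneSet]],
    target_size: int,
    n_random: int = DEFAULT_N_RANDOM,
    rng: Optional[np.random.Generator] = None,
    per_collection: int = DEFAULT_PER_COLLECTION,
    seed: Optional[int] = None,
    index: Optional[dict[str, frozenset[str]]] = None,
) -> ReferencePanel:
    """Build the size-matched panel anchoring normalization at ``target_size``.

    Slopes are fitted for the selected reference sets and for ``n_random``
    uniform random gene sets of size ``target_size``. Reference sets whose
    slope is undefined (no internal edges) are dropped with a warning;
    random sets with undefined slopes are redrawn. Fewer than 3 usable
    reference slopes is a panel error.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if index is None:
        index = adjacency_index(network)
    nodes = sorted(index)
    if target_size > len(nodes):
        raise PanelError(f"target size {target_size} exceeds network size {len(nodes)}")

    high_slopes: list[float] = []
    n_ref_dropped = 0
    for gs in select_size_matched_reference(collections, network, target_size, per_collection):
        try:
            high_slopes.append(fit_origin_slope(degrees_from_index(index, gs.genes, gs.set_id)).beta)
        except DegenerateSlopeError:
            n_ref_dropped += 1
            logger.warning("reference set %s has no internal edges at size %d; dropped", gs.set_id, target_size)
    if len(high_slopes) < 3:
        raise PanelError(
            f"only {len(high_slopes)} usable reference slopes for target size {target_size} (need >= 3)"
        )

    random_slopes: list[float] = []
    attempts = 0
    max_attempts = max(100 * n_random, 1000)
    while len(random_slopes) < n_random:
        if attempts >= max_attempts:
            raise PanelError(
                f"could not assemble {n_random} non-degenerate random slopes at size {target_size}"
            )
        attempts += 1
        draw = rng.choice(nodes, size=target_size, replace=False)
        try:
            random_slopes.append(fit_origin_slope(degrees_from_index(index, draw.tolist(), "random")).beta)
        except DegenerateSlopeError:
            continue

    return ReferencePanel(
        target_size=target_size,
        high_slopes=high_slopes,
        random_slopes=random_slopes,
        seed=seed,
        n_reference_dropped=n_ref_dropped,
    )


def normalize_slope(beta: float, panel: ReferencePanel) -> float:
    """Min-max normalized coherence of a raw slope against a panel.

    Returns ``(beta - beta_max) / (beta_min - beta_max)``; 0 at the random
    anchor, 1 at the high-coherence anchor, unclamped beyond.
    """
    if panel.degenerate:
        raise PanelError(
            f"panel at size {panel.target_size} is degenerate (beta_min == beta_max == {panel.beta_min})"
        )
    return (beta - panel.beta_max) / (panel.beta_min - panel.beta_max)


def normalize_ci(fit: SlopeFit, panel: ReferencePanel) -> tuple[float, float]:
    """Normalize a slope fit's confidence bounds like the slope itself.

    The normalization map is decreasing, so the transformed pair is
    re-ordered to (low, high) on the coherence scale.
    """
    a = normalize_slope(fit.ci_low, panel)
    b = normalize_slope(fit.ci_high, panel)
    return (a, b) if a <= b else (b, a)
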