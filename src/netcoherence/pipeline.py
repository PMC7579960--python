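"""End-to-end orchestration: config, coherence runs, permutation runs.

A run takes a global interactome, reference collections, and phenotype
gene sets, and produces one :class:`~netcoherence.types.CoherenceResult`
per phenotype: degree table -> eligibility -> through-origin slope ->
size-matched panel -> normalized coherence and CI, plus optional greedy
modularity and permutation p-value.

Reproducibility: the single run seed spawns fixed substreams — one per
panel target size and one per phenotype for permutations — so any stage
can be recomputed independently and reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import yaml

from . import io_formats
from .errors import DegenerateSlopeError, ModularityError, PanelError
from .inference import greedy_modularity, permutation_test
from .network_core import (
    DEFAULT_MIN_NONZERO,
    adjacency_index,
    assess_eligibility,
    build_global_network,
    compute_degrees,
)
from .references import (
    DEFAULT_N_RANDOM,
    DEFAULT_PER_COLLECTION,
    build_reference_panel,
    normalize_ci,
    normalize_slope,
)
from .slope import fit_origin_slope
from .types import CoherenceResult, GeneSet, ReferencePanel

logger = logging.getLogger(__name__)

_PANEL_TAG = 0x70616E  # distinct substream tags, kept below 2**31
_PERM_TAG = 0x7065726D


def panel_seed(seed: int, target_size: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((seed, _PANEL_TAG, target_size))


def perm_seed(seed: int, ordinal: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((seed, _PERM_TAG, ordinal))


@dataclass
class RunConfig:
    """Parameters of one pipeline run, loadable from a YAML file."""

    ppi_path: str
    ppi_dialect: str = "string"  # "string" | "biogrid"
    score_threshold: int = 500
    taxon_id: str = "9606"
    reference_gmts: list[str] = field(default_factory=list)
    phenotype_path: str = ""
    trait_column: str = "DISEASE/TRAIT"
    gene_column: str = "MAPPED_GENE"
    category_column: Optional[str] = None
    alias_map_path: Optional[str] = None
    strict_aliases: bool = False
    min_nonzero: int = DEFAULT_MIN_NONZERO
    per_collection: int = DEFAULT_PER_COLLECTION
    n_random: int = DEFAULT_N_RANDOM
    n_perm: int = 10_000
    tail: str = "coherent"
    ci_level: float = 0.95
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.ppi_dialect not in ("string", "biogrid"):
            raise ValueError(f"unknown PPI dialect {self.ppi_dialect!r}")
        if self.tail not in ("coherent", "paper"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 <= self.score_threshold <= 1000:
            raise ValueError("score_threshold must be in [0, 1000]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def load_inputs(config: RunConfig) -> tuple[nx.Graph, dict[str, list[GeneSet]], list[GeneSet]]:
    """Read and filter the PPI edge list, reference GMTs, and phenotype
    table named by ``config``, applying the alias map if given."""
    if config.ppi_dialect == "string":
        edges = io_formats.read_string_links(config.ppi_path, config.score_threshold)
    else:
        edges = io_formats.read_biogrid_tab(config.ppi_path, config.taxon_id)
    network = build_global_network(edges)

    collections: dict[str, list[GeneSet]] = {}
    for gmt in config.reference_gmts:
        sets = io_formats.read_gmt(gmt)
        collections[Path(gmt).stem] = sets

    phenotypes = io_formats.read_phenotype_table(
        config.phenotype_path,
        gene_column=config.gene_column,
        trait_column=config.trait_column,
        category_column=config.category_column,
    )
    if config.alias_map_path:
        aliases = io_formats.read_alias_map(config.alias_map_path)
        phenotypes = io_formats.apply_alias_map(phenotypes, aliases, strict=config.strict_aliases)
        collections = {
            name: io_formats.apply_alias_map(sets, aliases, strict=config.strict_aliases)
            for name, sets in collections.items()
        }
    return network, collections, phenotypes


class PanelCache:
    """Per-run cache of reference panels keyed by target size.

    Each size gets its own seed substream derived from the run seed, so a
    panel is identical whether it is built first or last.
    """

    def __init__(
        self,
        network: nx.Graph,
        collections: Mapping[str, Sequence[GeneSet]],
        seed: int,
        n_random: int = DEFAULT_N_RANDOM,
        per_collection: int = DEFAULT_PER_COLLECTION,
    ) -> None:
        self.network = network
        self.collections = collections
        self.seed = seed
        self.n_random = n_random
        self.per_collection = per_collection
        self.index = adjacency_index(network)
        self._panels: dict[int, ReferencePanel] = {}

    def get(self, target_size: int) -> ReferencePanel:
        if target_size not in self._panels:
            rng = np.random.default_rng(panel_seed(self.seed, target_size))
            self._panels[target_size] = build_reference_panel(
                self.network,
                self.collections,
                target_size,
                n_random=self.n_random,
                rng=rng,
                per_collection=self.per_collection,
                seed=self.seed,
                index=self.index,
            )
            p = self._panels[target_size]
            logger.info(
                "panel size=%d beta_min=%.4g beta_max=%.4g (refs=%d, random=%d)",
                target_size, p.beta_min, p.beta_max, len(p.high_slopes), len(p.random_slopes),
            )
        return self._panels[target_size]

    def summary_rows(self) -> list[dict]:
        return [
            dict(
                target_size=size,
                beta_min=p.beta_min,
                beta_max=p.beta_max,
                n_reference=len(p.high_slopes),
                n_random=len(p.random_slopes),
            )
            for size, p in sorted(self._panels.items())
        ]


def run_coherence(
    network: nx.Graph,
    collections: Mapping[str, Sequence[GeneSet]],
    phenotypes: Sequence[GeneSet],
    seed: int,
    min_nonzero: int = DEFAULT_MIN_NONZERO,
    n_random: int = DEFAULT_N_RANDOM,
    per_collection: int = DEFAULT_PER_COLLECTION,
    ci_level: float = 0.95,
    compute_modularity: bool = True,
    cache: Optional[PanelCache] = None,
) -> tuple[list[CoherenceResult], PanelCache]:
    """Estimate normalized coherence for every phenotype.

    Ineligible phenotypes are reported with their reason and NA values.
    Returns the results (input order) and the panel cache for reuse by a
    subsequent permutation stage.
    """
    if cache is None:
        cache = PanelCache(network, collections, seed, n_random=n_random, per_collection=per_collection)
    results: list[CoherenceResult] = []
    for gs in phenotypes:
        table = compute_degrees(network, gs)
        report = assess_eligibility(table, min_nonzero=min_nonzero)
        result = CoherenceResult(
            set_id=gs.set_id,
            category=gs.category,
            n_genes=gs.size,
            n_nonzero=report.n_nonzero,
            n_in_network=report.n_in_network,
            eligible=report.eligible,
            reason=report.reason,
        )
        if report.eligible:
            fit = fit_origin_slope(table, ci_level=ci_level)
            result.slope, result.ci_low, result.ci_high = fit.beta, fit.ci_low, fit.ci_high
            try:
                panel = cache.get(report.n_in_network)
                result.coherence = normalize_slope(fit.beta, panel)
                result.coherence_ci_low, result.coherence_ci_high = normalize_ci(fit, panel)
            except PanelError as exc:
                logger.warning("%s: %s", gs.set_id, exc)
                result.reason = "panel_error"
            if compute_modularity:
                try:
                    result.modularity = greedy_modularity(network, gs).q
                except ModularityError:
                    pass
        results.append(result)
    return results, cache


def run_permtest(
    network: nx.Graph,
    phenotypes: Sequence[GeneSet],
    results: Sequence[CoherenceResult],
    seed: int,
    n_perm: int = 10_000,
    tail: str = "coherent",
    threads: int = 1,
    index: Optional[dict[str, frozenset[str]]] = None,
) -> list[CoherenceResult]:
    """Add a permutation p-value to every eligible result, in place.

    Each phenotype uses a fixed substream derived from (seed, ordinal), so
    p-values do not depend on thread count or on which other phenotypes
    are present in the run.
    """
    by_id = {gs.set_id: gs for gs in phenotypes}
    missing = [r.set_id for r in results if r.set_id not in by_id]
    if missing:
        raise ValueError(f"results reference unknown phenotype set_ids: {missing}")
    if index is None:
        index = adjacency_index(network)

    jobs = [
        (ordinal, r)
        for ordinal, r in enumerate(results)
        if r.eligible and r.slope is not None
    ]

    def _one(ordinal: int, r: CoherenceResult) -> float:
        rng = np.random.default_rng(perm_seed(seed, ordinal))
        perm = permutation_test(
            beta_obs=r.slope,
            network=network,
            g=r.n_in_network,
            n_required=r.n_nonzero,
            n_perm=n_perm,
            rng=rng,
            tail=tail,
            index=index,
        )
        return perm.p_value

    if threads > 1:
        from joblib import Parallel, delayed

        p_values = Parallel(n_jobs=threads, backend="threading")(
            delayed(_one)(ordinal, r) for ordinal, r in jobs
        )
    else:
        p_values = [_one(ordinal, r) for ordinal, r in jobs]
    for (ordinal, r), p in zip(jobs, p_values):
        r.perm_p = p
    return list(results)


def category_summary(results: Sequence[CoherenceResult]) -> "object":
    """Unweighted per-category mean coherence (plus counts), one row per
    category — the layout of a categories summary table."""
    import pandas as pd

    rows = []
    by_cat: dict[str, list[CoherenceResult]] = {}
    for r in results:
        by_cat.setdefault(r.category, []).append(r)
    for cat in sorted(by_cat):
        group = by_cat[cat]
        coherences = [r.coherence for r in group if r.coherence is not None]
        rows.append(
            dict(
                category=cat,
                n_phenotypes=len(group),
                n_estimated=len(coherences),
                mean_coherence=float(np.mean(coherences)) if coherences else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["category", "n_phenotypes", "n_estimated", "mean_coherence"])
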