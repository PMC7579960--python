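"""Shared in-memory containers for the coherence pipeline.

The pipeline moves from an interactome edge list, through per-gene
internal/external degree tables for a gene set, to a through-origin
regression slope and its min-max normalized coherence. Each stage has a
small frozen container defined here so modules can interoperate without
import cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import pandas as pd


class EdgeRecord(NamedTuple):
    """One undirected interaction between two gene symbols.

    ``score`` is the source database's integer confidence in [0, 1000],
    or ``None`` for unscored sources (e.g. BioGrid).
    """

    gene_a: str
    gene_b: str
    score: Optional[int] = None

    def key(self) -> tuple[str, str]:
        """Canonical unordered endpoint pair, for undirected dedup."""
        return (self.gene_a, self.gene_b) if self.gene_a <= self.gene_b else (self.gene_b, self.gene_a)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a category label.

    Categories distinguish phenotypes, reference collections, and random
    draws; the genes are deduplicated by construction (a ``frozenset``).
    """

    set_id: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"GeneSet {self.set_id!r} is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class DegreeTable:
    """Per-gene internal and external degrees of a gene set within the
    global interactome.

    ``table`` has one row per set gene *present in the network*, columns
    ``gene`` (str), ``k_int`` (int), ``k_ext`` (int). Genes with no PPI
    annotation are dropped (their count is kept in ``n_dropped``). Genes
    with ``k_int == 0`` but edges to outside genes are retained: they
    carry external-degree information.
    """

    set_id: str
    table: pd.DataFrame
    n_dropped: int = 0

    @property
    def n_in_network(self) -> int:
        return len(self.table)

    @property
    def n_nonzero(self) -> int:
        """Genes with at least one interaction inside the set."""
        return int((self.table["k_int"] >= 1).sum())


@dataclass(frozen=True)
class EligibilityReport:
    """Outcome of the pre-fit filters on a degree table."""

    n_in_network: int
    n_nonzero: int
    eligible: bool
    reason: str  # "ok" | "too_few_nonzero" | "degenerate_internal_degrees"


@dataclass(frozen=True)
class SlopeFit:
    """Through-origin least-squares slope of sqrt(k_ext) on sqrt(k_int).

    Small slopes mean high coherence (many internal, few external edges).
    The confidence interval is the normal-theory interval for a no-intercept
    regression with ``residual_df = n_points - 1``.
    """

    beta: float
    ci_low: float
    ci_high: float
    n_points: int
    residual_df: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high or math.isnan(self.ci_low)):
            raise ValueError("confidence bounds must bracket beta")


@dataclass
class ReferencePanel:
    """Size-matched reference slope distributions for normalization.

    ``beta_min`` is the median slope of the high-coherence (pathway-style)
    reference networks; ``beta_max`` the median slope of random gene sets of
    the same effective size. Coherence is the min-max position of a query
    slope between these two anchors.
    """

    target_size: int
    high_slopes: list[float]
    random_slopes: list[float]
    seed: Optional[int] = None
    n_reference_dropped: int = 0

    @property
    def beta_min(self) -> float:
        s = sorted(self.high_slopes)
        n = len(s)
        return (s[(n - 1) // 2] + s[n // 2]) / 2.0

    @property
    def beta_max(self) -> float:
        s = sorted(self.random_slopes)
        n = len(s)
        return (s[(n - 1) // 2] + s[n // 2]) / 2.0

    @property
    def degenerate(self) -> bool:
        return self.beta_min == self.beta_max


@dataclass(frozen=True)
class PermutationResult:
    """Permutation significance of an observed slope against assembled
    random networks; add-one smoothed, so p is never exactly zero."""

    p_value: float
    n_permutations: int
    n_exceeding: int
    tail: str  # "coherent" | "paper"
    seed: Optional[int] = None
    random_slopes: Optional[tuple[float, ...]] = None


@dataclass(frozen=True)
class ModularityResult:
    """Greedy (Clauset-Newman-Moore) modularity of the internal subnetwork."""

    q: float
    n_communities: int
    method: str = "greedy"


@dataclass
class CoherenceResult:
    """Everything reported for one phenotype in the results table."""

    set_id: str
    category: str
    n_genes: int
    n_nonzero: int = 0
    n_in_network: int = 0
    eligible: bool = False
    reason: str = "ok"
    slope: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    coherence: Optional[float] = None
    coherence_ci_low: Optional[float] = None
    coherence_ci_high: Optional[float] = None
    perm_p: Optional[float] = None
    modularity: Optional[float] = None


@dataclass
class SyntheticWorld:
    """A generated interactome with planted reference collections and
    phenotypes of known coherence level, for end-to-end testing."""

    network: "object"  # networkx.Graph; typed loosely to avoid a hard import here
    reference_collections: dict[str, list[GeneSet]]
    phenotypes: list[tuple[GeneSet, str]]  # (set, level) with level in {high, medium, random}
    seed: int
    params: dict = field(default_factory=dict)
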