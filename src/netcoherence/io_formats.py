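"""Readers and writers for the file dialects the pipeline touches.

Supported inputs: STRING ``protein.links``-style whitespace-delimited edge
lists with a ``combined_score`` column (0-1000), BioGrid TAB-style TSVs
with per-interactor organism columns, MSigDB GMT gene-set files, and
GWAS-catalog-style phenotype tables with a mapped-genes column. Source
specific filters (score threshold, taxon restriction) are applied at read
time; every reader removes self-loops and symmetric duplicate edges.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import FormatError
from .types import CoherenceResult, EdgeRecord, GeneSet

#: Regex patterns for gene classes without useful PPI annotation
#: (antisense, LINC/LOC non-coding, readthrough fusions). Opt-in via
#: ``read_phenotype_table(exclude_patterns=DEFAULT_EXCLUDE_PATTERNS)``.
DEFAULT_EXCLUDE_PATTERNS: tuple[str, ...] = (
    r"-AS\d*$",
    r"^LINC\d+",
    r"^LOC\d+",
    r"^C\d+orf\d+$",
)

#: Separators seen in GWAS-catalog MAPPED_GENE cells: list separators and
#: the "A - B" / "A x B" intergenic/interaction notations.
DEFAULT_GENE_DELIMITERS: tuple[str, ...] = (";", ",", " - ", " x ")

RESULT_COLUMNS = [
    "set_id",
    "category",
    "n_genes",
    "n_nonzero",
    "slope",
    "ci_low",
    "ci_high",
    "coherence",
    "coherence_ci_low",
    "coherence_ci_high",
    "perm_p",
    "modularity",
]


def _dedup_edges(records: Iterable[EdgeRecord]) -> list[EdgeRecord]:
    """Drop self-loops and keep the first occurrence of each unordered pair."""
    seen: set[tuple[str, str]] = set()
    out: list[EdgeRecord] = []
    for rec in records:
        if rec.gene_a == rec.gene_b:
            continue
        key = rec.key()
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def read_string_links(
    path: str | Path,
    score_threshold: int = 500,
    protein_columns: tuple[str, str] = ("protein1", "protein2"),
    score_column: str = "combined_score",
) -> list[EdgeRecord]:
    """Read a STRING protein-links file, keeping edges with
    ``score > score_threshold`` (strict inequality).

    The file is whitespace-delimited with a header row. Identifiers are
    passed through verbatim; mapping to gene symbols is a separate step
    (:func:`apply_alias_map`).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [c for c in (*protein_columns, score_column) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    scores = pd.to_numeric(df[score_column], errors="coerce")
    bad = scores.index[scores.isna()]
    if len(bad):
        # +2: header line plus 1-based indexing
        raise FormatError(
            f"{path}: unparseable score {df[score_column].iloc[bad[0]]!r} at line {bad[0] + 2}"
        )
    if ((scores < 0) | (scores > 1000)).any():
        line = int(scores.index[(scores < 0) | (scores > 1000)][0]) + 2
        raise FormatError(f"{path}: score outside [0, 1000] at line {line}")
    kept = df.loc[scores > score_threshold]
    records = [
        EdgeRecord(a, b, int(s))
        for a, b, s in zip(kept[protein_columns[0]], kept[protein_columns[1]], scores.loc[kept.index])
    ]
    return _dedup_edges(records)


def read_biogrid_tab(
    path: str | Path,
    taxon_id: str = "9606",
    symbol_columns: tuple[str, str] = ("Official Symbol Interactor A", "Official Symbol Interactor B"),
    taxon_columns: tuple[str, str] = ("Organism ID Interactor A", "Organism ID Interactor B"),
) -> list[EdgeRecord]:
    """Read a BioGrid TAB-style TSV, keeping interactions where *both*
    interactors belong to ``taxon_id``.

    All interaction types (physical and genetic) are kept and no
    confidence score is attached; duplicates across interaction types
    collapse to one undirected edge.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in (*symbol_columns, *taxon_columns) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    mask = (df[taxon_columns[0]].astype(str) == str(taxon_id)) & (
        df[taxon_columns[1]].astype(str) == str(taxon_id)
    )
    kept = df.loc[mask]
    records = [EdgeRecord(a, b) for a, b in zip(kept[symbol_columns[0]], kept[symbol_columns[1]])]
    return _dedup_edges(records)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, tab-delimited as
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    The description field becomes the set's category when non-empty.
    Duplicate symbols within a line are collapsed.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-delimited fields")
            name, description = fields[0], fields[1]
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name, description if description else "reference", genes))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets in GMT format (deterministic gene order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.category, *sorted(gs.genes)]) + "\n")


def split_gene_cell(cell: str, delimiters: Sequence[str] = DEFAULT_GENE_DELIMITERS) -> list[str]:
    """Split a multi-gene cell on the configured separators, trimming
    whitespace and dropping empty tokens."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    pattern = "|".join(re.escape(d) for d in delimiters)
    return [tok.strip() for tok in re.split(pattern, str(cell)) if tok.strip()]


def read_phenotype_table(
    path: str | Path,
    gene_column: str = "MAPPED_GENE",
    trait_column: str = "DISEASE/TRAIT",
    category_column: Optional[str] = None,
    delimiters: Sequence[str] = DEFAULT_GENE_DELIMITERS,
    exclude: Iterable[str] = (),
    exclude_patterns: Sequence[str] = (),
) -> list[GeneSet]:
    """Read a GWAS-catalog-style phenotype table into one GeneSet per trait.

    Genes are pooled over all rows of a trait; multi-gene cells are split
    on ``delimiters``. Symbols in ``exclude`` or matching any regex in
    ``exclude_patterns`` (e.g. non-protein-coding transcript names) are
    dropped. Traits whose genes are entirely excluded are omitted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in (gene_column, trait_column) if c not in df.columns]
    if category_column and category_column not in df.columns:
        missing.append(category_column)
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    excluded = set(exclude)
    compiled = [re.compile(p) for p in exclude_patterns]

    pooled: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        trait = row[trait_column]
        if pd.isna(trait):
            continue
        trait = str(trait).strip()
        if trait not in pooled:
            pooled[trait] = set()
            order.append(trait)
            if category_column:
                categories[trait] = str(row[category_column])
        for gene in split_gene_cell(row[gene_column], delimiters):
            if gene in excluded or any(rx.search(gene) for rx in compiled):
                continue
            pooled[trait].add(gene)
    return [
        GeneSet(trait, categories.get(trait, "phenotype"), frozenset(pooled[trait]))
        for trait in order
        if pooled[trait]
    ]


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of ``alias<TAB>canonical`` symbol pairs.

    Canonical symbols are added as identity entries so the map is stable
    under repeated application.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["alias", "canonical"], comment="#")
    mapping = dict(zip(df["alias"].astype(str), df["canonical"].astype(str)))
    for canonical in list(mapping.values()):
        mapping.setdefault(canonical, canonical)
    return mapping


def apply_alias_map(
    sets: Sequence[GeneSet], aliases: Mapping[str, str], strict: bool = False
) -> list[GeneSet]:
    """Replace every symbol by its canonical form.

    Symbols absent from the map are kept verbatim, or dropped when
    ``strict`` is true (mirroring exclusion of unmappable gene names).
    Sets are re-deduplicated after mapping; sets that become empty are
    omitted.
    """
    out: list[GeneSet] = []
    for gs in sets:
        mapped: set[str] = set()
        for gene in gs.genes:
            if gene in aliases:
                mapped.add(aliases[gene])
            elif not strict:
                mapped.add(gene)
        if mapped:
            out.append(GeneSet(gs.set_id, gs.category, frozenset(mapped)))
    return out


def _fmt(value: Optional[float]) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, (int,)) or (isinstance(value, float) and value.is_integer() and abs(value) < 1e15):
        return str(int(value))
    return format(value, ".6g")


def write_results_table(results: Sequence[CoherenceResult], path: str | Path) -> None:
    """Write one TSV row per phenotype with slope, normalized coherence,
    CI bounds, permutation p and modularity; missing values as ``NA``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            row = [
                r.set_id,
                r.category,
                str(r.n_genes),
                str(r.n_nonzero),
                _fmt(r.slope),
                _fmt(r.ci_low),
                _fmt(r.ci_high),
                _fmt(r.coherence),
                _fmt(r.coherence_ci_low),
                _fmt(r.coherence_ci_high),
                _fmt(r.perm_p),
                _fmt(r.modularity),
            ]
            fh.write("\t".join(row) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (``NA`` -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
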