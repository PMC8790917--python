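"""Pathway enrichment of driver groups and rollup to top-level categories.

Enrichment compares the proportion of a driver set in each pathway
(hierarchy levels 2-8) to the rest of the gene universe with a one-sided
(greater) Fisher's exact test, BH-corrected across tested pathways.
Enriched pathways (FDR < 0.05) are then tallied by their level-1 ancestor
category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .stats import bh_adjust, fisher_test

__all__ = ["PathwayRecord", "pathway_enrichment", "rollup_to_level1",
           "validate_hierarchy"]


@dataclass(frozen=True)
class PathwayRecord:
    pathway_id: str
    name: str
    level: int
    parent_level1: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("pathway level must be >= 1")
        if self.level == 1 and self.parent_level1 != self.pathway_id:
            raise ValueError(
                f"level-1 pathway {self.pathway_id} must be its own parent")


def validate_hierarchy(hierarchy: Mapping[str, str]) -> None:
    """Reject cyclic or self-referential child->level1 mappings."""
    for child, parent in hierarchy.items():
        if parent in hierarchy and hierarchy[parent] != parent and parent != child:
            raise ValueError(f"hierarchy is not flat: {child} -> {parent} -> ...")


def pathway_enrichment(
    gene_set: Iterable[str],
    pathways: Iterable[PathwayRecord],
    universe: Iterable[str],
    fdr_level: float = 0.05,
    levels: tuple[int, int] = (2, 8),
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``gene_set`` in each pathway.

    Pathways outside ``levels`` are ignored. The 2x2 table per pathway is
    (in set vs rest of universe) x (in pathway vs not); ``enriched`` marks
    FDR < ``fdr_level``. Pathway gene sets are intersected with the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe must be non-empty")
    gene_set = set(gene_set) & universe
    rows = []
    for pw in pathways:
        if not levels[0] <= pw.level <= levels[1]:
            continue
        members = pw.genes & universe
        a = len(gene_set & members)
        b = len(gene_set) - a
        c = len(members) - a
        d = len(universe) - len(gene_set) - c
        p = fisher_test([[a, b], [c, d]], alternative="greater")
        rows.append((pw.pathway_id, pw.name, pw.level, pw.parent_level1,
                     a, len(members), p))
    table = pd.DataFrame(rows, columns=["pathway_id", "name", "level",
                                        "parent_level1", "n_overlap",
                                        "n_pathway", "p_value"])
    if table.empty:
        table["fdr"] = []
        table["enriched"] = []
        return table
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["enriched"] = table["fdr"] < fdr_level
    return table


def rollup_to_level1(
    enrichment_table: pd.DataFrame,
    hierarchy: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Proportion of enriched pathways mapping to each level-1 category.

    The level-1 ancestor comes from the enrichment table's ``parent_level1``
    column, overridden by ``hierarchy`` (child_id -> level1_id) when given.
    Proportions sum to 1 whenever any pathway is enriched.
    """
    if hierarchy is not None:
        validate_hierarchy(hierarchy)
    enriched = enrichment_table.loc[enrichment_table["enriched"]]
    counts: dict[str, int] = {}
    for row in enriched.itertuples(index=False):
        parent = (hierarchy or {}).get(row.pathway_id, row.parent_level1)
        if not parent or (isinstance(parent, float) and pd.isna(parent)):
            raise ValueError(f"enriched pathway {row.pathway_id} has no level-1 ancestor")
        counts[parent] = counts.get(parent, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}
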