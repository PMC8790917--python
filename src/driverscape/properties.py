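"""Systems-level gene properties and group-vs-rest comparisons.

Properties cover gene duplication (protein-sequence sharing), evolutionary
origin (pre-metazoan orthology), gene/protein expression breadth across
tissues, network centrality in protein-protein and miRNA-gene interaction
graphs, germline constraint and variation burden (LOEUF, damaging variants
and structural variants per coding bp), and essentiality across cell-line
knockdown/knockout screens.

Group comparisons use Fisher's exact test for categorical properties
(proportions) and the Wilcoxon rank-sum test for continuous properties
(distributions), with Benjamini-Hochberg correction within each property
across groups. For each (property, group) the effect size Δ — difference of
proportions or of medians, group minus rest — feeds a signed min-max
normalized property score:

    score(d) = sgn(Δ_d) * (|Δ_d| - min_t |Δ_t|) / (max_t |Δ_t| - min_t |Δ_t|)

where t ranges over all configured gene groups for that property. The score
is in [-1, 1]; the group with the largest |Δ| attains ±1 and the one with
the smallest attains 0. When all |Δ| are equal the formula is degenerate
(0/0) and all scores are defined as 0 ("no contrast").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_test, rank_sum_test

__all__ = [
    "GroupComparison",
    "PREMETAZOAN_CLADES",
    "DEFAULT_PROPERTY_TYPES",
    "flag_duplicates",
    "assign_origin",
    "expression_breadth",
    "network_metrics",
    "germline_burden",
    "flag_essential",
    "compare_groups",
    "normalized_property_score",
    "attach_scores",
]

#: Clades whose presence marks a gene as pre-metazoan (old).
PREMETAZOAN_CLADES = frozenset({"prokaryotes", "eukaryotes", "opisthokonts"})

#: Known clade vocabulary for ortholog presence tables.
KNOWN_CLADES = PREMETAZOAN_CLADES | {"metazoa", "vertebrates", "mammals", "primates"}

#: Property typing used by :func:`compare_groups` when no config overrides it.
DEFAULT_PROPERTY_TYPES: dict[str, str] = {
    "duplicated": "categorical",
    "premetazoan": "categorical",
    "in_complex": "categorical",
    "essential_any": "categorical",
    "n_tissues_expressed": "continuous",
    "n_tissues_protein": "continuous",
    "ppi_degree": "continuous",
    "ppi_betweenness": "continuous",
    "ppi_clustering": "continuous",
    "mirna_degree": "continuous",
    "mirna_betweenness": "continuous",
    "mirna_clustering": "continuous",
    "loeuf": "continuous",
    "germline_damaging_per_bp": "continuous",
    "sv_per_bp": "continuous",
    "essential_line_fraction": "continuous",
}


@dataclass(frozen=True)
class GroupComparison:
    property: str
    group: str
    delta: float
    test: str  # fisher_two_sided | wilcoxon_two_sided
    p_value: float
    fdr: float
    normalized_score: float = float("nan")


def flag_duplicates(
    pairwise_identity: Iterable[tuple[str, str, float]],
    genes: Iterable[str] | None = None,
    threshold: float = 0.60,
) -> dict[str, bool]:
    """Flag genes sharing at least ``threshold`` of their protein sequence
    with any other gene. The shared fraction is expected relative to the
    longer protein of the pair; pairs are unordered and self-pairs are
    ignored with a warning."""
    flagged: set[str] = set()
    seen: set[str] = set(genes or ())
    for a, b, frac in pairwise_identity:
        if a == b:
            warnings.warn(f"ignoring self-pair for gene {a}")
            continue
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"identity fraction {frac} for pair ({a}, {b}) not in [0,1]")
        seen.update((a, b))
        if frac >= threshold:
            flagged.update((a, b))
    return {g: g in flagged for g in sorted(seen)}


def assign_origin(
    ortholog_presence: Mapping[str, Iterable[str]],
    premetazoan_clades: frozenset = PREMETAZOAN_CLADES,
    known_clades: frozenset = KNOWN_CLADES,
) -> dict[str, bool]:
    """Pre-metazoan (evolutionarily old) iff the gene has orthologs in any
    pre-metazoan clade."""
    out = {}
    for gene, clades in ortholog_presence.items():
        clades = set(clades)
        unknown = clades - known_clades
        if unknown:
            raise ValueError(f"unknown clade label(s) {sorted(unknown)} for gene {gene}")
        out[gene] = bool(clades & premetazoan_clades)
    return out


def expression_breadth(tpm: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Number of tissues in which each gene is expressed (TPM >= threshold,
    inclusive). ``tpm`` is a genes x tissues matrix."""
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return (tpm >= threshold).sum(axis=1)


def network_metrics(edges: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Degree, betweenness, and local clustering coefficient per node.

    The edge list is read as a simple undirected graph; self-loops and
    duplicate edges are dropped with a warning. Betweenness is unnormalized
    shortest-path betweenness with endpoints excluded and fractional credit
    over equally short paths. Clustering is undefined (NaN) for nodes of
    degree < 2.
    """
    g = nx.Graph()
    dropped = 0
    for u, v in edges:
        if u == v or g.has_edge(u, v):
            dropped += 1
            continue
        g.add_edge(u, v)
    if dropped:
        warnings.warn(f"dropped {dropped} self-loop/duplicate edge(s)")
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["degree", "betweenness", "clustering"])
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False, endpoints=False)
    clustering = nx.clustering(g)
    rows = {
        n: (degree[n], betweenness[n],
            clustering[n] if degree[n] >= 2 else float("nan"))
        for n in g.nodes
    }
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["degree", "betweenness", "clustering"])
    return df.sort_index()


def germline_burden(
    damaging_variant_counts: Mapping[str, int],
    sv_counts: Mapping[str, int],
    coding_length: Mapping[str, int],
) -> pd.DataFrame:
    """Per-bp germline damaging-variant and SV rates per gene."""
    genes = sorted(set(damaging_variant_counts) | set(sv_counts))
    rows = []
    for gene in genes:
        length = coding_length.get(gene)
        if length is None or length <= 0:
            raise ValueError(f"gene {gene} has missing or zero coding length")
        rows.append((gene,
                     damaging_variant_counts.get(gene, 0) / length,
                     sv_counts.get(gene, 0) / length))
    return pd.DataFrame(rows, columns=["gene", "germline_damaging_per_bp", "sv_per_bp"]
                        ).set_index("gene")


def flag_essential(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-gene essentiality from cell-line screen scores.

    ``scores`` columns: gene, cell_line, score_type (ceres | demeter |
    bayes), score. A gene is essential in a line when its CERES or DEMETER
    score is < -1 or its Bayes factor is > 5. Returns per-gene
    ``essential_line_fraction`` (over lines with data) and ``essential_any``.
    """
    unknown = set(scores["score_type"]) - {"ceres", "demeter", "bayes"}
    if unknown:
        raise ValueError(f"unknown score type(s): {sorted(unknown)}")
    s = scores.copy()
    s["essential"] = np.where(
        s["score_type"].isin(["ceres", "demeter"]),
        s["score"] < -1.0,
        s["score"] > 5.0,
    )
    per_line = s.groupby(["gene", "cell_line"])["essential"].any()
    frac = per_line.groupby("gene").mean().rename("essential_line_fraction")
    out = frac.to_frame()
    out["essential_any"] = out["essential_line_fraction"] > 0
    return out


def infer_property_types(table: pd.DataFrame) -> dict[str, str]:
    """Heuristic property typing for tables with undeclared columns:
    boolean or strictly 0/1 columns are categorical, numeric columns
    continuous. Declared defaults take precedence."""
    types: dict[str, str] = {}
    for col in table.columns:
        if col in DEFAULT_PROPERTY_TYPES:
            types[col] = DEFAULT_PROPERTY_TYPES[col]
            continue
        vals = table[col].dropna()
        if vals.dtype == bool or set(np.unique(vals)) <= {0, 1, True, False}:
            types[col] = "categorical"
        else:
            types[col] = "continuous"
    return types


def compare_groups(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    property_types: Mapping[str, str] | None = None,
    baseline: str | None = None,
) -> list[GroupComparison]:
    """Compare each gene group against the rest of genes for every property.

    ``table`` is genes x properties (index = gene); ``groups`` maps gene ->
    group label (genes absent from ``groups`` belong only to the "rest").
    A label equal to ``baseline`` names the rest-of-genes background: its
    genes enter every comparison's rest side but it is not compared against
    itself. Categorical properties use a two-sided Fisher's exact test on
    the 2x2 group/rest x has/has-not table and Δ = proportion difference;
    continuous properties use a two-sided Wilcoxon rank-sum test and Δ =
    median difference (group minus rest). FDR is corrected within each
    property across groups. Missing values are dropped per property.
    """
    types = dict(DEFAULT_PROPERTY_TYPES)
    if property_types:
        types.update(property_types)
    labels = sorted(set(groups.values()) - {baseline})
    results: list[GroupComparison] = []
    for prop in table.columns:
        ptype = types.get(prop)
        if ptype is None:
            raise ValueError(f"property {prop!r} has no declared type")
        col = table[prop].dropna()
        prop_rows: list[GroupComparison] = []
        for label in labels:
            members = [g for g in col.index if groups.get(g) == label]
            rest = [g for g in col.index if groups.get(g) != label]
            gvals = col.loc[members]
            rvals = col.loc[rest]
            if len(gvals) == 0 or len(rvals) == 0:
                warnings.warn(
                    f"property {prop}: group {label} empty after dropping missing; skipped")
                continue
            if ptype == "categorical":
                a = int(gvals.astype(bool).sum())
                b = len(gvals) - a
                c = int(rvals.astype(bool).sum())
                d = len(rvals) - c
                p = fisher_test([[a, b], [c, d]], alternative="two-sided")
                delta = a / len(gvals) - c / len(rvals)
                test = "fisher_two_sided"
            else:
                p = rank_sum_test(gvals.to_numpy(float), rvals.to_numpy(float))
                delta = float(np.median(gvals) - np.median(rvals))
                test = "wilcoxon_two_sided"
            prop_rows.append(GroupComparison(prop, label, delta, test, p, float("nan")))
        if prop_rows:
            fdrs = bh_adjust([r.p_value for r in prop_rows])
            prop_rows = [GroupComparison(r.property, r.group, r.delta, r.test,
                                         r.p_value, float(q))
                         for r, q in zip(prop_rows, fdrs)]
        results.extend(prop_rows)
    return results


def normalized_property_score(deltas: Mapping[str, float]) -> dict[str, float]:
    """Signed min-max rescaling of per-group effect sizes for one property.

    Requires at least two groups and finite Δ values. Returns 0 for every
    group when all |Δ| are equal (degenerate 0/0 case, no contrast).
    """
    if len(deltas) < 2:
        raise ValueError("normalized property score needs at least two groups")
    for group, d in deltas.items():
        if not math.isfinite(d):
            raise ValueError(f"non-finite delta for group {group}")
    mags = {g: abs(d) for g, d in deltas.items()}
    lo, hi = min(mags.values()), max(mags.values())
    if hi == lo:
        return {g: 0.0 for g in deltas}
    return {g: math.copysign(1.0, deltas[g]) * (mags[g] - lo) / (hi - lo)
            if mags[g] != lo else 0.0
            for g in deltas}


def attach_scores(
    comparisons: Sequence[GroupComparison],
    include_rest_baseline: bool = True,
) -> list[GroupComparison]:
    """Fill normalized scores across groups, property by property.

    The normalization roster per property is the compared groups plus, when
    ``include_rest_baseline`` is set, the rest-of-genes background whose
    effect against itself is 0 by construction (so min |Δ| is anchored at 0
    and each group's score is its |Δ| relative to the largest contrast).
    """
    by_prop: dict[str, list[GroupComparison]] = {}
    for c in comparisons:
        by_prop.setdefault(c.property, []).append(c)
    out: list[GroupComparison] = []
    for prop, rows in by_prop.items():
        deltas = {r.group: r.delta for r in rows}
        if include_rest_baseline:
            deltas["__rest__"] = 0.0
        if len(deltas) >= 2:
            scores = normalized_property_score(deltas)
        else:
            scores = {r.group: 0.0 for r in rows}
        out.extend(GroupComparison(r.property, r.group, r.delta, r.test,
                                   r.p_value, r.fdr, scores[r.group])
                   for r in rows)
    return out
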