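"""Curated driver catalog: canonical-source merging, driver-group
classification, non-coding support levels, and organ-system summaries.

The catalog distinguishes five mutually exclusive driver groups:

* ``canonical_cancer`` — experimentally validated cancer drivers present in
  at least one canonical reference source;
* ``candidate_cancer`` — genes with only statistical support from cancer
  sequencing screens;
* ``canonical_healthy`` / ``candidate_healthy`` — drivers of somatic clonal
  expansion in non-cancer tissue that are also canonical / candidate cancer
  drivers;
* ``healthy_only`` — healthy drivers with no cancer involvement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "DriverRecord",
    "ScreenRecord",
    "OrganSystemSummary",
    "normalize_symbol",
    "merge_canonical_sources",
    "classify_driver_groups",
    "assign_noncoding_support_level",
    "summarize_by_organ_system",
]

DRIVER_GROUPS = (
    "canonical_cancer",
    "candidate_cancer",
    "canonical_healthy",
    "candidate_healthy",
    "healthy_only",
)
MODES_OF_ACTION = ("tsg", "og", "dual", "unclassified")
VERDICTS = ("keep_canonical", "keep_candidate", "remove", "not_listed")


@dataclass
class DriverRecord:
    """One gene's curated annotation."""

    gene: str
    canonical_sources: frozenset = frozenset()
    screens: tuple = ()
    driver_group: str = "candidate_cancer"
    mode_of_action: str = "unclassified"
    coding_support: bool = True
    noncoding_support: bool = False
    experimental_noncoding_evidence: bool = False
    false_positive_verdict: str = "not_listed"

    def __post_init__(self) -> None:
        if self.driver_group not in DRIVER_GROUPS:
            raise ValueError(f"unknown driver group {self.driver_group!r}")
        if self.mode_of_action not in MODES_OF_ACTION:
            raise ValueError(f"unknown mode of action {self.mode_of_action!r}")
        if self.false_positive_verdict not in VERDICTS:
            raise ValueError(
                f"unknown false-positive verdict {self.false_positive_verdict!r}")


@dataclass
class ScreenRecord:
    """One sequencing screen (cancer or non-cancer)."""

    screen_id: str
    kind: str  # cancer | non_cancer
    assay: str  # wgs | wes | targeted
    region: str  # coding | noncoding
    tissue: str
    cancer_type: str | None
    n_donors: int
    organ_system: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("cancer", "non_cancer"):
            raise ValueError(f"unknown screen kind {self.kind!r}")
        if self.n_donors < 0:
            raise ValueError("n_donors must be non-negative")
        if self.kind == "cancer" and not self.cancer_type:
            raise ValueError(f"cancer screen {self.screen_id} lacks a cancer_type")


@dataclass
class OrganSystemSummary:
    organ_system: str
    n_canonical: int
    n_candidate: int
    n_healthy: int
    n_donors: int
    fraction_canonical_recovered: float
    fraction_noncoding: float
    genes: frozenset = field(default=frozenset(), repr=False)


def normalize_symbol(symbol: str) -> str:
    """Canonical gene key: uppercase, surrounding whitespace stripped."""
    return symbol.strip().upper()


def merge_canonical_sources(
    source_lists: Mapping[str, Iterable[str]],
    false_positive_table: Mapping[str, str] | None = None,
    fusion_list: Iterable[str] = (),
) -> tuple[dict[str, DriverRecord], set[str], dict[int, int]]:
    """Merge canonical driver sources into one curated canonical set.

    Parameters
    ----------
    source_lists
        Mapping source name -> iterable of gene symbols (three sources in the
        reference configuration, but any number >= 1 is accepted).
    false_positive_table
        Gene -> verdict for genes flagged as possible false positives during
        curation. ``remove`` drops the gene entirely, ``keep_candidate``
        demotes it out of the canonical set, ``keep_canonical`` retains it.
    fusion_list
        Genes acting through gene fusion, excluded because their properties
        cannot be mapped.

    Returns
    -------
    (canonical, demoted_candidates, overlap_histogram)
        ``canonical`` maps gene -> DriverRecord; ``demoted_candidates`` holds
        verdict=keep_candidate genes; the histogram counts canonical genes by
        the number of sources listing them (keys 1..n_sources partition the
        canonical set).
    """
    false_positive_table = dict(false_positive_table or {})
    for gene, verdict in list(false_positive_table.items()):
        if verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {verdict!r} for gene {gene}")

    membership: dict[str, set[str]] = {}
    for source, genes in source_lists.items():
        seen_here: set[str] = set()
        for raw in genes:
            g = normalize_symbol(raw)
            if g in seen_here:
                raise ValueError(
                    f"conflicting duplicate rows for gene {g} in source {source}")
            seen_here.add(g)
            membership.setdefault(g, set()).add(source)

    fusion = {normalize_symbol(g) for g in fusion_list}
    verdicts = {normalize_symbol(g): v for g, v in false_positive_table.items()}

    canonical: dict[str, DriverRecord] = {}
    demoted: set[str] = set()
    histogram: Counter[int] = Counter()
    for gene in sorted(membership):
        if gene in fusion:
            continue
        verdict = verdicts.get(gene, "not_listed")
        if verdict == "remove":
            continue
        if verdict == "keep_candidate":
            demoted.add(gene)
            continue
        n_sources = len(membership[gene])
        canonical[gene] = DriverRecord(
            gene=gene,
            canonical_sources=frozenset(membership[gene]),
            driver_group="canonical_cancer",
            false_positive_verdict=verdict,
        )
        histogram[n_sources] += 1
    return canonical, demoted, dict(histogram)


def classify_driver_groups(
    canonical: Iterable[str],
    screen_drivers: Mapping[str, Iterable[str]],
    healthy_drivers: Iterable[str],
) -> tuple[dict[str, str], set[str]]:
    """Assign every gene exactly one driver group.

    ``screen_drivers`` maps gene -> ids of the cancer screens that reported
    it. A healthy driver also in the canonical set becomes
    ``canonical_healthy``; one reported only by cancer screens becomes
    ``candidate_healthy``; one with no cancer involvement ``healthy_only``.
    Non-healthy genes split into ``canonical_cancer`` / ``candidate_cancer``.
    Canonical genes never reported by any screen are additionally returned as
    the *undetected* set (they keep their canonical group).
    """
    canon = {normalize_symbol(g) for g in canonical}
    screens = {normalize_symbol(g): set(s) for g, s in screen_drivers.items() if s}
    healthy = {normalize_symbol(g) for g in healthy_drivers}

    groups: dict[str, str] = {}
    for gene in canon | set(screens) | healthy:
        if gene in healthy:
            if gene in canon:
                groups[gene] = "canonical_healthy"
            elif gene in screens:
                groups[gene] = "candidate_healthy"
            else:
                groups[gene] = "healthy_only"
        else:
            groups[gene] = "canonical_cancer" if gene in canon else "candidate_cancer"
    undetected = {g for g in canon if g not in screens}
    return groups, undetected


def assign_noncoding_support_level(
    gene: str,
    noncoding_screen_hits: int,
    experimental_evidence: bool = False,
    is_canonical: bool = False,
) -> int:
    """Support level (1-4) for a gene backed only by non-coding screens.

    Level equals the number of screens reporting the gene, capped at 4;
    experimental evidence or canonical status raises the level to at least 2.
    """
    if noncoding_screen_hits < 1:
        raise ValueError(
            f"gene {gene} has no non-coding screen hits; not a non-coding-only driver")
    level = min(int(noncoding_screen_hits), 4)
    if experimental_evidence or is_canonical:
        level = max(level, 2)
    return level


def summarize_by_organ_system(
    records: Mapping[str, DriverRecord],
    screens: Sequence[ScreenRecord],
    screen_genes: Mapping[str, Iterable[str]],
    organ_map: Mapping[str, str],
    healthy_genes: Iterable[str] = (),
    n_canonical_total: int | None = None,
) -> tuple[list[OrganSystemSummary], dict[str, float], tuple[float, float]]:
    """Aggregate drivers and donors by organ system.

    ``screen_genes`` maps screen_id -> genes the screen reported. Genes are
    de-duplicated within an organ system across its screens. Returns the
    per-organ summaries, medians of the per-organ canonical / candidate /
    healthy counts, and the Spearman correlation (rho, p) between donor and
    driver counts across organ systems.
    """
    healthy = {normalize_symbol(g) for g in healthy_genes}
    canonical_all = {g for g, r in records.items()
                     if r.driver_group in ("canonical_cancer", "canonical_healthy")}
    denom = n_canonical_total if n_canonical_total is not None else len(canonical_all)

    by_organ: dict[str, dict] = {}
    for screen in screens:
        organ = screen.organ_system or organ_map.get(screen.tissue)
        if organ is None:
            raise ValueError(f"tissue {screen.tissue!r} has no organ-system mapping")
        slot = by_organ.setdefault(
            organ, {"genes": set(), "noncoding": set(), "donors": 0})
        genes = {normalize_symbol(g) for g in screen_genes.get(screen.screen_id, ())}
        slot["genes"] |= genes
        if screen.region == "noncoding":
            slot["noncoding"] |= genes
        slot["donors"] += screen.n_donors

    summaries: list[OrganSystemSummary] = []
    for organ in sorted(by_organ):
        slot = by_organ[organ]
        genes = slot["genes"]
        n_canon = len(genes & canonical_all)
        n_healthy = len(genes & healthy)
        n_cand = len(genes - canonical_all - healthy)
        noncoding_only = slot["noncoding"] - (genes - slot["noncoding"])
        summaries.append(OrganSystemSummary(
            organ_system=organ,
            n_canonical=n_canon,
            n_candidate=n_cand,
            n_healthy=n_healthy,
            n_donors=slot["donors"],
            fraction_canonical_recovered=(n_canon / denom) if denom else 0.0,
            fraction_noncoding=(len(noncoding_only) / len(genes)) if genes else 0.0,
            genes=frozenset(genes),
        ))

    medians = {
        "canonical": float(np.median([s.n_canonical for s in summaries])) if summaries else float("nan"),
        "candidate": float(np.median([s.n_candidate for s in summaries])) if summaries else float("nan"),
        "healthy": float(np.median([s.n_healthy for s in summaries])) if summaries else float("nan"),
    }
    if len(summaries) >= 2:
        donors = [s.n_donors for s in summaries]
        drivers = [len(s.genes) for s in summaries]
        if len(set(donors)) < 2 or len(set(drivers)) < 2:
            spearman = (float("nan"), float("nan"))  # constant input: undefined
        else:
            rho, p = sps.spearmanr(donors, drivers)
            spearman = (float(rho), float(p))
    else:
        spearman = (float("nan"), float("nan"))
    return summaries, medians, spearman
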