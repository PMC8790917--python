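"""Per-(gene, sample) somatic alteration classification.

The pipeline integrates three data layers per tumor sample — small mutations
(SNVs/indels with precomputed damaging-predictor votes and hotspot flags),
copy-number segments with sample ploidy/purity, and expression (FPKM) — and
labels each damaged (gene, sample) pair as loss-of-function (LoF) or
gain-of-function (GoF):

* LoF — homozygous deletion; truncating, damaging missense or damaging
  splicing mutation; or a double hit (heterozygous loss, CN = 1, combined
  with a LoF damaging mutation).
* GoF — hotspot mutation, or copy-number gain (CN > 2x sample ploidy) whose
  expression is significantly raised relative to samples without the gain.

Per gene, the prevalence of LoF vs GoF across samples yields a putative
tumor-suppressor / oncogene role.

Two threshold presets are provided: ``tcga`` (tumor samples with purity
correction) and ``cell_line`` (ploidy-relative deletion bands, TPM units).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .stats import bh_adjust, rank_sum_test

__all__ = [
    "MutationRecord",
    "SampleProfile",
    "GeneCN",
    "AlterationCall",
    "RoleCall",
    "Thresholds",
    "PRESETS",
    "classify_mutation",
    "map_segments_to_genes",
    "call_cnv_state",
    "filter_gains_by_expression",
    "assign_alterations",
    "infer_putative_role",
    "sample_driver_burden",
    "compare_alteration_counts",
    "naive_hotspots",
]

EFFECT_CLASSES = ("stopgain", "stoploss", "frameshift", "missense", "splicing", "other")
TRUNCATING = ("stopgain", "stoploss", "frameshift")
LOF_EVIDENCE = ("truncating", "missense_damaging", "splicing_damaging",
                "homozygous_deletion", "double_hit")
GOF_EVIDENCE = ("hotspot", "gain_with_expression")


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene: str
    effect_class: str
    missense_damaging_votes: int = 0
    splicing_damaging_votes: int = 0
    hotspot_flag: bool = False
    protein_position: int | None = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if not 0 <= self.missense_damaging_votes <= 10:
            raise ValueError("missense damaging votes must be in 0..10")
        if not 0 <= self.splicing_damaging_votes <= 2:
            raise ValueError("splicing damaging votes must be in 0..2")


@dataclass(frozen=True)
class SampleProfile:
    sample_id: str
    ploidy: float
    purity: float
    fpkm: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")


@dataclass(frozen=True)
class GeneCN:
    sample_id: str
    gene: str
    cn: float
    covered_fraction: float


@dataclass(frozen=True)
class AlterationCall:
    sample_id: str
    gene: str
    category: str  # lof | gof
    evidence: frozenset

    def __post_init__(self) -> None:
        if self.category not in ("lof", "gof"):
            raise ValueError(f"unknown category {self.category!r}")
        if not self.evidence:
            raise ValueError("evidence must be non-empty")
        allowed = LOF_EVIDENCE if self.category == "lof" else GOF_EVIDENCE
        bad = set(self.evidence) - set(allowed)
        if bad:
            raise ValueError(f"evidence {bad} inconsistent with category {self.category}")


@dataclass(frozen=True)
class RoleCall:
    gene: str
    n_lof_samples: int
    n_gof_samples: int
    putative_role: str


@dataclass(frozen=True)
class Thresholds:
    """Rule constants for the alteration classifier."""

    missense_votes_min: int = 7
    splicing_votes_min: int = 1
    min_covered_fraction: float = 0.25
    gain_ploidy_multiplier: float = 2.0
    cn_tolerance: float = 0.1        # slack when testing CN "= 0" and "= 1"
    expression_cutoff: float = 1.0   # FPKM/purity (tcga) or TPM (cell_line)
    fdr_level: float = 0.05
    # cell-line deletion bands, as multiples of ploidy
    homdel_ploidy_max: float | None = None   # CN < this x ploidy -> homozygous
    hetdel_ploidy_range: tuple[float, float] | None = None
    purity_correction: bool = True


PRESETS: dict[str, Thresholds] = {
    "tcga": Thresholds(),
    "cell_line": Thresholds(
        homdel_ploidy_max=0.25,
        hetdel_ploidy_range=(0.25, 0.75),
        purity_correction=False,
    ),
}


def classify_mutation(m: MutationRecord, thresholds: Thresholds | None = None) -> str:
    """Classify one mutation as ``lof_damaging``, ``gof_hotspot`` or
    ``not_damaging``.

    Hotspot flags take precedence: a hotspot-flagged mutation is GoF even if
    its predictor votes would also make it LoF damaging.
    """
    t = thresholds or PRESETS["tcga"]
    if m.hotspot_flag:
        return "gof_hotspot"
    if m.effect_class in TRUNCATING:
        return "lof_damaging"
    if m.effect_class == "missense" and m.missense_damaging_votes >= t.missense_votes_min:
        return "lof_damaging"
    if m.effect_class == "splicing" and m.splicing_damaging_votes >= t.splicing_votes_min:
        return "lof_damaging"
    return "not_damaging"


def _mutation_evidence(m: MutationRecord, thresholds: Thresholds | None = None) -> str | None:
    t = thresholds or PRESETS["tcga"]
    if m.effect_class in TRUNCATING:
        return "truncating"
    if m.effect_class == "missense" and m.missense_damaging_votes >= t.missense_votes_min:
        return "missense_damaging"
    if m.effect_class == "splicing" and m.splicing_damaging_votes >= t.splicing_votes_min:
        return "splicing_damaging"
    return None


def map_segments_to_genes(
    segments: pd.DataFrame,
    gene_models: pd.DataFrame,
    min_covered_fraction: float = 0.25,
) -> list[GeneCN]:
    """Intersect copy-number segments with gene transcribed coordinates.

    ``segments`` columns: sample, chrom, start, end, cn (0-based half-open).
    ``gene_models`` columns: gene, chrom, start, end — one row per transcribed
    block; multiple rows per gene are summed.

    A gene is assigned a copy number in a sample only when at least
    ``min_covered_fraction`` of its transcribed length is covered by
    segments; the CN is the coverage-weighted mean over covered bases.
    """
    lengths: dict[str, int] = defaultdict(int)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for row in gene_models.itertuples(index=False):
        if row.end <= row.start:
            raise ValueError(f"gene {row.gene} has a zero or negative-length block")
        lengths[row.gene] += row.end - row.start
        trees[row.chrom].addi(row.start, row.end, row.gene)
    for gene, length in lengths.items():
        if length <= 0:
            raise ValueError(f"gene {gene} has zero transcribed length")

    acc: dict[tuple[str, str], list[float]] = defaultdict(lambda: [0.0, 0.0])
    for seg in segments.itertuples(index=False):
        tree = trees.get(seg.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(seg.start, seg.end):
            bp = min(seg.end, iv.end) - max(seg.start, iv.begin)
            slot = acc[(seg.sample, iv.data)]
            slot[0] += bp
            slot[1] += bp * seg.cn

    out: list[GeneCN] = []
    for (sample, gene), (covered, cn_bp) in sorted(acc.items()):
        frac = covered / lengths[gene]
        if frac >= min_covered_fraction:
            out.append(GeneCN(sample_id=sample, gene=gene,
                              cn=cn_bp / covered, covered_fraction=min(frac, 1.0)))
    return out


def call_cnv_state(g: GeneCN, profile: SampleProfile,
                   thresholds: Thresholds | None = None) -> str:
    """Call the copy-number state of one gene in one sample.

    Tumor (``tcga``) rules: gain candidate when CN > 2x ploidy; homozygous
    loss when CN = 0 and FPKM/purity < 1; heterozygous loss when CN = 1, or
    CN = 0 with FPKM/purity > 1 (expression rescues the call); else neutral.
    CN equality is tested with ``cn_tolerance`` slack because gene-level CN
    is a weighted mean of fractional segment values.

    Cell-line rules replace the loss calls with ploidy-relative bands
    (homozygous: CN < 0.25x ploidy and expression < 1 TPM; heterozygous:
    0.25-0.75x ploidy).
    """
    t = thresholds or PRESETS["tcga"]
    if g.cn > t.gain_ploidy_multiplier * profile.ploidy:
        return "gain_candidate"
    if t.homdel_ploidy_max is not None:
        # cell-line style ploidy-relative bands
        lo, hi = t.hetdel_ploidy_range
        if g.cn < t.homdel_ploidy_max * profile.ploidy:
            expr = profile.fpkm.get(g.gene)
            if expr is None:
                raise ValueError(
                    f"missing expression for {g.gene} in {g.sample_id} at low CN")
            if expr < t.expression_cutoff:
                return "homozygous_loss"
            return "heterozygous_loss"
        if lo * profile.ploidy <= g.cn < hi * profile.ploidy:
            return "heterozygous_loss"
        return "neutral"
    if g.cn <= t.cn_tolerance:  # CN = 0
        expr = profile.fpkm.get(g.gene)
        if expr is None:
            raise ValueError(
                f"missing expression for {g.gene} in {g.sample_id} at CN=0")
        corrected = expr / profile.purity if t.purity_correction else expr
        if corrected < t.expression_cutoff:
            return "homozygous_loss"
        if corrected > t.expression_cutoff:
            return "heterozygous_loss"
        return "neutral"
    if abs(g.cn - 1.0) <= t.cn_tolerance:  # CN = 1
        return "heterozygous_loss"
    return "neutral"


def filter_gains_by_expression(
    gain_candidates: Mapping[str, Iterable[str]],
    expression: pd.DataFrame,
    fdr_level: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Retain gene gains whose expression is significantly raised.

    ``gain_candidates`` maps gene -> samples carrying the candidate gain;
    ``expression`` is a genes x samples FPKM matrix. Per gene, expression in
    gain vs non-gain samples is compared with a two-sided Wilcoxon rank-sum
    test; Benjamini-Hochberg is applied across all tested genes and a gene's
    gains are kept iff FDR < ``fdr_level`` and the gain-group median is the
    higher one.

    Returns the set of retained genes and the per-gene test table.
    """
    rows = []
    for gene in sorted(gain_candidates):
        if gene not in expression.index:
            continue
        gain_samples = [s for s in gain_candidates[gene] if s in expression.columns]
        rest = [s for s in expression.columns if s not in set(gain_samples)]
        if not gain_samples or not rest:
            import warnings
            warnings.warn(f"gene {gene}: empty gain or non-gain group; skipped")
            continue
        gv = expression.loc[gene, gain_samples].to_numpy(dtype=float)
        rv = expression.loc[gene, rest].to_numpy(dtype=float)
        rows.append((gene, rank_sum_test(gv, rv),
                     float(np.median(gv)), float(np.median(rv))))
    table = pd.DataFrame(rows, columns=["gene", "p_value", "gain_median", "rest_median"])
    if table.empty:
        table["fdr"] = []
        table["retained"] = []
        return set(), table
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["retained"] = (table["fdr"] < fdr_level) & (table["gain_median"] > table["rest_median"])
    return set(table.loc[table["retained"], "gene"]), table


def assign_alterations(
    mutations: Sequence[MutationRecord],
    cnv_states: Mapping[tuple[str, str], str],
    retained_gains: Iterable[str] = (),
    thresholds: Thresholds | None = None,
    gene_cn: Mapping[tuple[str, str], float] | None = None,
) -> list[AlterationCall]:
    """Combine mutation and copy-number evidence into LoF/GoF calls.

    ``cnv_states`` maps (gene, sample) -> state from :func:`call_cnv_state`;
    ``retained_gains`` holds the genes whose gain candidates passed the
    expression filter. A double hit requires a heterozygous loss at CN = 1
    (checked against ``gene_cn`` when provided, with the preset's CN
    tolerance) together with a LoF damaging mutation. A (gene, sample) pair
    with both LoF and GoF evidence yields two calls, one per category.
    """
    t = thresholds or PRESETS["tcga"]
    retained = set(retained_gains)
    lof_ev: dict[tuple[str, str], set[str]] = defaultdict(set)
    gof_ev: dict[tuple[str, str], set[str]] = defaultdict(set)

    for m in mutations:
        key = (m.gene, m.sample_id)
        cls = classify_mutation(m, t)
        if cls == "gof_hotspot":
            gof_ev[key].add("hotspot")
        # a hotspot mutation may still carry damaging votes; those votes are
        # not double-counted as LoF for the same record (hotspot precedence),
        # but other records for the pair can contribute LoF evidence
        elif cls == "lof_damaging":
            lof_ev[key].add(_mutation_evidence(m, t))

    for (gene, sample), state in cnv_states.items():
        key = (gene, sample)
        if state == "homozygous_loss":
            lof_ev[key].add("homozygous_deletion")
        elif state == "heterozygous_loss":
            cn_ok = True
            if gene_cn is not None and key in gene_cn:
                cn_ok = abs(gene_cn[key] - 1.0) <= t.cn_tolerance
            if cn_ok and lof_ev[key] & {"truncating", "missense_damaging", "splicing_damaging"}:
                lof_ev[key].add("double_hit")
        elif state == "gain_candidate" and gene in retained:
            gof_ev[key].add("gain_with_expression")

    calls: list[AlterationCall] = []
    for (gene, sample), ev in sorted(lof_ev.items()):
        if ev:
            calls.append(AlterationCall(sample, gene, "lof", frozenset(ev)))
    for (gene, sample), ev in sorted(gof_ev.items()):
        if ev:
            calls.append(AlterationCall(sample, gene, "gof", frozenset(ev)))
    return calls


def infer_putative_role(calls: Iterable[AlterationCall],
                        genes: Iterable[str] | None = None) -> list[RoleCall]:
    """Classify each gene by its prevalent alteration category.

    Counts distinct samples per category; a strict majority of LoF samples
    gives ``putative_tsg``, of GoF samples ``putative_og``; ties (including
    0 vs 0) stay ``unclassified``. ``genes`` extends the roster beyond the
    genes with calls (an undamaged gene is a 0-vs-0 tie).
    """
    lof: dict[str, set[str]] = defaultdict(set)
    gof: dict[str, set[str]] = defaultdict(set)
    genes = set(genes or ())
    for c in calls:
        genes.add(c.gene)
        (lof if c.category == "lof" else gof)[c.gene].add(c.sample_id)
    out = []
    for gene in sorted(genes):
        nl, ng = len(lof[gene]), len(gof[gene])
        role = "putative_tsg" if nl > ng else "putative_og" if ng > nl else "unclassified"
        out.append(RoleCall(gene, nl, ng, role))
    return out


def sample_driver_burden(
    calls: Iterable[AlterationCall],
    all_samples: Iterable[str],
    catalog_genes: Iterable[str],
    canonical_genes: Iterable[str] = (),
    healthy_genes: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-sample damaged-driver counts and cohort burden fractions.

    A gene counts once per sample regardless of how many calls it has.
    Fractions reported over all samples in ``all_samples``:

    * ``frac_lt5_all`` — samples with < 5 damaged catalog drivers;
    * ``frac_lt5_canonical`` — same restricted to canonical drivers;
    * ``frac_zero`` — samples with no damaged driver;
    * ``frac_ge2_with_healthy`` — samples with >= 2 damaged drivers of which
      at least one is a healthy driver.
    """
    catalog = set(catalog_genes)
    canonical = set(canonical_genes)
    healthy = set(healthy_genes)
    samples = sorted(set(all_samples))
    damaged: dict[str, set[str]] = {s: set() for s in samples}
    for c in calls:
        if c.gene in catalog and c.sample_id in damaged:
            damaged[c.sample_id].add(c.gene)

    rows = []
    for s in samples:
        genes = damaged[s]
        rows.append((s, len(genes), len(genes & canonical), len(genes & healthy)))
    df = pd.DataFrame(rows, columns=["sample", "n_drivers", "n_canonical", "n_healthy"])
    n = len(df)
    fractions = {
        "frac_lt5_all": float((df["n_drivers"] < 5).mean()) if n else float("nan"),
        "frac_lt5_canonical": float((df["n_canonical"] < 5).mean()) if n else float("nan"),
        "frac_zero": float((df["n_drivers"] == 0).mean()) if n else float("nan"),
        "frac_ge2_with_healthy": float(
            ((df["n_drivers"] >= 2) & (df["n_healthy"] >= 1)).mean()) if n else float("nan"),
    }
    return df, fractions


def compare_alteration_counts(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two per-gene sample-count
    distributions (exact for small tie-free groups, tie-corrected normal
    approximation otherwise)."""
    return rank_sum_test(group_a, group_b)


def naive_hotspots(
    mutations: Sequence[MutationRecord], min_samples: int = 3
) -> list[MutationRecord]:
    """Fallback hotspot annotation when no clustering-based flags exist.

    Flags exonic mutations at a (gene, protein position) mutated in at least
    ``min_samples`` distinct samples cohort-wide. This is a deliberately
    simple recurrence rule, not a positional-clustering method; calls made
    from it should be treated as provisional.
    """
    pos_samples: dict[tuple[str, int], set[str]] = defaultdict(set)
    for m in mutations:
        if m.protein_position is not None and m.effect_class != "splicing":
            pos_samples[(m.gene, m.protein_position)].add(m.sample_id)
    hot = {k for k, v in pos_samples.items() if len(v) >= min_samples}
    out = []
    for m in mutations:
        if (m.protein_position is not None
                and (m.gene, m.protein_position) in hot
                and m.effect_class != "splicing"):
            out.append(replace(m, hotspot_flag=True))
        else:
            out.append(m)
    return out
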