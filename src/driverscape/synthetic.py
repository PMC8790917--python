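"""Seeded synthetic-data generators for every pipeline stage.

The cohort generator emulates a pan-cancer collection with planted tumor
suppressors (truncating mutations, homozygous deletions, double hits),
planted oncogenes (hotspot mutations, copy-number gains with raised
expression), and passenger genes carrying only non-damaging background
mutations. The property generator plants median/proportion shifts between
gene groups on top of unimodal baselines. The catalog generator constructs
source lists and screen hits whose driver-group classification is known by
design.

All generators are pure functions of their spec (seed included): the same
spec yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "PropertySpec", "generate_cohort",
           "generate_property_tables", "generate_catalog_fixture",
           "generate_pathways"]

#: Transcribed length of every synthetic gene (bp).
GENE_LENGTH = 1000
#: Spacing between synthetic gene starts (bp); keeps CNV segments
#: non-overlapping per sample.
GENE_SPACING = 2000


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic tumor cohort.

    Defaults follow the reference configuration used throughout the test
    suite: 500 samples, 200 tumor suppressors, 200 oncogenes, 1600
    passengers, with per-sample event probabilities sized so planted genes
    are damaged in tens of samples while passengers stay quiet.
    """

    n_samples: int = 500
    n_tsg: int = 200
    n_og: int = 200
    n_passenger: int = 1600
    p_truncating: float = 0.06
    p_homdel: float = 0.04
    p_hetloss: float = 0.04
    p_hotspot: float = 0.06
    p_gain: float = 0.05
    gain_expression_logfc: float = 1.5
    background_mutation_rate: float = 0.01
    ploidy_mean: float = 2.0
    purity_range: tuple[float, float] = (0.5, 0.95)
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_truncating", "p_homdel", "p_hetloss", "p_hotspot",
                     "p_gain", "background_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if min(self.n_samples, self.n_tsg, self.n_og, self.n_passenger) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_samples == 0 and (self.n_tsg or self.n_og or self.n_passenger):
            raise ValueError("cannot plant genes in a cohort with zero samples")
        if self.gain_expression_logfc <= 0:
            raise ValueError("gain_expression_logfc must be positive")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class PropertySpec:
    """Study conditions for synthetic per-gene property tables."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"drivers": 100, "rest": 1000})
    planted_shifts: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("drivers", "score_a"): 1.0})
    noise_sd: float = 1.0
    continuous_properties: tuple[str, ...] = ("score_a", "score_b")
    categorical_properties: tuple[str, ...] = ("flag_a",)
    categorical_baseline: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        props = set(self.continuous_properties) | set(self.categorical_properties)
        for (group, prop), shift in self.planted_shifts.items():
            if group not in self.group_sizes:
                raise ValueError(f"planted shift for unknown group {group!r}")
            if prop not in props:
                raise ValueError(f"planted shift for unknown property {prop!r}")
            if prop in self.categorical_properties:
                p = self.categorical_baseline + shift
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"proportion offset {shift} pushes {prop} outside [0, 1]")


def _gene_names(spec: CohortSpec) -> tuple[list[str], list[str], list[str]]:
    tsg = [f"TSG{i:04d}" for i in range(spec.n_tsg)]
    og = [f"OG{i:04d}" for i in range(spec.n_og)]
    psg = [f"PSG{i:04d}" for i in range(spec.n_passenger)]
    return tsg, og, psg


def generate_cohort(spec: CohortSpec) -> dict[str, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns a dict of DataFrames: ``mutations`` (sample, gene, effect_class,
    missense_votes, splicing_votes, hotspot, protein_pos), ``segments``
    (sample, chrom, start, end, cn; 0-based half-open), ``profiles``
    (sample, ploidy, purity), ``expression`` (genes x samples FPKM),
    ``gene_models`` (gene, chrom, start, end) and ``truth`` (gene, role).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tsg, og, psg = _gene_names(spec)
    genes = tsg + og + psg
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]

    gene_models = pd.DataFrame({
        "gene": genes,
        "chrom": "chr1",
        "start": [i * GENE_SPACING for i in range(len(genes))],
        "end": [i * GENE_SPACING + GENE_LENGTH for i in range(len(genes))],
    })
    gene_start = dict(zip(genes, gene_models["start"]))

    ploidy = np.clip(rng.normal(spec.ploidy_mean, 0.1, spec.n_samples), 1.0, None)
    purity = rng.uniform(*spec.purity_range, spec.n_samples)
    profiles = pd.DataFrame({"sample": samples,
                             "ploidy": np.round(ploidy, 4),
                             "purity": np.round(purity, 4)})

    # log-normal FPKM baseline, per-gene log-mean around log(10)
    log_mu = rng.normal(np.log(10.0), 0.7, len(genes))
    expr = np.exp(log_mu[:, None] + rng.normal(0.0, 0.5, (len(genes), spec.n_samples)))

    mut_rows: list[tuple] = []
    seg_rows: list[tuple] = []
    gene_index = {g: i for i, g in enumerate(genes)}
    n = spec.n_samples

    for g in tsg:
        gi = gene_index[g]
        start, end = gene_start[g], gene_start[g] + GENE_LENGTH
        trunc = rng.random(n) < spec.p_truncating
        homdel = rng.random(n) < spec.p_homdel
        hetloss = rng.random(n) < spec.p_hetloss
        for si in np.flatnonzero(trunc):
            effect = ("stopgain", "frameshift", "stoploss")[int(rng.integers(3))]
            mut_rows.append((samples[si], g, effect, 0, 0, False,
                             int(rng.integers(1, GENE_LENGTH // 3))))
        for si in np.flatnonzero(homdel):
            seg_rows.append((samples[si], "chr1", start - 50, end + 50, 0.0))
            expr[gi, si] *= 0.01  # deleted genes are (nearly) silenced
        for si in np.flatnonzero(hetloss & ~homdel):
            seg_rows.append((samples[si], "chr1", start - 50, end + 50, 1.0))

    for g in og:
        gi = gene_index[g]
        start, end = gene_start[g], gene_start[g] + GENE_LENGTH
        hot_pos = 100 + (gi % 200)  # one recurrent protein position per gene
        hotspot = rng.random(n) < spec.p_hotspot
        gain = rng.random(n) < spec.p_gain
        for si in np.flatnonzero(hotspot):
            mut_rows.append((samples[si], g, "missense",
                             int(rng.integers(0, 7)), 0, True, hot_pos))
        for si in np.flatnonzero(gain):
            cn = round(2.0 * ploidy[si] + 1.0 + rng.uniform(0.0, 2.0), 3)
            seg_rows.append((samples[si], "chr1", start - 50, end + 50, cn))
            expr[gi, si] *= np.exp(spec.gain_expression_logfc)

    # non-damaging background noise over all genes
    if spec.background_mutation_rate > 0 and n > 0:
        counts = rng.binomial(n, spec.background_mutation_rate, len(genes))
        for gi, k in enumerate(counts):
            if k == 0:
                continue
            for si in rng.choice(n, size=k, replace=False):
                if rng.random() < 0.5:
                    mut_rows.append((samples[si], genes[gi], "other", 0, 0, False, None))
                else:
                    mut_rows.append((samples[si], genes[gi], "missense",
                                     int(rng.integers(0, 7)), 0, False,
                                     int(rng.integers(1, GENE_LENGTH // 3))))

    mutations = pd.DataFrame(
        mut_rows, columns=["sample", "gene", "effect_class", "missense_votes",
                           "splicing_votes", "hotspot", "protein_pos"])
    mutations = mutations.sort_values(["sample", "gene"], kind="stable",
                                      ignore_index=True)
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "cn"])
    segments = segments.sort_values(["sample", "start"], kind="stable",
                                    ignore_index=True)
    expression = pd.DataFrame(np.round(expr, 4), index=genes, columns=samples)
    expression.index.name = "gene"
    truth = pd.DataFrame({
        "gene": genes,
        "role": ["tsg"] * len(tsg) + ["og"] * len(og) + ["passenger"] * len(psg),
    })
    return {"mutations": mutations, "segments": segments, "profiles": profiles,
            "expression": expression, "gene_models": gene_models, "truth": truth}


def generate_property_tables(spec: PropertySpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a per-gene property table with planted group contrasts.

    Continuous properties are Normal(0, noise_sd) plus the planted offset for
    (group, property); categorical properties are Bernoulli at the baseline
    proportion plus the planted offset. Returns (table, gene -> group).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes: list[str] = []
    labels: list[str] = []
    for group in spec.group_sizes:
        size = spec.group_sizes[group]
        genes.extend(f"{group.upper()}_{i:05d}" for i in range(size))
        labels.extend([group] * size)
    groups = pd.Series(labels, index=genes, name="group")

    data: dict[str, np.ndarray] = {}
    for prop in spec.continuous_properties:
        vals = rng.normal(0.0, spec.noise_sd, len(genes))
        for i, group in enumerate(labels):
            shift = spec.planted_shifts.get((group, prop), 0.0)
            if shift:
                vals[i] += shift
        data[prop] = np.round(vals, 6)
    for prop in spec.categorical_properties:
        probs = np.array([
            spec.categorical_baseline + spec.planted_shifts.get((g, prop), 0.0)
            for g in labels])
        data[prop] = rng.random(len(genes)) < probs
    table = pd.DataFrame(data, index=genes)
    table.index.name = "gene"
    return table, groups


def generate_catalog_fixture(
    design: Mapping[str, int],
    seed: int = 0,
    n_screens: int = 4,
    n_undetected_canonical: int = 0,
) -> tuple[dict, dict[str, int]]:
    """Construct catalog inputs whose group classification is known.

    ``design`` maps driver-group name (canonical_cancer, candidate_cancer,
    canonical_healthy, candidate_healthy, healthy_only) to the number of
    genes. ``n_undetected_canonical`` canonical-cancer genes are kept out of
    every screen. Returns (inputs, expected_counts) where inputs holds
    ``canonical`` (set), ``screen_drivers`` (gene -> screen ids),
    ``healthy`` (set), and ``sources`` (three overlapping canonical source
    lists). Emission order is shuffled by the seed; classification must not
    depend on it.
    """
    valid = {"canonical_cancer", "candidate_cancer", "canonical_healthy",
             "candidate_healthy", "healthy_only"}
    unknown = set(design) - valid
    if unknown:
        raise ValueError(f"unknown driver group(s) in design: {sorted(unknown)}")
    if any(v < 0 for v in design.values()):
        raise ValueError("design counts must be non-negative")
    if n_undetected_canonical > design.get("canonical_cancer", 0):
        raise ValueError("more undetected canonical genes than canonical genes")

    rng = np.random.default_rng(seed)
    counter = 0
    members: dict[str, list[str]] = {}
    for group in sorted(design):
        members[group] = [f"G{counter + i:05d}" for i in range(design[group])]
        counter += design[group]

    canonical = set(members.get("canonical_cancer", ())) | set(
        members.get("canonical_healthy", ()))
    healthy = (set(members.get("canonical_healthy", ()))
               | set(members.get("candidate_healthy", ()))
               | set(members.get("healthy_only", ())))
    screened = (set(members.get("candidate_cancer", ()))
                | set(members.get("candidate_healthy", ()))
                | set(members.get("canonical_cancer", ())[n_undetected_canonical:])
                | set(members.get("canonical_healthy", ())))
    screen_ids = [f"SCR{i:02d}" for i in range(max(n_screens, 1))]
    screen_drivers = {
        g: set(rng.choice(screen_ids, size=int(rng.integers(1, len(screen_ids) + 1)),
                          replace=False))
        for g in sorted(screened)
    }

    # split the canonical set across three partially overlapping sources
    canon_list = sorted(canonical)
    rng.shuffle(canon_list)
    sources: dict[str, list[str]] = {"sourceA": [], "sourceB": [], "sourceC": []}
    names = list(sources)
    for g in canon_list:
        k = int(rng.integers(1, 4))
        for s in rng.choice(names, size=k, replace=False):
            sources[s].append(g)
    for s in sources:
        rng.shuffle(sources[s])

    inputs = {"canonical": canonical, "screen_drivers": screen_drivers,
              "healthy": healthy, "sources": sources}
    expected = {g: design.get(g, 0) for g in valid}
    return inputs, expected


def generate_pathways(truth: pd.DataFrame, seed: int = 0,
                      n_level1: int = 4, pathways_per_category: int = 3,
                      pathway_size: int = 40, driver_bias: float = 0.6):
    """Small synthetic pathway hierarchy for end-to-end pipeline runs.

    Builds ``n_level1`` level-1 categories each with level-2 child pathways.
    Children of the first category draw a fraction ``driver_bias`` of their
    genes from planted drivers so the driver set shows real enrichment.
    Returns (PathwayRecord list, hierarchy child->level1 mapping).
    """
    from .enrichment import PathwayRecord

    rng = np.random.default_rng(seed)
    drivers = truth.loc[truth["role"] != "passenger", "gene"].tolist()
    passengers = truth.loc[truth["role"] == "passenger", "gene"].tolist()
    records: list[PathwayRecord] = []
    hierarchy: dict[str, str] = {}
    for c in range(n_level1):
        level1 = f"CAT{c}"
        records.append(PathwayRecord(level1, f"Category {c}", 1, level1))
        hierarchy[level1] = level1
        for j in range(pathways_per_category):
            pid = f"PW{c}_{j}"
            size = min(pathway_size, max(2, (len(drivers) + len(passengers)) // 4))
            n_drv = int(size * driver_bias) if c == 0 else int(size * 0.05)
            n_drv = min(n_drv, len(drivers))
            n_psg = min(size - n_drv, len(passengers))
            picked = list(rng.choice(drivers, size=n_drv, replace=False)) + list(
                rng.choice(passengers, size=n_psg, replace=False))
            records.append(PathwayRecord(pid, f"Pathway {c}.{j}", 2, level1,
                                         frozenset(picked)))
            hierarchy[pid] = level1
    return records, hierarchy
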