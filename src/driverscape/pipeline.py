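"""End-to-end orchestration: cohort classification, role recovery, and the
synthetic demonstration pipeline chaining curation, alteration
classification, property comparison and pathway enrichment."""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import alterations as alt
from . import catalog as cat
from . import enrichment as enr
from . import properties as prop
from . import synthetic as syn

__all__ = ["classify_cohort", "role_recovery", "run_synthetic_pipeline"]


def _mutation_records(df: pd.DataFrame) -> list[alt.MutationRecord]:
    records = []
    for row in df.itertuples(index=False):
        pos = row.protein_pos
        if pos is None or (isinstance(pos, float) and np.isnan(pos)):
            pos = None
        else:
            pos = int(pos)
        records.append(alt.MutationRecord(
            sample_id=row.sample, gene=row.gene, effect_class=row.effect_class,
            missense_damaging_votes=int(row.missense_votes),
            splicing_damaging_votes=int(row.splicing_votes),
            hotspot_flag=bool(row.hotspot), protein_position=pos))
    return records


def classify_cohort(
    tables: Mapping[str, pd.DataFrame],
    thresholds: alt.Thresholds | None = None,
    fdr_level: float = 0.05,
    naive_hotspot_min: int | None = None,
) -> dict:
    """Run the full per-(gene, sample) alteration pipeline on one cohort.

    ``tables`` must provide ``mutations``, ``segments``, ``profiles``,
    ``expression`` and ``gene_models`` in the dialects produced by
    :mod:`driverscape.synthetic` / read by :mod:`driverscape.io`. When
    ``naive_hotspot_min`` is set, recurrence-based hotspot flags are added
    before classification (fallback when no precomputed flags exist).

    Returns a dict with ``calls``, ``roles``, ``cnv_states``, ``gene_cn``,
    ``gain_table`` and event totals.
    """
    t = thresholds or alt.PRESETS["tcga"]
    mutations = _mutation_records(tables["mutations"])
    if naive_hotspot_min is not None:
        mutations = alt.naive_hotspots(mutations, min_samples=naive_hotspot_min)

    gene_cn = alt.map_segments_to_genes(
        tables["segments"], tables["gene_models"], t.min_covered_fraction)
    expression = tables["expression"]
    base = {r.sample: (float(r.ploidy), float(r.purity))
            for r in tables["profiles"].itertuples(index=False)}

    # expression lookups are only needed for genes with a CN record in the
    # sample; build per-sample FPKM maps restricted to those genes
    needed: dict[str, set[str]] = defaultdict(set)
    for g in gene_cn:
        needed[g.sample_id].add(g.gene)
    profiles = {
        s: alt.SampleProfile(
            s, base[s][0], base[s][1],
            {g: float(expression.at[g, s]) for g in sorted(needed[s])
             if g in expression.index})
        for s in needed
    }

    cnv_states: dict[tuple[str, str], str] = {}
    gain_candidates: dict[str, set[str]] = defaultdict(set)
    for g in gene_cn:
        state = alt.call_cnv_state(g, profiles[g.sample_id], t)
        cnv_states[(g.gene, g.sample_id)] = state
        if state == "gain_candidate":
            gain_candidates[g.gene].add(g.sample_id)

    retained, gain_table = alt.filter_gains_by_expression(
        gain_candidates, expression, fdr_level)
    cn_map = {(g.gene, g.sample_id): g.cn for g in gene_cn}
    calls = alt.assign_alterations(mutations, cnv_states, retained, t, cn_map)
    roles = alt.infer_putative_role(calls)
    n_lof = sum(1 for c in calls if c.category == "lof")
    n_gof = sum(1 for c in calls if c.category == "gof")
    return {"calls": calls, "roles": roles, "cnv_states": cnv_states,
            "gene_cn": cn_map, "gain_table": gain_table,
            "n_lof_events": n_lof, "n_gof_events": n_gof,
            "n_events": n_lof + n_gof}


def role_recovery(roles, truth: pd.DataFrame, min_damaged: int = 10) -> dict:
    """Accuracy of putative-role inference against planted roles.

    Considers genes with at least ``min_damaged`` distinct damaged samples
    (LoF + GoF) and a planted tsg/og role; accuracy is the fraction whose
    putative role matches the planted one.
    """
    planted = dict(zip(truth["gene"], truth["role"]))
    expected = {"tsg": "putative_tsg", "og": "putative_og"}
    n_eval = n_correct = 0
    for r in roles:
        if r.n_lof_samples + r.n_gof_samples < min_damaged:
            continue
        want = expected.get(planted.get(r.gene, "passenger"))
        if want is None:
            continue
        n_eval += 1
        n_correct += r.putative_role == want
    return {"n_evaluated": n_eval,
            "accuracy": (n_correct / n_eval) if n_eval else float("nan")}


def run_synthetic_pipeline(
    seed: int = 0,
    preset: str = "tcga",
    fdr_level: float = 0.05,
    cohort_spec: syn.CohortSpec | None = None,
    property_spec: syn.PropertySpec | None = None,
) -> dict:
    """Full synthetic demonstration run: curate -> classify -> properties ->
    enrich, returning one JSON-serializable summary of headline statistics.

    Deterministic given (seed, specs): sub-seeds for each stage are derived
    from the master seed.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, 4)]

    # --- curation on a designed catalog fixture ---
    design = {"canonical_cancer": 120, "candidate_cancer": 300,
              "canonical_healthy": 15, "candidate_healthy": 10,
              "healthy_only": 5}
    inputs, expected = syn.generate_catalog_fixture(design, seed=sub[0],
                                                    n_undetected_canonical=8)
    groups, undetected = cat.classify_driver_groups(
        inputs["canonical"], inputs["screen_drivers"], inputs["healthy"])
    group_sizes = {g: sum(1 for v in groups.values() if v == g)
                   for g in cat.DRIVER_GROUPS}
    _, _, overlap_hist = cat.merge_canonical_sources(inputs["sources"])

    # --- alteration classification on a synthetic cohort ---
    cspec = cohort_spec or syn.CohortSpec(seed=sub[1])
    tables = syn.generate_cohort(cspec)
    result = classify_cohort(tables, alt.PRESETS[preset], fdr_level)
    recovery = role_recovery(result["roles"], tables["truth"])
    role_counts = {"putative_tsg": 0, "putative_og": 0, "unclassified": 0}
    for r in result["roles"]:
        role_counts[r.putative_role] += 1
    all_genes = set(tables["truth"]["gene"])
    drivers = set(tables["truth"].loc[tables["truth"]["role"] != "passenger", "gene"])
    _, fractions = alt.sample_driver_burden(
        result["calls"], tables["expression"].columns, drivers, drivers)

    # --- systems-level properties with planted contrasts ---
    pspec = property_spec or syn.PropertySpec(seed=sub[2])
    ptable, pgroups = syn.generate_property_tables(pspec)
    ptypes = {p: "continuous" for p in pspec.continuous_properties}
    ptypes.update({p: "categorical" for p in pspec.categorical_properties})
    comparisons = prop.attach_scores(
        prop.compare_groups(ptable, dict(pgroups), ptypes, baseline="rest"))
    scores = {f"{c.property}:{c.group}": c.normalized_score for c in comparisons}

    # --- pathway enrichment of planted drivers ---
    pathways, hierarchy = syn.generate_pathways(tables["truth"], seed=sub[3])
    universe = sorted(all_genes)
    enrich_tab = enr.pathway_enrichment(drivers, pathways, universe, fdr_level)
    rollup = enr.rollup_to_level1(enrich_tab, hierarchy)

    return {
        "seed": seed,
        "catalog": {"group_sizes": group_sizes,
                    "expected_group_sizes": expected,
                    "n_undetected_canonical": len(undetected),
                    "canonical_overlap_histogram": overlap_hist},
        "alterations": {"n_lof_events": result["n_lof_events"],
                        "n_gof_events": result["n_gof_events"],
                        "n_events": result["n_events"],
                        "role_counts": role_counts,
                        "role_recovery": recovery,
                        "burden_fractions": fractions},
        "properties": {"normalized_scores": scores,
                       "n_comparisons": len(comparisons)},
        "enrichment": {"n_enriched": int(enrich_tab["enriched"].sum())
                       if len(enrich_tab) else 0,
                       "level1_rollup": rollup},
    }
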