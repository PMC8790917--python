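"""Readers and writers for the tab-separated dialects the pipeline consumes.

Every reader validates rows against the type invariants of its target
records and reports violations as ``file:line`` (1-based, counting the
header). Unknown columns are ignored with a warning; CRLF and LF inputs
parse identically.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .alterations import MutationRecord
from .catalog import ScreenRecord
from .enrichment import PathwayRecord

__all__ = [
    "read_mutations", "read_segments", "read_profiles", "read_expression",
    "read_gene_models", "read_organ_map", "read_edges", "read_gmt",
    "read_hierarchy", "read_screens", "read_gene_list", "write_table",
    "write_cohort", "load_config",
]

_DIALECTS: dict[str, list[str]] = {
    "mutations": ["sample", "gene", "effect_class", "missense_votes",
                  "splicing_votes", "hotspot", "protein_pos"],
    "segments": ["sample", "chrom", "start", "end", "cn"],
    "profiles": ["sample", "ploidy", "purity"],
    "gene_models": ["gene", "chrom", "start", "end"],
    "organ_map": ["tissue", "organ_system"],
    "edges": ["node_a", "node_b"],
    "hierarchy": ["child_id", "level1_id"],
    "screens": ["screen_id", "kind", "assay", "region", "tissue",
                "cancer_type", "n_donors"],
}


def _read_tsv(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["", "NA"])
    required = _DIALECTS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}")
    return df[required]


def _fail(path, idx: int, message: str):
    # +2: 1-based line numbering plus the header line
    raise ValueError(f"{path}:{idx + 2}: {message}")


def read_mutations(path: str | Path) -> list[MutationRecord]:
    df = _read_tsv(path, "mutations")
    records = []
    for idx, row in df.iterrows():
        try:
            pos = row["protein_pos"]
            records.append(MutationRecord(
                sample_id=row["sample"], gene=row["gene"],
                effect_class=row["effect_class"],
                missense_damaging_votes=int(row["missense_votes"]),
                splicing_damaging_votes=int(row["splicing_votes"]),
                hotspot_flag=str(row["hotspot"]).lower() in ("true", "1", "yes"),
                protein_position=None if pd.isna(pos) else int(float(pos))))
        except (ValueError, TypeError) as exc:
            _fail(path, idx, str(exc))
    return records


def read_segments(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, "segments")
    for col in ("start", "end"):
        df[col] = df[col].astype(int)
    df["cn"] = df["cn"].astype(float)
    for idx, row in df.iterrows():
        if row["end"] <= row["start"]:
            _fail(path, idx, f"empty interval [{row['start']}, {row['end']})")
        if row["cn"] < 0:
            _fail(path, idx, f"negative copy number {row['cn']}")
    return df


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, "profiles")
    df["ploidy"] = df["ploidy"].astype(float)
    df["purity"] = df["purity"].astype(float)
    for idx, row in df.iterrows():
        if row["ploidy"] <= 0:
            _fail(path, idx, f"non-positive ploidy {row['ploidy']}")
        if not 0 < row["purity"] <= 1:
            _fail(path, idx, f"purity {row['purity']} outside (0, 1]")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    df.index.name = "gene"
    return df


def read_gene_models(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, "gene_models")
    for col in ("start", "end"):
        df[col] = df[col].astype(int)
    for idx, row in df.iterrows():
        if row["end"] <= row["start"]:
            _fail(path, idx, f"gene {row['gene']}: empty transcribed block")
    return df


def read_organ_map(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, "organ_map")
    return dict(zip(df["tissue"], df["organ_system"]))


def read_edges(path: str | Path) -> list[tuple[str, str]]:
    df = _read_tsv(path, "edges")
    return list(df.itertuples(index=False, name=None))


def read_screens(path: str | Path) -> list[ScreenRecord]:
    df = _read_tsv(path, "screens")
    records = []
    for idx, row in df.iterrows():
        try:
            ct = row["cancer_type"]
            records.append(ScreenRecord(
                screen_id=row["screen_id"], kind=row["kind"], assay=row["assay"],
                region=row["region"], tissue=row["tissue"],
                cancer_type=None if pd.isna(ct) else ct,
                n_donors=int(row["n_donors"])))
        except ValueError as exc:
            _fail(path, idx, str(exc))
    return records


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def read_gmt(path: str | Path, hierarchy: Mapping[str, str] | None = None,
             level: int = 2) -> list[PathwayRecord]:
    """Read a GMT gene-set file into pathway records.

    GMT fields: set id, description, genes... The level-1 ancestor per
    pathway comes from ``hierarchy`` when given; otherwise each pathway is
    its own level-1 parent at level 1.
    """
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: malformed GMT line {fields[:1]}")
        pid, name, genes = fields[0], fields[1], frozenset(fields[2:])
        if hierarchy and pid in hierarchy:
            records.append(PathwayRecord(pid, name, level, hierarchy[pid], genes))
        else:
            records.append(PathwayRecord(pid, name, 1, pid, genes))
    return records


def read_hierarchy(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, "hierarchy")
    return dict(zip(df["child_id"], df["level1_id"]))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write one table in the package's TSV dialect (NA for missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA", lineterminator="\n")


def write_cohort(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> None:
    """Write a generated cohort's tables to ``outdir`` (one TSV each)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        write_table(df, outdir / f"{name}.tsv", index=(name == "expression"))


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (preset, fdr, seed, paths, thresholds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    preset = cfg.get("preset", "tcga")
    if preset not in ("tcga", "cell_line"):
        raise ValueError(f"unknown preset {preset!r}")
    fdr = float(cfg.get("fdr", 0.05))
    if not 0 < fdr < 1:
        raise ValueError(f"fdr {fdr} outside (0, 1)")
    cfg["preset"] = preset
    cfg["fdr"] = fdr
    cfg.setdefault("seed", 0)
    return cfg
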