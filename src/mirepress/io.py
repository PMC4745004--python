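"""Readers and writers for the three input formats and result tables.

Profiles travel as wide TSV (first column ``mirna_id``, one column per
sample), interactions as a three-column TSV (``mirna_id``, ``gene_id``,
``score``) and pathway gene sets as Broad-dialect GMT (id, description,
member genes, tab-separated).  All files are UTF-8, unquoted,
tab-separated.  Identifiers are matched by exact, case-sensitive string
equality; mapping raw miRanda output (positive alignment scores vs.
negative binding energies) onto non-negative repression scores is the
caller's responsibility.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import (
    ContributionTable,
    DifferentialTable,
    EnrichmentResult,
    ExpressionProfile,
    FormatError,
    InteractionTable,
    NormalizedProfile,
    PathwayCollection,
    RepressionResult,
)

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_normalized_profiles",
    "write_normalized_profiles",
    "read_interactions",
    "write_interactions",
    "read_gene_sets",
    "write_gene_sets",
    "write_differential_table",
    "read_differential_table",
    "write_enrichment_result",
    "read_enrichment_result",
    "write_repression_result",
    "read_repression_result",
    "write_contribution_table",
    "read_contribution_table",
    "write_manifest",
]


def _read_profile_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"profile file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a miRNA-id column plus at least one sample column")
    id_col = df.columns[0]
    dup = df[id_col].duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicate miRNA id {df.loc[dup, id_col].iloc[0]!r}")
    for col in df.columns[1:]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0)
        if bad.any():
            row = df.loc[bad, id_col].iloc[0]
            raise FormatError(
                f"{path}: cell at row {row!r}, column {col!r} is not a non-negative number "
                f"({df.loc[bad, col].iloc[0]!r})"
            )
        df[col] = values.astype(float)
    return df.set_index(id_col)


def read_profiles(path: str | Path) -> list[ExpressionProfile]:
    """Read a wide profile TSV into one :class:`ExpressionProfile` per sample column."""
    df = _read_profile_frame(path)
    return [ExpressionProfile(str(col), df[col].to_dict()) for col in df.columns]


def read_normalized_profiles(path: str | Path) -> list[NormalizedProfile]:
    """Read a wide TPM TSV (same layout as raw profiles, values sum to 1e6)."""
    df = _read_profile_frame(path)
    return [NormalizedProfile(str(col), df[col].to_dict()) for col in df.columns]


def _write_profile_frame(columns: dict[str, dict[str, float]], path: str | Path) -> None:
    df = pd.DataFrame(columns)
    df.index.name = "mirna_id"
    # keep stable row order: first-seen miRNA order across samples
    order: list[str] = []
    seen: set[str] = set()
    for col_values in columns.values():
        for mirna in col_values:
            if mirna not in seen:
                seen.add(mirna)
                order.append(mirna)
    df = df.reindex(order).fillna(0.0)
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_profiles(profiles: Sequence[ExpressionProfile], path: str | Path) -> None:
    _write_profile_frame({p.sample_id: dict(p.counts) for p in profiles}, path)


def write_normalized_profiles(profiles: Sequence[NormalizedProfile], path: str | Path) -> None:
    _write_profile_frame({p.sample_id: dict(p.tpm) for p in profiles}, path)


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a 3-column interaction TSV (mirna_id, gene_id, score)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interaction file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    missing = [c for c in InteractionTable.COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        return InteractionTable(df[list(InteractionTable.COLUMNS)])
    except (FormatError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_sets(path: str | Path) -> PathwayCollection:
    """Read a GMT file: one pathway per line, id TAB description TAB genes..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set file not found: {path}")
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}, line {lineno}: expected id, description and ≥1 gene")
            pid, name, genes = fields[0], fields[1], frozenset(fields[2:])
            if pid in pathways:
                raise FormatError(f"{path}, line {lineno}: duplicate pathway id {pid!r}")
            pathways[pid] = (name, genes)
    return PathwayCollection(pathways)


def write_gene_sets(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(collection.ids()):
            name = collection.name_of(pid)
            genes = sorted(collection.genes_of(pid))
            fh.write("\t".join([pid, name] + genes) + "\n")


def _key_frame(table: DifferentialTable) -> pd.DataFrame:
    df = table.rows.copy()
    if isinstance(df.index, pd.MultiIndex):
        df.insert(0, "mirna_id", df.index.get_level_values(0))
        df.insert(1, "gene_id", df.index.get_level_values(1))
    else:
        df.insert(0, "gene_id", df.index)
    return df.reset_index(drop=True)


def write_differential_table(table: DifferentialTable, path: str | Path) -> None:
    _key_frame(table).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_enrichment_result(result: EnrichmentResult, path: str | Path) -> None:
    df = result.rows.copy()
    df.insert(0, "pathway_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_differential_table(path: str | Path) -> DifferentialTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "mirna_id": str})
    if "mirna_id" in df.columns:
        df = df.set_index(["mirna_id", "gene_id"])
    else:
        df = df.set_index("gene_id")
        df.index.name = None
    df["significant"] = df["significant"].astype(bool)
    return DifferentialTable(df)


def read_enrichment_result(path: str | Path) -> EnrichmentResult:
    df = pd.read_csv(path, sep="\t", dtype={"pathway_id": str})
    df = df.set_index("pathway_id")
    df.index.name = None
    df["enriched"] = df["enriched"].astype(bool)
    return EnrichmentResult(df)


def write_repression_result(result: RepressionResult, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": result.repression.index, result.sample_id: result.repression.values})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_repression_result(path: str | Path) -> RepressionResult:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df.shape[1] != 2 or df.columns[0] != "gene_id":
        raise FormatError(f"{path}: expected columns gene_id, <sample_id>")
    sample_id = str(df.columns[1])
    series = pd.Series(df[sample_id].astype(float).to_numpy(), index=df["gene_id"])
    series.index.name = None
    return RepressionResult(sample_id, series)


def write_contribution_table(table: ContributionTable, path: str | Path) -> None:
    df = table.contributions.rename(table.sample_id).reset_index()
    df.columns = ["mirna_id", "gene_id", table.sample_id]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_contribution_table(path: str | Path) -> ContributionTable:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    if df.shape[1] != 3 or list(df.columns[:2]) != ["mirna_id", "gene_id"]:
        raise FormatError(f"{path}: expected columns mirna_id, gene_id, <sample_id>")
    sample_id = str(df.columns[2])
    series = df.set_index(["mirna_id", "gene_id"])[sample_id].astype(float)
    series.name = None
    return ContributionTable(sample_id, series)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
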