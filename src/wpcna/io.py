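"""Readers and writers for the plain-text formats the pipeline uses.

Peptide tables, protein matrices, partitions and decile profiles are
tab-separated; sample trait tables are CSV; gene sets use the GMT
convention (one named set per line: name, description, members).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from wpcna.datatypes import ModulePartition, ProteinAbundanceMatrix

log = logging.getLogger(__name__)

PEPTIDE_COLUMNS = [
    "peptide_sequence",
    "protein_group",
    "gene_symbol",
    "sample_id",
    "fraction",
    "intensity",
    "spectral_counts",
    "is_unique",
]


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table {path} lacks columns: {missing}")
    df["is_unique"] = df["is_unique"].astype(bool)
    log.info("read %d peptide rows from %s", len(df), path)
    return df


def write_peptide_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
    log.info("wrote %d peptide rows to %s", len(df), path)


def read_protein_matrix(path: str | Path, is_log2: bool = True) -> ProteinAbundanceMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("protein_id")
    symbols = df.pop("gene_symbol")
    log.info("read %d x %d protein matrix from %s", *df.shape, path)
    return ProteinAbundanceMatrix(df, symbols, is_log2=is_log2)


def write_protein_matrix(mat: ProteinAbundanceMatrix, path: str | Path) -> None:
    out = mat.values.copy()
    out.insert(0, "gene_symbol", mat.gene_symbols)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")
    log.info("wrote %d x %d protein matrix to %s", *mat.values.shape, path)


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError("duplicated sample ids in trait table")
    log.info("read traits for %d samples from %s", len(df), path)
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: set name, description, then member symbols."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            members = {g.strip().upper() for g in parts[2:] if g.strip()}
            if members:
                sets[parts[0]] = members
    log.info("read %d gene sets from %s", len(sets), path)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_partition(path: str | Path, stage: str = "initial") -> tuple[ModulePartition, pd.Series]:
    """Read a partition TSV; returns (partition, gene_symbol series).

    Requires at least columns ``gene_symbol`` and ``module``; uses
    ``protein_id`` as index when present, else gene_symbol.
    """
    df = pd.read_csv(path, sep="\t")
    if "module" not in df.columns or "gene_symbol" not in df.columns:
        raise ValueError(f"partition table {path} needs gene_symbol and module columns")
    idx = df["protein_id"] if "protein_id" in df.columns else df["gene_symbol"]
    assignment = pd.Series(df["module"].values, index=pd.Index(idx, name="protein_id"))
    return ModulePartition(assignment, stage=stage), pd.Series(
        df["gene_symbol"].values, index=assignment.index
    )


def write_partition(
    part: ModulePartition,
    gene_symbols: pd.Series,
    path: str | Path,
    kme_own: pd.Series | None = None,
) -> None:
    out = pd.DataFrame(
        {
            "gene_symbol": gene_symbols.reindex(part.assignment.index),
            "module": part.assignment,
            "stage": part.stage,
        }
    )
    if kme_own is not None:
        out.insert(2, "kme_own", kme_own.reindex(part.assignment.index))
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")
    log.info("wrote partition (%d proteins, %d modules) to %s",
             len(out), len(part.modules), path)


def write_square_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def linkage_to_newick(Z, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(leaf_names)
    clusters: dict[int, str] = {i: leaf_names[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        clusters[n + i] = f"({clusters[a]}:{la:.6g},{clusters[b]}:{lb:.6g})"
        heights[n + i] = h
        del clusters[a], clusters[b]
    (root,) = clusters.values()
    return root + ";"
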