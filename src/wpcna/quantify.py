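"""Peptide-level label-free quantification.

Protein groups are retained when supported by at least one unique
peptide and two peptide-spectrum matches (cohort-wide total).
Protein abundance per sample is the arithmetic mean of the three most
intense peptides (all available peptides when fewer than three were
identified). Membrane-vs-soluble enrichment is profiled by ranking
proteins on their log2 spectral-count ratio and binning into deciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wpcna.datatypes import ProteinAbundanceMatrix

log = logging.getLogger(__name__)

#: Pseudocount added to spectral counts in the membrane/soluble ratio,
#: so membrane-only or soluble-only proteins keep a finite signed ratio.
RATIO_PSEUDOCOUNT = 0.5


def filter_protein_groups(
    peptides: pd.DataFrame,
    min_unique_peptides: int = 1,
    min_spectral_counts: int = 2,
) -> set[str]:
    """Protein groups with >= 1 unique peptide and >= 2 total PSMs.

    Spectral counts are summed over the group's peptides across all
    samples and fractions (cohort-wide reading of the threshold).
    """
    if peptides.empty:
        log.warning("empty peptide table: no protein groups retained")
        return set()
    per_group = peptides.groupby("protein_group").agg(
        n_unique=("is_unique", "sum"),
        total_counts=("spectral_counts", "sum"),
    )
    # a unique peptide observed in several samples counts once
    unique_peps = (
        peptides[peptides["is_unique"]]
        .groupby("protein_group")["peptide_sequence"]
        .nunique()
        .reindex(per_group.index, fill_value=0)
    )
    keep = (unique_peps >= min_unique_peptides) & (
        per_group["total_counts"] >= min_spectral_counts
    )
    retained = set(per_group.index[keep])
    log.info("retained %d / %d protein groups", len(retained), len(per_group))
    return retained


def top3_protein_abundance(
    peptides: pd.DataFrame,
    retained_groups: set[str] | None = None,
    log2: bool = True,
    fraction: str | None = "membrane",
) -> ProteinAbundanceMatrix:
    """Top-3 ion-intensity protein abundance matrix.

    Per protein and sample, abundance is the mean of the three largest
    peptide intensities; proteins seen with fewer than three peptides
    use the mean of all available. Zero or absent intensity in a
    sample is missing. When ``fraction`` is given only that fraction's
    rows are quantified.

    Parameters
    ----------
    retained_groups
        Protein groups to quantify (e.g. from ``filter_protein_groups``);
        ``None`` quantifies every group present.
    log2
        Return log2 intensities (the scale the downstream statistics
        assume).
    """
    df = peptides
    if fraction is not None:
        df = df[df["fraction"] == fraction]
    if retained_groups is not None:
        unknown = retained_groups - set(df["protein_group"])
        if unknown:
            raise ValueError(f"retained groups absent from table: {sorted(unknown)[:5]}")
        df = df[df["protein_group"].isin(retained_groups)]
    df = df[df["intensity"] > 0]

    def _top3(x: pd.Series) -> float:
        return float(np.sort(x.values)[::-1][:3].mean())

    wide = (
        df.groupby(["protein_group", "sample_id"])["intensity"]
        .apply(_top3)
        .unstack("sample_id")
    )
    all_missing = wide.isna().all(axis=1)
    if all_missing.any():
        log.info("dropping %d proteins with no nonzero intensity", int(all_missing.sum()))
        wide = wide.loc[~all_missing]
    symbols = (
        df.drop_duplicates("protein_group")
        .set_index("protein_group")["gene_symbol"]
        .reindex(wide.index)
    )
    n_peptides = df.groupby("protein_group")["peptide_sequence"].nunique().reindex(wide.index)
    if log2:
        wide = np.log2(wide)
    mat = ProteinAbundanceMatrix(wide, symbols, is_log2=log2)
    mat.n_peptides = n_peptides  # type: ignore[attr-defined]
    return mat


@dataclass
class EnrichmentDecileProfile:
    """Decile profile of membrane/soluble spectral-count ratios."""

    table: pd.DataFrame          # decile, mean_log2_ratio, n_proteins, per-class fraction
    ratios: pd.Series            # per protein log2 ratio (filtered set)
    deciles: pd.Series           # per protein decile 1..10
    enriched_fraction: pd.Series  # per class, fraction with ratio > 0


def membrane_enrichment_profile(
    peptides: pd.DataFrame,
    class_map: dict[str, set[str]],
    min_total_counts: int = 3,
    pseudocount: float = RATIO_PSEUDOCOUNT,
    n_bins: int = 10,
) -> EnrichmentDecileProfile:
    """Profile membrane-fraction enrichment by spectral-count ratio.

    Ratio = log2((membrane counts + c) / (soluble counts + c)) summed
    per protein across samples; proteins with fewer than
    ``min_total_counts`` total PSMs are excluded; the ranked list is
    cut into ``n_bins`` near-equal bins (sizes differing by at most 1).
    ``class_map`` maps compartment class name -> gene symbols.
    """
    present = set(peptides["fraction"].unique())
    for needed in ("membrane", "soluble"):
        if needed not in present:
            raise ValueError(f"peptide table lacks the '{needed}' fraction")
    counts = (
        peptides.groupby(["protein_group", "fraction"])["spectral_counts"]
        .sum()
        .unstack("fraction", fill_value=0)
    )
    for needed in ("membrane", "soluble"):
        if needed not in counts.columns:
            counts[needed] = 0
    total = counts["membrane"] + counts["soluble"]
    counts = counts[total >= min_total_counts]
    ratios = np.log2(
        (counts["membrane"] + pseudocount) / (counts["soluble"] + pseudocount)
    )
    symbols = (
        peptides.drop_duplicates("protein_group")
        .set_index("protein_group")["gene_symbol"]
        .str.upper()
    )
    # stable sort on (ratio, protein_id) for reproducible decile edges
    order = ratios.to_frame("ratio").sort_values(
        ["ratio", "protein_group"], kind="mergesort"
    ).index
    n = len(order)
    if n < n_bins:
        raise ValueError(f"only {n} proteins pass the count filter; need >= {n_bins}")
    # near-equal bins: first (n % n_bins) bins get the extra protein
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    decile_of = pd.Series(
        np.repeat(np.arange(1, n_bins + 1), sizes), index=order, name="decile"
    )

    sym_of_filtered = symbols.reindex(ratios.index)
    rows = []
    for d in range(1, n_bins + 1):
        members = decile_of.index[decile_of == d]
        row = {
            "decile": d,
            "mean_log2_ratio": float(ratios.loc[members].mean()),
            "n_proteins": len(members),
        }
        for cls, genes in class_map.items():
            in_class = sym_of_filtered.isin(genes)
            n_class = int(in_class.sum())
            n_here = int(in_class.reindex(members).sum())
            row[f"frac_{cls}"] = n_here / n_class if n_class else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    enriched = {}
    sym_of = symbols.reindex(ratios.index)
    for cls, genes in class_map.items():
        mask = sym_of.isin(genes).values
        enriched[cls] = float((ratios[mask] > 0).mean()) if mask.any() else np.nan
    return EnrichmentDecileProfile(
        table=table,
        ratios=ratios,
        deciles=decile_of.reindex(ratios.index),
        enriched_fraction=pd.Series(enriched),
    )
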