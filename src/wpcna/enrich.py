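"""Gene-set over-representation and cross-network module overlap.

One-tailed Fisher's exact test (hypergeometric upper tail) of each
module's gene symbols against each gene set, with Benjamini--Hochberg
FDR across all (module, set) pairs of a collection. The background is
the quantified proteome, not the genome. Cross-network overlap applies
the same test to module pairs of two partitions on their shared
gene-symbol universe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from wpcna.datatypes import UNASSIGNED, ModulePartition

log = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the one-tailed Fisher p."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_odds_ratio(k: int, N: int, K: int, n: int) -> float:
    """Sample odds ratio of the 2x2 table (inf when a margin is exhausted)."""
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return a * d / (b * c)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values, input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _module_symbols(part: ModulePartition, gene_symbols: pd.Series) -> dict[str, set[str]]:
    """Module -> uppercased, deduplicated gene symbols of its members."""
    syms = gene_symbols.reindex(part.assignment.index).astype(str).str.upper()
    out = {}
    for m in part.modules:
        out[m] = set(syms.loc[part.members(m)].dropna())
    return out


def fisher_enrichment(
    part: ModulePartition,
    gene_symbols: pd.Series,
    sets: dict[str, set[str]],
    background: set[str] | None = None,
) -> pd.DataFrame:
    """One-tailed Fisher ORA of every module against every gene set.

    ``background`` defaults to all gene symbols of the partition
    (quantified-proteome universe). Set members absent from the
    background are dropped (counts logged). FDR is applied across all
    (module, set) pairs.
    """
    mod_syms = _module_symbols(part, gene_symbols)
    if background is None:
        background = set(gene_symbols.astype(str).str.upper().dropna())
    N = len(background)
    rows = []
    for set_name, members in sets.items():
        members_up = {g.upper() for g in members}
        in_bg = members_up & background
        dropped = len(members_up) - len(in_bg)
        if dropped:
            log.info("set %s: %d genes outside background excluded", set_name, dropped)
        for m, genes in mod_syms.items():
            genes_bg = genes & background
            k = len(genes_bg & in_bg)
            n = len(genes_bg)
            K = len(in_bg)
            rows.append(
                {
                    "module": m,
                    "set_name": set_name,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "odds_ratio": fisher_odds_ratio(k, N, K, n),
                    "p_one_tailed": hypergeom_upper_tail(k, N, K, n),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p_one_tailed"].values)
    return out


def cross_network_overlap(
    part_a: ModulePartition,
    symbols_a: pd.Series,
    part_b: ModulePartition,
    symbols_b: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Module-by-module over-representation between two networks.

    The background is the intersection of the two gene-symbol
    universes. Returns dict of aligned DataFrames (rows: part_a
    modules, columns: part_b modules): ``counts``, ``p``, ``fdr`` and
    ``neg_log10_fdr`` (signed -log10 of the FDR-adjusted p; positive
    for over-representation, 0 where the overlap is below expectation).
    """
    mods_a = _module_symbols(part_a, symbols_a)
    mods_b = _module_symbols(part_b, symbols_b)
    universe = (
        set(symbols_a.astype(str).str.upper().dropna())
        & set(symbols_b.astype(str).str.upper().dropna())
    )
    if not universe:
        raise ValueError("empty shared gene-symbol universe")
    log.info("cross-network background: %d shared symbols", len(universe))
    N = len(universe)
    a_names, b_names = list(mods_a), list(mods_b)
    counts = pd.DataFrame(0, index=a_names, columns=b_names, dtype=int)
    pvals = pd.DataFrame(1.0, index=a_names, columns=b_names)
    for ma in a_names:
        ga = mods_a[ma] & universe
        for mb in b_names:
            gb = mods_b[mb] & universe
            k = len(ga & gb)
            counts.loc[ma, mb] = k
            pvals.loc[ma, mb] = hypergeom_upper_tail(k, N, len(gb), len(ga))
    fdr = pd.DataFrame(
        bh_fdr(pvals.values.ravel()).reshape(pvals.shape),
        index=a_names, columns=b_names,
    )
    expected = pd.DataFrame(
        np.outer(
            [len(mods_a[m] & universe) for m in a_names],
            [len(mods_b[m] & universe) for m in b_names],
        ) / N,
        index=a_names, columns=b_names,
    )
    sign = (counts > expected).astype(float)
    neg_log10 = -np.log10(fdr.clip(lower=1e-300)) * sign
    return {"counts": counts, "p": pvals, "fdr": fdr, "neg_log10_fdr": neg_log10}
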