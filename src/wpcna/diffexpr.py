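"""Differential abundance across clinical groups.

One-way fixed-effects ANOVA per protein followed by Tukey's HSD
post-hoc test for the three pairwise comparisons (AsymAD vs control,
AD vs control, AD vs AsymAD), with Tukey--Kramer standard errors for
unbalanced designs. Proteins with a Tukey p below the threshold
(default 0.05) in a comparison are called significantly altered.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from wpcna.datatypes import COMPARISONS, GROUPS, ProteinAbundanceMatrix

log = logging.getLogger(__name__)


def tukey_pvalue(mean_diff: float, mse: float, n1: int, n2: int, k: int, df: int) -> float:
    """Tukey(-Kramer) p for one pairwise comparison.

    q = |diff| / sqrt(mse/2 * (1/n1 + 1/n2)); p from the studentized
    range distribution with k groups and df error degrees of freedom.
    """
    if df <= 0:
        return np.nan
    if mse == 0:
        return 0.0 if mean_diff != 0 else 1.0
    se = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
    q = abs(mean_diff) / se
    return float(stats.studentized_range.sf(q, k, df))


def anova_tukey(
    matrix: ProteinAbundanceMatrix,
    traits: pd.DataFrame,
    groups: tuple[str, ...] = GROUPS,
) -> pd.DataFrame:
    """Per-protein one-way ANOVA with Tukey HSD pairwise p-values.

    Returns a DataFrame indexed by protein_id with anova_F, anova_p,
    and per comparison ``log2_diff_<a>_vs_<b>`` (mean(a) - mean(b)) and
    ``tukey_p_<a>_vs_<b>``. Proteins with fewer than two groups having
    two non-missing observations get NA and a reason code.
    """
    group_of = traits["group"].reindex(matrix.sample_ids)
    present = [g for g in groups if (group_of == g).any()]
    if len(present) < 2:
        raise ValueError("need at least two clinical groups")
    col_idx = {g: np.where(group_of.values == g)[0] for g in present}

    rows = []
    Y = matrix.values.values
    for i, pid in enumerate(matrix.protein_ids):
        y = Y[i]
        obs = {g: y[ix][~np.isnan(y[ix])] for g, ix in col_idx.items()}
        usable = [g for g in present if len(obs[g]) >= 2]
        row: dict[str, object] = {"protein_id": pid, "reason": ""}
        if len(usable) < 2:
            row.update(anova_F=np.nan, anova_p=np.nan, reason="insufficient_observations")
            for a, b in COMPARISONS:
                row[f"log2_diff_{a}_vs_{b}"] = np.nan
                row[f"tukey_p_{a}_vs_{b}"] = np.nan
            rows.append(row)
            continue
        samples = [obs[g] for g in usable]
        ns = np.array([len(s) for s in samples])
        means = {g: float(np.mean(obs[g])) for g in usable}
        grand = np.concatenate(samples)
        k, N = len(samples), len(grand)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        ss_between = sum(n * (s.mean() - grand.mean()) ** 2 for n, s in zip(ns, samples))
        df_b, df_w = k - 1, N - k
        mse = ss_within / df_w if df_w > 0 else np.nan
        if ss_within == 0:
            if ss_between == 0:
                F, p = 0.0, 1.0
            else:  # zero within-group variance: F -> inf limit convention
                F, p = np.inf, 0.0
                row["reason"] = "zero_within_variance"
        else:
            F = (ss_between / df_b) / mse
            p = float(stats.f.sf(F, df_b, df_w))
        row.update(anova_F=F, anova_p=p)
        for a, b in COMPARISONS:
            if a in usable and b in usable:
                diff = means[a] - means[b]
                row[f"log2_diff_{a}_vs_{b}"] = diff
                row[f"tukey_p_{a}_vs_{b}"] = tukey_pvalue(
                    diff, mse, len(obs[a]), len(obs[b]), k, df_w
                )
            else:
                row[f"log2_diff_{a}_vs_{b}"] = np.nan
                row[f"tukey_p_{a}_vs_{b}"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("protein_id")
    n_tested = int(out["anova_p"].notna().sum())
    log.info("ANOVA/Tukey computed for %d / %d proteins", n_tested, len(out))
    return out


def significant_sets(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-comparison significant protein sets and Venn region counts.

    Returns ``(sets, regions)`` where sets maps "a_vs_b" to the
    proteins with tukey_p < alpha and regions holds the 7 Venn region
    counts keyed by sorted '&'-joined comparison names plus "union".
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    names = [f"{a}_vs_{b}" for a, b in COMPARISONS]
    sets = {
        name: set(table.index[table[f"tukey_p_{name}"] < alpha]) for name in names
    }
    regions: dict[str, int] = {}
    union: set[str] = set().union(*sets.values())
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in names if c not in combo)) if r < len(names) else set()
            regions["&".join(combo)] = len(inside - outside)
    regions["union"] = len(union)
    return sets, regions


def volcano_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format volcano-plot data: comparison, log2_diff, -log10 p."""
    frames = []
    for a, b in COMPARISONS:
        name = f"{a}_vs_{b}"
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": table.index,
                    "comparison": name,
                    "log2_difference": table[f"log2_diff_{name}"].values,
                    "neg_log10_p": -np.log10(table[f"tukey_p_{name}"].values),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
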