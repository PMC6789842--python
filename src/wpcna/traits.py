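"""Module--trait association.

Biweight midcorrelation of module eigenproteins with clinical and
pathological traits (diagnosis coded ordinally control=0, AsymAD=1,
AD=2 by default; CASI, CERAD, Braak as given), with Student-t
p-values, and Kruskal--Wallis tests of eigenprotein differences across
the three clinical groups. For dichotomous traits (e.g. sex, or a
binary diagnosis coding) the median/MAD machinery of bicor is
degenerate, so those columns fall back to Pearson correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from wpcna.datatypes import GROUPS, EigenproteinSet
from wpcna.network import bicor_pair

log = logging.getLogger(__name__)

DEFAULT_DIAGNOSIS_CODING = {"control": 0, "AsymAD": 1, "AD": 2}
DEFAULT_TRAITS = ("diagnosis", "casi", "cerad", "braak")


def encode_traits(
    traits: pd.DataFrame,
    columns: tuple[str, ...] = DEFAULT_TRAITS,
    diagnosis_coding: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Numeric trait columns for correlation.

    ``diagnosis`` is derived from the group factor via the ordinal
    coding; other requested columns are taken from the table as-is.
    """
    coding = diagnosis_coding or DEFAULT_DIAGNOSIS_CODING
    out = pd.DataFrame(index=traits.index)
    for col in columns:
        if col == "diagnosis":
            out[col] = traits["group"].map(coding).astype(float)
        else:
            series = traits[col]
            if series.dtype == object:
                levels = sorted(series.dropna().unique())
                series = (series == levels[-1]).astype(float)
            out[col] = series.astype(float)
    return out


def correlation_p(r: float, n: int) -> float:
    """Two-sided p for a correlation via t = r sqrt((n-2)/(1-r^2))."""
    if np.isnan(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_bicor(
    eig: EigenproteinSet,
    traits: pd.DataFrame,
    columns: tuple[str, ...] = DEFAULT_TRAITS,
    diagnosis_coding: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bicor of each eigenprotein with each trait; returns (r, p).

    Constant traits yield NA with a warning; dichotomous traits use
    Pearson (logged).
    """
    encoded = encode_traits(traits, columns, diagnosis_coding).reindex(eig.sample_ids)
    n = len(encoded)
    if n < 5:
        raise ValueError("need at least 5 samples for trait correlation")
    R = pd.DataFrame(index=eig.modules, columns=encoded.columns, dtype=float)
    P = R.copy()
    for col in encoded.columns:
        t = encoded[col].values.astype(float)
        ok = ~np.isnan(t)
        if np.nanstd(t) == 0:
            log.warning("trait %s is constant; correlations set to NA", col)
            continue
        dichotomous = len(np.unique(t[ok])) <= 2
        if dichotomous:
            log.info("trait %s is dichotomous; using Pearson", col)
        for m in eig.modules:
            e = eig.values.loc[m].values[ok]
            tv = t[ok]
            if dichotomous:
                r = float(np.corrcoef(e, tv)[0, 1])
            else:
                r = bicor_pair(e, tv)
            R.loc[m, col] = r
            P.loc[m, col] = correlation_p(r, int(ok.sum()))
    return R, P


def eigenprotein_group_test(
    eig: EigenproteinSet, traits: pd.DataFrame, groups: tuple[str, ...] = GROUPS
) -> pd.DataFrame:
    """Kruskal--Wallis H (tie-corrected) per module across groups."""
    group_of = traits["group"].reindex(eig.sample_ids)
    split = [np.where(group_of.values == g)[0] for g in groups]
    if any(len(ix) == 0 for ix in split):
        missing = [g for g, ix in zip(groups, split) if len(ix) == 0]
        raise ValueError(f"groups with no samples: {missing}")
    rows = []
    for m in eig.modules:
        vals = eig.values.loc[m].values
        samples = [vals[ix] for ix in split]
        if np.ptp(np.concatenate(samples)) == 0:
            H, p = 0.0, 1.0  # all values tied: no evidence of group differences
        else:
            H, p = stats.kruskal(*samples)
        rows.append({"module": m, "H": float(H), "p": float(p)})
    return pd.DataFrame(rows).set_index("module")


def star_annotation(p: float) -> str:
    """Significance stars at 0.05 / 0.01."""
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def trait_grid_table(R: pd.DataFrame, P: pd.DataFrame) -> pd.DataFrame:
    """Long-format module x trait grid with r, p, BH FDR and stars.

    CASI is correlated as measured (higher = better cognition), so a
    negative r reads as higher module expression with worse cognition.
    """
    from wpcna.enrich import bh_fdr

    rows = []
    for m in R.index:
        for col in R.columns:
            rows.append(
                {"module": m, "trait": col, "r": R.loc[m, col], "p": P.loc[m, col]}
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr"] = np.nan
    out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"].values)
    out["stars"] = out["p"].map(star_annotation)
    return out
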