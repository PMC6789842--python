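"""Bootstrap covariate regression.

Each protein's log2 abundance is modelled as

    abundance ~ group + age + sex + PMI

on bootstrap resamples drawn with replacement within each clinical
group (so group counts are preserved in every draw). The covariate
coefficients are aggregated by their median over bootstraps and the
mean-centered covariate contribution is subtracted, leaving the
diagnosis signal (the protected ``group`` term) untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wpcna.datatypes import GROUPS, ProteinAbundanceMatrix

log = logging.getLogger(__name__)


@dataclass
class RegressionConfig:
    n_bootstrap: int = 1000
    seed: int = 0
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "pmi"])
    protect: list[str] = field(default_factory=lambda: ["group"])

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if set(self.protect) & set(self.covariates):
            raise ValueError("protect and covariates must be disjoint")


def _encode_design(traits: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design: intercept + group dummies + covariates.

    Sex is coded 0/1 (alphabetical level order); the group factor uses
    control as reference with AsymAD/AD dummies.
    """
    X = pd.DataFrame(index=traits.index)
    X["intercept"] = 1.0
    for g in GROUPS[1:]:
        X[f"group_{g}"] = (traits["group"] == g).astype(float)
    for cov in covariates:
        col = traits[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {cov} has >2 categorical levels")
            X[cov] = (col == levels[-1]).astype(float)
        else:
            X[cov] = col.astype(float)
    return X


def regress_covariates(
    matrix: ProteinAbundanceMatrix,
    traits: pd.DataFrame,
    cfg: RegressionConfig,
) -> ProteinAbundanceMatrix:
    """Remove bootstrap-median covariate effects from each protein.

    Returns a matrix with the same shape and missingness; per protein,
    output = input - sum_cov b_cov * (x_cov - mean(x_cov)), where each
    b_cov is the median over ``cfg.n_bootstrap`` stratified-bootstrap
    OLS fits of abundance ~ group + covariates. Deterministic given
    ``cfg.seed``.
    """
    if not matrix.sample_ids.equals(traits.index):
        traits = traits.reindex(matrix.sample_ids)
        if traits.isna().all(axis=1).any():
            raise ValueError("matrix and trait samples differ")
    rng = np.random.default_rng(cfg.seed)
    X = _encode_design(traits, cfg.covariates)
    cov_cols = [X.columns.get_loc(c) for c in cfg.covariates]
    Xv = X.values
    n_samples, n_terms = Xv.shape
    Y = matrix.values.values  # proteins x samples
    n_prot = Y.shape[0]

    group_idx = [np.where(traits["group"].values == g)[0] for g in GROUPS]
    group_idx = [ix for ix in group_idx if len(ix)]

    # pre-draw all bootstrap index sets (stratified within group)
    boot_rows = np.empty((cfg.n_bootstrap, n_samples), dtype=np.intp)
    for b in range(cfg.n_bootstrap):
        for attempt in range(100):
            draw = np.concatenate([rng.choice(ix, size=len(ix), replace=True) for ix in group_idx])
            if np.linalg.matrix_rank(Xv[draw]) == n_terms:
                boot_rows[b] = draw
                break
        else:
            raise RuntimeError("could not draw a full-rank bootstrap design in 100 tries")

    complete = ~np.isnan(Y)
    min_obs = n_terms + 1
    coefs = np.zeros((n_prot, len(cov_cols)))
    skipped = 0

    # proteins with identical missingness share the bootstrap fits
    patterns: dict[bytes, list[int]] = {}
    for i in range(n_prot):
        patterns.setdefault(complete[i].tobytes(), []).append(i)

    for key, rows_i in patterns.items():
        obs = np.frombuffer(key, dtype=bool)
        if obs.sum() < min_obs:
            skipped += len(rows_i)
            continue
        Ysub = Y[np.ix_(rows_i, np.where(obs)[0])]
        pos_of = -np.ones(n_samples, dtype=np.intp)
        pos_of[np.where(obs)[0]] = np.arange(obs.sum())
        B = np.zeros((cfg.n_bootstrap, len(rows_i), len(cov_cols)))
        for b in range(cfg.n_bootstrap):
            draw = boot_rows[b]
            draw = draw[obs[draw]]
            if len(draw) < min_obs or np.linalg.matrix_rank(Xv[draw]) < n_terms:
                B[b] = np.nan
                continue
            beta, *_ = np.linalg.lstsq(Xv[draw], Ysub[:, pos_of[draw]].T, rcond=None)
            B[b] = beta[cov_cols].T
        coefs[rows_i] = np.nanmedian(B, axis=0)

    if skipped:
        log.warning("skipped %d proteins with too few complete observations", skipped)

    centered = np.empty((len(cov_cols), n_samples))
    for j, c in enumerate(cov_cols):
        col = Xv[:, c]
        centered[j] = col - col.mean()
    adjustment = coefs @ centered  # proteins x samples
    out = Y - np.where(complete, adjustment, 0.0)
    out[~complete] = np.nan
    values = pd.DataFrame(out, index=matrix.protein_ids, columns=matrix.sample_ids)
    return ProteinAbundanceMatrix(values, matrix.gene_symbols, is_log2=matrix.is_log2)
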