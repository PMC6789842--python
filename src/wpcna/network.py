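"""Signed weighted co-expression network construction.

Pipeline: biweight midcorrelation (bicor) -> signed adjacency
a_ij = ((1 + s_ij)/2)^beta -> topological overlap (mean or min
denominator) -> average-linkage clustering of 1 - TOM -> Dynamic
Hybrid tree cut with a medoid stage -> module eigenproteins (first
principal component of the standardized module submatrix), kME
(protein-to-eigenprotein Pearson correlation), eigenprotein-similarity
module merging and kME-based reassignment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from wpcna.datatypes import (
    UNASSIGNED,
    EigenproteinSet,
    ModulePartition,
    NetworkParams,
    ProteinAbundanceMatrix,
)
from wpcna.treecut import cut_tree_hybrid

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- correlation

def _bicor_transform(X: np.ndarray) -> np.ndarray:
    """Row-wise Tukey-biweight transform used by bicor.

    u_i = (x_i - med(x)) / (9 mad(x)); w_i = (1 - u_i^2)^2 for |u_i|<1
    else 0; returns (x - med) * w normalized to unit L2 norm per row.
    Rows with mad = 0 fall back to the Pearson transform (centered,
    unit norm) with a warning.
    """
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    out = dev * w
    if zero_mad.any():
        log.warning("bicor: %d rows have mad = 0; using Pearson for those rows",
                    int(zero_mad.sum()))
        centered = X[zero_mad] - X[zero_mad].mean(axis=1, keepdims=True)
        out[zero_mad] = centered
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    bad = norms[:, 0] == 0
    if bad.any():
        raise ValueError(
            f"constant rows (no variability): indices {np.where(bad)[0][:10].tolist()}"
        )
    return out / norms


def bicor_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors (pairwise-complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    t = _bicor_transform(np.vstack([x[ok], y[ok]]))
    return float(np.clip(t[0] @ t[1], -1.0, 1.0))


def bicor_matrix(matrix: ProteinAbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """All-pairs bicor of protein profiles (rows); complete data only."""
    values = matrix.values if isinstance(matrix, ProteinAbundanceMatrix) else matrix
    X = np.asarray(values, dtype=float)
    if X.shape[1] < 4:
        raise ValueError("bicor needs at least 4 samples")
    if np.isnan(X).any():
        raise ValueError("bicor_matrix requires complete data; drop missing first")
    T = _bicor_transform(X)
    C = np.clip(T @ T.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    idx = values.index
    return pd.DataFrame(C, index=idx, columns=idx)


def pearson_matrix(matrix: ProteinAbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    values = matrix.values if isinstance(matrix, ProteinAbundanceMatrix) else matrix
    X = np.asarray(values, dtype=float)
    C = np.corrcoef(X)
    np.fill_diagonal(C, 1.0)
    idx = values.index
    return pd.DataFrame(np.clip(C, -1, 1), index=idx, columns=idx)


# ----------------------------------------------------------- adjacency & TOM

def signed_adjacency(cor: pd.DataFrame, beta: float = 11.5) -> pd.DataFrame:
    """Signed soft-threshold adjacency a_ij = ((1 + s_ij)/2)^beta."""
    A = ((1.0 + cor.values) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=cor.index, columns=cor.columns)


def unsigned_adjacency(cor: pd.DataFrame, beta: float = 11.5) -> pd.DataFrame:
    A = np.abs(cor.values) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=cor.index, columns=cor.columns)


def tom_similarity(adj: pd.DataFrame, denom: str = "mean") -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (D_ij + 1 - a_ij).

    l_ij sums a_iu * a_uj over u != i, j; k_i is node connectivity
    excluding the diagonal; D_ij = (k_i + k_j)/2 for ``denom='mean'``
    or min(k_i, k_j) for ``denom='min'``.
    """
    if denom not in ("mean", "min"):
        raise ValueError("denom must be 'mean' or 'min'")
    A = adj.values.astype(float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # includes u=i,j terms only via zeroed diagonal: none remain
    k = A.sum(axis=1)
    if denom == "mean":
        D = (k[:, None] + k[None, :]) / 2.0
    else:
        D = np.minimum(k[:, None], k[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A) / (D + 1.0 - A)
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(np.clip(T, 0.0, 1.0), index=adj.index, columns=adj.columns)


# -------------------------------------------------------------- tree cutting

def detect_modules(
    tom: pd.DataFrame, params: NetworkParams
) -> tuple[ModulePartition, np.ndarray]:
    """Dynamic Hybrid module detection on 1 - TOM.

    Returns the size-ranked partition and the scipy linkage matrix of
    the average-linkage dendrogram.
    """
    n = tom.shape[0]
    if n <= params.min_module_size:
        log.warning("fewer proteins (%d) than min_module_size; all unassigned", n)
        part = ModulePartition(pd.Series([UNASSIGNED] * n, index=tom.index))
        return part, np.empty((0, 4))
    dissim = 1.0 - tom.values
    np.fill_diagonal(dissim, 0.0)
    dissim = np.maximum(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    labels = cut_tree_hybrid(
        Z,
        dissim,
        deep_split=params.deep_split,
        min_module_size=params.min_module_size,
        cut_height=params.cut_height,
        pam_respects_dendro=params.pam_respects_dendro,
    )
    raw = pd.Series(
        [str(lab) if lab > 0 else UNASSIGNED for lab in labels], index=tom.index
    )
    part = ModulePartition.from_labels(raw, stage="initial",
                                       min_size=params.min_module_size)
    log.info("detected %d modules; %d proteins unassigned",
             len(part.modules), int((part.assignment == UNASSIGNED).sum()))
    return part, Z


# ------------------------------------------------------------- eigenproteins

def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance protein rows in module")
    return (X - mu) / sd


def module_eigenproteins(
    matrix: ProteinAbundanceMatrix, part: ModulePartition
) -> EigenproteinSet:
    """First principal component of each module's standardized submatrix.

    The eigenprotein is the first right-singular vector over samples
    (unit norm), sign-oriented to correlate positively with the module
    mean standardized profile; variance_explained = s1^2 / sum s^2.
    """
    values = {}
    varexp = {}
    for m in part.modules:
        members = part.members(m)
        members = members.intersection(matrix.protein_ids)
        sub = matrix.values.loc[members].dropna(axis=0)
        if len(sub) < 2:
            raise ValueError(f"module {m} has fewer than 2 complete proteins")
        X = _standardize_rows(sub.values)
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        v = Vt[0]
        mean_profile = X.mean(axis=0)
        if v @ mean_profile < 0:
            v = -v
        values[m] = v
        varexp[m] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(values, index=matrix.sample_ids).T
    eig = eig.loc[part.modules]
    return EigenproteinSet(eig, pd.Series(varexp).loc[part.modules])


def compute_kme(
    matrix: ProteinAbundanceMatrix, eig: EigenproteinSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kME = Pearson correlation of each protein with each eigenprotein.

    Returns (kme, p) DataFrames, proteins x modules; p from the
    two-sided t transform with n - 2 degrees of freedom.
    """
    X = matrix.values.values
    n = X.shape[1]
    if n < 3:
        raise ValueError("kME needs at least 3 samples")
    Xc = X - np.nanmean(X, axis=1, keepdims=True)
    Xc = np.nan_to_num(Xc)  # complete-case matrices upstream; guard only
    Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    E = eig.values.values
    Ec = E - E.mean(axis=1, keepdims=True)
    En = Ec / np.linalg.norm(Ec, axis=1, keepdims=True)
    R = np.clip(Xn @ En.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    kme = pd.DataFrame(R, index=matrix.protein_ids, columns=eig.modules)
    pvals = pd.DataFrame(P, index=matrix.protein_ids, columns=eig.modules)
    return kme, pvals


# --------------------------------------------------------- merge & reassign

def merge_modules(
    matrix: ProteinAbundanceMatrix,
    part: ModulePartition,
    cut_height: float = 0.07,
) -> tuple[ModulePartition, EigenproteinSet]:
    """Merge modules whose eigenproteins are closer than ``cut_height``.

    Eigenprotein dissimilarity 1 - cor(ME_a, ME_b) is clustered by
    average linkage and cut at ``cut_height``; merging and eigenprotein
    recomputation iterate until no pair remains below threshold.
    Labels are re-ranked by size afterward.
    """
    assignment = part.assignment.copy()
    for _ in range(100):
        current = ModulePartition.from_labels(assignment, stage="merged")
        mods = current.modules
        if len(mods) < 2:
            break
        eig = module_eigenproteins(matrix, current)
        diss = 1.0 - np.corrcoef(eig.values.values)
        np.fill_diagonal(diss, 0.0)
        off = diss[np.triu_indices_from(diss, k=1)]
        if (off >= cut_height).all():
            break
        Z = linkage(squareform(np.maximum((diss + diss.T) / 2, 0), checks=False),
                    method="average")
        groups = fcluster(Z, t=cut_height, criterion="distance")
        remap = {m: f"g{g}" for m, g in zip(mods, groups)}
        assignment = assignment.map(lambda lab: remap.get(lab, lab))
    merged = ModulePartition.from_labels(assignment, stage="merged")
    log.info("merged %d -> %d modules", len(part.modules), len(merged.modules))
    return merged, module_eigenproteins(matrix, merged)


def reassign_low_kme(
    matrix: ProteinAbundanceMatrix,
    part: ModulePartition,
    kme: pd.DataFrame,
    kme_p: pd.DataFrame,
    reassign_p: float = 0.05,
    adopt_unassigned: bool = True,
) -> ModulePartition:
    """Move proteins whose own-module membership is not significant.

    A single pass: protein in module m moves to the module of its
    maximal kME when its own-module kME p exceeds ``reassign_p`` and
    the best alternative's kME p is below it. When
    ``adopt_unassigned`` is set, unassigned proteins whose best kME is
    significant at reassign_p / n_modules (Bonferroni over modules,
    since the best of k correlations is selected) join that module.
    """
    assignment = part.assignment.copy()
    n_modules = max(len(part.modules), 1)
    moved = adopted = 0
    for pid, own in part.assignment.items():
        if own == UNASSIGNED:
            if not adopt_unassigned:
                continue
            best = kme.loc[pid].idxmax()
            if kme_p.loc[pid, best] < reassign_p / n_modules:
                assignment.loc[pid] = best
                adopted += 1
            continue
        own_p = kme_p.loc[pid, own]
        if own_p <= reassign_p:
            continue
        best = kme.loc[pid].idxmax()
        if best != own and kme_p.loc[pid, best] < reassign_p:
            assignment.loc[pid] = best
            moved += 1
    log.info("reassigned %d proteins, adopted %d unassigned", moved, adopted)
    return ModulePartition.from_labels(assignment, stage="reassigned")


# -------------------------------------------------------------- soft power

def pick_soft_threshold(
    matrix: ProteinAbundanceMatrix,
    candidate_betas: list[float] | None = None,
    cor_method: str = "bicor",
    signed: bool = True,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free topology fit across candidate soft powers.

    For each beta: build the adjacency, compute connectivities, and fit
    log10 p(k) ~ log10 k over ``n_bins`` connectivity bins; the signed
    R^2 (negative when the slope is positive) and mean connectivity
    are reported.
    """
    if candidate_betas is None:
        candidate_betas = [1, 2, 4, 6, 8, 10, 11.5, 12, 14, 16, 18, 20]
    if len(candidate_betas) < 2:
        raise ValueError("need at least 2 candidate powers")
    cor = bicor_matrix(matrix) if cor_method == "bicor" else pearson_matrix(matrix)
    rows = []
    for beta in candidate_betas:
        adj = signed_adjacency(cor, beta) if signed else unsigned_adjacency(cor, beta)
        A = adj.values.copy()
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        rows.append(
            {"beta": beta, "r_squared": scale_free_fit(k, n_bins),
             "mean_connectivity": float(k.mean())}
        )
    return pd.DataFrame(rows)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) vs log10 k regression."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return np.nan
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        kb = k[which == b]
        if len(kb) == 0:
            continue
        xs.append(np.log10(kb.mean()))
        ys.append(np.log10(len(kb) / len(k)))
    if len(xs) < 3:
        return np.nan
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)
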