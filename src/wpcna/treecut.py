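"""Dynamic Hybrid cutting of a hierarchical-clustering dendrogram.

Flat module detection from an average-linkage tree of a dissimilarity
matrix, in the Dynamic Hybrid style: the tree is first decomposed at a
static cut height into maximal sub-branches, each sub-branch is then
recursively split wherever both children qualify as distinct clusters
(size, core scatter and gap criteria, parameterized by ``deep_split``
presets), and a final medoid (PAM-like) stage attaches borderline
unlabeled objects to the nearest qualifying module — optionally
restricted to modules on the object's own static branch.

Objects that qualify for no module remain unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: deep_split presets: maximum core scatter of a module branch,
#: relative to the span between the dendrogram's low-height reference
#: (5th percentile of merge heights, the within-module scale) and the
#: static cut height. Higher deep_split tolerates looser branches, so
#: more sub-branches qualify as separate modules (finer splitting).
_MAX_CORE_SCATTER = {0: 0.25, 1: 0.35, 2: 0.45, 3: 0.55, 4: 0.65}

#: Medoid-stage admission: an unlabeled object joins its nearest
#: module only when its average dissimilarity to that module is below
#: this fraction of its average dissimilarity to all objects.
_PAM_RATIO = 0.94


@dataclass
class _Node:
    id: int
    height: float
    left: "_Node | None" = None
    right: "_Node | None" = None
    leaves: np.ndarray | None = None       # leaf indices, filled bottom-up
    merge_heights: np.ndarray | None = None  # heights of merges inside subtree

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _build_tree(Z: np.ndarray, n: int) -> list[_Node]:
    """Materialize linkage nodes with cached leaves and merge heights."""
    nodes: list[_Node] = [_Node(i, 0.0, leaves=np.array([i]), merge_heights=np.empty(0))
                          for i in range(n)]
    for i, (a, b, h, _) in enumerate(Z):
        left, right = nodes[int(a)], nodes[int(b)]
        node = _Node(n + i, float(h), left, right)
        node.leaves = np.concatenate([left.leaves, right.leaves])
        node.merge_heights = np.sort(
            np.concatenate([left.merge_heights, right.merge_heights, [float(h)]])
        )
        nodes.append(node)
    return nodes


def _core_scatter(node: _Node, core_size: int) -> float:
    """Mean of the lowest merge heights forming the branch core."""
    if node.is_leaf:
        return 0.0
    k = max(min(core_size - 1, len(node.merge_heights)), 1)
    return float(node.merge_heights[:k].mean())


def cut_tree_hybrid(
    Z: np.ndarray,
    dissim: np.ndarray,
    deep_split: int = 4,
    min_module_size: int = 20,
    cut_height: float | None = None,
    pam_stage: bool = True,
    pam_respects_dendro: bool = True,
) -> np.ndarray:
    """Detect clusters from a linkage tree; returns integer labels.

    Label 0 means unassigned; positive labels are arbitrary (callers
    re-rank by size). ``cut_height`` defaults to 99% of the dendrogram
    height range above its minimum merge height.
    """
    n = dissim.shape[0]
    if len(Z) == 0:
        return np.zeros(n, dtype=int)
    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    if cut_height is None:
        cut_height = hmin + 0.99 * (hmax - hmin)
    if hmax == hmin:  # degenerate: all merges at one height
        log.warning("degenerate dendrogram (all merge heights equal)")
        lab = np.ones(n, dtype=int) if n >= min_module_size else np.zeros(n, dtype=int)
        return lab

    max_rel_scatter = _MAX_CORE_SCATTER[deep_split]
    ref = float(np.quantile(heights, 0.05))
    scale = max(cut_height - ref, 1e-12)
    max_abs_scatter = ref + max_rel_scatter * scale

    nodes = _build_tree(Z, n)
    root = nodes[-1]

    # static decomposition: maximal subtrees entirely below cut_height
    static_roots: list[_Node] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.height <= cut_height:
            static_roots.append(node)
        else:
            stack.extend([node.left, node.right])

    def is_candidate(node: _Node) -> bool:
        """Subtree of module-forming size with a tight core.

        Core scatter is the mean of the subtree's lowest merge
        heights; a subtree whose scatter exceeds the threshold
        contains no sufficiently dense cluster anywhere inside it
        (scatter is computed from the lowest merges), so the descent
        can discard it wholesale.
        """
        if len(node.leaves) < min_module_size:
            return False
        return _core_scatter(node, min_module_size) <= max_abs_scatter

    clusters: list[np.ndarray] = []
    branch_of_cluster: list[int] = []

    # Descend each static branch:
    #  - both children candidates -> the branch splits, recurse into both;
    #  - one child candidate -> the module continues below that child;
    #    the sibling holds late-attaching stragglers, left for the PAM
    #    stage;
    #  - no candidate child -> this node is the module core: accept it.
    # Non-candidate subtrees (loose blobs, outlier chains) dissolve
    # into unlabeled leaves.
    for b, sub in enumerate(static_roots):
        if not is_candidate(sub):
            continue
        work: list[_Node] = [sub]
        while work:
            node = work.pop()
            ql = (not node.is_leaf) and is_candidate(node.left)
            qr = (not node.is_leaf) and is_candidate(node.right)
            if ql and qr:
                work.extend([node.left, node.right])
            elif ql or qr:
                work.append(node.left if ql else node.right)
            else:
                clusters.append(node.leaves)
                branch_of_cluster.append(b)

    labels = np.zeros(n, dtype=int)
    kept_branch: list[int] = []
    next_label = 1
    for leaves, b in zip(clusters, branch_of_cluster):
        if len(leaves) >= min_module_size:
            labels[leaves] = next_label
            kept_branch.append(b)
            next_label += 1

    if pam_stage and next_label > 1:
        labels = _pam_stage(
            labels, dissim, static_roots, kept_branch, pam_respects_dendro
        )
    return labels


def _pam_stage(
    labels: np.ndarray,
    dissim: np.ndarray,
    static_roots: list[_Node],
    cluster_branch: list[int],
    respect_dendro: bool,
) -> np.ndarray:
    """Attach borderline unlabeled objects to the nearest module.

    An object joins the module with the smallest average dissimilarity
    among eligible modules, but only if it sits no farther from that
    module than the module's own most peripheral member — objects
    outside every module's scatter stay unassigned. With
    ``respect_dendro`` eligibility is limited to modules on the
    object's static branch.
    """
    out = labels.copy()
    module_ids = [m for m in np.unique(labels) if m > 0]
    branch_of_module = dict(zip(module_ids, cluster_branch))
    branch_of_obj = np.full(len(labels), -1, dtype=int)
    for b, sub in enumerate(static_roots):
        branch_of_obj[sub.leaves] = b

    # an object belongs near a module when its average dissimilarity
    # to the module is clearly below its average dissimilarity to the
    # dataset at large; unstructured objects sit at ratio ~1
    d_all = dissim.sum(axis=1) / max(dissim.shape[0] - 1, 1)

    total_assigned = 0
    for _ in range(10):  # grow modules outward until stable
        members = {m: np.where(out == m)[0] for m in module_ids}
        avg_to = {m: dissim[:, ix].mean(axis=1) for m, ix in members.items()}
        n_assigned = 0
        for i in np.where(out == 0)[0]:
            eligible = [
                m for m in module_ids
                if not respect_dendro or branch_of_module[m] == branch_of_obj[i]
            ]
            best, best_d = 0, np.inf
            for m in eligible:
                d = avg_to[m][i]
                if d < best_d and d <= _PAM_RATIO * d_all[i]:
                    best, best_d = m, d
            if best:
                out[i] = best
                n_assigned += 1
        total_assigned += n_assigned
        if n_assigned == 0:
            break
    log.info("PAM stage assigned %d of %d unlabeled objects",
             total_assigned, int((labels == 0).sum()))
    return out
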