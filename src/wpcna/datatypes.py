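"""Core containers shared across pipeline stages.

Tabular data travels as pandas objects; the thin dataclasses below add
the invariants and metadata the pipeline relies on (log2 flag, module
label ordering, eigenprotein sign convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "AsymAD", "AD")
UNASSIGNED = "unassigned"

#: Pairwise comparisons in fixed order: (first, second); the reported
#: difference is mean(first) - mean(second).
COMPARISONS = (
    ("AsymAD", "control"),
    ("AD", "control"),
    ("AD", "AsymAD"),
)


@dataclass
class ProteinAbundanceMatrix:
    """Proteins x samples abundance matrix.

    ``values`` is a DataFrame indexed by protein_id with sample_id
    columns; NaN marks missing cells. ``gene_symbols`` maps protein_id
    to gene symbol. ``is_log2`` records whether values are on the log2
    scale (required by the regression/network stages).
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    is_log2: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated protein ids in abundance matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample ids in abundance matrix")
        self.gene_symbols = self.gene_symbols.reindex(self.values.index)

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def complete_cases(self) -> "ProteinAbundanceMatrix":
        """Sub-matrix of proteins with no missing cell."""
        keep = ~self.values.isna().any(axis=1)
        return ProteinAbundanceMatrix(
            self.values.loc[keep].copy(), self.gene_symbols.loc[keep], self.is_log2
        )


@dataclass
class NetworkParams:
    """Tuning knobs of the network stage.

    Defaults follow the signed-bicor configuration used for deeply
    fractionated brain proteomes: soft power 11.5, deepSplit 4, minimum
    module size 20, mean-denominator TOM, merge height 0.07 and a kME
    reassignment threshold of p = 0.05.
    """

    beta: float = 11.5
    deep_split: int = 4
    min_module_size: int = 20
    tom_denom: str = "mean"
    cor_method: str = "bicor"
    signed: bool = True
    merge_cut_height: float = 0.07
    reassign_p: float = 0.05
    pam_respects_dendro: bool = True
    cut_height: float | None = None  # default: 99% of dendrogram height range

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0 <= self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in [0, 1)")
        if not 0 < self.reassign_p < 1:
            raise ValueError("reassign_p must be in (0, 1)")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be an integer in 0..4")
        if self.tom_denom not in ("mean", "min"):
            raise ValueError("tom_denom must be 'mean' or 'min'")
        if self.cor_method not in ("bicor", "pearson"):
            raise ValueError("cor_method must be 'bicor' or 'pearson'")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModulePartition:
    """Assignment of proteins to modules.

    ``assignment`` maps protein_id -> label; labels are "M1..Mk"
    ordered by decreasing module size, plus "unassigned". ``stage``
    records provenance (initial | merged | reassigned).
    """

    assignment: pd.Series
    stage: str = "initial"

    def __post_init__(self) -> None:
        self.assignment = self.assignment.astype(str)

    @property
    def modules(self) -> list[str]:
        """Module labels in rank order, excluding unassigned."""
        labels = [m for m in self.assignment.unique() if m != UNASSIGNED]
        return sorted(labels, key=lambda m: int(m[1:]))

    def members(self, module: str) -> pd.Index:
        return self.assignment.index[self.assignment == module]

    def sizes(self) -> pd.Series:
        counts = self.assignment[self.assignment != UNASSIGNED].value_counts()
        return counts.reindex(self.modules)

    @staticmethod
    def from_labels(
        labels: pd.Series, stage: str = "initial", min_size: int = 1
    ) -> "ModulePartition":
        """Build a partition from arbitrary labels.

        Labels occurring fewer than ``min_size`` times become
        unassigned; the rest are renamed M1..Mk by decreasing size
        (ties broken by the smallest original member order for
        determinism).
        """
        labels = labels.astype(object)
        counts = labels[labels != UNASSIGNED].value_counts()
        kept = [lab for lab in counts.index if counts[lab] >= min_size]
        # rank by (-size, first-occurrence position) for reproducibility
        first_pos = {lab: int(np.argmax(labels.values == lab)) for lab in kept}
        kept.sort(key=lambda lab: (-counts[lab], first_pos[lab]))
        rename = {lab: f"M{i + 1}" for i, lab in enumerate(kept)}
        out = labels.map(lambda lab: rename.get(lab, UNASSIGNED))
        return ModulePartition(out, stage=stage)


@dataclass
class EigenproteinSet:
    """Module eigenproteins: first principal component per module.

    ``values`` is modules x samples with unit-norm rows; sign is
    oriented so each eigenprotein correlates positively with its
    module's mean standardized profile.
    """

    values: pd.DataFrame
    variance_explained: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def modules(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
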