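"""Synthetic cohorts with planted co-expression structure.

Emulates the statistical design the pipeline targets: three clinical
groups (control, AsymAD, AD) of six post-mortem cases each, planted
protein co-expression modules whose latent factors follow
disease-stage archetypes (stable, progressive increase/decrease, early
decrease then stable, transient up/down across the disease continuum),
linear age/sex/PMI covariate effects on a subset of proteins,
pathology and cognition traits coupled to chosen module latents, plus
unstructured noise proteins. Every stage returns its ground truth so
each pipeline step can be scored against what was planted.

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wpcna.datatypes import GROUPS, UNASSIGNED, ModulePartition, ProteinAbundanceMatrix

#: Group-mean latent patterns (control, AsymAD, AD) in log2 units.
ARCHETYPES: dict[str, tuple[float, float, float]] = {
    "stable": (0.0, 0.0, 0.0),
    "progressive_increase": (0.0, 0.5, 1.0),
    "progressive_decrease": (0.0, -0.5, -1.0),
    "early_decrease_then_stable": (0.0, -0.8, -0.9),
    "transient_up": (0.0, 0.8, -0.5),
    "transient_down": (0.0, -0.8, 0.5),
}


@dataclass
class ModuleDesign:
    size: int
    archetype: str
    cor_target: float = 0.7  # median within-module pairwise correlation

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 0 < self.cor_target < 1:
            raise ValueError("cor_target must be in (0, 1)")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype}")


@dataclass
class CovariateEffects:
    b_age: float = 0.05   # log2 units per year
    b_sex: float = 0.3    # log2 shift between sexes
    b_pmi: float = 0.1    # log2 units per hour
    affected_fraction: float = 0.3


def default_module_designs() -> list[ModuleDesign]:
    """Eight modules spanning the archetypes, sizes 25--120."""
    spec = [
        (120, "stable"),
        (100, "progressive_decrease"),
        (80, "transient_up"),
        (60, "progressive_increase"),
        (50, "early_decrease_then_stable"),
        (40, "transient_down"),
        (30, "stable"),
        (25, "early_decrease_then_stable"),
    ]
    return [ModuleDesign(size, arch) for size, arch in spec]


@dataclass
class SyntheticSpec:
    seed: int
    n_per_group: int = 6
    module_designs: list[ModuleDesign] = field(default_factory=default_module_designs)
    n_noise_proteins: int = 300
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    #: module label (M1.. by decreasing size) -> (trait column, target r)
    trait_couplings: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {"M4": ("cerad", 0.7), "M2": ("casi", 0.7)}
    )
    latent_sd: float = 0.4       # sample scatter of module latents, log2 units
    noise_sd: float = 0.5        # independent protein noise, log2 units
    baseline_mean: float = 20.0  # log2 baseline abundance
    baseline_sd: float = 1.5


def _rng(spec: SyntheticSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Sample trait table for an age-matched 3-group cohort.

    Ages are matched in triplets (one member per group sharing a base
    age), PMI is uniform on 2.5--8.5 h, and CASI/CERAD/Braak are drawn
    consistent with group: controls show low pathology and intact
    cognition, AsymAD shows AD-range pathology with control-like CASI,
    AD shows pathology with reduced CASI.
    """
    rng = _rng(spec, 1)
    n = spec.n_per_group
    rows = []
    base_ages = rng.normal(86.0, 4.0, size=n)
    for gi, group in enumerate(GROUPS):
        for j in range(n):
            age = base_ages[j] + rng.normal(0.0, 1.0)
            pmi = rng.uniform(2.5, 8.5)
            sex = "F" if rng.random() < 0.5 else "M"
            if group == "control":
                casi = rng.normal(94.0, 2.0)
                cerad = rng.uniform(0.0, 1.0)
                braak = rng.uniform(0.0, 2.5)
            elif group == "AsymAD":
                casi = rng.normal(93.0, 2.5)
                cerad = rng.uniform(1.5, 3.0)
                braak = rng.uniform(2.5, 5.0)
            else:
                casi = rng.normal(72.0, 8.0)
                cerad = rng.uniform(2.0, 3.0)
                braak = rng.uniform(3.5, 6.0)
            rows.append(
                {
                    "sample_id": f"s{gi * n + j + 1:02d}",
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "pmi": pmi,
                    "casi": float(np.clip(casi, 0, 100)),
                    "cerad": float(np.clip(cerad, 0, 3)),
                    "braak": float(np.clip(braak, 0, 6)),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class AbundanceTruth:
    """Ground truth returned alongside a generated matrix."""

    partition: ModulePartition          # planted labels (noise -> unassigned)
    latents: pd.DataFrame               # module x sample latent factors
    covariate_affected: pd.Index        # proteins carrying covariate effects
    traits: pd.DataFrame                # trait table with coupled columns


def generate_abundance(
    spec: SyntheticSpec, traits: pd.DataFrame
) -> tuple[ProteinAbundanceMatrix, AbundanceTruth]:
    """Planted-module log2 abundance matrix plus ground truth.

    Each module m has a latent factor L_m = archetype group mean +
    N(0, latent_sd) per sample; member proteins are
    baseline + loading * L_m + N(0, sigma_m) with sigma_m calibrated so
    the within-module pairwise correlation matches the design target
    (cor = var(L) / (var(L) + sigma^2) at unit loading). Covariate
    effects are added linearly to a random protein subset; coupled
    trait columns are rebuilt as r * z(L_m) + sqrt(1-r^2) * noise on
    the original trait scale.
    """
    rng = _rng(spec, 2)
    samples = traits.index
    n_samples = len(samples)
    group_idx = traits["group"].map({g: i for i, g in enumerate(GROUPS)}).values

    designs = sorted(spec.module_designs, key=lambda d: -d.size)
    labels: list[str] = []
    rows: list[np.ndarray] = []
    pids: list[str] = []
    latents = {}
    for mi, design in enumerate(designs):
        name = f"M{mi + 1}"
        pattern = np.array(ARCHETYPES[design.archetype])[group_idx]
        latent = pattern + rng.normal(0.0, spec.latent_sd, size=n_samples)
        latents[name] = latent
        var_l = latent.var(ddof=1)
        sigma = np.sqrt(var_l * (1.0 - design.cor_target) / design.cor_target)
        for j in range(design.size):
            loading = rng.uniform(0.8, 1.2)
            baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
            prof = baseline + loading * latent + rng.normal(0.0, sigma, size=n_samples)
            pids.append(f"P{len(pids) + 1:05d}")
            labels.append(name)
            rows.append(prof)
    for _ in range(spec.n_noise_proteins):
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
        prof = baseline + rng.normal(0.0, spec.noise_sd, size=n_samples)
        pids.append(f"P{len(pids) + 1:05d}")
        labels.append(UNASSIGNED)
        rows.append(prof)

    values = pd.DataFrame(np.vstack(rows), index=pids, columns=samples)

    # covariate effects on a random subset of proteins
    cov = spec.covariate_effects
    n_prot = len(pids)
    n_affected = int(round(cov.affected_fraction * n_prot))
    affected = rng.choice(n_prot, size=n_affected, replace=False)
    age = traits["age"].values - traits["age"].values.mean()
    sex01 = (traits["sex"] == "M").astype(float).values
    sex01 -= sex01.mean()
    pmi = traits["pmi"].values - traits["pmi"].values.mean()
    shift = cov.b_age * age + cov.b_sex * sex01 + cov.b_pmi * pmi
    values.iloc[affected] += shift

    # couple requested trait columns to module latents
    out_traits = traits.copy()
    bounds = {"casi": (0, 100), "cerad": (0, 3), "braak": (0, 6)}
    for module, (trait, r) in spec.trait_couplings.items():
        if module not in latents:
            raise ValueError(f"trait coupling references unknown module {module}")
        z = (latents[module] - latents[module].mean()) / latents[module].std(ddof=1)
        mixed = r * z + np.sqrt(1.0 - r * r) * rng.normal(0.0, 1.0, size=n_samples)
        orig = out_traits[trait].values
        new = orig.mean() + orig.std(ddof=1) * mixed
        lo, hi = bounds.get(trait, (-np.inf, np.inf))
        out_traits[trait] = np.clip(new, lo, hi)

    symbols = pd.Series([f"GENE{i + 1}" for i in range(n_prot)], index=pids)
    matrix = ProteinAbundanceMatrix(values, symbols, is_log2=True)
    truth = AbundanceTruth(
        partition=ModulePartition(pd.Series(labels, index=pids), stage="truth"),
        latents=pd.DataFrame(latents, index=samples).T,
        covariate_affected=pd.Index([pids[i] for i in sorted(affected)]),
        traits=out_traits,
    )
    return matrix, truth


#: membrane:soluble spectral-count ratios per planted compartment class
FRACTION_CLASSES = {
    "intrinsic_membrane": 4.0,
    "membrane": 2.0,
    "cytoplasmic": 0.25,
}


def generate_peptides(
    matrix: ProteinAbundanceMatrix,
    spec: SyntheticSpec,
    peptide_noise_sd: float = 0.1,
    max_peptides: int = 8,
) -> tuple[pd.DataFrame, pd.Series]:
    """Peptide-level table consistent with a protein matrix.

    Each protein gets 1--8 tryptic peptides with lognormal ionization
    efficiencies; per sample, peptide intensity = efficiency * protein
    abundance * lognormal noise. Spectral counts are Poisson with rate
    monotone in log intensity. Membrane and soluble fraction rows are
    emitted with per-class count ratios (returned as the second
    element: protein -> class).
    """
    rng = _rng(spec, 3)
    linear = 2.0 ** matrix.values if matrix.is_log2 else matrix.values
    class_names = list(FRACTION_CLASSES)
    records = []
    classes = {}
    for pid in matrix.protein_ids:
        gene = matrix.gene_symbols.loc[pid]
        cls = class_names[rng.integers(len(class_names))]
        classes[pid] = cls
        ratio = FRACTION_CLASSES[cls]
        n_pep = int(rng.integers(1, max_peptides + 1))
        effs = np.exp(rng.normal(0.0, 0.5, size=n_pep))
        unique_flags = rng.random(n_pep) < 0.9
        abund = linear.loc[pid].values
        for k in range(n_pep):
            pep = f"{pid}_pep{k + 1}"
            noise = np.exp(rng.normal(0.0, peptide_noise_sd, size=len(abund)))
            inten = effs[k] * abund * noise
            lam = np.maximum(np.log2(np.maximum(inten, 1.0)) - 14.0, 0.1) * 0.4
            mem_counts = rng.poisson(lam)
            sol_counts = rng.poisson(lam / ratio)
            for s, sample in enumerate(matrix.sample_ids):
                records.append(
                    (pep, pid, gene, sample, "membrane",
                     float(inten[s]), int(mem_counts[s]), bool(unique_flags[k]))
                )
                records.append(
                    (pep, pid, gene, sample, "soluble",
                     float(inten[s] / ratio), int(sol_counts[s]),
                     bool(unique_flags[k]))
                )
    table = pd.DataFrame(
        records,
        columns=[
            "peptide_sequence", "protein_group", "gene_symbol", "sample_id",
            "fraction", "intensity", "spectral_counts", "is_unique",
        ],
    )
    return table, pd.Series(classes, name="class")


def generate_dataset(spec: SyntheticSpec):
    """Convenience wrapper: cohort + abundance + truth in one call."""
    cohort = generate_cohort(spec)
    matrix, truth = generate_abundance(spec, cohort)
    return matrix, truth
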