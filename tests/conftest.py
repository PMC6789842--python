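import numpy as np
import pandas as pd
import pytest

from wpcna.synthetic import (
    ModuleDesign,
    SyntheticSpec,
    generate_abundance,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale design for unit tests: 3 modules + 60 noise proteins."""
    return SyntheticSpec(
        seed=41,
        module_designs=[
            ModuleDesign(40, "progressive_decrease"),
            ModuleDesign(30, "transient_up"),
            ModuleDesign(25, "stable"),
        ],
        n_noise_proteins=60,
        trait_couplings={"M1": ("cerad", 0.7)},
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    traits = generate_cohort(small_spec)
    matrix, truth = generate_abundance(small_spec, traits)
    return matrix, truth


def toy_peptide_table() -> pd.DataFrame:
    """Hand-sized peptide table: 2 proteins x 2 samples, membrane only."""
    rows = []
    intens = {
        ("PA", "s1"): [10.0, 5.0, 3.0, 1.0],
        ("PA", "s2"): [8.0, 4.0],
        ("PB", "s1"): [6.0, 2.0, 2.0],
        ("PB", "s2"): [0.0, 7.0, 1.0],
    }
    for (prot, sample), vals in intens.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "peptide_sequence": f"{prot}_p{i}",
                    "protein_group": prot,
                    "gene_symbol": prot.replace("P", "G"),
                    "sample_id": sample,
                    "fraction": "membrane",
                    "intensity": v,
                    "spectral_counts": 2,
                    "is_unique": True,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
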