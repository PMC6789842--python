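"""Pipeline orchestration from a declarative YAML configuration.

Stages run in order simulate -> quantify -> preprocess -> diffexpr ->
network -> enrich -> traits -> overlap; each writes its outputs into
the run directory and a manifest records parameters, input hashes,
seed and package version, so re-running an unchanged configuration
reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from wpcna import __version__, io
from wpcna.datatypes import NetworkParams, ProteinAbundanceMatrix
from wpcna.preprocess import RegressionConfig, regress_covariates
from wpcna.synthetic import (
    CovariateEffects,
    ModuleDesign,
    SyntheticSpec,
    generate_abundance,
    generate_cohort,
    generate_peptides,
)

log = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate", "quantify", "preprocess", "diffexpr",
    "network", "enrich", "traits", "overlap",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    paths: dict[str, str] = field(default_factory=dict)
    quantify: dict[str, Any] = field(default_factory=dict)
    regression: dict[str, Any] = field(default_factory=dict)
    diffexpr: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)
    enrich: dict[str, Any] = field(default_factory=dict)
    traits: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict[str, Any]) -> "RunConfig":
        cfg = RunConfig(
            out_dir=Path(raw.get("out_dir", "wpcna_run")),
            seed=int(raw.get("seed", 0)),
            stages=list(raw.get("stages", STAGE_ORDER)),
            paths=dict(raw.get("paths", {})),
            quantify=dict(raw.get("quantify", {})),
            regression=dict(raw.get("regression", {})),
            diffexpr=dict(raw.get("diffexpr", {})),
            network=dict(raw.get("network", {})),
            enrich=dict(raw.get("enrich", {})),
            traits=dict(raw.get("traits", {})),
            simulate=dict(raw.get("simulate", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        # parameter bounds are enforced by the stage dataclasses
        self.network_params()
        if "simulate" not in self.stages:
            for key, p in self.paths.items():
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"configured input {key} not found: {p}")

    def network_params(self) -> NetworkParams:
        kw = {k: v for k, v in self.network.items() if k != "save_matrices"}
        return NetworkParams(**kw)

    def regression_config(self) -> RegressionConfig:
        kw = dict(self.regression)
        kw.setdefault("seed", self.seed)
        return RegressionConfig(**kw)

    def synthetic_spec(self) -> SyntheticSpec:
        kw = dict(self.simulate)
        kw.setdefault("seed", self.seed)
        if "module_designs" in kw:
            kw["module_designs"] = [ModuleDesign(**d) for d in kw["module_designs"]]
        if "covariate_effects" in kw:
            kw["covariate_effects"] = CovariateEffects(**kw["covariate_effects"])
        if "trait_couplings" in kw:
            kw["trait_couplings"] = {
                m: (t, float(r)) for m, (t, r) in kw["trait_couplings"].items()
            }
        return SyntheticSpec(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns a results bundle.

    On stage failure the run aborts with the failing stage named and a
    FAILED marker file; outputs of completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": cfg.stages,
        "parameters": {
            "quantify": cfg.quantify, "regression": cfg.regression,
            "diffexpr": cfg.diffexpr, "network": cfg.network,
            "enrich": cfg.enrich, "traits": cfg.traits,
            "simulate": cfg.simulate,
        },
        "inputs": {},
        "outputs": {},
    }
    for key, p in cfg.paths.items():
        if p and Path(p).exists():
            manifest["inputs"][key] = _sha256(Path(p))

    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        log.info("stage %s starting", stage)
        try:
            _STAGES[stage](cfg, out, results)
        except Exception:
            (out / "FAILED").write_text(stage + "\n")
            log.error("stage %s failed", stage)
            raise RuntimeError(f"pipeline stage '{stage}' failed") from None
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


# ------------------------------------------------------------------- stages

def _stage_simulate(cfg: RunConfig, out: Path, res: dict) -> None:
    spec = cfg.synthetic_spec()
    cohort = generate_cohort(spec)
    matrix, truth = generate_abundance(spec, cohort)
    peptides, classes = generate_peptides(matrix, spec)
    io.write_peptide_table(peptides, out / "peptides.tsv")
    io.write_traits(truth.traits, out / "traits.csv")
    io.write_protein_matrix(matrix, out / "true_matrix.tsv")
    io.write_partition(truth.partition, matrix.gene_symbols, out / "true_partition.tsv")
    truth.latents.to_csv(out / "true_latents.tsv", sep="\t")
    class_sets: dict[str, set[str]] = {}
    for pid, cls in classes.items():
        class_sets.setdefault(cls, set()).add(str(matrix.gene_symbols.loc[pid]).upper())
    io.write_gmt(class_sets, out / "compartment_classes.gmt")
    res["peptides"], res["traits_table"], res["truth"] = peptides, truth.traits, truth
    res["class_map"] = class_sets


def _load_traits(cfg: RunConfig, res: dict) -> pd.DataFrame:
    if "traits_table" in res:
        return res["traits_table"]
    return io.read_traits(cfg.paths["traits"])


def _stage_quantify(cfg: RunConfig, out: Path, res: dict) -> None:
    from wpcna import quantify as q

    if "matrix" in cfg.paths and cfg.paths["matrix"]:
        res["matrix"] = io.read_protein_matrix(cfg.paths["matrix"])
        log.info("quantify: using provided protein matrix, peptide stage bypassed")
        return
    peptides = res.get("peptides")
    if peptides is None:
        peptides = io.read_peptide_table(cfg.paths["peptides"])
    retained = q.filter_protein_groups(
        peptides,
        min_unique_peptides=int(cfg.quantify.get("min_unique_peptides", 1)),
        min_spectral_counts=int(cfg.quantify.get("min_spectral_counts", 2)),
    )
    matrix = q.top3_protein_abundance(peptides, retained)
    io.write_protein_matrix(matrix, out / "protein_matrix.tsv")
    res["matrix"] = matrix
    class_map = res.get("class_map")
    if class_map is None and cfg.paths.get("class_gmt"):
        class_map = io.read_gmt(cfg.paths["class_gmt"])
    if class_map:
        try:
            profile = q.membrane_enrichment_profile(peptides, class_map)
            profile.table.to_csv(out / "enrichment_deciles.tsv", sep="\t", index=False)
            res["decile_profile"] = profile
        except ValueError as exc:
            log.warning("decile profile skipped: %s", exc)


def _stage_preprocess(cfg: RunConfig, out: Path, res: dict) -> None:
    traits = _load_traits(cfg, res)
    reg = regress_covariates(res["matrix"], traits, cfg.regression_config())
    io.write_protein_matrix(reg, out / "regressed_matrix.tsv")
    res["regressed"] = reg


def _stage_diffexpr(cfg: RunConfig, out: Path, res: dict) -> None:
    from wpcna import diffexpr as dx

    traits = _load_traits(cfg, res)
    matrix = res.get("regressed", res.get("matrix"))
    table = dx.anova_tukey(matrix, traits)
    table.to_csv(out / "diffexpr.tsv", sep="\t")
    alpha = float(cfg.diffexpr.get("alpha", 0.05))
    sets, regions = dx.significant_sets(table, alpha)
    with open(out / "diffexpr_sets.json", "w") as fh:
        json.dump(
            {"alpha": alpha, "regions": regions,
             "sets": {k: sorted(v) for k, v in sets.items()}},
            fh, indent=2, sort_keys=True,
        )
    dx.volcano_table(table).to_csv(out / "volcano.tsv", sep="\t", index=False)
    res["diffexpr"], res["significant"] = table, (sets, regions)


def _stage_network(cfg: RunConfig, out: Path, res: dict) -> None:
    from wpcna import network as nw

    params = cfg.network_params()
    matrix = res.get("regressed", res.get("matrix"))
    complete = matrix.complete_cases()
    dropped = len(matrix.protein_ids) - len(complete.protein_ids)
    if dropped:
        log.info("network: %d proteins with missing cells excluded", dropped)
    cor = (nw.bicor_matrix(complete) if params.cor_method == "bicor"
           else nw.pearson_matrix(complete))
    adj = (nw.signed_adjacency(cor, params.beta) if params.signed
           else nw.unsigned_adjacency(cor, params.beta))
    tom = nw.tom_similarity(adj, params.tom_denom)
    if cfg.network.get("save_matrices"):
        io.write_square_matrix(cor, out / "correlation.tsv")
        io.write_square_matrix(adj, out / "adjacency.tsv")
        io.write_square_matrix(tom, out / "tom.tsv")
    part, Z = nw.detect_modules(tom, params)
    if len(part.modules) >= 2:
        part, eig = nw.merge_modules(complete, part, params.merge_cut_height)
    else:
        eig = nw.module_eigenproteins(complete, part) if part.modules else None
    if eig is not None:
        kme, kme_p = nw.compute_kme(complete, eig)
        part = nw.reassign_low_kme(complete, part, kme, kme_p, params.reassign_p)
        eig = nw.module_eigenproteins(complete, part)
        kme, kme_p = nw.compute_kme(complete, eig)
        kme.to_csv(out / "kme.tsv", sep="\t")
        eig.values.to_csv(out / "eigenproteins.tsv", sep="\t")
        eig.variance_explained.to_csv(out / "variance_explained.tsv", sep="\t",
                                      header=["variance_explained"])
        own = pd.Series(
            [kme.loc[p, m] if m != "unassigned" else float("nan")
             for p, m in part.assignment.items()],
            index=part.assignment.index,
        )
    else:
        kme = kme_p = None
        own = None
    io.write_partition(part, complete.gene_symbols, out / "partition.tsv", kme_own=own)
    if len(Z):
        (out / "dendrogram.nwk").write_text(
            io.linkage_to_newick(Z, list(complete.protein_ids))
        )
    res.update(network_matrix=complete, partition=part, eigenproteins=eig,
               kme=kme, kme_p=kme_p, tom=tom)


def _stage_enrich(cfg: RunConfig, out: Path, res: dict) -> None:
    from wpcna import enrich as en

    part = res["partition"]
    symbols = res["network_matrix"].gene_symbols
    for key, fname in (("cell_type_gmt", "cell_type_enrichment.tsv"),
                       ("ontology_gmt", "ontology_enrichment.tsv")):
        path = cfg.paths.get(key)
        sets = io.read_gmt(path) if path else None
        if sets is None and key == "cell_type_gmt":
            sets = res.get("class_map")  # simulated compartment classes
        if not sets:
            continue
        table = en.fisher_enrichment(part, symbols, sets)
        table.to_csv(out / fname, sep="\t", index=False)
        res[key.replace("_gmt", "_enrichment")] = table


def _stage_traits(cfg: RunConfig, out: Path, res: dict) -> None:
    from wpcna import traits as tr

    if res.get("eigenproteins") is None:
        log.warning("traits stage skipped: no eigenproteins")
        return
    traits = _load_traits(cfg, res)
    columns = tuple(cfg.traits.get("columns", tr.DEFAULT_TRAITS))
    R, P = tr.module_trait_bicor(res["eigenproteins"], traits, columns)
    grid = tr.trait_grid_table(R, P)
    grid.to_csv(out / "module_trait_correlation.tsv", sep="\t", index=False)
    kw = tr.eigenprotein_group_test(res["eigenproteins"], traits)
    kw.to_csv(out / "eigenprotein_group_test.tsv", sep="\t")
    res["trait_correlation"], res["group_test"] = (R, P), kw


def _stage_overlap(cfg: RunConfig, out: Path, res: dict) -> None:
    from wpcna import enrich as en

    ref = cfg.paths.get("reference_partition")
    if not ref:
        log.info("overlap stage skipped: no reference partition configured")
        return
    part_b, symbols_b = io.read_partition(ref, stage="reference")
    result = en.cross_network_overlap(
        res["partition"], res["network_matrix"].gene_symbols, part_b, symbols_b
    )
    for name, df in result.items():
        df.to_csv(out / f"overlap_{name}.tsv", sep="\t")
    res["overlap"] = result


_STAGES = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "preprocess": _stage_preprocess,
    "diffexpr": _stage_diffexpr,
    "network": _stage_network,
    "enrich": _stage_enrich,
    "traits": _stage_traits,
    "overlap": _stage_overlap,
}
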