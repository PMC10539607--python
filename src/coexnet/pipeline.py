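"""Pipeline configuration and end-to-end orchestration.

``run_pipeline`` wires the stages together in study order — network
construction, external preservation, functional enrichment, cell-type
localization and phenotype association, drug-panel susceptibility scoring,
and directional signature interaction — reading every input from the paths
in a validated :class:`PipelineConfig` and writing diff-able TSV/JSON
reports. Outputs are a pure function of (inputs, config, seed): re-running
with the same seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io, localization, network, osm, preservation, simulate
from ._rng import substream
from .enrichment import enrich_modules
from .interaction import build_interaction_report
from .types import GREY

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "write_simulated_inputs"]

log = logging.getLogger("coexnet")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputPaths(_Strict):
    expression: Path
    expression_external: Optional[Path] = None
    gene_sets: Optional[Path] = None
    markers: Optional[Path] = None
    signature_matrix: Optional[Path] = None
    covariates: Optional[Path] = None
    drug_signatures: Optional[Path] = None


class NetworkParams(_Strict):
    power: Optional[int] = Field(default=None, ge=1, le=30)  # None = pick automatically
    powers: list[int] = Field(default_factory=lambda: list(range(1, 21)))
    r2_target: float = Field(default=0.8, gt=0.0, lt=1.0)
    mode: Literal["unsigned", "signed"] = "unsigned"
    correlation: Literal["pearson", "spearman"] = "pearson"
    min_module_size: int = Field(default=30, ge=3)
    cut_quantile: float = Field(default=0.5, gt=0.0, lt=1.0)
    merge_corr: float = Field(default=0.75, gt=0.0, lt=1.0)


class PreservationParams(_Strict):
    n_perm: int = Field(default=200, ge=10)
    z_threshold: float = Field(default=2.0, gt=0.0)


class EnrichmentParams(_Strict):
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    or_threshold: float = Field(default=1.0, ge=0.0)


class OsmParams(_Strict):
    top_fraction: float = Field(default=0.05, gt=0.0, lt=0.5)
    aggregation: Literal["stouffer", "mean", "max"] = "stouffer"


class AssociationParams(_Strict):
    fdr: float = Field(default=0.1, gt=0.0, lt=1.0)


class InteractionParams(_Strict):
    sig_a: Optional[str] = None
    sig_b: Optional[str] = None
    min_overlap: int = Field(default=2, ge=2)
    min_abs_score: Optional[float] = Field(default=None, gt=0.0)


class PipelineConfig(_Strict):
    """Validated pipeline parameters; unknown keys are rejected."""

    inputs: InputPaths
    network: NetworkParams = NetworkParams()
    preservation: PreservationParams = PreservationParams()
    enrichment: EnrichmentParams = EnrichmentParams()
    osm: OsmParams = OsmParams()
    association: AssociationParams = AssociationParams()
    interaction: InteractionParams = InteractionParams()
    seed: int = 0

    @model_validator(mode="after")
    def _check_powers(self):
        if any(p < 1 for p in self.network.powers):
            raise ValueError("network.powers must be positive integers")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    cfg = PipelineConfig.model_validate(data)
    base = Path(path).parent
    # resolve input paths relative to the config file
    for name in InputPaths.model_fields:
        p = getattr(cfg.inputs, name)
        if p is not None and not p.is_absolute():
            setattr(cfg.inputs, name, base / p)
    return cfg


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every configured stage and write the report directory.

    Writes, in order: modules.tsv, eigengenes.tsv, preservation.tsv,
    enrichment.tsv, localization.tsv, osm.tsv, interaction.json, plus
    soft_threshold.tsv / proportions.tsv / associations.tsv side tables and
    run_log.txt recording the seed and all resolved parameters. Stages whose
    inputs are not configured emit empty (header-only) tables so the full
    report set always exists.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = _read_expression(config)
    modules, eigengenes, kme, st_report = _stage("network")(_run_network)(config, expr)
    _write_modules(outdir, modules, kme)
    io.write_table(eigengenes.values, outdir / "eigengenes.tsv")
    if st_report is not None:
        io.write_table(st_report.to_frame(), outdir / "soft_threshold.tsv", index=False)

    _stage("preservation")(_run_preservation)(config, expr, modules, outdir)
    _stage("enrichment")(_run_enrichment)(config, expr, modules, outdir)
    _stage("localization")(_run_localization)(config, expr, modules, eigengenes, outdir)
    panel = _stage("osm")(_run_osm)(config, expr, modules, outdir)
    _stage("interaction")(_run_interaction)(config, expr, panel, outdir)

    with open(outdir / "run_log.txt", "w", encoding="utf-8") as fh:
        fh.write("coexnet pipeline run\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write("resolved parameters:\n")
        fh.write(json.dumps(json.loads(config.model_dump_json()), indent=2, sort_keys=True))
        fh.write("\n")
    return outdir


def _read_expression(config: PipelineConfig) -> pd.DataFrame:
    expr = io.read_expression_matrix(config.inputs.expression)
    variances = expr.var(axis=1, ddof=1)
    keep = variances > 0
    if (~keep).any():
        log.warning("dropping %d zero-variance gene(s)", int((~keep).sum()))
        expr = expr.loc[keep]
    return expr


def _run_network(config: PipelineConfig, expr: pd.DataFrame):
    p = config.network
    st_report = None
    if p.power is None:
        st_report = network.pick_soft_threshold(
            expr, powers=p.powers, r2_target=p.r2_target, mode=p.mode,
            method=p.correlation,
        )
        power = st_report.chosen_power
    else:
        power = p.power
    adj = network.build_adjacency(expr, power, mode=p.mode, method=p.correlation)
    tom = network.topological_overlap(adj)
    modules = network.detect_modules(tom, p.min_module_size, p.cut_quantile)
    modules = network.merge_close_modules(expr, modules, p.merge_corr)
    eigengenes = network.compute_eigengenes(expr, modules)
    kme = network.module_membership(expr, eigengenes)
    return modules, eigengenes, kme, st_report


def _write_modules(outdir: Path, modules: pd.Series, kme: pd.DataFrame) -> None:
    own_kme = [
        kme.loc[g, m] if m != GREY and m in kme.columns else float("nan")
        for g, m in modules.items()
    ]
    table = pd.DataFrame({"gene": modules.index, "module": modules.values, "kme": own_kme})
    io.write_table(table, outdir / "modules.tsv", index=False)


_PRESERVATION_COLS = [
    "module", "n_genes", "density_obs", "z_density", "z_connectivity",
    "z_summary", "evaluable", "replicable",
]


def _run_preservation(config, expr, modules, outdir: Path) -> None:
    path = config.inputs.expression_external
    if path is None:
        io.write_table(
            pd.DataFrame(columns=_PRESERVATION_COLS), outdir / "preservation.tsv",
            index=False,
        )
        return
    test_expr = io.read_expression_matrix(path)
    result = preservation.module_preservation(
        expr, test_expr, modules,
        n_perm=config.preservation.n_perm,
        seed=int(substream(config.seed, "preservation-stage").integers(2**31)),
    )
    replicable = preservation.replicable_modules(result, config.preservation.z_threshold)
    out = result.reset_index()
    out["replicable"] = out["module"].isin(replicable)
    io.write_table(out[_PRESERVATION_COLS], outdir / "preservation.tsv", index=False)


def _run_enrichment(config, expr, modules, outdir: Path) -> None:
    path = config.inputs.gene_sets
    cols = ["module", "set", "a", "b", "c", "d", "odds_ratio", "p", "q", "significant"]
    if path is None:
        io.write_table(pd.DataFrame(columns=cols), outdir / "enrichment.tsv", index=False)
        return
    lib = io.read_gmt(path)
    table = enrich_modules(
        modules, lib, universe=set(expr.index),
        alpha=config.enrichment.alpha, or_threshold=config.enrichment.or_threshold,
    )
    io.write_table(table, outdir / "enrichment.tsv", index=False)


def _run_localization(config, expr, modules, eigengenes, outdir: Path) -> None:
    cols = ["module", "set", "a", "b", "c", "d", "odds_ratio", "p", "q", "significant"]
    if config.inputs.markers is not None:
        markers = io.read_gmt(config.inputs.markers)
        table = localization.celltype_specificity(
            modules, markers, universe=set(expr.index),
            alpha=config.enrichment.alpha, or_threshold=config.enrichment.or_threshold,
        )
    else:
        table = pd.DataFrame(columns=cols)
    io.write_table(table, outdir / "localization.tsv", index=False)

    proportions = None
    if config.inputs.signature_matrix is not None:
        sig_mat = io.read_table(config.inputs.signature_matrix)
        # constrained least squares needs non-negative bulk values
        bulk = expr - float(expr.values.min())
        proportions = localization.deconvolve(bulk, sig_mat)
        io.write_table(proportions, outdir / "proportions.tsv")

    covariates = []
    if config.inputs.covariates is not None:
        covariates.append(io.read_table(config.inputs.covariates))
    if proportions is not None:
        covariates.append(proportions)
    if covariates:
        cov = pd.concat(covariates, axis=1)
        assoc = localization.correlate_eigengene_covariate(
            eigengenes, cov, fdr=config.association.fdr
        )
        io.write_table(assoc, outdir / "associations.tsv", index=False)


def _run_osm(config, expr, modules, outdir: Path):
    path = config.inputs.drug_signatures
    if path is None:
        io.write_table(pd.DataFrame(columns=["module"]), outdir / "osm.tsv", index=False)
        return None
    panel = io.read_drug_signatures(path)
    drug_sets = osm.panel_genesets(panel, config.osm.top_fraction)
    z_table = osm.network_drug_zscores(modules, drug_sets, universe=set(expr.index))
    if z_table.shape[0] >= 2 and z_table.shape[1] >= 2:
        scores = osm.osm_scores(z_table, aggregation=config.osm.aggregation)
    else:
        scores = z_table
    io.write_table(scores.reset_index(), outdir / "osm.tsv", index=False)
    return panel


def _run_interaction(config, expr, panel, outdir: Path) -> None:
    p = config.interaction
    if panel is None or p.sig_a is None or p.sig_b is None:
        io.write_json({"skipped": "no signature pair configured"}, outdir / "interaction.json")
        return
    sig_a, sig_b = panel[p.sig_a], panel[p.sig_b]
    if p.min_abs_score is not None:
        sig_a = sig_a.filter_abs(p.min_abs_score)
        sig_b = sig_b.filter_abs(p.min_abs_score)
    report = build_interaction_report(
        sig_a, sig_b, universe=set(expr.index),
        alpha=config.enrichment.alpha, or_threshold=config.enrichment.or_threshold,
        min_overlap=p.min_overlap,
    )
    with open(outdir / "interaction.json", "w", encoding="utf-8") as fh:
        fh.write(report.to_json())
        fh.write("\n")
    io.write_table(report.pair_table, outdir / "scatter.tsv", index=False)


# ---------------------------------------------------------------------------
# Simulated-input bundle


def write_simulated_inputs(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 1300,
    n_samples: int = 200,
    n_modules: int = 5,
    module_size: int = 60,
    noise_sd: float = 1.0,
    n_external_samples: int = 160,
) -> Path:
    """Generate the full synthetic input bundle plus a matching config.

    Plants ``n_modules`` coexpression modules; preserves all but the last in
    the external cohort; builds a drug panel with four pan-panel drugs on
    module 1, an opposing morphine-like / ICI-like pair on module 1, and a
    neutral ketamine-like drug on the last module; derives the cell-type
    signature matrix, marker sets, pathway library and an sTIL-like
    phenotype from the ground truth. Writes ``config.yaml`` and
    ``ground_truth.json`` alongside the inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = simulate.simulate_cohort(
        n_genes=n_genes, n_samples=n_samples, n_modules=n_modules,
        module_size=module_size, noise_sd=noise_sd, seed=seed,
    )
    preserved = truth.planted_modules[:-1] if n_modules > 1 else truth.planted_modules
    external = simulate.simulate_external_cohort(
        truth, preserved, n_samples=n_external_samples, seed=seed
    )
    specs = [
        simulate.DrugSpec(f"opioid_{i}", 1, +1 if i % 2 else -1, 2.0, 0.8)
        for i in range(1, 5)
    ]
    specs += [
        simulate.DrugSpec("morphine_analog", 1, -1, 2.0, 0.8),
        simulate.DrugSpec("ici_analog", 1, +1, 2.0, 0.8),
        simulate.DrugSpec("ketamine_analog", truth.planted_modules[-1], +1, 2.0, 0.3),
    ]
    panel = simulate.simulate_drug_panel(truth, specs, background_sd=0.5, seed=seed)
    phenotype = simulate.simulate_phenotype(
        truth, driver_modules=[1], beta=1.0, noise_sd=0.5, seed=seed
    )
    sig_mat = simulate.signature_matrix_from_truth(truth)
    markers = simulate.markers_from_signature_matrix(sig_mat, top_n=50)

    io.write_expression_matrix(expr, outdir / "expression.tsv")
    io.write_expression_matrix(external, outdir / "expression_external.tsv")
    io.write_drug_signatures(panel, outdir / "drug_signatures.tsv")
    io.write_table(sig_mat, outdir / "signature_matrix.tsv")
    io.write_table(phenotype.to_frame("sTIL"), outdir / "covariates.tsv")

    from .types import GeneSetLibrary

    marker_lib = GeneSetLibrary()
    for ct, genes in markers.items():
        marker_lib.add(f"{ct}_markers", genes, f"top markers of cell type {ct}")
    io.write_gmt(marker_lib, outdir / "markers.gmt")

    rng = substream(seed, "pathway-library")
    pathway_lib = GeneSetLibrary()
    all_genes = list(expr.index)
    for m in truth.planted_modules:
        genes = truth.module_genes(m)
        extra = list(rng.choice(all_genes, size=10, replace=False))
        pathway_lib.add(f"pathway_module_{m}", set(genes) | set(extra),
                        f"planted pathway overlapping module {m}")
    for i in range(3):
        pathway_lib.add(
            f"pathway_random_{i + 1}",
            list(rng.choice(all_genes, size=50, replace=False)),
            "random control set",
        )
    io.write_gmt(pathway_lib, outdir / "pathways.gmt")

    io.write_json(
        {
            "module_labels": {g: int(m) for g, m in truth.module_labels.items()},
            "loadings": {g: float(v) for g, v in truth.loadings.items()},
            "preserved_modules": sorted(truth.preserved_modules),
            "phenotype_drivers": sorted(truth.phenotype_drivers),
            "drugs": {
                name: {
                    "target_module": s.target_module,
                    "direction": s.direction,
                    "effect_size": s.effect_size,
                    "frac_affected": s.frac_affected,
                }
                for name, s in truth.drug_map.items()
            },
        },
        outdir / "ground_truth.json",
    )

    cfg = {
        "inputs": {
            "expression": "expression.tsv",
            "expression_external": "expression_external.tsv",
            "gene_sets": "pathways.gmt",
            "markers": "markers.gmt",
            "signature_matrix": "signature_matrix.tsv",
            "covariates": "covariates.tsv",
            "drug_signatures": "drug_signatures.tsv",
        },
        "network": {"power": 6},
        "interaction": {
            "sig_a": "morphine_analog",
            "sig_b": "ici_analog",
            "min_abs_score": 1.5,
        },
        "seed": int(seed),
    }
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir
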