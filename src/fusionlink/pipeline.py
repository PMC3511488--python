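"""End-to-end orchestration: trimming, parallel clustering, enrichment
intersection and fusion-slope classification, with stage outputs on disk
and a deterministic JSON run summary."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as flio
from .cluster import DEND, MetaClade, SOM, hcluster_metaclades, som_metaclades, \
    tissue_cell_ratio, train_som
from .enrichment import PathwayCollection, co_occurring_pathways, overrepresentation_test
from .fusion import FusionPanel, classify_targets, codebook_correlation_map, \
    fit_gene_slopes
from .matrix import ExpressionMatrix
from .pca import GridSpec, fit_pca2, grid_density_trim, side_labels
from .preprocess import filter_present_calls, log_average_normalize, log_ratio, \
    pool_patients
from .synthetic import Cohort, SimConfig, generate_cohort, make_planted_pathways

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class InputPaths:
    tissue: str
    cell: str
    fusion: str
    gmt: str


@dataclass
class PipelineParams:
    grid: GridSpec = field(default_factory=GridSpec)
    dend_k: int = 5
    som_rows: int = 20
    som_cols: int = 12
    som_epochs: int = 200
    som_k: int = 10
    enrich_threshold: float = 0.05
    min_overlap: int = 2
    sign_threshold: float = 0.05
    require_significance: bool = False
    collapse_replicates: bool = True


@dataclass
class PipelineConfig:
    """Exactly one of ``simulate`` / ``inputs`` drives the run."""

    outdir: str
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: InputPaths | None = None
    n_background_sets: int = 25
    background_set_size: int = 40
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise PipelineError("exactly one of simulate/inputs must be given")


def config_from_yaml(path) -> PipelineConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    params = PipelineParams(**{
        **{k: v for k, v in (raw.get("params") or {}).items() if k != "grid"},
        **({"grid": GridSpec(**raw["params"]["grid"])}
           if raw.get("params", {}).get("grid") else {}),
    })
    sim = None
    if raw.get("simulate") is not None:
        sim = SimConfig(**raw["simulate"])
    inputs = InputPaths(**raw["inputs"]) if raw.get("inputs") else None
    return PipelineConfig(
        outdir=raw["outdir"],
        seed=int(raw.get("seed", 0)),
        simulate=sim,
        inputs=inputs,
        n_background_sets=int(raw.get("n_background_sets", 25)),
        background_set_size=int(raw.get("background_set_size", 40)),
        params=params,
    )


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o).__name__)

    fields = dataclasses.asdict(config)
    fields.pop("outdir", None)  # scientific configuration only
    payload = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
@dataclass
class PipelineResult:
    summary: dict
    candidates: pd.DataFrame
    controls: pd.DataFrame
    outdir: Path


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        cohort = generate_cohort(sim)
        collection = make_planted_pathways(
            cohort.truth,
            n_background=config.n_background_sets,
            background_size=config.background_set_size,
            seed=(config.seed + 1000) % 2**31,
        )
        return cohort.tissue, cohort.cell, cohort.fusion, collection, cohort.truth
    paths = config.inputs
    tissue = flio.read_expression_table(paths.tissue)
    cell = flio.read_expression_table(paths.cell)
    fusion = flio.read_fusion_panel(paths.fusion)
    gmt = flio.parse_gmt(paths.gmt)
    return tissue, cell, fusion, gmt, None


def _write_metaclades(clades: list[MetaClade], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("gene_id\troute\tlabel\n")
        for clade in clades:
            for gene in clade.genes:
                fh.write(f"{gene}\t{clade.route_tag}\t{clade.label}\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute filter -> normalize -> pool -> PCA trim -> (Ward + SOM)
    -> enrichment -> co-occurrence -> fusion fits -> classification.

    Writes every stage table plus ``summary.json`` under ``config.outdir``;
    two runs with the same configuration produce byte-identical summaries.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params

    logger.info("stage input: loading data (seed=%d)", config.seed)
    tissue, cell, fusion, collection, truth = _load_inputs(config)
    n_input = tissue.n_genes
    if config.simulate is not None:
        flio.write_expression_table(tissue, outdir / "tissue_expression.tsv")
        flio.write_expression_table(cell, outdir / "cell_expression.tsv")
        flio.write_fusion_panel(fusion, outdir / "fusion_panel.csv")
        flio.write_truth_json(truth, outdir / "ground_truth.json")
        flio.write_gmt(collection, outdir / "pathways.gmt")

    logger.info("stage filter: present-call trimming of %d genes", n_input)
    tissue_f = filter_present_calls(tissue)
    cell_f = filter_present_calls(cell)
    present = tissue_f.gene_ids.intersection(cell_f.gene_ids)
    tissue_f = tissue_f.subset_genes(present)
    cell_f = cell_f.subset_genes(present)
    logger.info("stage filter: %d genes retained", len(present))
    if len(present) < 10:
        raise PipelineError("fewer than 10 genes survive the present-call filter")

    logger.info("stage normalize: log2 ratio to reference, replicate averaging")
    tissue_log = log_average_normalize(tissue_f)
    cell_log = log_average_normalize(cell_f)
    tissue_pooled = pool_patients(tissue_log)
    cell_profile = pool_patients(cell_log)

    logger.info("stage pca: two-variable PCA and grid-density trim")
    pca = fit_pca2(tissue_pooled, cell_profile)
    trim = grid_density_trim(pca, p.grid)
    side = side_labels(trim)
    logger.info(
        "stage pca: variance_fraction=%.3f, retained=%d (above=%d below=%d)",
        pca.variance_fraction, len(trim.retained_genes),
        len(trim.above_pc1), len(trim.below_pc1),
    )
    trim_table = pd.DataFrame({
        "pc1_score": pca.scores["pc1"],
        "pc2_score": pca.scores["pc2"],
        "retained": pca.scores.index.isin(trim.retained_genes),
        "side": [
            ("above" if g in set(trim.above_pc1) else
             "below" if g in set(trim.below_pc1) else "")
            for g in pca.scores.index
        ],
    })
    trim_table.to_csv(outdir / "pca_trim.tsv", sep="\t", index_label="gene_id")

    if len(trim.above_pc1) < p.dend_k or len(trim.below_pc1) < p.dend_k:
        raise PipelineError("too few retained genes on one side of the first PC")

    logger.info("stage dend: Ward meta-clades (k=%d per side)", p.dend_k)
    letters_above = [chr(ord("A") + i) for i in range(p.dend_k)]
    letters_below = [chr(ord("A") + p.dend_k + i) for i in range(p.dend_k)]
    dend_above = hcluster_metaclades(
        tissue_pooled.loc[trim.above_pc1], p.dend_k, route_tag=DEND, labels=letters_above
    )
    dend_below = hcluster_metaclades(
        cell_profile.loc[trim.below_pc1], p.dend_k, route_tag=DEND, labels=letters_below
    )
    dend_clades = dend_above + dend_below
    _write_metaclades(dend_clades, outdir / "dend_metaclades.tsv")

    logger.info("stage som: %dx%d map, %d epochs", p.som_rows, p.som_cols, p.som_epochs)
    patient_matrix = log_ratio(tissue_f).values.loc[trim.retained_genes]
    grid = train_som(
        patient_matrix,
        rows=p.som_rows,
        cols=p.som_cols,
        epochs=p.som_epochs,
        seed=config.seed,
        patients=tissue_f.patients,
    )
    som_clades, node_labels = som_metaclades(grid, p.som_k)
    ratios = tissue_cell_ratio(som_clades, side)
    pcc_map = codebook_correlation_map(grid, fusion)
    node_table = pd.DataFrame({
        "node_row": np.repeat(np.arange(grid.rows), grid.cols),
        "node_col": np.tile(np.arange(grid.cols), grid.rows),
        "meta_clade": node_labels.ravel(),
        "n_genes": np.bincount(grid.bmu.to_numpy(), minlength=grid.n_nodes),
        "neighbor_similarity": grid.neighbor_similarity.ravel(),
        "fusion_pcc": pcc_map.ravel(),
    })
    node_table.to_csv(outdir / "som_nodes.tsv", sep="\t", index=False)
    _write_metaclades(som_clades, outdir / "som_metaclades.tsv")

    logger.info("stage enrichment: over-representation per meta-clade")
    universe_collection = PathwayCollection(
        pathways=collection.pathways,
        universe=frozenset(present),
        descriptions=collection.descriptions,
    )
    dend_results = {
        clade.label: overrepresentation_test(
            clade.genes, universe_collection,
            threshold=p.enrich_threshold, min_overlap=p.min_overlap,
            source_clade=f"{DEND}:{clade.label}",
        )
        for clade in dend_clades
    }
    som_results = {
        clade.label: overrepresentation_test(
            clade.genes, universe_collection,
            threshold=p.enrich_threshold, min_overlap=p.min_overlap,
            source_clade=f"{SOM}:{clade.label}",
        )
        for clade in som_clades
    }
    enrich_rows = [
        (r.source_clade, r.pathway_name, r.overlap_count, r.p_value, r.q_value,
         ",".join(sorted(r.overlap_genes)))
        for results in list(dend_results.values()) + list(som_results.values())
        for r in results
    ]
    pd.DataFrame(
        enrich_rows,
        columns=["source_clade", "pathway", "overlap", "p_value", "q_value", "genes"],
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    logger.info("stage co-occurrence: intersecting the two routes")
    co = co_occurring_pathways(dend_results, som_results)
    co.matrix.to_csv(outdir / "co_occurrence_matrix.tsv", sep="\t")
    co.shared.to_csv(outdir / "shared_pathways.tsv", sep="\t", index=False)

    logger.info("stage fusion: per-gene slope fits against the fusion panel")
    fits = fit_gene_slopes(
        tissue_f.subset_genes(trim.retained_genes), fusion,
        collapse_replicates=p.collapse_replicates,
        sign_threshold=p.sign_threshold,
    )
    fits.to_csv(outdir / "gene_slope_fits.tsv", sep="\t")

    if co.shared.empty:
        report_candidates = pd.DataFrame(
            columns=["slope", "pcc", "p_value", "pathways"])
        report_controls = report_candidates.copy()
    else:
        report = classify_targets(co.shared, fits,
                                  require_significance=p.require_significance)
        report_candidates, report_controls = report.candidates, report.controls
    report_candidates.to_csv(outdir / "candidate_targets.tsv", sep="\t")
    report_controls.to_csv(outdir / "control_genes.tsv", sep="\t")

    summary = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "counts": {
            "input_genes": int(n_input),
            "present_genes": int(len(present)),
            "retained_genes": int(len(trim.retained_genes)),
            "above_pc1": int(len(trim.above_pc1)),
            "below_pc1": int(len(trim.below_pc1)),
        },
        "variance_fraction": float(pca.variance_fraction),
        "grid_count_threshold": float(trim.count_threshold),
        "som_nodes": int(grid.n_nodes),
        "dend_clade_sizes": {c.label: int(len(c.genes)) for c in dend_clades},
        "som_clade_sizes": {c.label: int(len(c.genes)) for c in som_clades},
        "tissue_cell_ratio": {
            k: (None if not np.isfinite(v) else float(v)) for k, v in ratios.items()
        },
        "co_occurrence_total": int(co.matrix.to_numpy().sum()),
        "shared_pathways": int(co.shared["pathway"].nunique()) if len(co.shared) else 0,
        "shared_genes": int(co.shared["gene"].nunique()) if len(co.shared) else 0,
        "n_candidate_targets": int(len(report_candidates)),
        "n_control_genes": int(len(report_controls)),
    }
    if truth is not None:
        recovery = {}
        cand = set(report_candidates.index)
        ctrl = set(report_controls.index)
        for mod in truth.modules:
            genes = set(truth.module_genes(mod.name))
            hits = cand if mod.ratio > 1 else ctrl
            recovery[mod.name] = len(genes & hits) / len(genes) if genes else None
        summary["planted_recovery"] = recovery

    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    logger.info("pipeline complete: %s", outdir / "summary.json")
    return PipelineResult(
        summary=summary,
        candidates=report_candidates,
        controls=report_controls,
        outdir=outdir,
    )
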