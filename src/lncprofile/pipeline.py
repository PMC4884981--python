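"""End-to-end orchestration: synthetic generation or file inputs, then
preprocess -> diffexpr -> annotate -> gba -> cerna -> som, with a manifest
recording seeds, dimensions and filter attrition at every stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import cerna, diffexpr, gba, som, synthetic
from .preprocess import ExpressionMatrix, median_center, quantile_normalize

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the root seed, recorded in the manifest
STAGE_SEED_OFFSETS = {
    "annotation": 11,
    "expression": 23,
    "targets": 37,
    "gba": 53,
    "som": 71,
}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    synthetic: dict | None = None  # generation parameters
    inputs: dict | None = None  # paths: matrix, samples, bed, biotypes, gmt, targets
    alpha: float = 0.05
    fc_threshold: float = 1.5
    r_min: float = 0.45
    p_max: float = 0.01
    enrichment_q: float = 0.1
    som_margin: float = 1.0
    som_rows: int = 6
    som_cols: int = 6
    som_epochs: int = 30
    gba_n_perm: int = 200
    gba_max_lnc: int = 20  # cap on lncRNAs profiled in the NES matrix
    de_mode: str = "unpaired"
    # per-tissue quantile normalization; None = only for file inputs (the
    # synthetic generator already emits normalized log2 values)
    normalize: bool | None = None

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic/inputs must be configured")
        if not (0 < self.alpha < 1 and 0 < self.p_max < 1 and 0 < self.enrichment_q < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not (-1 <= self.r_min < 1):
            raise ValueError("r_min must lie in [-1, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method against a reference gene and
    a calibrator sample."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))


def _synthetic_inputs(cfg: PipelineConfig, outdir: Path):
    p = dict(cfg.synthetic or {})
    seeds = {k: cfg.seed + off for k, off in STAGE_SEED_OFFSETS.items()}
    annotation = synthetic.make_annotation(
        n_pcg=p.get("n_pcg", 300),
        n_lnc=p.get("n_lnc", 120),
        class_mix=p.get(
            "class_mix",
            {"intergenic": 0.5, "antisense": 0.2, "intronic": 0.2, "sense_exonic": 0.1},
        ),
        chrom_length=p.get("chrom_length", 50_000_000),
        seed=seeds["annotation"],
    )
    design = synthetic.StudyDesign(
        tissues=p.get("tissues", ["gastric", "colon", "liver", "lung"]),
        pairs_per_tissue=p.get("pairs_per_tissue", 10),
        noise_sd=p.get("noise_sd", 0.5),
        baseline_mean=p.get("baseline_mean", 8.0),
        seed=seeds["expression"],
    )
    spec = synthetic.TruthSpec(
        n_common_up=p.get("n_common_up", 15),
        n_common_down=p.get("n_common_down", 15),
        de_effect=p.get("de_effect", 1.5),
        block_genes_per_tissue=p.get("block_genes_per_tissue", 10),
        block_elevation=p.get("block_elevation", 2.0),
        n_cis_pairs=p.get("n_cis_pairs", 10),
        cis_target_r=p.get("cis_target_r", 0.7),
        n_cerna_triples=p.get("n_cerna_triples", 5),
    )
    matrix, truth = synthetic.simulate_expression(annotation, design, spec)
    targets = synthetic.simulate_mirna_targets(
        annotation,
        truth,
        background_rate=p.get("target_background_rate", 0.005),
        seed=seeds["targets"],
        n_mirnas=p.get("n_mirnas", 20),
    )
    # gene sets: random PCG sets for the enrichment stage
    rng = np.random.default_rng(seeds["gba"])
    pcg_ids = [g.gene_id for g in annotation.pcgs]
    gene_sets = {
        f"SET_{i + 1:03d}": set(
            rng.choice(pcg_ids, size=min(p.get("set_size", 25), len(pcg_ids)), replace=False)
        )
        for i in range(p.get("n_sets", 8))
    }
    annotation.to_bed12(outdir / "annotation.bed")
    annotation.biotype_table().to_csv(outdir / "biotypes.tsv", sep="\t", index=False)
    matrix.to_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
    targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    gba.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    return annotation, matrix, targets, gene_sets, seeds


def _file_inputs(cfg: PipelineConfig):
    paths = cfg.inputs or {}
    annotation = ann.GeneAnnotation.from_bed12(paths["bed"], paths["biotypes"])
    matrix = ExpressionMatrix.from_tsv(paths["matrix"], paths["samples"])
    targets = pd.read_csv(paths["targets"], sep="\t")
    gene_sets = gba.read_gmt(paths["gmt"]) if "gmt" in paths else {}
    seeds = {k: cfg.seed + off for k, off in STAGE_SEED_OFFSETS.items()}
    return annotation, matrix, targets, gene_sets, seeds


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, writing outputs under cfg.outdir. Returns the
    manifest (also written as manifest.json)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"root_seed": cfg.seed, "stages": {}}

    if cfg.synthetic is not None:
        annotation, matrix, targets, gene_sets, seeds = _synthetic_inputs(cfg, outdir)
    else:
        annotation, matrix, targets, gene_sets, seeds = _file_inputs(cfg)
    manifest["stage_seeds"] = seeds
    manifest["stages"]["inputs"] = {
        "n_genes": len(annotation),
        "n_pcg": len(annotation.pcgs),
        "n_lnc": len(annotation.lncrnas),
        "n_samples": int(matrix.values.shape[1]),
        "n_target_rows": int(len(targets)),
    }

    # ---- preprocess: per-tissue quantile normalization on log2 values -----
    do_normalize = cfg.normalize if cfg.normalize is not None else cfg.inputs is not None
    if do_normalize:
        grouping = {t: matrix.sample_ids(tissue=t) for t in matrix.tissues}
        norm = quantile_normalize(matrix.values, grouping)
        matrix = ExpressionMatrix(norm, matrix.samples)
        manifest["stages"]["preprocess"] = {"normalized": True, "groups": sorted(grouping)}
    else:
        manifest["stages"]["preprocess"] = {"normalized": False}
    matrix.values.to_csv(outdir / "expression.normalized.tsv", sep="\t", index_label="gene_id")

    # ---- differential expression ------------------------------------------
    biotypes = pd.Series(
        {g.gene_id: g.biotype for g in annotation}, name="biotype"
    )
    per_tissue = diffexpr.call_de_all_tissues(
        matrix, biotypes, alpha=cfg.alpha, fc_threshold=cfg.fc_threshold, mode=cfg.de_mode
    )
    for tissue, res in per_tissue.items():
        res.to_csv(outdir / f"de.{tissue}.tsv", sep="\t", index=False)
    common = diffexpr.intersect_common(per_tissue)
    common.to_frame().to_csv(outdir / "common_de.tsv", sep="\t", index=False)
    manifest["stages"]["diffexpr"] = {
        "per_tissue_up": {t: int((r["direction"] == "up").sum()) for t, r in per_tissue.items()},
        "per_tissue_down": {t: int((r["direction"] == "down").sum()) for t, r in per_tissue.items()},
        "common_up_pcg": len(common.common_up_pcg),
        "common_down_pcg": len(common.common_down_pcg),
        "common_up_lnc": len(common.common_up_lnc),
        "common_down_lnc": len(common.common_down_lnc),
    }

    # ---- genomic context ---------------------------------------------------
    contexts = ann.classify_all(annotation)
    ctx_frame = ann.contexts_to_frame(contexts)
    ctx_frame.to_csv(outdir / "lnc_contexts.tsv", sep="\t", index=False)
    manifest["stages"]["annotate"] = {
        "class_counts": ctx_frame["context_class"].value_counts().sort_index().to_dict()
    }

    # ---- guilt-by-association ---------------------------------------------
    pcg_ids = [g.gene_id for g in annotation.pcgs if g.gene_id in matrix.values.index]
    pcg_matrix = matrix.values.loc[pcg_ids]
    de_lncs = sorted(common.lnc)[: cfg.gba_max_lnc]
    gba_summary: dict = {"n_de_lnc_profiled": len(de_lncs), "n_gene_sets": 0}
    if de_lncs and gene_sets:
        usable = gba.filter_gene_sets(
            gene_sets, set(pcg_ids), min_size=2, max_size=max(10, len(pcg_ids))
        )
        gba_summary["n_gene_sets"] = len(usable)
        if usable:
            nes, _, _ = gba.enrichment_matrix(
                matrix.values.loc[de_lncs],
                pcg_matrix,
                usable,
                n_perm=cfg.gba_n_perm,
                seed=seeds["gba"],
            )
            nes.to_csv(outdir / "nes_matrix.tsv", sep="\t", index_label="lnc_id")
            gba_summary["nes_shape"] = list(nes.shape)
    # cis correlation: DE-lnc neighbor pairs vs genome-wide background
    pair_r: dict[str, float] = {}
    for ctx in contexts:
        if ctx.neighbor_pcg_id is None:
            continue
        if ctx.lnc_id in matrix.values.index and ctx.neighbor_pcg_id in matrix.values.index:
            r, _ = gba.pearson_r_with_p(
                matrix.values.loc[ctx.lnc_id].to_numpy(),
                matrix.values.loc[ctx.neighbor_pcg_id].to_numpy(),
            )
            pair_r[ctx.lnc_id] = r
    de_r = [r for l, r in pair_r.items() if l in common.lnc]
    bg_r = [r for l, r in pair_r.items() if l not in common.lnc]
    if de_r and bg_r:
        u, p = gba.cis_correlation_test(de_r, bg_r)
        gba_summary["cis_test"] = {"U": u, "p": p, "n_de": len(de_r), "n_bg": len(bg_r)}
    manifest["stages"]["gba"] = gba_summary

    # ---- ceRNA network -----------------------------------------------------
    de_contexts = [c for c in contexts if c.lnc_id in common.lnc]
    network = cerna.build_network(
        de_contexts, matrix, targets, r_min=cfg.r_min, p_max=cfg.p_max
    )
    motifs = cerna.find_motifs(network)
    network.to_sif(outdir / "network.sif")
    network.to_graphml(outdir / "network.graphml")
    cerna.motifs_to_frame(motifs).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    cerna.degree_table(network).to_csv(outdir / "degrees.tsv", sep="\t")
    manifest["stages"]["cerna"] = {
        "n_nodes": len(network.node_types),
        "n_targeting": len(network.targeting),
        "n_neighbor": len(network.neighbor),
        "n_coexpression": len(network.coexpression),
        "n_motifs": len(motifs),
    }

    # ---- SOM tissue specificity -------------------------------------------
    centered = median_center(matrix.values, axis="genes")
    grid = som.train_som(
        centered, rows=cfg.som_rows, cols=cfg.som_cols,
        epochs=cfg.som_epochs, seed=seeds["som"],
    )
    assignments = som.assign_bmu(grid, centered)
    assignments.to_csv(outdir / "som_units.tsv", sep="\t", index_label="gene_id")
    summaries = som.unit_tissue_means(assignments, matrix)
    selected = som.select_specific_units(
        summaries, matrix.samples["tissue"], margin=cfg.som_margin, alpha=cfg.alpha
    )
    spec_genes = som.tissue_specific_genes(summaries, selected)
    with open(outdir / "tissue_specific_genes.json", "w") as fh:
        json.dump({t: sorted(g) for t, g in spec_genes.items()}, fh, indent=1)
    manifest["stages"]["som"] = {
        "grid": [cfg.som_rows, cfg.som_cols],
        "selected_units": {t: sorted(u) for t, u in selected.items()},
        "n_specific_genes": {t: len(g) for t, g in spec_genes.items()},
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
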