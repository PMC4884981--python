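"""Synthetic study generator with planted ground truth.

Produces the three pipeline inputs — gene annotation, paired tumor/normal
expression across several tissues, and a miRNA-target table — together with a
:class:`PlantedTruth` record describing every planted effect, so that each
downstream stage can be scored for parameter recovery.

Planted roles:

* common-DE genes: shifted by +/- a log2 effect in the tumor samples of every
  tissue;
* tissue-block genes: elevated in all samples (tumor and normal) of one tissue;
* cis pairs: a lncRNA and its genomic-neighbor PCG share a latent Gaussian
  factor. With total per-gene sd sigma, the pair's values are
  ``sigma*(sqrt(r)*f + sqrt(1-r)*eps)`` around baseline, so the loading
  lambda = sqrt(r)*sigma and residual sd sqrt(1-r)*sigma give
  corr = lambda^2 / (lambda^2 + residual^2) = r exactly;
* ceRNA triples: the lncRNA/PCG pair is a cis pair, the lncRNA additionally
  carries a common-DE shift (so the network stage, which is restricted to
  common DE-lncRNAs, can see it), and both members appear as targets of the
  triple's miRNA in the target table.

Roles whose effects would conflict are never assigned to the same gene.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import CONTEXT_CLASSES, Gene, GeneAnnotation, classify_all
from .preprocess import ExpressionMatrix


class PackingError(ValueError):
    """Loci cannot be placed on the chromosome without unintended overlap."""


@dataclass
class StudyDesign:
    tissues: list[str]
    pairs_per_tissue: int
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissues or len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissues must be non-empty and unique")
        if self.pairs_per_tissue < 2:
            raise ValueError("need >= 2 pairs per tissue")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class TruthSpec:
    """Counts and effect sizes for each planted role."""

    n_common_up: int = 0
    n_common_down: int = 0
    de_effect: float = 1.5  # log2 shift in tumor samples
    block_genes_per_tissue: int = 0
    block_elevation: float = 2.0  # log2 elevation in one tissue
    n_cis_pairs: int = 0
    cis_target_r: float = 0.7
    n_cerna_triples: int = 0
    gene_sds: dict[str, float] = field(default_factory=dict)  # heteroscedastic hook


@dataclass
class PlantedTruth:
    common_de: dict[str, tuple[str, float]]  # gene -> (direction, |log2 effect|)
    tissue_blocks: dict[str, tuple[frozenset, float]]  # tissue -> (genes, elevation)
    cis_pairs: list[tuple[str, str, float]]  # (lnc, pcg, target r)
    cerna_triples: list[tuple[str, str, str]]  # (mirna, lnc, pcg)
    null_genes: frozenset

    def to_json(self, path) -> None:
        payload = {
            "common_de": {g: list(v) for g, v in self.common_de.items()},
            "tissue_blocks": {
                t: [sorted(genes), elev] for t, (genes, elev) in self.tissue_blocks.items()
            },
            "cis_pairs": [list(p) for p in self.cis_pairs],
            "cerna_triples": [list(t) for t in self.cerna_triples],
            "null_genes": sorted(self.null_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _class_counts(class_mix: dict[str, float], n_lnc: int) -> dict[str, int]:
    """Largest-remainder apportionment of n_lnc over the four classes."""
    bad = set(class_mix) - set(CONTEXT_CLASSES)
    if bad:
        raise ValueError(f"unknown context classes in mix: {sorted(bad)}")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class mix must sum to 1, got {total}")
    quotas = {c: class_mix.get(c, 0.0) * n_lnc for c in CONTEXT_CLASSES}
    counts = {c: math.floor(q) for c, q in quotas.items()}
    remainder = n_lnc - sum(counts.values())
    by_frac = sorted(
        CONTEXT_CLASSES, key=lambda c: (-(quotas[c] - counts[c]), c)
    )
    for c in by_frac[:remainder]:
        counts[c] += 1
    return counts


def make_annotation(
    n_pcg: int,
    n_lnc: int,
    class_mix: dict[str, float],
    chrom_length: int = 50_000_000,
    seed: int = 0,
    chrom: str = "chrS",
) -> GeneAnnotation:
    """Lay out PCG and lncRNA loci on one synthetic chromosome.

    Each lncRNA is placed so the genomic-context classifier recovers its
    intended class: intergenic lncRNAs sit between PCG loci, antisense and
    intronic lncRNAs sit inside a distinct host PCG's intron (on the opposite
    and same strand respectively), and sense-exonic lncRNAs straddle an exon
    boundary of their host on the same strand. PCG loci never overlap each
    other. Raises :class:`PackingError` if everything cannot be placed.
    """
    if n_pcg < 1:
        raise ValueError("need at least one PCG")
    if n_lnc < 0:
        raise ValueError("n_lnc must be >= 0")
    rng = np.random.default_rng(seed)
    counts = _class_counts(class_mix, n_lnc)
    n_hosted = counts["antisense"] + counts["intronic"] + counts["sense_exonic"]
    if n_hosted > n_pcg:
        raise PackingError(
            f"{n_hosted} hosted lncRNAs need distinct PCG hosts but only "
            f"{n_pcg} PCGs requested"
        )

    # hosted classes drawn onto distinct host PCGs
    host_classes: list[str | None] = [None] * n_pcg
    host_ids = rng.permutation(n_pcg)[:n_hosted]
    hosted_roles = (
        ["antisense"] * counts["antisense"]
        + ["intronic"] * counts["intronic"]
        + ["sense_exonic"] * counts["sense_exonic"]
    )
    for idx, role in zip(host_ids, hosted_roles):
        host_classes[idx] = role

    spacing = 1000
    genes: list[Gene] = []
    pos = 0
    lnc_serial = 0

    def next_lnc_id() -> str:
        nonlocal lnc_serial
        lnc_serial += 1
        return f"LNC{lnc_serial:05d}"

    # intergenic lncRNAs interleave with the PCG loci: one unit list
    units: list[tuple[str, int | None]] = [("pcg", i) for i in range(n_pcg)]
    units += [("intergenic_lnc", None)] * counts["intergenic"]
    units = [units[i] for i in rng.permutation(len(units))]
    # a leading intergenic unit is fine: nearest PCG is downstream

    for kind, idx in units:
        if kind == "pcg":
            length = int(rng.integers(4800, 8001))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + length
            q = length // 4
            exon1 = (start, start + q)
            exon2 = (end - q, end)
            pcg = Gene(f"PCG{idx + 1:05d}", chrom, start, end, strand, "pcg", (exon1, exon2))
            genes.append(pcg)
            role = host_classes[idx]
            if role is not None:
                intron_start, intron_end = exon1[1], exon2[0]
                if role in ("antisense", "intronic"):
                    ls = intron_start + 200
                    le = ls + 400
                    lstrand = ("-" if strand == "+" else "+") if role == "antisense" else strand
                else:  # sense_exonic straddles the first exon/intron boundary
                    ls = exon1[1] - 200
                    le = exon1[1] + 200
                    lstrand = strand
                if le > intron_end:
                    raise PackingError(f"host {pcg.gene_id} intron too small")
                genes.append(
                    Gene(next_lnc_id(), chrom, ls, le, lstrand, "lncrna", ((ls, le),))
                )
            pos = end + spacing
        else:
            length = int(rng.integers(400, 1201))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + length
            genes.append(Gene(next_lnc_id(), chrom, start, end, strand, "lncrna", ((start, end),)))
            pos = end + spacing

    if pos > chrom_length:
        raise PackingError(
            f"layout needs {pos} bp but chromosome is {chrom_length} bp"
        )
    return GeneAnnotation(sorted(genes, key=lambda g: (g.start, g.gene_id)))


def _sample_sheet(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for tissue in design.tissues:
        for i in range(1, design.pairs_per_tissue + 1):
            patient = f"{tissue}_p{i:02d}"
            for cond, suffix in (("tumor", "T"), ("normal", "N")):
                rows.append(
                    {
                        "sample_id": f"{patient}_{suffix}",
                        "tissue": tissue,
                        "condition": cond,
                        "patient": patient,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_expression(
    annotation: GeneAnnotation,
    design: StudyDesign,
    truth_spec: TruthSpec,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw a log2-scale expression matrix with the planted structure.

    Role assignment: ceRNA lncRNAs (and their planted-correlation partners)
    are chosen first among lncRNAs that have a genomic neighbor; extra cis
    pairs next; common-DE and tissue-block genes are drawn from the remaining
    pool, disjointly; everything else is null.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    for name in ("de_effect", "block_elevation"):
        if not np.isfinite(getattr(truth_spec, name)):
            raise ValueError(f"{name} must be finite")
    if not (0.0 <= truth_spec.cis_target_r <= 1.0):
        raise ValueError("cis_target_r must be in [0, 1]")
    rng = np.random.default_rng(design.seed)
    sheet = _sample_sheet(design)
    gene_ids = [g.gene_id for g in annotation]
    n_genes, n_samples = len(gene_ids), len(sheet)

    # ---- choose roles -----------------------------------------------------
    contexts = classify_all(annotation)
    paired_lncs = [c for c in contexts if c.neighbor_pcg_id is not None]
    paired_lncs = [paired_lncs[i] for i in rng.permutation(len(paired_lncs))]
    n_pairs_needed = truth_spec.n_cerna_triples + truth_spec.n_cis_pairs
    if n_pairs_needed > len(paired_lncs):
        raise ValueError(
            f"requested {n_pairs_needed} cis pairs but only {len(paired_lncs)} "
            "lncRNAs have neighbors"
        )
    cerna_triples: list[tuple[str, str, str]] = []
    cis_pairs: list[tuple[str, str, float]] = []
    taken: set[str] = set()
    k = 0
    for ctx in paired_lncs:
        if k >= n_pairs_needed:
            break
        if ctx.lnc_id in taken or ctx.neighbor_pcg_id in taken:
            continue
        cis_pairs.append((ctx.lnc_id, ctx.neighbor_pcg_id, truth_spec.cis_target_r))
        taken |= {ctx.lnc_id, ctx.neighbor_pcg_id}
        if k < truth_spec.n_cerna_triples:
            cerna_triples.append((f"MIR{k + 1:04d}", ctx.lnc_id, ctx.neighbor_pcg_id))
        k += 1
    if k < n_pairs_needed:
        raise ValueError("not enough disjoint lncRNA-neighbor pairs available")

    common_de: dict[str, tuple[str, float]] = {}
    # ceRNA lncRNAs must be common-DE for the network stage to include them;
    # the shared tumor shift goes on BOTH pair members so it reinforces (not
    # attenuates) the planted pair correlation
    if truth_spec.de_effect != 0:
        for _, lnc, pcg in cerna_triples:
            common_de[lnc] = ("up", truth_spec.de_effect)
            common_de[pcg] = ("up", truth_spec.de_effect)

    free = [g for g in gene_ids if g not in taken]
    free = [free[i] for i in rng.permutation(len(free))]
    n_blocks = truth_spec.block_genes_per_tissue * len(design.tissues)
    need = truth_spec.n_common_up + truth_spec.n_common_down + n_blocks
    if need > len(free):
        raise ValueError(
            f"planted counts require {need} free genes but only {len(free)} remain"
        )
    cursor = 0
    if truth_spec.de_effect != 0:
        for g in free[cursor : cursor + truth_spec.n_common_up]:
            common_de[g] = ("up", truth_spec.de_effect)
        cursor += truth_spec.n_common_up
        for g in free[cursor : cursor + truth_spec.n_common_down]:
            common_de[g] = ("down", truth_spec.de_effect)
        cursor += truth_spec.n_common_down
    tissue_blocks: dict[str, tuple[frozenset, float]] = {}
    if truth_spec.block_elevation != 0 and truth_spec.block_genes_per_tissue > 0:
        for tissue in design.tissues:
            block = frozenset(free[cursor : cursor + truth_spec.block_genes_per_tissue])
            cursor += truth_spec.block_genes_per_tissue
            tissue_blocks[tissue] = (block, truth_spec.block_elevation)

    role_genes = (
        set(common_de)
        | {g for genes, _ in tissue_blocks.values() for g in genes}
        | taken
    )
    null_genes = frozenset(g for g in gene_ids if g not in role_genes)

    # ---- draw the matrix --------------------------------------------------
    sds = np.array(
        [truth_spec.gene_sds.get(g, design.noise_sd) for g in gene_ids]
    )[:, None]
    values = design.baseline_mean + sds * rng.standard_normal((n_genes, n_samples))

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    r = truth_spec.cis_target_r
    for lnc, pcg, target_r in cis_pairs:
        f = rng.standard_normal(n_samples)
        for g in (lnc, pcg):
            i = gene_pos[g]
            sd = float(sds[i, 0])
            resid = rng.standard_normal(n_samples)
            values[i, :] = design.baseline_mean + sd * (
                math.sqrt(target_r) * f + math.sqrt(1.0 - target_r) * resid
            )

    tumor_mask = (sheet["condition"] == "tumor").to_numpy()
    for g, (direction, effect) in common_de.items():
        shift = effect if direction == "up" else -effect
        values[gene_pos[g], tumor_mask] += shift
    for tissue, (genes, elev) in tissue_blocks.items():
        tmask = (sheet["tissue"] == tissue).to_numpy()
        for g in genes:
            values[gene_pos[g], tmask] += elev

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sheet.index),
        sheet,
    )
    matrix.validate()
    truth = PlantedTruth(common_de, tissue_blocks, cis_pairs, cerna_triples, null_genes)
    return matrix, truth


def simulate_mirna_targets(
    annotation: GeneAnnotation,
    truth: PlantedTruth,
    background_rate: float,
    seed: int = 0,
    n_mirnas: int | None = None,
) -> pd.DataFrame:
    """Emulate a miRNA-target prediction table.

    Every planted ceRNA triple contributes its two targeting rows; every
    other (miRNA, gene) combination is included independently with
    probability ``background_rate``. ``n_mirnas`` sets the total miRNA
    universe size (default: just the planted miRNAs).
    """
    if not (0.0 <= background_rate < 1.0):
        raise ValueError("background_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    planted_mirnas = []
    for m, _, _ in truth.cerna_triples:
        if m not in planted_mirnas:
            planted_mirnas.append(m)
    if n_mirnas is None:
        mirnas = list(planted_mirnas)
    else:
        if n_mirnas < len(planted_mirnas):
            raise ValueError("n_mirnas smaller than the planted miRNA count")
        mirnas = list(planted_mirnas)
        i = len(planted_mirnas)
        while len(mirnas) < n_mirnas:
            i += 1
            cand = f"MIR{i:04d}"
            if cand not in mirnas:
                mirnas.append(cand)
    gene_ids = [g.gene_id for g in annotation]
    planted_edges = {(m, t) for m, l, p in truth.cerna_triples for t in (l, p)}

    rows = [
        {"mirna_id": m, "target_id": t, "score": 1.0} for m, t in sorted(planted_edges)
    ]
    if background_rate > 0 and mirnas:
        hits = rng.random((len(mirnas), len(gene_ids))) < background_rate
        scores = rng.random((len(mirnas), len(gene_ids)))
        for i, j in zip(*np.nonzero(hits)):
            edge = (mirnas[i], gene_ids[j])
            if edge in planted_edges:
                continue
            rows.append(
                {"mirna_id": edge[0], "target_id": edge[1], "score": round(float(scores[i, j]), 6)}
            )
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "score"])
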