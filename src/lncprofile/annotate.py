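"""Genomic-context classification of lncRNAs relative to protein-coding genes.

Every lncRNA is assigned one of four context classes based on its locus
relative to the PCG universe, then paired with a class-specific neighbor PCG:

* ``intergenic``   — no PCG overlap; neighbor = nearest PCG by boundary distance
* ``antisense``    — opposite-strand PCG locus overlap; neighbor = PCG with
  maximal locus overlap
* ``intronic``     — same-strand locus overlap with no exon overlap; neighbor =
  host PCG (maximal locus overlap)
* ``sense_exonic`` — same-strand exon overlap; neighbor = PCG with maximal exon
  overlap

All coordinates are 0-based half-open (BED convention). Antisense takes
priority over the same-strand classes when a lncRNA overlaps PCGs on both
strands; this priority is configurable via ``antisense_first=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

CONTEXT_CLASSES = ("intergenic", "antisense", "intronic", "sense_exonic")


@dataclass(frozen=True)
class Gene:
    """A gene locus with exon blocks. Coordinates 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str  # "pcg" | "lncrna"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in ("pcg", "lncrna"):
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def effective_exons(self) -> tuple[tuple[int, int], ...]:
        """Exon blocks, falling back to the full locus for single-block genes."""
        return self.exons if self.exons else ((self.start, self.end),)


@dataclass
class GeneAnnotation:
    """An ordered collection of gene loci with fast id lookup."""

    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids must be unique")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def subset(self, biotype: str) -> list[Gene]:
        return [g for g in self.genes if g.biotype == biotype]

    @property
    def pcgs(self) -> list[Gene]:
        return self.subset("pcg")

    @property
    def lncrnas(self) -> list[Gene]:
        return self.subset("lncrna")

    # ---- I/O -------------------------------------------------------------

    def to_bed12(self, path) -> None:
        """Write as BED12 (one line per gene, exon blocks encoded)."""
        with open(path, "w") as fh:
            for g in self.genes:
                exons = g.effective_exons
                sizes = ",".join(str(e - s) for s, e in exons) + ","
                starts = ",".join(str(s - g.start) for s, e in exons) + ","
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                            g.start, g.end, "0,0,0", len(exons), sizes, starts,
                        )
                    )
                    + "\n"
                )

    def biotype_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": [g.gene_id for g in self.genes],
             "biotype": [g.biotype for g in self.genes]}
        )

    @classmethod
    def from_bed12(cls, bed_path, biotype_path) -> "GeneAnnotation":
        bio = pd.read_csv(biotype_path, sep="\t")
        biomap = dict(zip(bio["gene_id"], bio["biotype"]))
        genes = []
        with open(bed_path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
                )
                genes.append(
                    Gene(name, chrom, start, end, strand, biomap[name], exons)
                )
        return cls(genes)


@dataclass(frozen=True)
class LncContext:
    """Classification result for one lncRNA."""

    lnc_id: str
    context_class: str
    neighbor_pcg_id: Optional[str]
    distance: int  # base pairs; 0 if overlapping
    flags: str = ""


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Base-pair overlap of two half-open intervals on the same chromosome."""
    a_start, a_end = a
    b_start, b_end = b
    if a_start >= a_end or b_start >= b_end:
        raise ValueError("malformed interval (start must be < end)")
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _locus_overlap(a: Gene, b: Gene) -> int:
    if a.chrom != b.chrom:
        return 0
    return interval_overlap((a.start, a.end), (b.start, b.end))


def _exon_overlap(a: Gene, b: Gene) -> int:
    if a.chrom != b.chrom:
        return 0
    total = 0
    for ea in a.effective_exons:
        for eb in b.effective_exons:
            lo = max(ea[0], eb[0])
            hi = min(ea[1], eb[1])
            if hi > lo:
                total += hi - lo
    return total


def _gap_distance(a: Gene, b: Gene) -> int:
    """Boundary-to-boundary gap between disjoint loci; 0 when overlapping."""
    if a.chrom != b.chrom:
        raise ValueError("distance undefined across chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def classify_lncrna(
    lnc: Gene, pcgs: Iterable[Gene], antisense_first: bool = True
) -> str:
    """Assign the genomic-context class of one lncRNA against a PCG set.

    Unstranded lncRNAs (strand ``.``) cannot be resolved against strand-based
    rules; they are classified by locus/exon overlap alone (overlap of any
    exon -> sense_exonic, locus-only -> intronic, none -> intergenic).
    """
    has_antisense = has_exonic = has_intronic = False
    for pcg in pcgs:
        if _locus_overlap(lnc, pcg) == 0:
            continue
        if lnc.strand != "." and pcg.strand != lnc.strand:
            has_antisense = True
        elif _exon_overlap(lnc, pcg) > 0:
            has_exonic = True
        else:
            has_intronic = True
    if antisense_first:
        order = (
            ("antisense", has_antisense),
            ("sense_exonic", has_exonic),
            ("intronic", has_intronic),
        )
    else:
        order = (
            ("sense_exonic", has_exonic),
            ("intronic", has_intronic),
            ("antisense", has_antisense),
        )
    for name, hit in order:
        if hit:
            return name
    return "intergenic"


def assign_neighbor(
    lnc: Gene, context_class: str, pcgs: Iterable[Gene]
) -> LncContext:
    """Pick the class-specific neighbor PCG for an already-classified lncRNA.

    Ties are broken by smaller distance, then lexicographically smaller id.
    """
    flags = "unstranded;" if lnc.strand == "." else ""
    same_chrom = [p for p in pcgs if p.chrom == lnc.chrom]
    if not same_chrom:
        return LncContext(lnc.gene_id, context_class, None, -1, flags + "no_pcg_on_chrom")

    def anti(p: Gene) -> bool:
        return lnc.strand == "." or p.strand != lnc.strand

    def sense(p: Gene) -> bool:
        return lnc.strand == "." or p.strand == lnc.strand

    if context_class == "intergenic":
        candidates = [(p, _gap_distance(lnc, p)) for p in same_chrom]
    elif context_class == "antisense":
        candidates = [
            (p, -_locus_overlap(lnc, p))
            for p in same_chrom
            if anti(p) and _locus_overlap(lnc, p) > 0
        ]
    elif context_class == "intronic":
        candidates = [
            (p, -_locus_overlap(lnc, p))
            for p in same_chrom
            if sense(p) and _locus_overlap(lnc, p) > 0 and _exon_overlap(lnc, p) == 0
        ]
    elif context_class == "sense_exonic":
        candidates = [
            (p, -_exon_overlap(lnc, p))
            for p in same_chrom
            if sense(p) and _exon_overlap(lnc, p) > 0
        ]
    else:
        raise ValueError(f"unknown context class {context_class!r}")

    if not candidates:
        return LncContext(lnc.gene_id, context_class, None, -1, flags + "no_candidate")
    best = min(
        candidates, key=lambda t: (t[1], _gap_distance(lnc, t[0]), t[0].gene_id)
    )
    pcg = best[0]
    return LncContext(
        lnc.gene_id, context_class, pcg.gene_id, _gap_distance(lnc, pcg), flags
    )


def classify_all(
    annotation: GeneAnnotation, antisense_first: bool = True
) -> list[LncContext]:
    """Classify every lncRNA in the annotation and assign its neighbor."""
    pcgs = annotation.pcgs
    out = []
    for lnc in annotation.lncrnas:
        cls = classify_lncrna(lnc, pcgs, antisense_first=antisense_first)
        out.append(assign_neighbor(lnc, cls, pcgs))
    return out


def contexts_to_frame(contexts: Iterable[LncContext]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": c.lnc_id,
                "context_class": c.context_class,
                "neighbor_pcg_id": c.neighbor_pcg_id,
                "distance": c.distance,
                "flags": c.flags,
            }
            for c in contexts
        ]
    )
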