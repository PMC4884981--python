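import numpy as np
import pandas as pd
import pytest

from lncprofile.annotate import Gene, GeneAnnotation
from lncprofile.preprocess import ExpressionMatrix
from lncprofile.synthetic import StudyDesign, TruthSpec, make_annotation, simulate_expression

DEFAULT_MIX = {
    "intergenic": 0.5,
    "antisense": 0.2,
    "intronic": 0.2,
    "sense_exonic": 0.1,
}


@pytest.fixture
def small_annotation() -> GeneAnnotation:
    return make_annotation(40, 16, DEFAULT_MIX, seed=11)


@pytest.fixture
def four_tissue_design() -> StudyDesign:
    return StudyDesign(["gastric", "colon", "liver", "lung"], 8, noise_sd=0.5, seed=5)


@pytest.fixture
def planted_study(small_annotation, four_tissue_design):
    spec = TruthSpec(
        n_common_up=4,
        n_common_down=4,
        de_effect=1.5,
        block_genes_per_tissue=2,
        block_elevation=2.0,
        n_cis_pairs=3,
        cis_target_r=0.7,
        n_cerna_triples=2,
    )
    matrix, truth = simulate_expression(small_annotation, four_tissue_design, spec)
    return small_annotation, matrix, truth


def toy_matrix(values: np.ndarray, gene_ids, tissues, conditions, patients) -> ExpressionMatrix:
    samples = pd.DataFrame(
        {
            "tissue": tissues,
            "condition": conditions,
            "patient": patients,
        },
        index=pd.Index([f"s{i}" for i in range(len(tissues))], name="sample_id"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples.index),
        samples,
    )


def make_gene(gene_id, start, end, strand="+", biotype="pcg", exons=None, chrom="chr1"):
    return Gene(gene_id, chrom, start, end, strand, biotype,
                tuple(exons) if exons else ())
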