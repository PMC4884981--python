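"""Expression-matrix preprocessing and the clustering distance used downstream.

The pipeline operates on log2-scale intensities. Quantile normalization is
applied per tissue group by default; probe-level matrices are collapsed to
gene level (mean by default); rows are median-centered before hierarchical
clustering with complete linkage on the centered-Pearson distance 1 - r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix plus per-sample metadata.

    ``values`` is indexed by gene id with one column per sample id;
    ``samples`` is indexed by sample id with columns tissue / condition /
    patient. Conditions are "tumor" and "normal"; each patient contributes
    exactly one sample per condition.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample columns do not match the sample sheet")
        for col in ("tissue", "condition", "patient"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if not self.samples["condition"].isin(["tumor", "normal"]).all():
            raise ValueError("condition must be tumor|normal")
        if self.samples.duplicated(subset=["patient", "condition"]).any():
            raise ValueError("(patient, condition) pairs must be unique")
        if self.values.isna().any().any():
            raise ValueError("matrix contains missing values")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    def sample_ids(self, tissue: str | None = None, condition: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def subset_tissue(self, tissue: str) -> "ExpressionMatrix":
        ids = self.sample_ids(tissue=tissue)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def to_tsv(self, matrix_path, sheet_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(sheet_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, matrix_path, sheet_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(sheet_path, sep="\t", index_col="sample_id")
        em = cls(values, samples)
        em.validate()
        return em


def quantile_normalize(
    matrix: pd.DataFrame, grouping: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Quantile-normalize columns so each shares the mean order-statistic vector.

    ``grouping`` maps group label -> column ids; normalization is carried out
    independently within each group (per tissue in the pipeline). ``None``
    normalizes all columns together.
    """
    if not np.isfinite(matrix.to_numpy()).all():
        bad = np.argwhere(~np.isfinite(matrix.to_numpy()))
        cells = [(matrix.index[i], matrix.columns[j]) for i, j in bad[:5]]
        raise ValueError(f"non-finite intensities at {cells}")
    if grouping is None:
        grouping = {"all": list(matrix.columns)}
    out = matrix.copy()
    for label, cols in grouping.items():
        if len(cols) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        block = matrix[cols].to_numpy(dtype=float)
        order = np.argsort(block, axis=0, kind="stable")
        ranks = np.empty_like(order)
        n = block.shape[0]
        rows = np.arange(n)
        for j in range(block.shape[1]):
            ranks[order[:, j], j] = rows
        reference = np.sort(block, axis=0).mean(axis=1)
        out[cols] = reference[ranks]
    return out


def log2_transform(matrix: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """Elementwise log2. Values <= 0 raise unless a positive floor is given."""
    arr = matrix.to_numpy(dtype=float)
    if floor is not None:
        if floor <= 0:
            raise ValueError("floor must be positive")
        arr = np.maximum(arr, floor)
    elif (arr <= 0).any():
        raise ValueError("non-positive intensities; pass floor= to clip")
    return pd.DataFrame(np.log2(arr), index=matrix.index, columns=matrix.columns)


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: dict[str, str] | pd.Series,
    method: str = "mean",
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level (mean|median|max per gene).

    Probes absent from the map are dropped (count logged).
    """
    if method not in ("mean", "median", "max"):
        raise ValueError(f"unknown collapse method {method!r}")
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise ValueError("empty probe-to-gene mapping")
    mapped = probe_matrix.index.intersection(mapping.index)
    dropped = len(probe_matrix.index) - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = probe_matrix.loc[mapped]
    grouped = sub.groupby(mapping.loc[mapped].to_numpy())
    collapsed = getattr(grouped, method)()
    collapsed.index.name = "gene_id"
    return collapsed


def median_center(matrix: pd.DataFrame, axis: str = "genes") -> pd.DataFrame:
    """Subtract each row's (genes) or column's (samples) median."""
    if axis == "genes":
        return matrix.sub(matrix.median(axis=1), axis=0)
    if axis == "samples":
        return matrix.sub(matrix.median(axis=0), axis=1)
    raise ValueError(f"axis must be genes|samples, got {axis!r}")


def centered_pearson_distance(x, y) -> float:
    """d = 1 - Pearson r, in [0, 2]. Errors on zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero-variance vector: distance undefined")
    r = float((xc * yc).sum() / denom)
    return 1.0 - r


def hierarchical_cluster(matrix: pd.DataFrame) -> np.ndarray:
    """Complete-linkage agglomeration on 1 - Pearson r over rows.

    Returns a scipy linkage matrix (heights non-decreasing for complete
    linkage).
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 items to cluster")
    arr = matrix.to_numpy(dtype=float)
    if (arr.std(axis=1) == 0).any():
        raise ValueError("zero-variance row: distance undefined")
    dists = pdist(arr, metric="correlation")
    return linkage(dists, method="complete")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string (heights as branch lengths)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"
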