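"""Self-organizing map over gene expression profiles for tissue specificity.

Genes are observations and samples are features. A batch SOM with a Gaussian
neighborhood on a hexagonal lattice tiles the gene space; each unit's member
genes are summarized per tissue, and units whose mean in one tissue exceeds
every other tissue by a margin (and passes a per-sample rank test) are called
tissue-specific. Unit ids are numbered row-major from 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cerna import target_set_overrepresentation
from .preprocess import ExpressionMatrix


def hex_grid_distances(rows: int, cols: int) -> np.ndarray:
    """Pairwise lattice distances between units of an odd-r hexagonal grid."""
    coords = []
    for r in range(rows):
        for c in range(cols):
            x = c - (r - (r & 1)) // 2
            z = r
            coords.append((x, -x - z, z))
    coords = np.asarray(coords)
    diff = np.abs(coords[:, None, :] - coords[None, :, :])
    return diff.sum(axis=2) / 2.0


@dataclass
class SOMGrid:
    rows: int
    cols: int
    prototypes: np.ndarray  # (rows*cols, n_features)
    feature_names: list[str]
    qe_history: list[float] = field(default_factory=list)
    topology: str = "hexagonal"

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise ValueError("grid needs at least 2 units")
        if self.prototypes.shape != (self.rows * self.cols, len(self.feature_names)):
            raise ValueError("prototype shape does not match grid/features")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_ids(self) -> np.ndarray:
        return np.arange(1, self.n_units + 1)


def train_som(
    matrix: pd.DataFrame,
    rows: int = 13,
    cols: int = 9,
    epochs: int = 50,
    seed: int = 0,
    sigma_start: float | None = None,
    sigma_end: float = 0.5,
) -> SOMGrid:
    """Batch-train a hexagonal SOM on the rows of ``matrix``.

    The Gaussian neighborhood width decays linearly from
    ``max(rows, cols)/2`` (default) to ``sigma_end`` over the epochs. Batch
    updates make training deterministic for a fixed seed (randomness enters
    only through prototype initialization).
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in SOM input")
    if rows * cols < 4:
        raise ValueError("grid must have at least 4 units")
    n_obs, n_feat = X.shape
    n_units = rows * cols
    if n_obs < n_units:
        warnings.warn(f"{n_obs} observations for {n_units} units; grid is oversized")
    rng = np.random.default_rng(seed)
    if n_obs >= n_units:
        init_idx = rng.choice(n_obs, size=n_units, replace=False)
        prototypes = X[init_idx].copy()
    else:
        center = X.mean(axis=0)
        spread = X.std(axis=0) + 1e-9
        prototypes = center + spread * rng.standard_normal((n_units, n_feat))
        prototypes[:n_obs] = X

    D2 = hex_grid_distances(rows, cols) ** 2
    sigma0 = max(rows, cols) / 2.0 if sigma_start is None else sigma_start
    qe_history = []
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma0 + (sigma_end - sigma0) * frac
        d2 = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
        bmu = np.argmin(d2, axis=1)
        qe_history.append(float(np.sqrt(d2[np.arange(n_obs), bmu]).mean()))
        H = np.exp(-D2[:, bmu] / (2.0 * sigma**2))  # (units, obs)
        weights = H.sum(axis=1)
        new_prot = H @ X
        ok = weights > 1e-12
        prototypes[ok] = new_prot[ok] / weights[ok, None]
    return SOMGrid(rows, cols, prototypes, list(matrix.columns), qe_history)


def assign_bmu(grid: SOMGrid, matrix: pd.DataFrame) -> pd.Series:
    """Best-matching unit per gene (minimum Euclidean distance, ties to the
    lowest unit id). Returns a Series gene -> unit id (1-based)."""
    if list(matrix.columns) != grid.feature_names:
        raise ValueError("feature mismatch between grid and matrix")
    X = matrix.to_numpy(dtype=float)
    d2 = ((X[:, None, :] - grid.prototypes[None, :, :]) ** 2).sum(axis=2)
    bmu = np.argmin(d2, axis=1) + 1  # argmin takes the first (lowest) index
    return pd.Series(bmu, index=matrix.index, name="unit")


def quantization_error(grid: SOMGrid, matrix: pd.DataFrame) -> float:
    X = matrix.to_numpy(dtype=float)
    d2 = ((X[:, None, :] - grid.prototypes[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


@dataclass
class UnitSummary:
    unit_id: int
    genes: list[str]
    tissue_means: dict[str, float]  # mean over member genes of per-tissue mean
    per_sample: pd.Series  # mean over member genes, per sample
    specificity: str | None = None


def unit_tissue_means(
    assignments: pd.Series, matrix: ExpressionMatrix
) -> list[UnitSummary]:
    """Summarize each non-empty unit: per-tissue overall expression and
    per-sample member-gene means."""
    tissues = matrix.tissues
    tissue_cols = {t: matrix.sample_ids(tissue=t) for t in tissues}
    summaries = []
    for unit in sorted(assignments.unique()):
        genes = sorted(assignments.index[assignments == unit])
        sub = matrix.values.loc[genes]
        per_sample = sub.mean(axis=0)
        means = {t: float(per_sample[tissue_cols[t]].mean()) for t in tissues}
        summaries.append(UnitSummary(int(unit), genes, means, per_sample))
    return summaries


def select_specific_units(
    summaries: list[UnitSummary],
    sample_tissues: pd.Series,
    margin: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, list[int]]:
    """Call a unit specific for tissue t iff its t mean exceeds every other
    tissue mean by >= margin AND a one-sided Mann-Whitney test of per-sample
    unit means (t samples vs rest) has p < alpha. At most one tissue per unit.
    """
    tissues = sorted(sample_tissues.unique())
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    out: dict[str, list[int]] = {t: [] for t in tissues}
    for s in summaries:
        means = s.tissue_means
        best = max(tissues, key=lambda t: means[t])
        others = [means[t] for t in tissues if t != best]
        if means[best] - max(others) < margin:
            s.specificity = None
            continue
        in_t = s.per_sample[sample_tissues[sample_tissues == best].index]
        rest = s.per_sample[sample_tissues[sample_tissues != best].index]
        p = stats.mannwhitneyu(in_t, rest, alternative="greater").pvalue
        if p < alpha:
            s.specificity = best
            out[best].append(s.unit_id)
        else:
            s.specificity = None
    return out


def tissue_specific_genes(
    summaries: list[UnitSummary], selected: dict[str, list[int]]
) -> dict[str, set[str]]:
    by_unit = {s.unit_id: s for s in summaries}
    return {
        tissue: {g for u in units for g in by_unit[u].genes}
        for tissue, units in selected.items()
    }


def enrich_unit_genes(
    gene_list: set[str],
    term_table: dict[str, set[str]],
    universe: set[str],
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of annotation terms in a unit's
    genes, BH-adjusted; rows with q < q_max are returned."""
    if not term_table:
        raise ValueError("term table is empty")
    in_universe = gene_list & universe
    if not in_universe:
        raise ValueError("gene list disjoint from universe")
    df = target_set_overrepresentation(in_universe, term_table, universe)
    df = df.rename(columns={"mirna_id": "term", "set_size": "term_size"})
    return df[df["q"] < q_max].reset_index(drop=True)
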