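"""Guilt-by-association functional inference for lncRNAs.

For each lncRNA, every PCG is ranked by its Pearson correlation with the
lncRNA's expression across all samples; the signed correlations serve as
weights in a weighted Kolmogorov-Smirnov enrichment score over pathway gene
sets. Scores are normalized against gene-set label permutations. A separate
rank test compares the lncRNA-neighbor correlations of DE lncRNAs against a
genome-wide background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import hierarchical_cluster

logger = logging.getLogger(__name__)


@dataclass
class RankedProfile:
    """All PCGs ordered by descending correlation with one lncRNA."""

    lnc_id: str
    gene_ids: list[str]  # descending by r, ties broken by gene id
    weights: np.ndarray  # signed r values, same order

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.gene_ids) != self.weights.size:
            raise ValueError("gene_ids and weights must align")

    @property
    def n(self) -> int:
        return len(self.gene_ids)


def pearson_r_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-tailed t-distribution p-value.

    p is computed from t = r*sqrt((n-2)/(1-r^2)) on n-2 df; |r| = 1 gives
    p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    n = x.size
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def _correlations(lnc_values: np.ndarray, pcg_matrix: pd.DataFrame) -> pd.Series:
    """Vectorized Pearson r of one vector against every row of a matrix."""
    X = pcg_matrix.to_numpy(dtype=float)
    y = np.asarray(lnc_values, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    return pd.Series(r, index=pcg_matrix.index)


def rank_by_correlation(
    lnc_id: str, lnc_values, pcg_matrix: pd.DataFrame
) -> RankedProfile:
    """Rank every PCG by Pearson r with the lncRNA profile (descending).

    Constant PCGs (NaN correlation) are excluded with a logged count; ties
    are broken by gene id for determinism.
    """
    lnc_values = np.asarray(lnc_values, dtype=float)
    if lnc_values.size != pcg_matrix.shape[1]:
        raise ValueError("lncRNA vector and PCG matrix samples misaligned")
    r = _correlations(lnc_values, pcg_matrix)
    n_nan = int(r.isna().sum())
    if n_nan:
        logger.info("rank_by_correlation(%s): dropped %d constant PCGs", lnc_id, n_nan)
        r = r.dropna()
    order = sorted(r.index, key=lambda g: (-r[g], g))
    return RankedProfile(lnc_id, order, r.loc[order].to_numpy())


def enrichment_score(
    profile: RankedProfile, gene_set: set[str], weight_exponent: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score of a gene set in a ranked profile.

    Walking down the ranking, hits advance P_hit by |r|^p / N_R and misses
    advance P_miss by 1/(N - N_H); the ES is the running difference of
    maximal absolute value (signed). Returns (ES, argmax index).
    """
    hits = np.fromiter(
        (g in gene_set for g in profile.gene_ids), dtype=bool, count=profile.n
    )
    n_h = int(hits.sum())
    if n_h == 0 or n_h == profile.n:
        raise ValueError("gene set must be a non-empty proper subset of the ranking")
    w = np.abs(profile.weights) ** weight_exponent
    n_r = w[hits].sum()
    if n_r == 0:
        # all hit weights zero: hits contribute no mass, score driven by misses
        p_hit_steps = np.zeros(profile.n)
    else:
        p_hit_steps = np.where(hits, w / n_r, 0.0)
    p_miss_steps = np.where(hits, 0.0, 1.0 / (profile.n - n_h))
    running = np.cumsum(p_hit_steps - p_miss_steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def normalize_es(
    profile: RankedProfile,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[float, float, float]:
    """Gene-set label permutation normalization. Returns (ES, NES, nominal p).

    Permutations draw random sets of the same size from the ranked universe.
    NES divides the ES by the mean |permutation ES| of matching sign; the
    nominal p is the fraction of same-sign permutation scores at least as
    extreme. When no same-sign permutation exists the p is reported as
    1/(n_perm+1) (flagged via log).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    set_in_universe = gene_set & set(profile.gene_ids)
    es, _ = enrichment_score(profile, set_in_universe, weight_exponent)
    rng = np.random.default_rng(seed)
    size = len(set_in_universe)
    perm_es = np.empty(n_perm)
    universe = np.asarray(profile.gene_ids, dtype=object)
    for b in range(n_perm):
        idx = rng.choice(profile.n, size=size, replace=False)
        perm_set = set(universe[idx])
        perm_es[b], _ = enrichment_score(profile, perm_set, weight_exponent)
    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    if not same_sign.any():
        logger.warning("normalize_es: no same-sign permutations; p < 1/%d", n_perm)
        return es, float(np.sign(es)) * np.inf, 1.0 / (n_perm + 1)
    mean_abs = np.abs(perm_es[same_sign]).mean()
    nes = es / mean_abs if mean_abs > 0 else np.sign(es) * np.inf
    more_extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
    p = more_extreme / int(same_sign.sum())
    return es, float(nes), float(p)


def enrichment_matrix(
    lnc_matrix: pd.DataFrame,
    pcg_matrix: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    n_perm: int = 200,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray | None, np.ndarray | None]:
    """NES matrix (lncRNA x gene set) plus row/column linkages for heatmaps.

    ``lnc_matrix`` and ``pcg_matrix`` must share sample columns.
    """
    if list(lnc_matrix.columns) != list(pcg_matrix.columns):
        raise ValueError("lncRNA and PCG matrices must share sample columns")
    if len(lnc_matrix) < 1 or len(gene_sets) < 1:
        raise ValueError("need at least one lncRNA and one gene set")
    rows = {}
    for lnc_id in lnc_matrix.index:
        profile = rank_by_correlation(lnc_id, lnc_matrix.loc[lnc_id].to_numpy(), pcg_matrix)
        row = {}
        for set_name, members in gene_sets.items():
            _, nes, _ = normalize_es(
                profile, members, n_perm=n_perm, seed=seed, weight_exponent=weight_exponent
            )
            row[set_name] = nes
        rows[lnc_id] = row
    nes = pd.DataFrame.from_dict(rows, orient="index").loc[
        list(lnc_matrix.index), list(gene_sets)
    ]
    row_link = col_link = None
    if len(nes) >= 2 and nes.to_numpy().std(axis=1).min() > 0:
        row_link = hierarchical_cluster(nes)
    if nes.shape[1] >= 2 and nes.to_numpy().std(axis=0).min() > 0:
        col_link = hierarchical_cluster(nes.T)
    return nes, row_link, col_link


def filter_gene_sets(
    gene_sets: dict[str, set[str]],
    universe: set[str],
    min_size: int = 10,
    max_size: int = 500,
) -> dict[str, set[str]]:
    """Intersect sets with the ranked universe and apply size bounds."""
    kept = {}
    for name, members in gene_sets.items():
        inter = members & universe
        if min_size <= len(inter) <= max_size:
            kept[name] = inter
        else:
            logger.info("dropping gene set %s (size %d after intersection)", name, len(inter))
    return kept


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: set name, description, then member ids (tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


def cis_correlation_test(de_pairs_r, background_pairs_r) -> tuple[float, float]:
    """One-sided Mann-Whitney U: are DE-pair correlations stochastically
    greater than the genome-wide background? Returns (U, one-sided p)."""
    de = np.asarray(de_pairs_r, dtype=float)
    bg = np.asarray(background_pairs_r, dtype=float)
    if de.size == 0 or bg.size == 0:
        raise ValueError("both correlation vectors must be non-empty")
    res = stats.mannwhitneyu(de, bg, alternative="greater")
    return float(res.statistic), float(res.pvalue)
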