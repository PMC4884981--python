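"""Per-tissue tumor-vs-normal differential expression and cross-tissue
intersection into common up/down sets.

Calls use a two-tailed Student's t-test (unpaired pooled-variance by default;
paired mode available), Benjamini-Hochberg FDR, and a linear-scale fold-change
threshold computed from log2 means. FDR is adjusted separately within the PCG
and lncRNA strata of each tissue by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix


@dataclass
class CommonDESets:
    """Genes called DE in the same direction in every tissue."""

    common_up_pcg: set[str] = field(default_factory=set)
    common_down_pcg: set[str] = field(default_factory=set)
    common_up_lnc: set[str] = field(default_factory=set)
    common_down_lnc: set[str] = field(default_factory=set)

    @property
    def up(self) -> set[str]:
        return self.common_up_pcg | self.common_up_lnc

    @property
    def down(self) -> set[str]:
        return self.common_down_pcg | self.common_down_lnc

    @property
    def lnc(self) -> set[str]:
        return self.common_up_lnc | self.common_down_lnc

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("common_up_pcg", "common_down_pcg", "common_up_lnc", "common_down_lnc"):
            for g in sorted(getattr(self, name)):
                rows.append({"set": name, "gene_id": g})
        return pd.DataFrame(rows, columns=["set", "gene_id"])


def gene_t_test(tumor_values, normal_values, mode: str = "unpaired"):
    """Two-tailed Student's t-test; returns (t, p).

    Unpaired mode is the pooled-variance two-sample t (df = n1+n2-2); paired
    mode is a one-sample t on per-patient differences. Zero-variance
    degenerate input yields (0.0, 1.0) with a warning.
    """
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(normal_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if mode == "unpaired":
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(x, y, equal_var=True)
    elif mode == "paired":
        if x.size != y.size:
            raise ValueError("paired mode requires equal group sizes")
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_rel(x, y)
    else:
        raise ValueError(f"mode must be unpaired|paired, got {mode!r}")
    if not np.isfinite(t):
        warnings.warn("zero variance in t-test; reporting t=0, p=1")
        return 0.0, 1.0
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def _vector_t(tumor: np.ndarray, normal: np.ndarray, mode: str):
    """Row-wise t-test over gene matrices; degenerate rows get t=0, p=1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "unpaired":
            t, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=True)
        else:
            t, p = stats.ttest_rel(tumor, normal, axis=1)
    bad = ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    return t, p


def call_de(
    matrix: ExpressionMatrix,
    biotypes: pd.Series,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    mode: str = "unpaired",
    stratify_biotype: bool = True,
) -> pd.DataFrame:
    """Call DE genes for one tissue (tumor vs normal).

    fold_change = 2**(mean_log2_tumor - mean_log2_normal). A gene is "up"
    iff fold_change > fc_threshold and fdr < alpha; "down" iff
    fold_change < 1/fc_threshold and fdr < alpha; otherwise "ns".
    Both inequalities are strict.
    """
    tissues = matrix.tissues
    if len(tissues) != 1:
        raise ValueError(f"expected a single-tissue matrix, got {tissues}")
    tumor_ids = matrix.sample_ids(condition="tumor")
    normal_ids = matrix.sample_ids(condition="normal")
    if not tumor_ids or not normal_ids:
        raise ValueError(f"tissue {tissues[0]!r} is missing a condition")
    if mode == "paired":
        # align columns patient-by-patient
        t_by_patient = matrix.samples.loc[tumor_ids].reset_index().set_index("patient")
        n_by_patient = matrix.samples.loc[normal_ids].reset_index().set_index("patient")
        patients = sorted(set(t_by_patient.index) & set(n_by_patient.index))
        tumor_ids = list(t_by_patient.loc[patients, "sample_id"])
        normal_ids = list(n_by_patient.loc[patients, "sample_id"])

    tumor = matrix.values[tumor_ids].to_numpy(dtype=float)
    normal = matrix.values[normal_ids].to_numpy(dtype=float)
    t, p = _vector_t(tumor, normal, mode)
    mean_t = tumor.mean(axis=1)
    mean_n = normal.mean(axis=1)
    fc = 2.0 ** (mean_t - mean_n)

    res = pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "tissue": tissues[0],
            "biotype": biotypes.reindex(matrix.values.index).to_numpy(),
            "mean_log2_tumor": mean_t,
            "mean_log2_normal": mean_n,
            "fold_change": fc,
            "t": t,
            "p_value": p,
        }
    ).set_index("gene_id")
    if res["biotype"].isna().any():
        raise ValueError("biotype missing for some genes in the matrix")

    res["fdr"] = np.nan
    if stratify_biotype:
        for bt in res["biotype"].unique():
            idx = res.index[res["biotype"] == bt]
            res.loc[idx, "fdr"] = bh_fdr(res.loc[idx, "p_value"].to_numpy())
    else:
        res["fdr"] = bh_fdr(res["p_value"].to_numpy())

    direction = np.full(len(res), "ns", dtype=object)
    sig = res["fdr"].to_numpy() < alpha
    direction[sig & (res["fold_change"].to_numpy() > fc_threshold)] = "up"
    direction[sig & (res["fold_change"].to_numpy() < 1.0 / fc_threshold)] = "down"
    res["direction"] = direction
    return res.reset_index()


def call_de_all_tissues(
    matrix: ExpressionMatrix, biotypes: pd.Series, **kwargs
) -> dict[str, pd.DataFrame]:
    return {
        t: call_de(matrix.subset_tissue(t), biotypes, **kwargs)
        for t in matrix.tissues
    }


def intersect_common(per_tissue_results: dict[str, pd.DataFrame]) -> CommonDESets:
    """Intersect per-tissue DE calls into common up/down sets.

    A gene is common-up iff direction == "up" in every tissue (likewise down);
    any tissue where it is ns or opposite excludes it.
    """
    if len(per_tissue_results) < 2:
        raise ValueError("need results from >= 2 tissues")
    up_sets, down_sets = [], []
    biotype: dict[str, str] = {}
    for res in per_tissue_results.values():
        up_sets.append(set(res.loc[res["direction"] == "up", "gene_id"]))
        down_sets.append(set(res.loc[res["direction"] == "down", "gene_id"]))
        biotype.update(zip(res["gene_id"], res["biotype"]))
    common_up = set.intersection(*up_sets)
    common_down = set.intersection(*down_sets)
    return CommonDESets(
        common_up_pcg={g for g in common_up if biotype[g] == "pcg"},
        common_down_pcg={g for g in common_down if biotype[g] == "pcg"},
        common_up_lnc={g for g in common_up if biotype[g] == "lncrna"},
        common_down_lnc={g for g in common_down if biotype[g] == "lncrna"},
    )
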