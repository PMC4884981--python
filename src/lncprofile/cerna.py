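"""Tri-color ceRNA network construction and minimal-motif enumeration.

Nodes are typed lncrna / mrna / mirna; edges are typed:

* ``targeting``    — miRNA -> lncRNA or mRNA (from the target table)
* ``neighbor``     — lncRNA - mRNA genomic neighbor pair
* ``coexpression`` — lncRNA - mRNA with Pearson r > r_min and p < p_max
  (strict, computed over all samples)

A minimal ceRNA motif is one miRNA targeting both members of a lncRNA-mRNA
pair that is connected by BOTH a neighbor and a coexpression edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .annotate import LncContext
from .diffexpr import bh_fdr
from .gba import pearson_r_with_p
from .preprocess import ExpressionMatrix
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TriColorNetwork:
    """Typed nodes and typed edge sets; canonically ordered for serialization."""

    node_types: dict[str, str] = field(default_factory=dict)  # id -> lncrna|mrna|mirna
    targeting: set[tuple[str, str]] = field(default_factory=set)  # (mirna, rna)
    neighbor: set[tuple[str, str]] = field(default_factory=set)  # (lnc, mrna)
    coexpression: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # (lnc, mrna) -> (r, p)

    def validate(self) -> None:
        for m, t in self.targeting:
            if self.node_types.get(m) != "mirna" or self.node_types.get(t) not in (
                "lncrna", "mrna",
            ):
                raise ValueError(f"bad targeting edge ({m}, {t})")
            if m == t:
                raise ValueError("self-edge")
        for edges in (self.neighbor, set(self.coexpression)):
            for l, g in edges:
                if self.node_types.get(l) != "lncrna" or self.node_types.get(g) != "mrna":
                    raise ValueError(f"bad lncRNA-mRNA edge ({l}, {g})")

    def nodes(self, node_type: str | None = None) -> list[str]:
        ids = (
            self.node_types
            if node_type is None
            else (n for n, t in self.node_types.items() if t == node_type)
        )
        return sorted(ids)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n in self.nodes():
            g.add_node(n, node_type=self.node_types[n])
        for m, t in sorted(self.targeting):
            g.add_edge(m, t, key="targets", edge_type="targets")
        for l, p in sorted(self.neighbor):
            g.add_edge(l, p, key="neighbor", edge_type="neighbor")
        for (l, p), (r, pv) in sorted(self.coexpression.items()):
            g.add_edge(l, p, key="coexpr", edge_type="coexpr", r=r, p=pv)
        return g

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for m, t in sorted(self.targeting):
                fh.write(f"{m}\ttargets\t{t}\n")
            for l, p in sorted(self.neighbor):
                fh.write(f"{l}\tneighbor\t{p}\n")
            for l, p in sorted(self.coexpression):
                fh.write(f"{l}\tcoexpr\t{p}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass(frozen=True)
class CeRNAMotif:
    mirna_id: str
    lnc_id: str
    mrna_id: str
    r: float
    p: float


def build_network(
    contexts: list[LncContext],
    matrix: ExpressionMatrix,
    targets: pd.DataFrame,
    r_min: float = 0.45,
    p_max: float = 0.01,
    keep_isolated: bool = False,
) -> TriColorNetwork:
    """Assemble the tri-color network from neighbor pairs, expression, and
    the target table.

    One neighbor edge per (lncRNA, neighbor PCG) pair; a coexpression edge is
    added iff r > r_min and p < p_max (both strict) over all samples;
    targeting edges are copied from the table restricted to RNAs already in
    the network. Isolated nodes are dropped unless ``keep_isolated``.
    """
    net = TriColorNetwork()
    for ctx in contexts:
        if ctx.neighbor_pcg_id is None:
            continue
        lnc, pcg = ctx.lnc_id, ctx.neighbor_pcg_id
        if lnc not in matrix.values.index or pcg not in matrix.values.index:
            logger.info("build_network: %s or %s absent from matrix; pair skipped", lnc, pcg)
            continue
        net.node_types[lnc] = "lncrna"
        net.node_types[pcg] = "mrna"
        net.neighbor.add((lnc, pcg))
        r, p = pearson_r_with_p(
            matrix.values.loc[lnc].to_numpy(), matrix.values.loc[pcg].to_numpy()
        )
        if r > r_min and p < p_max:
            net.coexpression[(lnc, pcg)] = (r, p)

    rnas = set(net.node_types)
    for row in targets.itertuples(index=False):
        if row.target_id in rnas:
            net.node_types.setdefault(row.mirna_id, "mirna")
            net.targeting.add((row.mirna_id, row.target_id))

    if not keep_isolated:
        connected = set()
        for m, t in net.targeting:
            connected |= {m, t}
        for l, p in net.neighbor | set(net.coexpression):
            connected |= {l, p}
        net.node_types = {n: t for n, t in net.node_types.items() if n in connected}
    net.validate()
    return net


def find_motifs(network: TriColorNetwork) -> list[CeRNAMotif]:
    """All (miRNA, lncRNA, mRNA) triples where the miRNA targets both members
    of a neighbor pair that also carries a coexpression edge."""
    by_mirna: dict[str, set[str]] = {}
    for m, t in network.targeting:
        by_mirna.setdefault(m, set()).add(t)
    motifs = []
    qualifying = sorted(network.neighbor & set(network.coexpression))
    for m in sorted(by_mirna):
        targets = by_mirna[m]
        for l, g in qualifying:
            if l in targets and g in targets:
                r, p = network.coexpression[(l, g)]
                motifs.append(CeRNAMotif(m, l, g, r, p))
    return motifs


def motifs_to_frame(motifs: list[CeRNAMotif]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mirna_id": m.mirna_id, "lnc_id": m.lnc_id, "mrna_id": m.mrna_id,
             "r": m.r, "p": m.p}
            for m in motifs
        ],
        columns=["mirna_id", "lnc_id", "mrna_id", "r", "p"],
    )


def degree_table(network: TriColorNetwork) -> pd.DataFrame:
    """Per-node degree split by edge type (targeting counts both directions)."""
    rows = {
        n: {"node_type": t, "targeting": 0, "neighbor": 0, "coexpression": 0}
        for n, t in network.node_types.items()
    }
    for m, t in network.targeting:
        rows[m]["targeting"] += 1
        rows[t]["targeting"] += 1
    for l, p in network.neighbor:
        rows[l]["neighbor"] += 1
        rows[p]["neighbor"] += 1
    for l, p in network.coexpression:
        rows[l]["coexpression"] += 1
        rows[p]["coexpression"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df["total"] = df[["targeting", "neighbor", "coexpression"]].sum(axis=1)
    df.index.name = "node_id"
    return df


def target_set_overrepresentation(
    gene_list: set[str],
    mirna_target_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of each miRNA's target set
    in a gene list, BH-adjusted across miRNAs.

    p = P(overlap >= observed) with population ``universe``, successes =
    target set within universe, draws = gene list.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_list <= universe:
        raise ValueError("gene list must be contained in the universe")
    rows = []
    n_draw = len(gene_list)
    for mirna, targets in sorted(mirna_target_sets.items()):
        k_set = len(targets & universe)
        overlap = len(targets & gene_list)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), k_set, n_draw))
        rows.append({"mirna_id": mirna, "overlap": overlap, "set_size": k_set, "p": p})
    df = pd.DataFrame(rows, columns=["mirna_id", "overlap", "set_size", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = []
    return df
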