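"""Typed multigraph integrating coexpression, PPI and miRNA-target evidence.

Nodes are lncRNAs, protein-coding mRNAs and miRNAs, annotated with
differential-expression direction and |log2 fold change|. A node pair
may carry several typed edges at once (e.g. both a PPI and a positive
coexpression link); miRNA-target edges are the only directed kind,
stored miRNA -> target, and only miRNAs whose direction is opposite to
their target's survive the regulation filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_TYPES = ("coexpr_pos", "coexpr_neg", "ppi", "mirna_target")
NODE_TYPES = ("lncRNA", "mRNA", "miRNA")
VALID_DIRECTIONS = {"up", "down"}


class IntegratedNetwork(nx.MultiGraph):
    """Multigraph with node attributes ``node_type``, ``direction``,
    ``log2_fc`` and edge attribute ``etype``. For mirna_target edges the
    attribute ``mirna`` records the regulating endpoint."""


@dataclass
class NetworkSummary:
    n_mirna_target: int
    n_coexpr_pos: int
    n_coexpr_neg: int
    n_ppi: int
    n_ppi_overlap_total: int
    n_ppi_overlap_pos: int
    n_ppi_overlap_neg: int
    n_mirna_lncrna_links: int

    def __post_init__(self) -> None:
        if self.n_ppi_overlap_total != self.n_ppi_overlap_pos + self.n_ppi_overlap_neg:
            raise ValueError("overlap split must sum to the total")
        if self.n_ppi_overlap_total > self.n_ppi:
            raise ValueError("overlap cannot exceed PPI count")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_mirna_targets(
    pairs: pd.DataFrame, mirna_directions: dict, gene_directions: dict
) -> pd.DataFrame:
    """Keep (miRNA, target) pairs whose miRNA is differentially expressed
    in the direction opposite to its target.

    Pairs with an unknown direction on either side are dropped and
    counted in the log; a direction outside {up, down} raises.
    """
    for name, table in (("miRNA", mirna_directions), ("gene", gene_directions)):
        bad = set(table.values()) - VALID_DIRECTIONS
        if bad:
            raise ValueError(f"malformed {name} directions: {sorted(bad)}")
    keep, n_unknown = [], 0
    for mirna, target in zip(pairs["mirna"], pairs["target"]):
        md = mirna_directions.get(mirna)
        gd = gene_directions.get(target)
        if md is None or gd is None:
            n_unknown += 1
            continue
        keep.append(md != gd)
    if n_unknown:
        logger.info("dropped %d miRNA-target pairs with unknown direction", n_unknown)
    known = pairs.loc[
        pairs["mirna"].map(mirna_directions.__contains__)
        & pairs["target"].map(gene_directions.__contains__)
    ]
    return known.loc[keep].reset_index(drop=True)


def integrate(
    coexpr_edges: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    mirna_edges: pd.DataFrame,
    node_table: pd.DataFrame,
) -> IntegratedNetwork:
    """Merge the three evidence layers into one typed multigraph.

    ``node_table`` needs columns gene, biotype (lncRNA | protein_coding |
    miRNA), direction and log2_fc for every node referenced by an edge;
    unknown nodes raise with the offenders listed. Coexpression edges
    carry their sign as coexpr_pos / coexpr_neg; PPI edges must join two
    non-miRNA nodes.
    """
    biotype_to_node = {"lncRNA": "lncRNA", "protein_coding": "mRNA", "miRNA": "miRNA"}
    net = IntegratedNetwork()
    attrs = {}
    for row in node_table.itertuples(index=False):
        bt = biotype_to_node.get(row.biotype)
        if bt is None:
            raise ValueError(f"unknown biotype {row.biotype!r} for node {row.gene!r}")
        attrs[row.gene] = {
            "node_type": bt,
            "direction": getattr(row, "direction", "unknown"),
            "log2_fc": float(getattr(row, "log2_fc", 0.0)),
        }

    def _require(nodes) -> None:
        unknown = sorted(set(nodes) - set(attrs))
        if unknown:
            raise ValueError(f"edges reference unknown nodes: {unknown[:10]}")

    if len(coexpr_edges):
        _require(list(coexpr_edges["gene_a"]) + list(coexpr_edges["gene_b"]))
    if len(ppi_edges):
        _require(list(ppi_edges["gene_a"]) + list(ppi_edges["gene_b"]))
    if len(mirna_edges):
        _require(list(mirna_edges["mirna"]) + list(mirna_edges["target"]))

    for gene, a in attrs.items():
        net.add_node(gene, **a)

    for row in coexpr_edges.itertuples(index=False):
        if row.gene_a == row.gene_b:
            raise ValueError(f"self-loop on {row.gene_a!r}")
        for g in (row.gene_a, row.gene_b):
            if attrs[g]["node_type"] == "miRNA":
                raise ValueError(f"coexpression edge touches miRNA node {g!r}")
        etype = "coexpr_pos" if getattr(row, "sign", "positive") == "positive" else "coexpr_neg"
        net.add_edge(row.gene_a, row.gene_b, etype=etype, r=float(getattr(row, "r", 0.0)))
    for row in ppi_edges.itertuples(index=False):
        if row.gene_a == row.gene_b:
            raise ValueError(f"self-loop on {row.gene_a!r}")
        net.add_edge(row.gene_a, row.gene_b, etype="ppi")
    for row in mirna_edges.itertuples(index=False):
        if row.mirna == row.target:
            raise ValueError(f"self-loop on {row.mirna!r}")
        if attrs[row.mirna]["node_type"] != "miRNA":
            raise ValueError(f"mirna_target edge source {row.mirna!r} is not a miRNA")
        if attrs[row.target]["node_type"] == "miRNA":
            raise ValueError(f"mirna_target edge target {row.target!r} is a miRNA")
        net.add_edge(row.mirna, row.target, etype="mirna_target", mirna=row.mirna)
    return net


def _pair(a, b) -> tuple:
    return (a, b) if a <= b else (b, a)


def summarize(network: IntegratedNetwork) -> NetworkSummary:
    """Edge-type counts and the PPI/coexpression overlap split by sign."""
    coexpr_sign: dict = {}
    ppi_pairs: set = set()
    counts = {t: 0 for t in EDGE_TYPES}
    n_mirna_lncrna = 0
    for a, b, data in network.edges(data=True):
        etype = data["etype"]
        counts[etype] += 1
        if etype in ("coexpr_pos", "coexpr_neg"):
            coexpr_sign[_pair(a, b)] = etype
        elif etype == "ppi":
            ppi_pairs.add(_pair(a, b))
        elif etype == "mirna_target":
            target = b if data.get("mirna", a) == a else a
            if network.nodes[target]["node_type"] == "lncRNA":
                n_mirna_lncrna += 1
    overlap = {p: coexpr_sign[p] for p in ppi_pairs if p in coexpr_sign}
    n_pos = sum(1 for s in overlap.values() if s == "coexpr_pos")
    n_neg = sum(1 for s in overlap.values() if s == "coexpr_neg")
    return NetworkSummary(
        n_mirna_target=counts["mirna_target"],
        n_coexpr_pos=counts["coexpr_pos"],
        n_coexpr_neg=counts["coexpr_neg"],
        n_ppi=counts["ppi"],
        n_ppi_overlap_total=n_pos + n_neg,
        n_ppi_overlap_pos=n_pos,
        n_ppi_overlap_neg=n_neg,
        n_mirna_lncrna_links=n_mirna_lncrna,
    )


def node_profile(network: IntegratedNetwork, node: str) -> dict:
    """Degree breakdown for one node: coexpressed protein-coding and
    lncRNA neighbors, and the number of miRNAs regulating it."""
    if node not in network:
        raise ValueError(f"node {node!r} not in network")
    coexpr_pcg: set = set()
    coexpr_lnc: set = set()
    mirnas: set = set()
    for _, other, data in network.edges(node, data=True):
        etype = data["etype"]
        if etype in ("coexpr_pos", "coexpr_neg"):
            ntype = network.nodes[other]["node_type"]
            if ntype == "mRNA":
                coexpr_pcg.add(other)
            elif ntype == "lncRNA":
                coexpr_lnc.add(other)
        elif etype == "mirna_target" and data.get("mirna") != node:
            mirnas.add(data["mirna"])
    return {
        "coexpressed_protein_coding": len(coexpr_pcg),
        "coexpressed_lncrna": len(coexpr_lnc),
        "regulating_mirnas": len(mirnas),
    }


def export_network(network: IntegratedNetwork, path: str, fmt: str = "graphml") -> None:
    """Write the network as GraphML (lossless), SIF or edge TSV."""
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b, data in network.edges(data=True):
                src, dst = a, b
                if data["etype"] == "mirna_target" and data.get("mirna") == b:
                    src, dst = b, a
                fh.write(f"{src}\t{data['etype']}\t{dst}\n")
    elif fmt == "tsv":
        rows = []
        for a, b, data in network.edges(data=True):
            src, dst = a, b
            if data["etype"] == "mirna_target" and data.get("mirna") == b:
                src, dst = b, a
            rows.append({"source": src, "target": dst, "etype": data["etype"]})
        pd.DataFrame(rows, columns=["source", "target", "etype"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r} (use graphml, sif or tsv)")


def load_graphml(path: str) -> IntegratedNetwork:
    """Read back a GraphML export; round-trips nodes, typed edges and
    attributes."""
    g = nx.read_graphml(path, force_multigraph=True)
    net = IntegratedNetwork()
    net.add_nodes_from(g.nodes(data=True))
    net.add_edges_from(g.edges(data=True))
    return net
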