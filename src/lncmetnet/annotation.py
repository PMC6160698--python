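"""Guilt-by-association GO annotation of lncRNAs.

A lncRNA inherits candidate functions from the protein-coding genes it
is directly coexpressed with: for each hub lncRNA (more than
``min_neighbors`` coexpressed protein-coding genes) every GO term is
scored by the hypergeometric upper-tail (over-representation) test over
the annotated universe, with per-lncRNA Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from lncmetnet.coexpression import CoexpressionNetwork, bh_adjust

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "lncrna", "term", "term_name", "x", "n_draw", "K", "N", "p", "p_adj", "assigned",
]


@dataclass
class GeneSetCollection:
    """GO-BP style gene sets: term id -> gene set, with display names.

    Gene symbols are case-normalized to upper case; empty terms are
    dropped with a warning.
    """

    sets: dict
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for term, genes in self.sets.items():
            genes = frozenset(g.upper() for g in genes)
            if not genes:
                logger.warning("dropping empty gene set %s", term)
                continue
            cleaned[term] = genes
            self.names.setdefault(term, term)
        self.sets = cleaned

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_upper_tail(x: int, K: int, n_draw: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n_draw).

    The over-representation p-value: probability of drawing at least
    ``x`` annotated genes when ``n_draw`` genes are sampled without
    replacement from a universe of ``N`` genes of which ``K`` are
    annotated to the term.
    """
    if not (0 <= x <= n_draw <= N):
        raise ValueError(f"need 0 <= x ({x}) <= n_draw ({n_draw}) <= N ({N})")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K ({K}) <= N ({N})")
    if x > min(n_draw, K):
        raise ValueError(f"x ({x}) exceeds min(n_draw, K) = {min(n_draw, K)}")
    return float(stats.hypergeom.sf(x - 1, N, K, n_draw))


def neighborhood(
    network: CoexpressionNetwork, lncrna: str, biotype_filter: str = "protein_coding"
) -> set:
    """Genes of the given biotype directly coexpressed with ``lncrna``
    (one hop, both correlation signs)."""
    if lncrna not in set(network.genes):
        raise ValueError(f"{lncrna!r} is not in the network")
    if network.biotype is None:
        raise ValueError("network has no biotype annotation")
    mask_a = network.edges["gene_a"] == lncrna
    mask_b = network.edges["gene_b"] == lncrna
    nb = set(network.edges.loc[mask_a, "gene_b"]) | set(network.edges.loc[mask_b, "gene_a"])
    if biotype_filter is None:
        return nb
    return {g for g in nb if network.biotype.get(g) == biotype_filter}


def annotate_lncrnas(
    network: CoexpressionNetwork,
    gene_sets: GeneSetCollection,
    min_neighbors: int = 3,
    alpha: float = 0.05,
    adjust: str = "per_lncrna",
) -> pd.DataFrame:
    """Hypergeometric GO enrichment for every hub lncRNA in the network.

    Only lncRNAs with strictly more than ``min_neighbors`` coexpressed
    protein-coding genes are tested. The universe N is the set of genes
    annotated in ``gene_sets`` that are also in the network's tested gene
    space; for each lncRNA, the draw is its annotated protein-coding
    neighbors. Terms with at least one annotated neighbor are tested and
    BH-adjusted per lncRNA (``adjust="global"`` pools all lncRNAs into
    one family). Terms with p_adj < alpha carry ``assigned=True``.
    """
    if len(gene_sets) == 0:
        raise ValueError("gene-set collection is empty")
    if adjust not in {"per_lncrna", "global"}:
        raise ValueError(f"unknown adjust mode {adjust!r}")
    if network.biotype is None:
        raise ValueError("network has no biotype annotation")
    net_genes = {g.upper() for g in network.genes}
    universe = gene_sets.universe & net_genes
    N = len(universe)
    term_sets = {
        term: genes & universe for term, genes in sorted(gene_sets.sets.items())
    }
    lncrnas = sorted(
        g for g in network.genes if network.biotype.get(g) == "lncRNA"
    )
    rows = []
    for lnc in lncrnas:
        nb = {g.upper() for g in neighborhood(network, lnc, "protein_coding")}
        if len(nb) <= min_neighbors:
            continue
        ann_nb = nb & universe
        n_draw = len(ann_nb)
        if n_draw == 0:
            continue
        for term, tgenes in term_sets.items():
            K = len(tgenes)
            if K == 0:
                continue
            x = len(tgenes & ann_nb)
            if x == 0:
                continue
            p = hypergeom_upper_tail(x, K, n_draw, N)
            rows.append(
                {
                    "lncrna": lnc,
                    "term": term,
                    "term_name": gene_sets.names.get(term, term),
                    "x": x,
                    "n_draw": n_draw,
                    "K": K,
                    "N": N,
                    "p": p,
                }
            )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    result = pd.DataFrame(rows)
    if adjust == "global":
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
    else:
        result["p_adj"] = (
            result.groupby("lncrna")["p"]
            .transform(lambda s: bh_adjust(s.to_numpy()))
        )
    result["assigned"] = result["p_adj"] < alpha
    return result.sort_values(
        ["lncrna", "p", "term"], kind="mergesort", ignore_index=True
    )[RESULT_COLUMNS]


def top_terms(results: pd.DataFrame, lncrna: str, k: int = 10) -> pd.DataFrame:
    """Top-k terms for one lncRNA: ascending p, ties broken by larger x,
    then by term id."""
    sub = results.loc[results["lncrna"] == lncrna]
    if sub.empty:
        raise ValueError(f"no enrichment results for {lncrna!r}")
    sub = sub.sort_values(
        ["p", "x", "term"], ascending=[True, False, True], kind="mergesort"
    )
    return sub.head(k).reset_index(drop=True)
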