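"""All-pairs Pearson coexpression networks with Fisher-z p-values.

Every unordered gene pair is tested; p-values come from the Fisher
z-transform normal approximation (z = atanh(r), z * sqrt(n-3) ~ N(0,1)
under the null) and are adjusted by Benjamini-Hochberg over the whole
family of tested pairs. Edges with adjusted p below alpha form the
network, signed by the correlation sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["gene_a", "gene_b", "r", "n", "p", "p_adj", "sign", "support"]


@dataclass
class CoexpressionNetwork:
    """Significant signed coexpression edges plus the tested gene universe.

    ``edges`` has columns gene_a, gene_b (canonical lexicographic order),
    r, n, p, p_adj, sign, support. ``genes`` is the full list of genes
    that entered testing (the universe for downstream enrichment), and
    ``biotype`` maps gene -> lncRNA | protein_coding.
    """

    edges: pd.DataFrame
    alpha: float
    genes: list
    biotype: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        if (self.edges["gene_a"] == self.edges["gene_b"]).any():
            raise ValueError("self-loops are not allowed")
        swapped = self.edges["gene_a"] > self.edges["gene_b"]
        if swapped.any():
            raise ValueError("edges must be stored in canonical (lexicographic) order")

    def adjacency(self) -> dict:
        adj: dict = {g: set() for g in self.genes}
        for a, b in zip(self.edges["gene_a"], self.edges["gene_b"]):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation, clipped to [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return float(np.clip(r, -1.0, 1.0))


def fisher_asymptotic_p(r, n: int, method: str = "fisherz"):
    """Two-sided p-value for a Pearson correlation.

    ``method="fisherz"`` (default): z = atanh(r), statistic z*sqrt(n-3),
    p = 2*Phi(-|statistic|). ``method="t"``: t = r*sqrt(n-2)/sqrt(1-r^2)
    against Student's t with n-2 degrees of freedom. |r| = 1 gives p = 0
    exactly under either method. Accepts scalars or arrays.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    r_arr = np.asarray(r, dtype=float)
    if (np.abs(r_arr) > 1).any():
        raise ValueError("|r| must be <= 1")
    extreme = np.abs(r_arr) == 1.0
    r_safe = np.where(extreme, 0.0, r_arr)
    if method == "fisherz":
        z = np.arctanh(r_safe)
        p = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(n - 3))
    elif method == "t":
        t = r_safe * np.sqrt(n - 2) / np.sqrt(1.0 - r_safe**2)
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.where(extreme, 0.0, np.minimum(p, 1.0))
    return float(p) if np.isscalar(r) or np.asarray(r).ndim == 0 else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_network(
    values: pd.DataFrame,
    biotype: pd.Series | None = None,
    alpha: float = 0.05,
    genes: list | None = None,
    method: str = "fisherz",
) -> CoexpressionNetwork:
    """Test all unordered gene pairs and keep edges with BH-adjusted p < alpha.

    ``values`` is a gene x sample log2 matrix; ``genes`` restricts the
    universe (e.g. to the differentially expressed subset). Constant rows
    are dropped with a warning before correlation.
    """
    if genes is not None:
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise ValueError(f"genes not in matrix: {missing[:5]}")
        values = values.loc[genes]
    n = values.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for Fisher's asymptotic method")
    arr = values.to_numpy(dtype=float)
    constant = arr.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "dropping %d constant genes before correlation: %s",
            int(constant.sum()),
            values.index[constant][:5].tolist(),
        )
        values = values.loc[~constant]
        arr = arr[~constant]
    gene_list = list(values.index)
    g = len(gene_list)
    if g < 2:
        return CoexpressionNetwork(
            edges=pd.DataFrame(columns=EDGE_COLUMNS), alpha=alpha,
            genes=gene_list, biotype=biotype,
        )
    rmat = np.corrcoef(arr)
    ia, ib = np.triu_indices(g, k=1)
    logger.info("testing %d gene pairs (%d genes)", len(ia), g)
    r = np.clip(rmat[ia, ib], -1.0, 1.0)
    p = fisher_asymptotic_p(r, n, method=method)
    p_adj = bh_adjust(p)
    keep = p_adj < alpha
    names = np.asarray(gene_list, dtype=object)
    a, b = names[ia[keep]], names[ib[keep]]
    # canonical lexicographic pair order
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    edges = pd.DataFrame(
        {
            "gene_a": a2,
            "gene_b": b2,
            "r": r[keep],
            "n": n,
            "p": p[keep],
            "p_adj": p_adj[keep],
            "sign": np.where(r[keep] > 0, "positive", "negative"),
            "support": 1,
        }
    ).sort_values(["gene_a", "gene_b"], kind="mergesort", ignore_index=True)
    return CoexpressionNetwork(edges=edges, alpha=alpha, genes=gene_list, biotype=biotype)


def aggregate_multi_dataset(
    edge_tables: list, min_support: int, require_consistent_sign: bool = False
) -> pd.DataFrame:
    """Consensus edges appearing in at least ``min_support`` datasets.

    Edge identity is the unordered gene pair; with
    ``require_consistent_sign`` an edge additionally needs the same sign
    in every dataset that contains it. Returns an edge table with a
    ``support`` count.
    """
    if not edge_tables:
        raise ValueError("need at least one edge table")
    if min_support > len(edge_tables):
        logger.warning(
            "min_support=%d exceeds dataset count %d; consensus is empty",
            min_support,
            len(edge_tables),
        )
    counts: dict = {}
    signs: dict = {}
    for table in edge_tables:
        seen = set()
        for a, b, s in zip(table["gene_a"], table["gene_b"], table.get("sign", [""] * len(table))):
            pair = (a, b) if a <= b else (b, a)
            if pair in seen:
                continue
            seen.add(pair)
            counts[pair] = counts.get(pair, 0) + 1
            signs.setdefault(pair, set()).add(s)
    rows = []
    for pair, c in counts.items():
        if c < min_support:
            continue
        if require_consistent_sign and len(signs[pair]) > 1:
            continue
        rows.append({"gene_a": pair[0], "gene_b": pair[1], "support": c})
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "support"])
    return out.sort_values(["gene_a", "gene_b"], kind="mergesort", ignore_index=True)
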