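"""Normalization, filtering and differential expression for paired arrays.

All expression values are log2 intensities. Fold changes are oriented
tumor over normal, so ``direction == "up"`` means higher in tumor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import cluster, spatial, stats

logger = logging.getLogger(__name__)

VALID_GROUPS = frozenset({"tumor", "normal"})
VALID_BIOTYPES = frozenset({"lncRNA", "protein_coding"})


@dataclass
class ExpressionMatrix:
    """Probe x sample log2 intensity matrix with sample and probe metadata.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, rows indexed by probe id, columns
        by sample id.
    sample_group
        Series mapping sample id -> ``"tumor"`` or ``"normal"``.
    pair_id
        Series mapping sample id -> patient/pair label; each pair must
        contain exactly one tumor and one normal sample.
    biotype
        Series mapping probe id -> ``"lncRNA"`` or ``"protein_coding"``.
    gene_symbol
        Optional Series mapping probe id -> gene symbol. Defaults to the
        probe id itself.
    """

    values: pd.DataFrame
    sample_group: pd.Series
    pair_id: pd.Series
    biotype: pd.Series
    gene_symbol: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_symbol is None:
            self.gene_symbol = pd.Series(
                self.values.index, index=self.values.index, name="gene_symbol"
            )
        self.validate()

    def validate(self) -> None:
        samples = list(self.values.columns)
        for name, series in (("sample_group", self.sample_group), ("pair_id", self.pair_id)):
            missing = [s for s in samples if s not in series.index]
            if missing:
                raise ValueError(f"{name} missing labels for samples: {missing}")
        bad_groups = set(self.sample_group.loc[samples]) - VALID_GROUPS
        if bad_groups:
            raise ValueError(f"invalid sample groups: {sorted(bad_groups)}")
        for pair, sub in self.sample_group.loc[samples].groupby(self.pair_id.loc[samples]):
            counts = sub.value_counts()
            if counts.get("tumor", 0) != 1 or counts.get("normal", 0) != 1:
                raise ValueError(
                    f"pair {pair!r} must have exactly one tumor and one normal sample"
                )
        missing_bt = [p for p in self.values.index if p not in self.biotype.index]
        if missing_bt:
            raise ValueError(f"biotype missing for probes: {missing_bt[:5]}")
        bad_bt = set(self.biotype.loc[self.values.index]) - VALID_BIOTYPES
        if bad_bt:
            raise ValueError(f"invalid biotypes: {sorted(bad_bt)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def tumor_samples(self) -> list:
        return [s for s in self.values.columns if self.sample_group[s] == "tumor"]

    @property
    def normal_samples(self) -> list:
        return [s for s in self.values.columns if self.sample_group[s] == "normal"]

    def subset(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[probes],
            sample_group=self.sample_group,
            pair_id=self.pair_id,
            biotype=self.biotype,
            gene_symbol=self.gene_symbol,
        )


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so each holds the same value multiset.

    The reference distribution is the per-rank mean across the sorted
    columns. Ties within a column receive the mean of the reference
    values spanning their tied ranks, so the result is deterministic and
    independent of input row order.
    """
    if values.shape[1] < 1:
        raise ValueError("need at least one column")
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values are not supported; impute or drop first")
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            mapped[order[i : k + 1]] = reference[i : k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def presence_filter(
    values: pd.DataFrame, presence_flags: pd.DataFrame, min_present: int
) -> pd.DataFrame:
    """Keep rows flagged as expressed in at least ``min_present`` samples.

    ``presence_flags`` is a boolean matrix of per-probe/sample detection
    calls with the same shape as ``values``. Row order is preserved.
    """
    if presence_flags.shape != values.shape:
        raise ValueError("presence_flags must have the same shape as values")
    if min_present > values.shape[1]:
        raise ValueError(
            f"min_present={min_present} exceeds sample count {values.shape[1]}"
        )
    flags = presence_flags.loc[values.index, values.columns].to_numpy(dtype=bool)
    keep = flags.sum(axis=1) >= min_present
    dropped = int((~keep).sum())
    if dropped:
        logger.info("presence_filter dropped %d of %d rows", dropped, len(values))
    return values.loc[keep]


def median_presence_flags(values: pd.DataFrame) -> pd.DataFrame:
    """Fallback detection calls: a probe is "expressed" in a sample if its
    intensity exceeds that sample's column median."""
    med = values.median(axis=0)
    return values.gt(med, axis=1)


def differential_test(
    matrix: ExpressionMatrix,
    paired: bool = False,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-probe tumor-vs-normal t-test and fold change.

    Returns a table with ``mean_tumor``, ``mean_normal``, ``log2_fc``
    (tumor minus normal), ``fold_change`` (= 2**log2_fc), ``p_value``,
    and ``direction`` in {up, down, ns} at the given thresholds.

    The default is the classic pooled two-sample t-test (``equal_var=True``);
    pass ``equal_var=False`` for Welch, or ``paired=True`` for a paired
    test on per-pair differences. Rows with zero variance and zero group
    difference are reported with p = 1 and a warning rather than NaN.
    """
    tum_cols = matrix.tumor_samples
    nor_cols = matrix.normal_samples
    if len(tum_cols) < 2 or len(nor_cols) < 2:
        raise ValueError("need at least two samples per group")
    tum = matrix.values[tum_cols].to_numpy(dtype=float)
    if paired:
        # align normal columns to tumor columns by pair id
        pair_of = matrix.pair_id
        nor_by_pair = {pair_of[s]: s for s in nor_cols}
        try:
            nor_cols_aligned = [nor_by_pair[pair_of[s]] for s in tum_cols]
        except KeyError as exc:  # pragma: no cover - validate() prevents this
            raise ValueError(f"incomplete pair: {exc}") from exc
        nor = matrix.values[nor_cols_aligned].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_rel(tum, nor, axis=1)
    else:
        nor = matrix.values[nor_cols].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(tum, nor, axis=1, equal_var=equal_var)
    mean_t = tum.mean(axis=1)
    mean_n = nor.mean(axis=1)
    log2_fc = mean_t - mean_n
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        # zero within-group variance: p undefined; report 1 when the group
        # means also agree, 0 when they differ (infinitely strong evidence)
        logger.warning(
            "%d rows had zero within-group variance; p set to 0/1 by mean difference",
            int(degenerate.sum()),
        )
        p = np.where(degenerate & (log2_fc == 0), 1.0, p)
        p = np.where(degenerate & (log2_fc != 0), 0.0, p)
    fold_change = np.power(2.0, log2_fc)
    direction = np.where(
        (fold_change > fc_threshold) & (p < alpha),
        "up",
        np.where((fold_change < 1.0 / fc_threshold) & (p < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": matrix.gene_symbol.loc[matrix.values.index].to_numpy(),
            "biotype": matrix.biotype.loc[matrix.values.index].to_numpy(),
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "log2_fc": log2_fc,
            "fold_change": fold_change,
            "p_value": p,
            "direction": direction,
        },
        index=matrix.values.index,
    )


def select_differential(
    table: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05
) -> tuple[list, list]:
    """Volcano-style selection: up = FC strictly > threshold and p < alpha,
    down = FC strictly < 1/threshold and p < alpha. The lists are disjoint."""
    sig = table["p_value"] < alpha
    up = table.loc[sig & (table["fold_change"] > fc_threshold), "gene"].tolist()
    down = table.loc[sig & (table["fold_change"] < 1.0 / fc_threshold), "gene"].tolist()
    return up, down


def intersect_external(
    up: list, down: list, external: pd.DataFrame
) -> tuple[list, list]:
    """Keep internally called genes confirmed with the same direction by an
    external differential-expression list.

    ``external`` needs columns ``gene`` and ``direction`` ("up"/"down");
    symbols are compared case-insensitively.
    """
    if external.empty:
        logger.warning("external DE list is empty; intersection is empty")
        return [], []
    bad = set(external["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"invalid external directions: {sorted(bad)}")
    ext_up = set(external.loc[external["direction"] == "up", "gene"].str.upper())
    ext_down = set(external.loc[external["direction"] == "down", "gene"].str.upper())
    both = ext_up & ext_down
    if both:
        raise ValueError(f"genes listed with both directions: {sorted(both)[:5]}")
    kept_up = [g for g in up if g.upper() in ext_up]
    kept_down = [g for g in down if g.upper() in ext_down]
    return kept_up, kept_down


def collapse_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse multiple probes per gene symbol to the probe with the
    largest mean intensity (deterministic; ties broken by probe id)."""
    means = matrix.values.mean(axis=1)
    order = pd.DataFrame(
        {"symbol": matrix.gene_symbol.loc[matrix.values.index], "mean": means}
    )
    order = order.sort_values(["symbol", "mean"], ascending=[True, False], kind="mergesort")
    keep = order.drop_duplicates("symbol").index
    keep = [p for p in matrix.values.index if p in set(keep)]  # preserve row order
    return matrix.subset(keep)


def hierarchical_cluster(values: pd.DataFrame) -> dict:
    """Average-linkage hierarchical clustering with 1 - Pearson r distance.

    Returns row and column linkage matrices and dendrogram leaf orders.
    Zero-variance rows make the correlation distance undefined and raise
    an error naming the offending rows.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    arr = values.to_numpy(dtype=float)
    row_sd = arr.std(axis=0)
    zero_rows = values.index[arr.std(axis=1) == 0].tolist()
    if zero_rows:
        raise ValueError(f"zero-variance rows (correlation undefined): {zero_rows[:5]}")

    def _linkage(x: np.ndarray) -> np.ndarray:
        d = spatial.distance.pdist(x, metric="correlation")
        # guard against tiny negative values from rounding
        d = np.clip(d, 0.0, 2.0)
        return cluster.hierarchy.linkage(d, method="average")

    row_link = _linkage(arr)
    result = {
        "row_linkage": row_link,
        "row_order": cluster.hierarchy.leaves_list(row_link).tolist(),
    }
    if values.shape[1] >= 2 and (row_sd > 0).all():
        col_link = _linkage(arr.T)
        result["col_linkage"] = col_link
        result["col_order"] = cluster.hierarchy.leaves_list(col_link).tolist()
    return result
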