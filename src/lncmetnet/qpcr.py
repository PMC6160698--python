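"""Comparative threshold-cycle (2^-ddCq) quantification and group tests.

dCq = Cq(target) - Cq(reference gene), so a LOWER dCq means HIGHER
expression. The relative tumor/normal fold change is
2^-(dCq_tumor - dCq_normal). Association with clinicopathological
categories uses a two-sample t-test (two categories) or one-way ANOVA
(three or more).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def delta_cq(cq, reference_cq):
    """dCq = Cq(detected gene) - Cq(reference gene), in cycles."""
    cq = np.asarray(cq, dtype=float)
    ref = np.asarray(reference_cq, dtype=float)
    if cq.shape != ref.shape:
        raise ValueError("cq and reference_cq must align")
    if np.isnan(cq).any() or np.isnan(ref).any():
        raise ValueError("missing Cq measurement")
    out = cq - ref
    return float(out) if out.ndim == 0 else out


def ddcq_fold_change(dcq_tumor, dcq_normal):
    """Relative expression 2^-(dCq_tumor - dCq_normal); always positive.

    ddCq = 0 gives fold change 1; positive ddCq (later amplification in
    tumor, i.e. lower expression) gives a fold change below 1.
    """
    out = np.power(2.0, -(np.asarray(dcq_tumor, dtype=float) - np.asarray(dcq_normal, dtype=float)))
    return float(out) if out.ndim == 0 else out


def paired_group_test(values_tumor, values_normal) -> float:
    """Two-sided paired t-test p-value on matched tumor/normal vectors."""
    t = np.asarray(values_tumor, dtype=float)
    n = np.asarray(values_normal, dtype=float)
    if t.shape != n.shape or t.ndim != 1:
        raise ValueError("paired vectors must be equal-length 1-d arrays")
    if len(t) < 2:
        raise ValueError("need at least two pairs")
    diffs = t - n
    if np.std(diffs) == 0:
        raise ValueError("zero variance of paired differences; t-test undefined")
    return float(stats.ttest_rel(t, n).pvalue)


def average_replicates(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicate Cq measurements per (patient, tissue,
    gene) before analysis."""
    keys = ["patient", "tissue", "gene"]
    other = [c for c in cq_table.columns if c not in keys + ["cq", "reference_cq"]]
    agg = {"cq": "mean", "reference_cq": "mean", **{c: "first" for c in other}}
    return cq_table.groupby(keys, as_index=False, sort=True).agg(agg)


def association_table(
    dcq_values: pd.Series,
    covariates: pd.DataFrame,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-characteristic association of dCq with clinical categories.

    ``dcq_values`` is indexed by patient; ``covariates`` holds one
    categorical column per characteristic, same index. Two categories are
    compared with an (equal-variance by default) two-sample t-test, three
    or more with one-way ANOVA. Categories with fewer than two patients
    are excluded with a warning. Returns one row per category with n,
    mean, sd, the shared p-value and the test used.
    """
    common = dcq_values.index.intersection(covariates.index)
    missing = covariates.index.difference(dcq_values.index)
    if len(missing):
        raise ValueError(f"patients without dCq values: {list(missing[:5])}")
    dcq = dcq_values.loc[common]
    rows = []
    for char in covariates.columns:
        labels = covariates.loc[common, char]
        groups, cats = [], []
        for cat in sorted(labels.dropna().unique(), key=str):
            vals = dcq[labels == cat].to_numpy(dtype=float)
            if len(vals) < 2:
                logger.warning(
                    "excluding category %r of %r with %d patient(s)", cat, char, len(vals)
                )
                continue
            groups.append(vals)
            cats.append(cat)
        if len(groups) < 2:
            logger.warning("characteristic %r has <2 usable categories; skipped", char)
            continue
        if len(groups) == 2:
            test = "t"
            p = float(stats.ttest_ind(groups[0], groups[1], equal_var=not welch).pvalue)
        else:
            test = "ANOVA"
            p = float(stats.f_oneway(*groups).pvalue)
        for cat, vals in zip(cats, groups):
            rows.append(
                {
                    "characteristic": char,
                    "category": cat,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)),
                    "p": p,
                    "test": test,
                }
            )
    return pd.DataFrame(
        rows, columns=["characteristic", "category", "n", "mean", "sd", "p", "test"]
    )


def group_compare(cq_table: pd.DataFrame, gene: str) -> dict:
    """Tumor-vs-normal comparison for one gene from a long Cq table.

    Averages technical replicates, computes per-sample dCq, pairs tumor
    and normal by patient, and returns the mean fold change (2^-ddCq)
    together with the paired t-test p-value on dCq.
    """
    sub = average_replicates(cq_table.loc[cq_table["gene"] == gene])
    if sub.empty:
        raise ValueError(f"no Cq records for gene {gene!r}")
    sub = sub.assign(dcq=delta_cq(sub["cq"], sub["reference_cq"]))
    wide = sub.pivot(index="patient", columns="tissue", values="dcq")
    if not {"tumor", "normal"}.issubset(wide.columns):
        raise ValueError("need both tumor and normal measurements")
    wide = wide.dropna()
    fc = ddcq_fold_change(wide["tumor"].to_numpy(), wide["normal"].to_numpy())
    return {
        "n_patients": int(len(wide)),
        "mean_dcq_tumor": float(wide["tumor"].mean()),
        "mean_dcq_normal": float(wide["normal"].mean()),
        "mean_fold_change": float(np.mean(fc)),
        "p_value": paired_group_test(wide["tumor"].to_numpy(), wide["normal"].to_numpy()),
    }
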