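"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates a small paired tumor/normal metabolism-pathway
array: ~965 lncRNA and ~458 protein-coding probes over 3 patient pairs
by default, with planted log2 fold changes, planted coexpression modules
driven by a shared latent factor, module-linked "signature" GO terms,
direction-consistent miRNA-target pairs (plus same-direction decoys),
and paired qPCR Cq tables with clinicopathological covariates.

Expression is simulated directly on the log2 scale as Gaussian noise
around per-gene baselines: the analysis consumes log2 intensities, so
intensity-scale realism is unnecessary. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lncmetnet.annotation import GeneSetCollection
from lncmetnet.expression import ExpressionMatrix


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic array.

    Defaults mirror the design the pipeline targets: 965 lncRNA and 458
    protein-coding probes on 3 tumor/normal pairs, a mean planted effect
    of 2 log2 units with 0.5 log2 units of residual noise, five 10-gene
    coexpression modules at within-module correlation 0.7.
    """

    n_lncrna: int = 965
    n_pcg: int = 458
    n_pairs: int = 3
    de_fraction: float = 0.1
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    n_modules: int = 5
    module_size: int = 10
    module_corr: float = 0.7
    n_go_terms: int = 25
    go_background_rate: float = 0.2
    mirna_count: int = 10
    allow_de_in_modules: bool = False
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lncrna", "n_pcg", "n_pairs", "n_modules", "module_size",
                     "n_go_terms", "mirna_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.n_modules > 0 and not 0.0 < self.module_corr < 1.0:
            raise ValueError("module_corr must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_modules * self.module_size > self.n_lncrna + self.n_pcg:
            raise ValueError("module genes exceed total gene count")
        if self.n_modules > 0:
            if self.n_lncrna < self.n_modules:
                raise ValueError("need one lncRNA hub per module")
            if self.n_pcg < self.n_modules * (self.module_size - 1):
                raise ValueError("not enough protein-coding genes for modules")


@dataclass
class GroundTruth:
    """Planted structure: what a perfect pipeline should recover."""

    de_genes: set = field(default_factory=set)  # {(gene, "up"|"down")}
    module_membership: dict = field(default_factory=dict)  # gene -> module id
    module_hubs: list = field(default_factory=list)  # hub lncRNA per module
    go_assignment: dict = field(default_factory=dict)  # gene -> set of terms
    signature_terms: dict = field(default_factory=dict)  # module id -> term
    mirna_planted: set = field(default_factory=set)  # {(mirna, target)}
    mirna_decoys: set = field(default_factory=set)  # same-direction pairs

    def de_direction(self) -> dict:
        return {g: d for g, d in self.de_genes}


def _gene_names(config: SimulationConfig) -> tuple[list, list]:
    lnc = [f"LNC{i:04d}" for i in range(1, config.n_lncrna + 1)]
    pcg = [f"PCG{i:04d}" for i in range(1, config.n_pcg + 1)]
    return lnc, pcg


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the paired log2 expression matrix with planted truth.

    Differentially expressed genes get a tumor-minus-normal mean shift of
    exactly +-log2_effect before noise. Each coexpression module shares a
    per-sample latent factor with loading sqrt(module_corr), so the
    expected within-module pairwise correlation equals module_corr. By
    default DE genes are drawn disjointly from module genes so planted
    contingencies stay unambiguous.
    """
    rng = np.random.default_rng(config.seed)
    lnc, pcg = _gene_names(config)
    genes = lnc + pcg
    n_genes = len(genes)
    n_samples = 2 * config.n_pairs
    truth = GroundTruth()

    # module membership: one lncRNA hub + protein-coding members per module
    lnc_pool = list(rng.permutation(lnc))
    pcg_pool = list(rng.permutation(pcg))
    for m in range(config.n_modules):
        hub = lnc_pool.pop()
        members = [hub] + [pcg_pool.pop() for _ in range(config.module_size - 1)]
        truth.module_hubs.append(hub)
        for g in members:
            truth.module_membership[g] = m

    # planted differential expression
    n_de = int(round(config.de_fraction * n_genes))
    candidates = [g for g in genes if config.allow_de_in_modules or g not in truth.module_membership]
    if n_de > len(candidates):
        raise ValueError("de_fraction too large for the non-module gene pool")
    de_genes = rng.choice(np.asarray(candidates, dtype=object), size=n_de, replace=False)
    directions = rng.choice(np.asarray(["up", "down"], dtype=object), size=n_de)
    truth.de_genes = set(zip(de_genes.tolist(), directions.tolist()))

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    eps = rng.standard_normal((n_genes, n_samples))
    values = baseline[:, None] + config.noise_sd * eps

    gene_index = {g: i for i, g in enumerate(genes)}
    if config.n_modules:
        factors = rng.standard_normal((config.n_modules, n_samples))
        lam = math.sqrt(config.module_corr)
        resid = math.sqrt(1.0 - config.module_corr)
        for g, m in truth.module_membership.items():
            i = gene_index[g]
            values[i] = baseline[i] + config.noise_sd * (
                lam * factors[m] + resid * eps[i]
            )

    columns = []
    for p in range(1, config.n_pairs + 1):
        columns += [f"P{p}_T", f"P{p}_N"]
    tumor_cols = [j for j, c in enumerate(columns) if c.endswith("_T")]
    for g, d in truth.de_genes:
        shift = config.log2_effect if d == "up" else -config.log2_effect
        values[gene_index[g], tumor_cols] += shift

    df = pd.DataFrame(values, index=genes, columns=columns)
    sample_group = pd.Series(
        {c: ("tumor" if c.endswith("_T") else "normal") for c in columns}
    )
    pair_id = pd.Series({c: c.split("_")[0] for c in columns})
    biotype = pd.Series(
        {g: ("lncRNA" if g.startswith("LNC") else "protein_coding") for g in genes}
    )
    matrix = ExpressionMatrix(
        values=df, sample_group=sample_group, pair_id=pair_id, biotype=biotype
    )
    return matrix, truth


def simulate_go(truth: GroundTruth, config: SimulationConfig) -> GeneSetCollection:
    """Build GO-BP style gene sets around the planted modules.

    Each module gets one signature term annotating at least 80% of its
    members (ceil(0.8 * size), always including the hub's protein-coding
    neighbors) and nothing else. The remaining terms are background:
    every non-module gene joins each background term independently at
    ``go_background_rate``. Deterministic under the config seed.
    """
    if config.n_modules > 0 and config.n_go_terms < config.n_modules:
        raise ValueError("need at least one GO term per planted module")
    if config.n_go_terms == 0 and config.n_modules > 0:
        raise ValueError("n_go_terms must be > 0 when modules are planted")
    rng = np.random.default_rng(config.seed + 1)
    lnc, pcg = _gene_names(config)
    genes = lnc + pcg
    sets: dict = {}
    module_members: dict = {}
    for g, m in truth.module_membership.items():
        module_members.setdefault(m, []).append(g)
    for m in sorted(module_members):
        members = sorted(module_members[m])
        n_ann = max(1, math.ceil(0.8 * len(members)))
        annotated = list(rng.choice(np.asarray(members, dtype=object), size=n_ann, replace=False))
        term = f"GO:SIG{m:04d}"
        sets[term] = set(annotated)
        truth.signature_terms[m] = term
        for g in annotated:
            truth.go_assignment.setdefault(g, set()).add(term)
    n_background = config.n_go_terms - len(sets)
    non_module = [g for g in genes if g not in truth.module_membership]
    for t in range(n_background):
        term = f"GO:BG{t:04d}"
        mask = rng.random(len(non_module)) < config.go_background_rate
        members = {g for g, keep in zip(non_module, mask) if keep}
        if not members:
            continue
        sets[term] = members
        for g in members:
            truth.go_assignment.setdefault(g, set()).add(term)
    return GeneSetCollection(sets=sets)


def simulate_mirna(
    truth: GroundTruth, config: SimulationConfig, n_decoys: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA direction table and miRNA-target pairs around planted DE genes.

    Planted pairs point each miRNA at a differentially expressed target
    with the OPPOSITE direction (the regulation signature); an equal
    number of same-direction decoy pairs is emitted too and recorded in
    the ground truth, so the direction filter can be validated end to end.
    """
    if not truth.de_genes:
        raise ValueError("no differentially expressed targets to regulate")
    if config.mirna_count == 0:
        raise ValueError("mirna_count must be > 0 when targets are requested")
    rng = np.random.default_rng(config.seed + 2)
    mirnas = [f"miR-{i:03d}" for i in range(1, config.mirna_count + 1)]
    de = sorted(truth.de_genes)
    n_pairs = min(len(de), config.mirna_count)
    if n_decoys is None:
        n_decoys = n_pairs
    idx = rng.choice(len(de), size=n_pairs, replace=False)
    directions: dict = {}
    pair_rows = []
    for k, i in enumerate(idx):
        target, tdir = de[i]
        mirna = mirnas[k % len(mirnas)]
        mdir = "down" if tdir == "up" else "up"
        directions.setdefault(mirna, mdir)
        if directions[mirna] == mdir:
            truth.mirna_planted.add((mirna, target))
            pair_rows.append({"mirna": mirna, "target": target})
    # decoys: miRNA with the SAME direction as its target
    decoy_idx = rng.choice(len(de), size=min(n_decoys, len(de)), replace=False)
    for k, i in enumerate(decoy_idx):
        target, tdir = de[i]
        decoy = f"miR-D{k:03d}"
        directions[decoy] = tdir
        truth.mirna_decoys.add((decoy, target))
        pair_rows.append({"mirna": decoy, "target": target})
    dir_table = pd.DataFrame(
        sorted(directions.items()), columns=["mirna", "direction"]
    )
    pairs = pd.DataFrame(pair_rows, columns=["mirna", "target"]).sort_values(
        ["mirna", "target"], kind="mergesort", ignore_index=True
    )
    return dir_table, pairs


DEFAULT_COVARIATES = {
    "age_group": (["<60", ">=60"], [0.45, 0.55]),
    "sex": (["male", "female"], [0.7, 0.3]),
    "invasion": (["negative", "positive"], [0.4, 0.6]),
    "lymphatic_metastasis": (["negative", "positive"], [0.4, 0.6]),
    "distal_metastasis": (["negative", "positive"], [0.8, 0.2]),
    "differentiation": (["well", "moderate", "poor"], [0.2, 0.4, 0.4]),
    "tnm_stage": (["I-II", "III-IV"], [0.4, 0.6]),
}


def simulate_cq(
    n_patients: int,
    effect_dcq: float,
    sd: float,
    covariate_effects: dict | None = None,
    seed: int = 0,
    gene: str = "GENE1",
    reference: str = "GAPDH",
) -> pd.DataFrame:
    """Paired tumor/normal qPCR Cq table with clinical covariates.

    Each patient gets a normal-tissue dCq baseline; the tumor dCq is
    shifted by ``effect_dcq`` plus N(0, sd) noise plus any planted
    covariate effects (mapping covariate name -> dCq shift added for the
    last category of that covariate). The reference gene Cq has no group
    effect. Returns a long table: patient, tissue, gene, cq,
    reference_cq, plus one column per covariate.
    """
    if n_patients < 2:
        raise ValueError("need at least two patients")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(seed)
    covariate_effects = covariate_effects or {}
    unknown = set(covariate_effects) - set(DEFAULT_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    patients = [f"PT{i:03d}" for i in range(1, n_patients + 1)]
    cov = {}
    for name, (cats, probs) in DEFAULT_COVARIATES.items():
        cov[name] = rng.choice(np.asarray(cats, dtype=object), size=n_patients, p=probs)
    base_dcq = rng.normal(8.0, 1.5, size=n_patients)
    tumor_dcq = base_dcq + effect_dcq + rng.normal(0.0, sd, size=n_patients)
    for name, eff in covariate_effects.items():
        last_cat = DEFAULT_COVARIATES[name][0][-1]
        tumor_dcq = tumor_dcq + np.where(cov[name] == last_cat, eff, 0.0)
    rows = []
    for i, pt in enumerate(patients):
        for tissue, dcq in (("tumor", tumor_dcq[i]), ("normal", base_dcq[i])):
            ref_cq = rng.normal(20.0, 0.5)
            row = {
                "patient": pt,
                "tissue": tissue,
                "gene": gene,
                "cq": ref_cq + dcq,
                "reference_cq": ref_cq,
            }
            row.update({name: cov[name][i] for name in DEFAULT_COVARIATES})
            rows.append(row)
    return pd.DataFrame(rows)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different seed (convenience for replicates)."""
    return replace(config, seed=seed)
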