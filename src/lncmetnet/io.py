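"""Readers/writers for all interchange formats and pipeline orchestration.

Tab-separated text throughout: expression matrices (first column probe
id, header row of sample ids), sample sheets (sample, group, pair),
GMT gene sets, edge/node tables, plus YAML pipeline configs and a JSON
run manifest. Gene symbols are upper-cased at every boundary so joins
across sources never break on case.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from lncmetnet import __version__
from lncmetnet.annotation import GeneSetCollection, annotate_lncrnas
from lncmetnet.coexpression import build_network
from lncmetnet.expression import (
    ExpressionMatrix,
    differential_test,
    intersect_external,
    quantile_normalize,
    select_differential,
)
from lncmetnet.integration import export_network, filter_mirna_targets, integrate, summarize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- readers

def read_expression(matrix_path, sample_sheet_path, biotype_path=None) -> ExpressionMatrix:
    """Read an expression TSV plus its sample sheet (and optional probe
    annotation) into an ExpressionMatrix.

    The sample sheet needs columns sample, group, pair; the probe
    annotation (biotype table) needs columns probe, biotype and
    optionally gene_symbol, and is required because every downstream
    stage distinguishes lncRNA from protein-coding probes.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids: {dup[:5]}")
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup[:5]}")
    bad = values.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        r, c = next(zip(*bad.isna().to_numpy().nonzero()))
        raise ValueError(
            f"non-numeric cell at probe {values.index[r]!r}, sample {values.columns[c]!r}"
        )
    values = bad
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    for col in ("sample", "group", "pair"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    missing = set(values.columns) - set(sheet["sample"])
    if missing:
        raise ValueError(f"sample sheet missing entries for: {sorted(missing)[:5]}")
    sheet = sheet.set_index("sample")
    if biotype_path is None:
        raise ValueError("a probe annotation table (probe, biotype) is required")
    ann = pd.read_csv(biotype_path, sep="\t")
    if "probe" not in ann.columns or "biotype" not in ann.columns:
        raise ValueError("probe annotation needs columns probe, biotype")
    ann = ann.set_index("probe")
    symbols = (
        ann["gene_symbol"].str.upper()
        if "gene_symbol" in ann.columns
        else pd.Series(ann.index, index=ann.index).str.upper()
    )
    values.index = values.index.astype(str).str.upper()
    ann.index = ann.index.astype(str).str.upper()
    symbols.index = ann.index
    return ExpressionMatrix(
        values=values,
        sample_group=sheet["group"],
        pair_id=sheet["pair"].astype(str),
        biotype=ann["biotype"],
        gene_symbol=symbols,
    )


def write_expression(matrix: ExpressionMatrix, matrix_path, sample_sheet_path,
                     biotype_path=None, float_format: str = "%.6f") -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="probe",
                         float_format=float_format)
    sheet = pd.DataFrame(
        {
            "sample": matrix.values.columns,
            "group": matrix.sample_group.loc[matrix.values.columns].to_numpy(),
            "pair": matrix.pair_id.loc[matrix.values.columns].to_numpy(),
        }
    )
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)
    if biotype_path is not None:
        ann = pd.DataFrame(
            {
                "probe": matrix.values.index,
                "biotype": matrix.biotype.loc[matrix.values.index].to_numpy(),
                "gene_symbol": matrix.gene_symbol.loc[matrix.values.index].to_numpy(),
            }
        )
        ann.to_csv(biotype_path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file (term, description, tab-separated genes)."""
    sets: dict = {}
    names: dict = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    for i, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {i} has fewer than 3 fields")
        term, desc, genes = fields[0], fields[1], fields[2:]
        sets[term] = {g.upper() for g in genes if g}
        names[term] = desc or term
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{collection.names.get(term, term)}\t{genes}\n")


def read_edges(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b"):
        if col not in edges.columns:
            raise ValueError(f"edge table missing column {col!r}")
        edges[col] = edges[col].astype(str).str.upper()
    return edges


def write_edges(edges: pd.DataFrame, path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        edges.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for row in edges.itertuples(index=False):
                rel = "coexpr_pos" if getattr(row, "sign", "positive") == "positive" else "coexpr_neg"
                fh.write(f"{row.gene_a}\t{rel}\t{row.gene_b}\n")
    else:
        raise ValueError(f"unknown edge format {fmt!r}")


def read_external_de(path) -> pd.DataFrame:
    ext = pd.read_csv(path, sep="\t")
    for col in ("gene", "direction"):
        if col not in ext.columns:
            raise ValueError(f"external DE list missing column {col!r}")
    ext["gene"] = ext["gene"].astype(str).str.upper()
    return ext


def read_mirna_pairs(path) -> pd.DataFrame:
    pairs = pd.read_csv(path, sep="\t")
    for col in ("mirna", "target"):
        if col not in pairs.columns:
            raise ValueError(f"miRNA-target table missing column {col!r}")
    pairs["target"] = pairs["target"].astype(str).str.upper()
    return pairs


def read_mirna_directions(path) -> dict:
    table = pd.read_csv(path, sep="\t")
    for col in ("mirna", "direction"):
        if col not in table.columns:
            raise ValueError(f"miRNA direction table missing column {col!r}")
    return dict(zip(table["mirna"], table["direction"]))


def read_cq(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("patient", "tissue", "gene", "cq", "reference_cq"):
        if col not in table.columns:
            raise ValueError(f"Cq table missing column {col!r}")
    return table


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """File paths, thresholds and toggles for a full pipeline run.

    Threshold defaults are the standard workflow values: fold change
    > 1.5 and p < 0.05 for differential calls, adjusted p < 0.05 for
    coexpression edges and enrichment, hubs with more than 3 coexpressed
    protein-coding neighbors, and >= 50-dataset consensus support.
    """

    matrix: str = ""
    samples: str = ""
    biotypes: str = ""
    gmt: str = ""
    external_de: str = ""
    ppi: str = ""
    mirna_targets: str = ""
    mirna_directions: str = ""
    outdir: str = "results"
    fc_threshold: float = 1.5
    alpha_de: float = 0.05
    alpha_edge: float = 0.05
    alpha_enrich: float = 0.05
    min_neighbors: int = 3
    min_support: int = 50
    min_present: int = 3
    paired: bool = False
    scope: str = "de"  # gene universe for coexpression: "de" or "all"
    stages: dict = field(default_factory=lambda: {
        "normalize": True,
        "diffexpr": True,
        "intersect": False,
        "coexpress": True,
        "annotate": True,
        "integrate": False,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_edge", "alpha_enrich"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if self.scope not in {"de", "all"}:
            raise ValueError("scope must be 'de' or 'all'")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write every intermediate.

    Order: normalize -> differential expression -> external intersection
    -> coexpression -> lncRNA annotation -> network integration and
    summary. Returns (and writes) a run manifest with the config
    snapshot, input checksums and per-stage counts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "inputs": {},
        "counts": {},
    }
    for name in ("matrix", "samples", "biotypes", "gmt", "external_de",
                 "ppi", "mirna_targets", "mirna_directions"):
        p = getattr(config, name)
        if p and Path(p).exists():
            manifest["inputs"][name] = _checksum(p)

    stage = "read"
    try:
        matrix = read_expression(config.matrix, config.samples, config.biotypes)
        if config.stages.get("normalize", True):
            stage = "normalize"
            matrix = ExpressionMatrix(
                values=quantile_normalize(matrix.values),
                sample_group=matrix.sample_group,
                pair_id=matrix.pair_id,
                biotype=matrix.biotype,
                gene_symbol=matrix.gene_symbol,
            )
            write_expression(
                matrix, outdir / "normalized.tsv", outdir / "samples.tsv"
            )
        stage = "diffexpr"
        de_table = differential_test(
            matrix, paired=config.paired,
            fc_threshold=config.fc_threshold, alpha=config.alpha_de,
        )
        de_out = de_table[["gene", "biotype", "log2_fc", "fold_change",
                           "p_value", "direction"]].sort_values("gene", kind="mergesort")
        de_out.to_csv(outdir / "de.tsv", sep="\t", index=False)
        up, down = select_differential(de_table, config.fc_threshold, config.alpha_de)
        manifest["counts"]["de_up"] = len(up)
        manifest["counts"]["de_down"] = len(down)

        if config.stages.get("intersect", False) and config.external_de:
            stage = "intersect"
            external = read_external_de(config.external_de)
            up, down = intersect_external(up, down, external)
            manifest["counts"]["de_up_confirmed"] = len(up)
            manifest["counts"]["de_down_confirmed"] = len(down)

        network = None
        if config.stages.get("coexpress", True):
            stage = "coexpress"
            genes = sorted(up + down) if config.scope == "de" else None
            network = build_network(
                matrix.values, biotype=matrix.biotype,
                alpha=config.alpha_edge, genes=genes,
            )
            write_edges(network.edges, outdir / "edges.tsv")
            manifest["counts"]["coexpr_edges"] = len(network.edges)

        if config.stages.get("annotate", True) and config.gmt and network is not None:
            stage = "annotate"
            gene_sets = read_gmt(config.gmt)
            enrich = annotate_lncrnas(
                network, gene_sets,
                min_neighbors=config.min_neighbors, alpha=config.alpha_enrich,
            )
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            manifest["counts"]["enrichment_rows"] = len(enrich)
            manifest["counts"]["annotated_lncrnas"] = int(
                enrich.loc[enrich["assigned"], "lncrna"].nunique()
            ) if len(enrich) else 0

        if config.stages.get("integrate", False) and network is not None:
            stage = "integrate"
            ppi = read_edges(config.ppi) if config.ppi else pd.DataFrame(
                columns=["gene_a", "gene_b"])
            direction = dict(zip(de_table["gene"], de_table["direction"]))
            direction = {g: d for g, d in direction.items() if d in ("up", "down")}
            if config.mirna_targets and config.mirna_directions:
                pairs = read_mirna_pairs(config.mirna_targets)
                mdir = read_mirna_directions(config.mirna_directions)
                mirna_edges = filter_mirna_targets(pairs, mdir, direction)
            else:
                mirna_edges, mdir = pd.DataFrame(columns=["mirna", "target"]), {}
            node_rows = [
                {
                    "gene": g,
                    "biotype": matrix.biotype.get(g, "protein_coding"),
                    "direction": direction.get(g, "unknown"),
                    "log2_fc": float(de_table.set_index("gene")["log2_fc"].get(g, 0.0)),
                }
                for g in set(network.edges["gene_a"]) | set(network.edges["gene_b"])
                | set(ppi.get("gene_a", [])) | set(ppi.get("gene_b", []))
                | set(mirna_edges.get("target", []))
            ] + [
                {"gene": m, "biotype": "miRNA", "direction": mdir.get(m, "unknown"),
                 "log2_fc": 0.0}
                for m in set(mirna_edges.get("mirna", []))
            ]
            node_table = pd.DataFrame(
                node_rows, columns=["gene", "biotype", "direction", "log2_fc"]
            )
            net = integrate(network.edges, ppi, mirna_edges, node_table)
            export_network(net, str(outdir / "network.graphml"), fmt="graphml")
            summary = summarize(net).to_dict()
            (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
            manifest["counts"].update({f"network_{k}": v for k, v in summary.items()})
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
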