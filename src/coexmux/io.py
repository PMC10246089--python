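"""Readers and writers for the pipeline's file formats.

Expression comes in as GCT 1.2 or plain TSV (genes x samples) with a
sample-attribute table mapping samples to donors and tissues; gene
coordinates as BED6 (0-based half-open, converted to 1-based inclusive on
read); eQTL associations as TSV.  Everything the pipeline writes -- matrix
TSVs, long-format coupling tables, partitions, significance and
localization reports -- parses back to an equal object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneLocus
from .community import Partition
from .layers import ExpressionLayer, InvalidDataError

__all__ = [
    "read_gct",
    "read_expression_tsv",
    "read_sample_attributes",
    "read_expression",
    "write_expression_tsv",
    "write_gct",
    "read_bed6",
    "write_bed6",
    "read_eqtl",
    "write_eqtl",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_omega_tsv",
    "read_omega_tsv",
    "write_partition_tsv",
    "read_partition_tsv",
    "write_significance_tsv",
    "write_localization_tsv",
    "write_json",
    "read_json",
]


def read_sample_attributes(path) -> pd.DataFrame:
    """Sample-attribute TSV with columns sample_id, donor_id, tissue."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "donor_id", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidDataError(
            f"sample attribute table missing columns: {sorted(missing)}"
        )
    return df


def _expression_layer(df: pd.DataFrame, attrs: pd.DataFrame, layer_name: str
                      ) -> ExpressionLayer:
    gene_ids = df.index.tolist()
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise InvalidDataError(f"duplicate gene ids: {', '.join(map(str, dupes))}")
    donor_of = dict(zip(attrs["sample_id"], attrs["donor_id"]))
    unmapped = [s for s in df.columns if s not in donor_of]
    if unmapped:
        raise InvalidDataError(
            f"samples missing from the attribute table: {unmapped[:5]}"
        )
    return ExpressionLayer(
        layer_name=layer_name,
        gene_ids=gene_ids,
        sample_ids=df.columns.tolist(),
        donor_ids=[donor_of[s] for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def read_gct(path, attrs: pd.DataFrame, layer_name: str) -> ExpressionLayer:
    """GCT 1.2: '#1.2' header, dims line, then Name/Description + samples."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise InvalidDataError(f"{path}: expected GCT 1.2 header, got {version!r}")
        dims = fh.readline().split()
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != n_genes or df.shape[1] - 2 != n_samples:
        raise InvalidDataError(
            f"{path}: GCT header declares {n_genes}x{n_samples}, body is "
            f"{df.shape[0]}x{df.shape[1] - 2}"
        )
    df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
    return _expression_layer(df, attrs, layer_name)


def write_gct(path, layer: ExpressionLayer):
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{layer.n_genes}\t{layer.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(layer.sample_ids) + "\n")
        for g, row in zip(layer.gene_ids, layer.values):
            fh.write(g + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_expression_tsv(path, attrs: pd.DataFrame, layer_name: str) -> ExpressionLayer:
    """Plain TSV: gene rows x sample columns, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return _expression_layer(df, attrs, layer_name)


def write_expression_tsv(path, layer: ExpressionLayer):
    df = pd.DataFrame(layer.values, index=layer.gene_ids, columns=layer.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=None)


def read_expression(path, attrs, layer_name, format=None) -> ExpressionLayer:
    """Dispatch on format ('gct' | 'tsv'); inferred from the suffix if None."""
    fmt = format or ("gct" if str(path).endswith(".gct") else "tsv")
    if fmt == "gct":
        return read_gct(path, attrs, layer_name)
    if fmt == "tsv":
        return read_expression_tsv(path, attrs, layer_name)
    raise ValueError(f"unknown expression format: {fmt}")


def _normalize_chrom(label: str) -> str:
    label = str(label)
    if label.lower().startswith("chr"):
        label = label[3:]
    return "M" if label.upper() == "MT" else label


def read_bed6(path) -> list:
    """BED6 gene coordinates -> GeneLocus records (1-based inclusive)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InvalidDataError(f"BED line with <4 fields: {line!r}")
            chrom, start, end, name = fields[:4]
            out.append(
                GeneLocus(
                    gene_id=name,
                    chromosome=_normalize_chrom(chrom),
                    start=int(start) + 1,  # BED is 0-based half-open
                    end=int(end),
                )
            )
    return out


def write_bed6(path, loci):
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chromosome}\t{locus.start - 1}\t{locus.end}\t"
                f"{locus.gene_id}\t0\t+\n"
            )


def read_eqtl(path) -> pd.DataFrame:
    """eQTL TSV with columns gene_id, variant_id[, pval_nominal]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "variant_id": str})
    missing = {"gene_id", "variant_id"} - set(df.columns)
    if missing:
        raise InvalidDataError(f"eQTL table missing columns: {sorted(missing)}")
    return df


def write_eqtl(path, table):
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(path, matrix: np.ndarray, ids):
    df = pd.DataFrame(matrix, index=ids, columns=ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.tolist()


def write_omega_tsv(path, omega: np.ndarray, gene_ids, layer_names):
    """Interlayer couplings in long format: gene, layer_a, layer_b, weight."""
    rows = []
    n_layers = len(layer_names)
    for a in range(n_layers):
        for b in range(a + 1, n_layers):
            for i, g in enumerate(gene_ids):
                rows.append((g, layer_names[a], layer_names[b], omega[i, a, b]))
    pd.DataFrame(
        rows, columns=["gene_id", "layer_a", "layer_b", "weight"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_omega_tsv(path, gene_ids, layer_names) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    gi = {g: i for i, g in enumerate(gene_ids)}
    li = {l: a for a, l in enumerate(layer_names)}
    omega = np.zeros((len(gene_ids), len(layer_names), len(layer_names)))
    for row in df.itertuples(index=False):
        i, a, b = gi[row.gene_id], li[row.layer_a], li[row.layer_b]
        omega[i, a, b] = omega[i, b, a] = row.weight
    return omega


def write_partition_tsv(path, partition: Partition):
    rows = [(g, layer, int(lab)) for (g, layer), lab in
            zip(partition.nodes, partition.labels)]
    pd.DataFrame(rows, columns=["gene_id", "layer", "community"]).to_csv(
        path, sep="\t", index=False
    )


def read_partition_tsv(path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "layer": str})
    nodes = [(g, layer) for g, layer in zip(df["gene_id"], df["layer"])]
    return Partition(nodes=nodes, labels=df["community"].to_numpy(dtype=int))


def write_significance_tsv(path, records):
    rows = [
        (r.label, r.n_nodes, r.n_pairs, r.W, r.mu, r.var,
         "" if r.z is None else r.z)
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["community", "n_nodes", "n_pairs", "W", "mu", "var", "z"]
    ).to_csv(path, sep="\t", index=False)


def write_localization_tsv(path, results):
    """Localization report: one row per group plus per-chromosome rows."""
    rows = []
    for res in results:
        rows.append(
            {
                "group": res.group_id, "chromosome": "all", "n_genes": res.n,
                "x_c": res.x_c, "z_x": res.z_x, "d_c": res.d_c, "z_d": res.z_d,
                "d_tilde": "", "z": "", "p_normal": "", "p_empirical": "",
                "bonferroni_significant": "",
            }
        )
        for chrom in res.per_chromosome:
            rows.append(
                {
                    "group": res.group_id, "chromosome": chrom.chromosome,
                    "n_genes": chrom.n_genes, "x_c": "", "z_x": "", "d_c": "",
                    "z_d": "", "d_tilde": chrom.d_tilde, "z": chrom.z,
                    "p_normal": chrom.p_normal,
                    "p_empirical": chrom.p_empirical,
                    "bonferroni_significant": chrom.bonferroni_significant,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
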