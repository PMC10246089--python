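"""End-to-end pipeline: expression layers in, annotated communities out.

Stages mirror the analysis workflow: gene selection by TPM variance,
correlation layers and interlayer couplings, configuration-model nulls,
resolution sweep + CHAMP, consensus detection at the selected resolutions,
community significance, specialist/generalist annotation, genomic
localization, and shared-eQTL discovery.  Every stochastic stage draws its
seed from the run configuration and the manifest records them all.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .annotate import (
    community_gene_set,
    community_summary,
    localization_tests,
    shared_eqtl_pairs,
)
from .champ import champ_1d, default_gamma_grid, gamma_sweep, partition_line, select_gamma
from .community import build_supra_modularity, detect_communities, modularity
from .confignull import fit_configuration_model
from .layers import (
    build_multilayer,
    drop_zero_variance_genes,
    select_top_variance_genes,
)
from .significance import significance_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full run.

    Defaults follow the reference analysis: top 75 genes per tissue by TPM
    variance, 15-point resolution grid on [1, 4], 200 consensus runs, 100
    localization randomizations, specialist threshold 0.5, co-expression
    threshold 0.5 for eQTL pairs, generalist gene filter at 3 layers and 3
    genes minimum per chromosome.
    """

    expression: dict = field(default_factory=dict)  # tissue -> path
    sample_attributes: str | None = None
    bed: str | None = None
    eqtl: str | None = None
    eqtl_layer: str | None = None  # layer whose correlations gate eQTL pairs
    output_dir: str = "coexmux_run"
    top_k: int = 75
    gamma_min: float = 1.0
    gamma_max: float = 4.0
    gamma_points: int = 15
    consensus_runs: int = 200
    localization_replicates: int = 100
    specialist_threshold: float = 0.5
    coexpression_threshold: float = 0.5
    min_layers: int = 3
    min_genes_per_chrom: int = 3
    null_tol: float = 1e-6
    seed: int = 0
    pinned_gammas: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.top_k <= 0 or self.consensus_runs <= 0 \
                or self.localization_replicates <= 0 or self.gamma_points <= 0:
            raise ValueError("counts must be positive")
        if not self.gamma_max > self.gamma_min:
            raise ValueError("gamma grid bounds must be ordered")


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _stage_seeds(seed: int) -> dict:
    """Named per-stage seeds derived deterministically from the run seed."""
    rng = np.random.default_rng(seed)
    names = ["sweep", "detect", "localize"]
    return {name: int(rng.integers(2**31 - 1)) for name in names}


def _file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, layers=None, loci=None, eqtl=None) -> dict:
    """Execute the full workflow and write all artifacts to the output dir.

    ``layers``, ``loci`` and ``eqtl`` may be passed in-memory (e.g. from the
    synthetic generator); otherwise they are read from the configured paths.
    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {"seeds": {"run": config.seed, **seeds}, "stages": {},
                "config": {k: v for k, v in asdict(config).items()
                           if k != "expression"} | {
                               "expression": dict(config.expression)}}

    # --- load -------------------------------------------------------------
    if layers is None:
        if not config.expression or not config.sample_attributes:
            raise ValueError(
                "config must name expression files and a sample-attribute table"
            )
        attrs = cio.read_sample_attributes(config.sample_attributes)
        layers = [
            cio.read_expression(path, attrs, tissue)
            for tissue, path in sorted(config.expression.items())
        ]
        manifest["stages"]["inputs"] = {
            tissue: _file_hash(path)
            for tissue, path in sorted(config.expression.items())
        }
    if loci is None and config.bed:
        loci = cio.read_bed6(config.bed)
    if eqtl is None and config.eqtl:
        eqtl = cio.read_eqtl(config.eqtl)

    # --- gene selection ---------------------------------------------------
    union, per_layer = select_top_variance_genes(layers, config.top_k)
    layers = [drop_zero_variance_genes(l.subset_genes(union)) for l in layers]
    common = sorted(set.intersection(*(set(l.gene_ids) for l in layers)))
    layers = [l.subset_genes(common) for l in layers]
    manifest["stages"]["gene_selection"] = {
        "top_k": config.top_k, "union_size": len(union),
        "analyzed_genes": len(common),
    }

    # --- correlation layers and couplings ----------------------------------
    mlc = build_multilayer(layers)
    for a, name in enumerate(mlc.layer_names):
        cio.write_matrix_tsv(out / f"rho_{name}.tsv", mlc.rho[a], mlc.gene_ids)
    cio.write_omega_tsv(out / "omega.tsv", mlc.omega, mlc.gene_ids, mlc.layer_names)

    # --- configuration-model nulls -----------------------------------------
    nulls = []
    for a, name in enumerate(mlc.layer_names):
        null = fit_configuration_model(
            mlc.rho[a], tol=config.null_tol, layer_name=name
        )
        nulls.append(null)
        cio.write_matrix_tsv(out / f"null_{name}.tsv", null.null_rho, mlc.gene_ids)
    cio.write_json(
        out / "null_fit.json",
        {n.layer_name: {"residual": n.residual, "iterations": n.iterations,
                        "log_det": n.log_det} for n in nulls},
    )

    # --- resolution sweep + CHAMP -------------------------------------------
    grid = default_gamma_grid(config.gamma_min, config.gamma_max, config.gamma_points)
    sweep = gamma_sweep(mlc, nulls, grid, seed=seeds["sweep"])
    lines = []
    for idx, (gamma, part) in enumerate(sweep):
        line = partition_line(part, mlc, nulls)
        line.partition_id = idx
        lines.append(line)
        cio.write_partition_tsv(out / f"sweep_gamma_{gamma:.3f}.tsv", part)
    domains = champ_1d(lines, config.gamma_min, config.gamma_max)
    cio.write_json(
        out / "champ_domains.json",
        [{"gamma_low": lo, "gamma_high": hi, "partition_id": pid}
         for lo, hi, pid in domains.intervals],
    )
    pd.DataFrame(
        [(g, max(float(line.value(g)) for line in lines)) for g in grid],
        columns=["gamma", "Q"],
    ).to_csv(out / "champ_envelope.tsv", sep="\t", index=False)
    selected = select_gamma(domains, pinned=config.pinned_gammas or None)
    manifest["stages"]["champ"] = {
        "intervals": domains.intervals, "selected": selected,
    }

    # --- consensus detection at the selected resolutions ---------------------
    results = {}
    for gamma, pid in selected:
        supra = build_supra_modularity(mlc, nulls, gamma)
        part = detect_communities(
            supra, n_runs=config.consensus_runs, seed=seeds["detect"]
        )
        tag = f"gamma_{gamma:.3f}"
        cio.write_partition_tsv(out / f"consensus_{tag}.tsv", part)
        records = significance_table(part, mlc, nulls)
        cio.write_significance_tsv(out / f"significance_{tag}.tsv", records)
        summaries = [
            community_summary(lab, nodes, config.specialist_threshold)
            for lab, nodes in sorted(part.communities().items())
        ]
        cio.write_json(
            out / f"communities_{tag}.json",
            [asdict(s) for s in summaries],
        )
        results[tag] = {
            "gamma": gamma, "partition": part, "records": records,
            "summaries": summaries, "Q": modularity(part, supra),
        }
        manifest["stages"][f"detect_{tag}"] = {
            "n_communities": part.n_communities, "Q": results[tag]["Q"],
        }

        # --- localization ---------------------------------------------------
        if loci:
            locs = []
            for s in summaries:
                genes = community_gene_set(
                    part.communities()[s.label], s.klass, config.min_layers
                )
                if len(genes) < 2:
                    continue
                locs.append(
                    localization_tests(
                        genes, loci,
                        n_rand=config.localization_replicates,
                        seed=seeds["localize"],
                        min_genes_per_chrom=config.min_genes_per_chrom,
                        group_id=f"{tag}_comm{s.label}",
                    )
                )
            cio.write_localization_tsv(out / f"localization_{tag}.tsv", locs)
            results[tag]["localization"] = locs

    # --- shared eQTL pairs ---------------------------------------------------
    if eqtl is not None:
        layer = config.eqtl_layer or mlc.layer_names[0]
        a = mlc.layer_names.index(layer)
        known = set(mlc.gene_ids)
        eqtl_known = {
            "gene_id": [g for g in eqtl["gene_id"] if g in known],
            "variant_id": [v for g, v in zip(eqtl["gene_id"], eqtl["variant_id"])
                           if g in known],
        }
        pairs = shared_eqtl_pairs(
            mlc.rho[a], mlc.gene_ids, eqtl_known,
            r_min=config.coexpression_threshold,
        )
        cio.write_json(
            out / "shared_eqtl_pairs.json",
            [{"gene_i": gi, "gene_j": gj, "r": r, "variants": v}
             for gi, gj, r, v in pairs],
        )
        manifest["stages"]["eqtl"] = {"layer": layer, "n_pairs": len(pairs)}

    cio.write_json(out / "manifest.json", manifest)
    manifest["results"] = results
    return manifest
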