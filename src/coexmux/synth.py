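"""Synthetic multilayer co-expression data with planted ground truth.

Log-expression is generated from a Gaussian factor model whose implied
correlation structure has planted equicorrelation blocks.  A weak global
per-donor factor, shared across layers, gives all globally expressed genes
the background correlation rho_out (within and across tissues -- donor-level
covariation is common to tissues).  *Generalist* blocks add a per-donor
block factor reused across all layers, so the same genes are co-expressed
in every tissue and their interlayer couplings are high.  The *specialist*
block is driven, in its home tissue only, by a private factor independent
of the global one -- mirroring tissue-restricted programs (digestive
enzymes, say) whose variation is unrelated to layer-wide covariation -- so
specialist genes correlate at rho_in among themselves, at ~0 with everything
else, and behave like background genes outside their home tissue.  Donors
partially overlap across layers and factors are drawn per donor, so the
overlap carries the interlayer signal.  TPM values are
exp(log-expression) - 1, clipped at zero.

Gene loci and a toy eQTL table with planted structure round out the inputs
needed to exercise every pipeline stage without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import GeneLocus
from .community import Partition
from .layers import ExpressionLayer

__all__ = [
    "SyntheticParams",
    "SyntheticDataset",
    "planted_multilayer_expression",
    "planted_gene_loci",
    "toy_eqtl_table",
]

DEFAULT_LAYERS = ("pancreas", "salivary_gland", "mammary_gland", "skin")


@dataclass
class SyntheticParams:
    """Generation parameters for the planted multilayer scenario.

    Defaults are the package's reference study conditions: 4 tissue layers
    of 60 genes, three 12-gene generalist blocks spanning all layers, one
    10-gene specialist block in the first layer, within-block correlation
    0.7 over a 0.05 background, 500 samples per layer with half the donors
    shared across all layers, and log-expression mean 5, scale 1 (so TPM is
    essentially always positive and log(TPM+1) recovers the planted
    correlations).
    """

    layer_names: tuple = DEFAULT_LAYERS
    n_genes: int = 60
    generalist_blocks: tuple = (12, 12, 12)
    specialist_block: int = 10
    specialist_layer: int = 0
    rho_in: float = 0.7
    rho_out: float = 0.05
    samples_per_layer: int = 500
    donor_overlap: float = 0.5
    mu_g: float = 5.0
    sigma_g: float = 1.0

    def __post_init__(self):
        if not self.rho_in > self.rho_out >= 0:
            raise ValueError("need rho_in > rho_out >= 0")
        if self.rho_in >= 1:
            raise ValueError("rho_in must be < 1")
        total = sum(self.generalist_blocks) + self.specialist_block
        if total > self.n_genes:
            raise ValueError("planted blocks exceed the gene count")
        if not 0 <= self.donor_overlap <= 1:
            raise ValueError("donor_overlap must lie in [0, 1]")

    @property
    def block_slices(self):
        """Gene index ranges: generalist blocks first, then the specialist block."""
        out, start = [], 0
        for size in self.generalist_blocks:
            out.append(("generalist", slice(start, start + size)))
            start += size
        out.append(("specialist", slice(start, start + self.specialist_block)))
        return out

    @property
    def n_background(self):
        return self.n_genes - sum(self.generalist_blocks) - self.specialist_block


@dataclass
class SyntheticDataset:
    layers: list
    truth_partition: Partition
    loci: list
    eqtl: dict  # column name -> list, ready for DataFrame construction
    params: SyntheticParams
    seed: int
    target_rho: np.ndarray = field(repr=False, default=None)
    clustered_genes: list = field(default_factory=list)


def _target_correlation(params: SyntheticParams, layer_idx: int) -> np.ndarray:
    n = params.n_genes
    rho = np.full((n, n), params.rho_out)
    for kind, sl in params.block_slices:
        if kind == "generalist":
            rho[sl, sl] = params.rho_in
        elif layer_idx == params.specialist_layer:
            # home tissue: tight block, orthogonal to the global factor
            rho[sl, :] = 0.0
            rho[:, sl] = 0.0
            rho[sl, sl] = params.rho_in
        # outside its home tissue the specialist block is background-like
    np.fill_diagonal(rho, 1.0)
    return rho


def _truth_partition(params: SyntheticParams) -> Partition:
    """Planted node labels implied by the factor model.

    Generalist blocks span all layers (their block factor is shared across
    layers).  The specialist block owns only its home-layer nodes.  Every
    remaining node -- background genes in all layers and specialist genes
    outside their home layer -- loads on the donor-shared global factor, so
    all of those nodes are weakly co-expressed with each other within and
    across layers: they form a single diffuse background community.
    """
    n, layer_names = params.n_genes, list(params.layer_names)
    gene_label = np.zeros(n, dtype=int)
    next_label = 1
    spec_slice = None
    for kind, sl in params.block_slices:
        gene_label[sl] = next_label
        if kind == "specialist":
            spec_slice = sl
        next_label += 1
    background_label = next_label
    nodes = [(f"g{i:03d}", layer) for layer in layer_names for i in range(n)]
    labels = np.empty(len(nodes), dtype=int)
    for a, layer in enumerate(layer_names):
        for i in range(n):
            lab = gene_label[i] if gene_label[i] else background_label
            if spec_slice is not None and spec_slice.start <= i < spec_slice.stop \
                    and a != params.specialist_layer:
                lab = background_label
            labels[a * n + i] = lab
    return Partition(nodes=nodes, labels=labels).canonicalize()


def planted_multilayer_expression(
    params: SyntheticParams | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate expression layers with planted block-correlation communities.

    Per layer the implied log-expression correlation matrix equals the
    planted target (verified positive definite before sampling); shared
    donors reuse the same generalist-block factors across layers, so
    interlayer couplings are high for generalist genes and near zero
    otherwise.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    n, layer_names = params.n_genes, list(params.layer_names)
    n_layers = len(layer_names)
    s = params.samples_per_layer
    for a in range(n_layers):
        w = np.linalg.eigvalsh(_target_correlation(params, a))
        if w[0] <= 0:
            raise ValueError(
                f"planted correlation target for layer {layer_names[a]} is not "
                f"positive definite (min eigenvalue {w[0]:.3e})"
            )

    n_shared = int(round(params.donor_overlap * s))
    shared_donors = [f"D{d:04d}" for d in range(n_shared)]
    gene_ids = [f"g{i:03d}" for i in range(n)]
    gene_mu = np.full(n, params.mu_g)

    # Factors for shared donors, reused across layers: the weak global
    # factor and the generalist block factors.
    n_blocks = len(params.block_slices)
    shared_global = rng.standard_normal(n_shared)
    shared_block = rng.standard_normal((n_blocks, n_shared))

    w_bg = np.sqrt(params.rho_out)
    w_block = np.sqrt(params.rho_in - params.rho_out)
    layers = []
    for a, layer in enumerate(layer_names):
        n_private = s - n_shared
        private_donors = [f"D_{layer}_{d:04d}" for d in range(n_private)]
        donors = shared_donors + private_donors
        sample_ids = [f"{layer}-S{c:04d}" for c in range(s)]
        g_fac = np.concatenate([shared_global, rng.standard_normal(n_private)])
        z = np.empty((n, s))
        noise_scale = np.empty(n)
        block_of = np.full(n, -1)
        for b, (kind, sl) in enumerate(params.block_slices):
            block_of[np.arange(sl.start, sl.stop)] = b
        for b, (kind, sl) in enumerate(params.block_slices):
            if kind == "generalist":
                f = np.concatenate(
                    [shared_block[b], rng.standard_normal(n_private)]
                )
            elif a == params.specialist_layer:
                # home tissue: private factor, independent of the global one
                f = rng.standard_normal(s)
            else:
                f = None  # specialist genes are background-like elsewhere
            for i in range(sl.start, sl.stop):
                eps = rng.standard_normal(s)
                if f is None:
                    z[i] = w_bg * g_fac + np.sqrt(1 - params.rho_out) * eps
                elif kind == "specialist":
                    z[i] = (
                        np.sqrt(params.rho_in) * f
                        + np.sqrt(1 - params.rho_in) * eps
                    )
                else:
                    z[i] = (
                        w_bg * g_fac + w_block * f
                        + np.sqrt(1 - params.rho_in) * eps
                    )
        for i in range(n):
            if block_of[i] == -1:
                eps = rng.standard_normal(s)
                z[i] = w_bg * g_fac + np.sqrt(1 - params.rho_out) * eps
        logx = gene_mu[:, None] + params.sigma_g * z
        tpm = np.clip(np.expm1(logx), 0.0, None)
        layers.append(
            ExpressionLayer(
                layer_name=layer,
                gene_ids=list(gene_ids),
                sample_ids=sample_ids,
                donor_ids=donors,
                values=tpm,
            )
        )
    target = np.stack([_target_correlation(params, a) for a in range(n_layers)])
    return SyntheticDataset(
        layers=layers,
        truth_partition=_truth_partition(params),
        loci=[],
        eqtl={"gene_id": [], "variant_id": []},
        params=params,
        seed=seed,
        target_rho=target,
    )


def planted_gene_loci(
    gene_ids,
    seed: int = 0,
    n_chromosomes: int = 5,
    chromosome_length: int = 100_000_000,
    clustered: dict | None = None,
    cluster_gap: int = 1_000,
    gene_length: int = 1_000,
):
    """Assign genes to synthetic chromosomes.

    ``clustered`` maps chromosome label -> list of gene ids to place as a
    tight consecutive run (gaps of ``cluster_gap`` bp); all other genes are
    placed uniformly at random across the chromosomes.  Returns the loci and
    the list of clustered gene ids (the planted truth).
    """
    rng = np.random.default_rng(seed)
    clustered = clustered or {}
    chrom_labels = [str(k + 1) for k in range(n_chromosomes)]
    for k in clustered:
        if str(k) not in chrom_labels:
            raise ValueError(f"unknown synthetic chromosome {k}")
    loci = []
    placed = set()
    for k, members in clustered.items():
        anchor = int(rng.integers(1, chromosome_length // 2))
        pos = anchor
        for g in members:
            loci.append(GeneLocus(g, str(k), pos, pos + gene_length - 1))
            placed.add(g)
            pos += gene_length + cluster_gap
    for g in gene_ids:
        if g in placed:
            continue
        chrom = chrom_labels[int(rng.integers(n_chromosomes))]
        start = int(rng.integers(1, chromosome_length - gene_length))
        loci.append(GeneLocus(g, chrom, start, start + gene_length - 1))
    order = {g: i for i, g in enumerate(gene_ids)}
    loci.sort(key=lambda x: order[x.gene_id])
    truth = sorted(placed, key=lambda g: order[g])
    return loci, truth


def toy_eqtl_table(
    gene_ids,
    seed: int = 0,
    variants_per_gene: int = 3,
    shared_pairs=(),
    n_shared_variants: int = 2,
):
    """Toy eQTL association table with planted shared variants.

    Every gene receives ``variants_per_gene`` private variants; each pair in
    ``shared_pairs`` additionally shares ``n_shared_variants`` variants.
    Returns a dict of columns (gene_id, variant_id, pval_nominal).
    """
    rng = np.random.default_rng(seed)
    rows_gene, rows_variant, rows_p = [], [], []
    counter = 0
    for g in gene_ids:
        for _ in range(variants_per_gene):
            rows_gene.append(g)
            rows_variant.append(f"snp_{counter:05d}")
            rows_p.append(float(10 ** rng.uniform(-12, -5)))
            counter += 1
    for a, b in shared_pairs:
        for _ in range(n_shared_variants):
            vid = f"snp_shared_{counter:05d}"
            counter += 1
            for g in (a, b):
                rows_gene.append(g)
                rows_variant.append(vid)
                rows_p.append(float(10 ** rng.uniform(-12, -5)))
    return {"gene_id": rows_gene, "variant_id": rows_variant,
            "pval_nominal": rows_p}
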