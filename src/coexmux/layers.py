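"""Co-expression correlation layers.

Each tissue contributes one layer: an N x N Pearson correlation matrix of
log(TPM + 1) gene expression across that tissue's samples.  Layers over a
shared, ordered gene list are stitched into a multiplex object whose
interlayer couplings are the per-gene cross-tissue correlations computed on
donors common to a pair of tissues (negative couplings clamped to zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionLayer",
    "MultilayerCorrelation",
    "InvalidDataError",
    "ZeroVarianceError",
    "log_transform",
    "layer_correlation",
    "drop_zero_variance_genes",
    "select_top_variance_genes",
    "expression_rank_stats",
    "interlayer_couplings",
    "assemble_multilayer",
]


class InvalidDataError(ValueError):
    """Raised when expression input violates a precondition (e.g. negative TPM)."""


class ZeroVarianceError(ValueError):
    """Raised when genes with zero variance of log(TPM+1) make Pearson r undefined."""

    def __init__(self, gene_ids):
        self.gene_ids = list(gene_ids)
        super().__init__(
            "zero variance of log(TPM+1) for genes: " + ", ".join(self.gene_ids)
        )


@dataclass
class ExpressionLayer:
    """TPM expression matrix for one tissue.

    Parameters
    ----------
    layer_name : str
        Tissue label.
    gene_ids : list of str
        Ordered gene identifiers (rows of ``values``).
    sample_ids : list of str
        Ordered sample identifiers (columns of ``values``).
    donor_ids : list of str
        Donor identifier for each sample, aligned with ``sample_ids``.
    values : ndarray, shape (N, S)
        Non-negative TPM values.
    """

    layer_name: str
    gene_ids: list
    sample_ids: list
    donor_ids: list
    values: np.ndarray
    log_means: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidDataError("values must be a 2-D genes x samples matrix")
        n, s = self.values.shape
        if len(self.gene_ids) != n:
            raise InvalidDataError(
                f"{len(self.gene_ids)} gene ids for {n} expression rows"
            )
        if len(self.sample_ids) != s:
            raise InvalidDataError(
                f"{len(self.sample_ids)} sample ids for {s} expression columns"
            )
        if len(self.donor_ids) != s:
            raise InvalidDataError("donor_ids must have one entry per sample")
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise InvalidDataError(f"duplicate gene ids: {', '.join(dupes)}")
        if np.any(self.values < 0):
            raise InvalidDataError("TPM values must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise InvalidDataError("TPM values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionLayer":
        """Return a new layer restricted to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from layer {self.layer_name}: {missing}")
        rows = [index[g] for g in gene_ids]
        return ExpressionLayer(
            layer_name=self.layer_name,
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            donor_ids=list(self.donor_ids),
            values=self.values[rows, :],
        )


def log_transform(expr: ExpressionLayer | np.ndarray) -> np.ndarray:
    """Natural log of (TPM + 1), entrywise; zero TPM maps to zero.

    The base is cosmetic for every downstream Pearson correlation; natural
    log is used throughout.
    """
    values = expr.values if isinstance(expr, ExpressionLayer) else np.asarray(expr, float)
    if np.any(values < 0):
        raise InvalidDataError("TPM values must be non-negative")
    return np.log1p(values)


def _pearson_rows(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows, with exact unit diagonal."""
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def layer_correlation(expr: ExpressionLayer) -> np.ndarray:
    """N x N Pearson correlation of log(TPM+1) across the layer's samples.

    Raises
    ------
    ZeroVarianceError
        If any gene has zero variance of log(TPM+1); correlation is undefined
        for such genes.  Use :func:`drop_zero_variance_genes` first in
        pipeline settings.
    """
    if expr.n_samples < 3:
        raise InvalidDataError(
            f"layer {expr.layer_name}: need at least 3 samples, got {expr.n_samples}"
        )
    logx = log_transform(expr)
    sd = logx.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise ZeroVarianceError(bad)
    expr.log_means = logx.mean(axis=1)
    return _pearson_rows(logx)


def drop_zero_variance_genes(expr: ExpressionLayer) -> ExpressionLayer:
    """Drop genes whose log(TPM+1) has zero variance, with a logged warning."""
    sd = np.log1p(expr.values).std(axis=1)
    bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
    if not bad:
        return expr
    logger.warning(
        "layer %s: dropping %d zero-variance gene(s): %s",
        expr.layer_name, len(bad), ", ".join(bad),
    )
    keep = [g for g in expr.gene_ids if g not in set(bad)]
    return expr.subset_genes(keep)


def select_top_variance_genes(layers, k, scale="tpm"):
    """Per-layer top-``k`` genes by expression variance, and their union.

    Variance is taken over raw TPM by default (``scale="tpm"``) or over
    log(TPM+1) (``scale="log"``).  Ties at rank ``k`` are broken by gene id
    (lexicographic) for reproducibility.

    Returns
    -------
    union : list of str
        Sorted union of the per-layer selections.
    per_layer : dict
        ``layer_name -> list`` of that layer's top-``k`` gene ids.
    """
    if scale not in ("tpm", "log"):
        raise ValueError("scale must be 'tpm' or 'log'")
    per_layer = {}
    for layer in layers:
        if k > layer.n_genes:
            raise ValueError(
                f"k={k} exceeds the {layer.n_genes} genes of layer {layer.layer_name}"
            )
        x = layer.values if scale == "tpm" else np.log1p(layer.values)
        var = x.var(axis=1)
        order = sorted(range(layer.n_genes), key=lambda i: (-var[i], layer.gene_ids[i]))
        per_layer[layer.layer_name] = [layer.gene_ids[i] for i in order[:k]]
    union = sorted(set().union(*per_layer.values())) if per_layer else []
    return union, per_layer


def expression_rank_stats(layer: ExpressionLayer, top_by_variance, k):
    """Overlap diagnostics between high-variance and high-mean genes.

    Returns the Jaccard index between the top-``k`` genes by mean TPM and the
    given gene set, and the average rank (by mean TPM, rank 1 = highest) of
    the given set over all of the layer's genes.
    """
    genes = set(top_by_variance)
    if not genes:
        raise ValueError("empty gene set")
    mean_tpm = layer.values.mean(axis=1)
    order = sorted(range(layer.n_genes), key=lambda i: (-mean_tpm[i], layer.gene_ids[i]))
    ranked = [layer.gene_ids[i] for i in order]
    top_mean = set(ranked[:k])
    jaccard = len(top_mean & genes) / len(top_mean | genes)
    rank_of = {g: r + 1 for r, g in enumerate(ranked)}
    missing = genes - rank_of.keys()
    if missing:
        raise KeyError(f"genes not in layer {layer.layer_name}: {sorted(missing)}")
    average_rank = float(np.mean([rank_of[g] for g in genes]))
    return jaccard, average_rank


def _one_sample_per_donor(layer: ExpressionLayer) -> dict:
    """Map donor -> column index, keeping the first sample by sample id."""
    chosen = {}
    for col in sorted(range(layer.n_samples), key=lambda c: layer.sample_ids[c]):
        donor = layer.donor_ids[col]
        if donor not in chosen:
            chosen[donor] = col
    return chosen


def interlayer_couplings(layers) -> np.ndarray:
    """Per-gene interlayer coupling tensor omega, shape (N, L, L).

    omega[i, a, b] is the Pearson correlation of gene i's log(TPM+1) between
    layers a and b across donors common to both tissues (one sample per donor
    per tissue; the first by sample id).  Negative couplings are clamped to 0
    and the layer diagonal is 0.

    Returns the tensor together with the matrix of common-donor counts.
    """
    if not layers:
        raise ValueError("no layers")
    gene_ids = layers[0].gene_ids
    for layer in layers[1:]:
        if layer.gene_ids != gene_ids:
            raise ValueError(
                f"gene lists differ between layers {layers[0].layer_name} "
                f"and {layer.layer_name}"
            )
    n, n_layers = len(gene_ids), len(layers)
    logx = [np.log1p(layer.values) for layer in layers]
    donor_cols = [_one_sample_per_donor(layer) for layer in layers]
    omega = np.zeros((n, n_layers, n_layers))
    pair_counts = np.zeros((n_layers, n_layers), dtype=int)
    n_clamped = 0
    for a in range(n_layers):
        for b in range(a + 1, n_layers):
            common = sorted(donor_cols[a].keys() & donor_cols[b].keys())
            if len(common) < 3:
                raise ValueError(
                    f"layers {layers[a].layer_name} and {layers[b].layer_name} "
                    f"share only {len(common)} donors (need >= 3)"
                )
            pair_counts[a, b] = pair_counts[b, a] = len(common)
            xa = logx[a][:, [donor_cols[a][d] for d in common]]
            xb = logx[b][:, [donor_cols[b][d] for d in common]]
            xa = xa - xa.mean(axis=1, keepdims=True)
            xb = xb - xb.mean(axis=1, keepdims=True)
            denom = np.sqrt((xa ** 2).sum(axis=1) * (xb ** 2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (xa * xb).sum(axis=1) / denom, 0.0)
            r = np.clip(r, -1.0, 1.0)
            n_clamped += int(np.sum(r < 0))
            r = np.maximum(r, 0.0)
            omega[:, a, b] = omega[:, b, a] = r
    if n_clamped:
        logger.warning("clamped %d negative interlayer couplings to 0", n_clamped)
    return omega, pair_counts


@dataclass
class MultilayerCorrelation:
    """Multiplex bundle of per-layer correlation matrices and couplings.

    ``rho`` stacks the L intralayer correlation matrices as an (L, N, N)
    array; ``omega`` holds the diagonal categorical interlayer couplings as
    an (N, L, L) tensor (zero on the layer diagonal, non-negative).
    """

    gene_ids: list
    layer_names: list
    rho: np.ndarray
    omega: np.ndarray
    sample_counts: np.ndarray
    pair_sample_counts: np.ndarray | None = None

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.sample_counts = np.asarray(self.sample_counts, dtype=int)
        n, L = len(self.gene_ids), len(self.layer_names)
        if self.rho.shape != (L, n, n):
            raise ValueError(f"rho shape {self.rho.shape} != {(L, n, n)}")
        if self.omega.shape != (n, L, L):
            raise ValueError(f"omega shape {self.omega.shape} != {(n, L, L)}")
        if self.sample_counts.shape != (L,):
            raise ValueError("sample_counts must have one entry per layer")
        for a in range(L):
            r = self.rho[a]
            if not np.allclose(r, r.T, atol=1e-10):
                raise ValueError(f"layer {self.layer_names[a]}: rho not symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-10):
                raise ValueError(f"layer {self.layer_names[a]}: rho diagonal != 1")
            if np.any(r < -1 - 1e-10) or np.any(r > 1 + 1e-10):
                raise ValueError(f"layer {self.layer_names[a]}: rho outside [-1, 1]")
        if np.any(self.omega < 0) or np.any(self.omega > 1 + 1e-10):
            raise ValueError("omega entries must lie in [0, 1]")
        if not np.allclose(self.omega, np.transpose(self.omega, (0, 2, 1)), atol=1e-10):
            raise ValueError("omega must be symmetric in its layer indices")
        diag = self.omega[:, range(L), range(L)]
        if np.any(diag != 0):
            raise ValueError("omega must be zero on the layer diagonal")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)


def assemble_multilayer(
    corrs, omega, gene_ids, layer_names, sample_counts, pair_sample_counts=None
) -> MultilayerCorrelation:
    """Validate and bundle per-layer correlations and couplings.

    ``corrs`` may be a list of N x N matrices (one per layer) or an already
    stacked (L, N, N) array.  All invariants of
    :class:`MultilayerCorrelation` are enforced.
    """
    rho = np.stack([np.asarray(c, float) for c in corrs]) if not isinstance(
        corrs, np.ndarray
    ) or np.asarray(corrs).ndim != 3 else np.asarray(corrs, float)
    return MultilayerCorrelation(
        gene_ids=list(gene_ids),
        layer_names=list(layer_names),
        rho=rho,
        omega=omega,
        sample_counts=np.asarray(sample_counts, int),
        pair_sample_counts=pair_sample_counts,
    )


def build_multilayer(layers) -> MultilayerCorrelation:
    """Full assembly from expression layers: correlations plus couplings."""
    corrs = [layer_correlation(layer) for layer in layers]
    omega, pair_counts = interlayer_couplings(layers)
    return assemble_multilayer(
        corrs,
        omega,
        gene_ids=layers[0].gene_ids,
        layer_names=[layer.layer_name for layer in layers],
        sample_counts=[layer.n_samples for layer in layers],
        pair_sample_counts=pair_counts,
    )
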