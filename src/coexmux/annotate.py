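"""Community annotation: specialist/generalist classification, genomic
localization permutation tests, and shared-eQTL pair discovery.

A community over (gene, layer) nodes is a *specialist* community when more
than half of its nodes are genes unique to a single tissue; the specialist
fraction is the largest per-tissue count of unique genes divided by the
community's node count.  Localization asks whether a gene group sits on
fewer chromosomes, and closer together on them, than groups drawn at random
from a fixed background gene set; all three statistics are calibrated by
label-shuffling / resampling randomizations.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CommunitySummary",
    "GeneLocus",
    "LocalizationResult",
    "ChromosomeLocalization",
    "specialist_fraction",
    "classify_community",
    "community_gene_set",
    "community_summary",
    "gene_distance",
    "same_chromosome_fraction",
    "mean_pair_distance",
    "localization_tests",
    "shared_eqtl_pairs",
]


@dataclass(frozen=True)
class GeneLocus:
    """1-based inclusive genomic interval of a gene."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end must be >= start")


@dataclass
class CommunitySummary:
    label: int
    n_nodes: int
    distinct_genes: int
    unique_counts: dict  # layer -> count of genes unique to that layer
    specialist_tissue: str | None
    specialist_tissues: list  # all tied layers (lexicographic first is summary)
    specialist_fraction: float
    klass: str  # "generalist" | "specialist"


def _unique_gene_counts(community) -> dict:
    """Per-layer counts of genes present in exactly one layer of the community."""
    layers_of = defaultdict(set)
    for gene, layer in community:
        layers_of[gene].add(layer)
    counts = Counter()
    for gene, layers in layers_of.items():
        if len(layers) == 1:
            counts[next(iter(layers))] += 1
    return dict(counts)


def specialist_fraction(community):
    """Specialist fraction and specialist tissue of a community.

    The specialist tissue is the layer with the largest number of genes
    unique to it within the community; the fraction is that count divided by
    the total node count.  Returns ``(0.0, None)`` when no gene is unique to
    a single layer.  Layer ties are broken lexicographically here; use
    :func:`community_summary` to see all tied layers.
    """
    community = set(community)
    if not community:
        raise ValueError("community must be non-empty")
    counts = _unique_gene_counts(community)
    n_nodes = len(community)
    if not counts:
        return 0.0, None
    best = max(counts.values())
    tied = sorted(layer for layer, c in counts.items() if c == best)
    return best / n_nodes, tied[0]


def classify_community(fraction: float, threshold: float = 0.5) -> str:
    """"specialist" iff the fraction strictly exceeds the threshold."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("specialist fraction must lie in [0, 1]")
    return "specialist" if fraction > threshold else "generalist"


def community_summary(label, community, threshold: float = 0.5) -> CommunitySummary:
    community = set(community)
    counts = _unique_gene_counts(community)
    frac, tissue = specialist_fraction(community)
    if counts:
        best = max(counts.values())
        tied = sorted(layer for layer, c in counts.items() if c == best)
    else:
        tied = []
    return CommunitySummary(
        label=int(label),
        n_nodes=len(community),
        distinct_genes=len({g for g, _ in community}),
        unique_counts=counts,
        specialist_tissue=tissue,
        specialist_tissues=tied,
        specialist_fraction=frac,
        klass=classify_community(frac, threshold),
    )


def community_gene_set(community, klass: str, min_layers: int = 3):
    """Gene list a community contributes to downstream genomic analyses.

    Specialist communities contribute all their distinct genes; generalist
    communities only the genes present in at least ``min_layers`` layers
    within the community (so that the genes plausibly act across tissues).
    """
    layers_of = defaultdict(set)
    for gene, layer in community:
        layers_of[gene].add(layer)
    if klass == "specialist":
        return sorted(layers_of)
    if klass != "generalist":
        raise ValueError("klass must be 'generalist' or 'specialist'")
    return sorted(g for g, layers in layers_of.items() if len(layers) >= min_layers)


def gene_distance(a: GeneLocus, b: GeneLocus):
    """Base-pair gap between two genes; None across chromosomes, 0 if they overlap."""
    if a.chromosome != b.chromosome:
        return None
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(second.start - first.end, 0)


def same_chromosome_fraction(genes, loci: dict) -> float:
    """Fraction of gene pairs on the same chromosome, x_c."""
    genes = list(genes)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least two genes")
    chroms = [loci[g].chromosome for g in genes]
    counts = Counter(chroms)
    same = sum(c * (c - 1) // 2 for c in counts.values())
    return same / (n * (n - 1) / 2)


def mean_pair_distance(genes, loci: dict):
    """Average pairwise gap d_c over same-chromosome pairs; None if no such pair."""
    by_chrom = defaultdict(list)
    for g in genes:
        by_chrom[loci[g].chromosome].append(loci[g])
    total, n_pairs = 0.0, 0
    for members in by_chrom.values():
        for i in range(len(members)):
            for j in range(i):
                total += gene_distance(members[i], members[j])
                n_pairs += 1
    if n_pairs == 0:
        return None
    return total / n_pairs


def _chrom_mean_distance(members) -> float:
    total, n_pairs = 0.0, 0
    for i in range(len(members)):
        for j in range(i):
            total += gene_distance(members[i], members[j])
            n_pairs += 1
    return total / n_pairs


@dataclass
class ChromosomeLocalization:
    chromosome: str
    n_genes: int
    d_tilde: float
    z: float | None
    p_normal: float | None
    p_empirical: float | None
    bonferroni_significant: bool


@dataclass
class LocalizationResult:
    group_id: str
    n: int
    x_c: float
    z_x: float | None
    d_c: float | None
    z_d: float | None
    per_chromosome: list = field(default_factory=list)
    n_rand: int = 100
    seed: int = 0


def _z_and_ps(observed, replicates, side: str):
    """Z against the randomization; one-sided normal and empirical p."""
    mean = float(np.mean(replicates))
    sd = float(np.std(replicates))
    # Constant replicates can leave a ~1e-17 rounding residue in np.std.
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return None, None, None
    z = (observed - mean) / sd
    if side == "greater":  # enrichment: large observed is interesting
        p_normal = float(stats.norm.sf(z))
        p_emp = float(np.mean(np.asarray(replicates) >= observed))
    else:  # clustering: small observed is interesting
        p_normal = float(stats.norm.cdf(z))
        p_emp = float(np.mean(np.asarray(replicates) <= observed))
    return float(z), p_normal, p_emp


def localization_tests(
    genes,
    background,
    n_rand: int = 100,
    seed: int = 0,
    min_genes_per_chrom: int = 3,
    alpha: float = 0.05,
    group_id: str = "",
) -> LocalizationResult:
    """Three randomization tests for genomic clustering of a gene group.

    1. Same-chromosome enrichment: x_c against ``n_rand`` shuffles of the
       chromosome labels across the background genes (Z positive when the
       group shares chromosomes more than chance).
    2. Overall proximity: d_c against draws of n_k background genes from
       each chromosome k carrying at least two group genes (Z negative when
       the group is tighter than chance).
    3. Per-chromosome proximity: d~_{c,k} for every chromosome with at
       least ``min_genes_per_chrom`` group genes, with one-sided normal and
       empirical p-values and a Bonferroni flag over the group's tested
       chromosomes.

    ``background`` is the list of GeneLocus records the group was selected
    from; the group must be a subset of it.
    """
    background = list(background)
    loci = {g.gene_id: g for g in background}
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least two genes in the group")
    missing = [g for g in genes if g not in loci]
    if missing:
        raise KeyError(f"group genes missing from background: {missing}")
    rng = np.random.default_rng(seed)
    bg_ids = [g.gene_id for g in background]
    bg_chroms = np.array([g.chromosome for g in background])
    group_pos = [bg_ids.index(g) for g in genes]
    n = len(genes)

    # Test 1: fraction of same-chromosome pairs under label shuffling.
    x_c = same_chromosome_fraction(genes, loci)
    x_rand = np.empty(n_rand)
    for rep in range(n_rand):
        shuffled = bg_chroms[rng.permutation(len(background))]
        group_chroms = shuffled[group_pos]
        counts = Counter(group_chroms)
        same = sum(c * (c - 1) // 2 for c in counts.values())
        x_rand[rep] = same / (n * (n - 1) / 2)
    z_x, _, _ = _z_and_ps(x_c, x_rand, side="greater")

    # Group composition per chromosome.
    group_by_chrom = defaultdict(list)
    for g in genes:
        group_by_chrom[loci[g].chromosome].append(loci[g])
    bg_by_chrom = defaultdict(list)
    for g in background:
        bg_by_chrom[g.chromosome].append(g)
    multi = {k: v for k, v in group_by_chrom.items() if len(v) >= 2}
    for k, members in multi.items():
        if len(bg_by_chrom[k]) < len(members):
            raise ValueError(
                f"chromosome {k}: background has fewer genes than the group"
            )

    # Test 2: average same-chromosome distance, counts preserved.
    d_c = mean_pair_distance(genes, loci)
    z_d = None
    if d_c is not None:
        all_same = all(
            len(bg_by_chrom[k]) == len(members) for k, members in multi.items()
        )
        d_rand = np.empty(n_rand)
        for rep in range(n_rand):
            total, n_pairs = 0.0, 0
            for k, members in multi.items():
                pool = bg_by_chrom[k]
                pick = rng.choice(len(pool), size=len(members), replace=False)
                chosen = [pool[i] for i in pick]
                for i in range(len(chosen)):
                    for j in range(i):
                        total += gene_distance(chosen[i], chosen[j])
                        n_pairs += 1
            d_rand[rep] = total / n_pairs
        z_d, _, _ = _z_and_ps(d_c, d_rand, side="less")
        if z_d is None and all_same:
            logger.info(
                "group %s: randomization is degenerate (group exhausts the "
                "background on its chromosomes)", group_id,
            )

    # Test 3: per-chromosome distances.
    per_chrom = []
    tested = [
        k for k, members in sorted(group_by_chrom.items())
        if len(members) >= min_genes_per_chrom
    ]
    raw = []
    for k in tested:
        members = group_by_chrom[k]
        d_obs = _chrom_mean_distance(members)
        pool = bg_by_chrom[k]
        reps = np.empty(n_rand)
        for rep in range(n_rand):
            pick = rng.choice(len(pool), size=len(members), replace=False)
            reps[rep] = _chrom_mean_distance([pool[i] for i in pick])
        z, p_norm, p_emp = _z_and_ps(d_obs, reps, side="less")
        raw.append((k, len(members), d_obs, z, p_norm, p_emp))
    n_tests = len(raw)
    for k, nk, d_obs, z, p_norm, p_emp in raw:
        significant = p_norm is not None and p_norm * n_tests <= alpha
        per_chrom.append(
            ChromosomeLocalization(
                chromosome=k, n_genes=nk, d_tilde=d_obs, z=z,
                p_normal=p_norm, p_empirical=p_emp,
                bonferroni_significant=bool(significant),
            )
        )
    return LocalizationResult(
        group_id=group_id, n=n, x_c=x_c, z_x=z_x, d_c=d_c, z_d=z_d,
        per_chromosome=per_chrom, n_rand=n_rand, seed=seed,
    )


def shared_eqtl_pairs(rho: np.ndarray, gene_ids, eqtl, r_min: float = 0.5):
    """Co-expressed gene pairs sharing associated variants.

    ``eqtl`` is a DataFrame-like with columns ``gene_id`` and ``variant_id``
    (rows assumed pre-filtered to significant associations).  Returns, for
    every unordered gene pair with correlation above ``r_min`` whose variant
    sets intersect, a tuple ``(gene_i, gene_j, r, sorted shared variants)``.
    """
    rho = np.asarray(rho, float)
    gene_ids = list(gene_ids)
    variants_of = defaultdict(set)
    for gene, variant in zip(eqtl["gene_id"], eqtl["variant_id"]):
        variants_of[str(gene)].add(str(variant))
    unknown = sorted(set(variants_of) - set(gene_ids))
    if unknown:
        raise KeyError(f"eQTL table references unknown genes: {unknown}")
    out = []
    n = len(gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if rho[i, j] <= r_min:
                continue
            shared = variants_of[gene_ids[i]] & variants_of[gene_ids[j]]
            if shared:
                out.append(
                    (gene_ids[i], gene_ids[j], float(rho[i, j]), sorted(shared))
                )
    return out
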