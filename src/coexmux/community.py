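"""Multilayer modularity maximization on correlation matrices.

Nodes are (gene, layer) pairs.  The supra-modularity matrix B couples the
intralayer blocks rho_a - gamma_a * <rho_a> (null from the configuration
model for correlation matrices) with per-gene interlayer entries omega.
Modularity of a partition is the normalized sum of B entries over
co-assigned node pairs, double-counting (i, j) and (j, i).

Maximization uses a generalized Louvain heuristic that accepts an arbitrary
symmetric modularity matrix: single-node moves by exact gain, then exact
block aggregation of B, repeated until no gain.  Iterated runs feed the
output back as the initial partition until a fixed point; consensus over
many seeded runs clusters the permutation-thresholded agreement matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SupraModularity",
    "Partition",
    "AdjacencyLayers",
    "build_supra_modularity",
    "build_supra_modularity_network",
    "modularity",
    "genlouvain",
    "iterated_genlouvain",
    "refine_partition",
    "pillar_moves",
    "detect_communities",
    "consensus_partition",
    "brute_force_max_modularity",
]


@dataclass
class Partition:
    """Assignment of each (gene, layer) node to a community label.

    ``nodes`` fixes the node order; ``labels`` holds one positive integer per
    node.  Canonical labels are consecutive starting at 1, in order of first
    appearance along ``nodes``.
    """

    nodes: list  # list of (gene, layer) keys
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.nodes) != self.labels.shape[0]:
            raise ValueError("one label per node required")

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def canonicalize(self) -> "Partition":
        """Relabel communities 1..K in order of first appearance."""
        mapping = {}
        new = np.empty_like(self.labels)
        for i, lab in enumerate(self.labels):
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            new[i] = mapping[lab]
        return Partition(nodes=self.nodes, labels=new)

    def as_dict(self) -> dict:
        return {node: int(lab) for node, lab in zip(self.nodes, self.labels)}

    def communities(self) -> dict:
        """Map label -> list of (gene, layer) nodes."""
        out = {}
        for node, lab in zip(self.nodes, self.labels):
            out.setdefault(int(lab), []).append(node)
        return out

    def same_assignment(self, other: "Partition") -> bool:
        """True if both partitions induce the same grouping (label-invariant)."""
        a = self.canonicalize().labels
        b = other.canonicalize().labels
        return self.nodes == other.nodes and np.array_equal(a, b)


@dataclass
class SupraModularity:
    """Supra-modularity matrix over the (gene, layer) node set."""

    order: list  # (gene, layer) node keys, layer-major
    B: np.ndarray
    gamma: np.ndarray
    c_norm: float

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        n = len(self.order)
        if self.B.shape != (n, n):
            raise ValueError("B must be square over the node order")
        if not np.allclose(self.B, self.B.T, atol=1e-10):
            raise ValueError("B must be symmetric")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("B must be finite")
        if self.c_norm <= 0:
            raise ValueError("normalization constant must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.order)


def build_supra_modularity(mlc, nulls, gamma) -> SupraModularity:
    """Supra-modularity matrix for a multilayer correlation matrix.

    B[(i,a),(j,b)] = (rho_ija - gamma_a <rho_ija>) delta_ab + omega_iab
    delta_ij, over layer-major node order.  The normalization is the total
    weight C_norm = sum_ia (sum_j rho_ija + sum_b omega_iab), diagonal rho
    terms included.
    """
    n, n_layers = mlc.n_genes, mlc.n_layers
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (n_layers,))
    if np.any(gamma <= 0):
        raise ValueError("resolution parameters must be positive")
    if len(nulls) != n_layers:
        raise ValueError("one fitted null per layer required")
    size = n * n_layers
    b = np.zeros((size, size))
    for a in range(n_layers):
        sl = slice(a * n, (a + 1) * n)
        b[sl, sl] = mlc.rho[a] - gamma[a] * nulls[a].null_rho
        for bb in range(n_layers):
            if bb == a:
                continue
            sl2 = slice(bb * n, (bb + 1) * n)
            b[sl, sl2][np.diag_indices(n)] = mlc.omega[:, a, bb]
    c_norm = float(mlc.rho.sum() + mlc.omega.sum())
    if c_norm <= 0:
        raise ValueError("normalization constant is non-positive")
    order = [(g, layer) for layer in mlc.layer_names for g in mlc.gene_ids]
    return SupraModularity(order=order, B=b, gamma=np.array(gamma), c_norm=c_norm)


@dataclass
class AdjacencyLayers:
    """Multiplex adjacency input for the network-modularity variant."""

    gene_ids: list
    layer_names: list
    layers: np.ndarray  # (L, N, N), symmetric, non-negative, zero diagonal
    omega: np.ndarray  # (N, L, L)

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        for a, adj in enumerate(self.layers):
            if not np.allclose(adj, adj.T, atol=1e-10):
                raise ValueError(f"layer {self.layer_names[a]}: not symmetric")
            if np.any(adj < 0):
                raise ValueError(f"layer {self.layer_names[a]}: negative weights")
            if np.any(np.diag(adj) != 0):
                raise ValueError(f"layer {self.layer_names[a]}: nonzero diagonal")

    @property
    def strengths(self) -> np.ndarray:
        return self.layers.sum(axis=2)  # (L, N)

    @property
    def layer_totals(self) -> np.ndarray:
        return self.layers.sum(axis=(1, 2)) / 2.0  # m_a


def build_supra_modularity_network(adj: AdjacencyLayers, gamma) -> SupraModularity:
    """Newman-Girvan-style supra-modularity matrix for multiplex adjacency input.

    B[(i,a),(j,b)] = (A_ija - gamma_a k_ia k_ja / (2 m_a)) delta_ab
    + omega_iab delta_ij, normalized by 2 mu (total edge weight, interlayer
    couplings included).
    """
    n, n_layers = len(adj.gene_ids), len(adj.layer_names)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (n_layers,))
    k = adj.strengths
    m = adj.layer_totals
    if np.any(m <= 0):
        empty = [adj.layer_names[a] for a in range(n_layers) if m[a] <= 0]
        raise ValueError(f"empty layer(s): {', '.join(empty)}")
    size = n * n_layers
    b = np.zeros((size, size))
    for a in range(n_layers):
        sl = slice(a * n, (a + 1) * n)
        b[sl, sl] = adj.layers[a] - gamma[a] * np.outer(k[a], k[a]) / (2.0 * m[a])
        for bb in range(n_layers):
            if bb == a:
                continue
            sl2 = slice(bb * n, (bb + 1) * n)
            b[sl, sl2][np.diag_indices(n)] = adj.omega[:, a, bb]
    two_mu = float(k.sum() + adj.omega.sum())
    order = [(g, layer) for layer in adj.layer_names for g in adj.gene_ids]
    return SupraModularity(order=order, B=b, gamma=np.array(gamma), c_norm=two_mu)


def modularity(partition: Partition, supra: SupraModularity) -> float:
    """Multilayer modularity Q of a partition.

    Sums B over ordered co-assigned node pairs (diagonal included, (i, j)
    and (j, i) double-counted) and divides by the normalization constant.
    """
    if partition.nodes != supra.order:
        raise ValueError("partition does not cover the supra matrix's node set")
    labels = partition.labels
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        total += supra.B[np.ix_(idx, idx)].sum()
    return float(total / supra.c_norm)


def _local_move(b: np.ndarray, labels: np.ndarray, rng) -> bool:
    """One Louvain phase of single-node moves; mutates labels in place.

    Gain of moving node v from community c to d is 2 (S_d - S_{c minus v})
    with S_x the sum of B[v, u] over u in x (self term excluded; it is
    partition-invariant).  Ties keep the current community, otherwise the
    lowest candidate label wins.
    """
    n = b.shape[0]
    improved_any = False
    while True:
        improved = False
        for v in rng.permutation(n):
            counts = np.bincount(labels, minlength=labels.max() + 2)
            weights = np.bincount(labels, weights=b[v], minlength=counts.shape[0])
            weights[labels[v]] -= b[v, v]
            # A first empty label is always available as a "split off" move
            # with gain 0 relative to a fresh singleton.
            empty = np.flatnonzero(counts == 0)
            if empty.size:
                weights[empty[1:]] = -np.inf
            best = weights.max()
            if best > weights[labels[v]] + 1e-12:
                target = int(np.flatnonzero(weights >= best - 1e-12)[0])
                if target != labels[v]:
                    labels[v] = target
                    improved = improved_any = True
        if not improved:
            break
    return improved_any


def _compress_labels(labels: np.ndarray) -> np.ndarray:
    _, compact = np.unique(labels, return_inverse=True)
    return compact


def _aggregate(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Sum B blocks into the community-level matrix (exact, no rescaling)."""
    k = labels.max() + 1
    ind = np.zeros((b.shape[0], k))
    ind[np.arange(b.shape[0]), labels] = 1.0
    return ind.T @ b @ ind


def genlouvain(
    supra: SupraModularity, seed: int = 0, init: Partition | None = None
) -> Partition:
    """Generalized Louvain on an arbitrary symmetric modularity matrix.

    Repeats (i) greedy single-node moves maximizing the within-community sum
    of B and (ii) exact community aggregation until neither yields a gain.
    Node visiting order is shuffled per sweep by ``seed``; the search starts
    from ``init`` or from singletons.
    """
    rng = np.random.default_rng(seed)
    n = supra.n_nodes
    if init is not None:
        if init.nodes != supra.order:
            raise ValueError("initial partition is over a different node set")
        labels = _compress_labels(init.labels.copy())
    else:
        labels = np.arange(n)
    mapping = labels.copy()  # original node -> current community
    b = _aggregate(supra.B, labels) if init is not None else supra.B.copy()
    meta_labels = np.arange(b.shape[0])
    first = True
    while True:
        moved = _local_move(b, meta_labels, rng)
        if not moved and not first:
            break
        meta_labels = _compress_labels(meta_labels)
        mapping = meta_labels[mapping]
        if not moved:
            break
        b = _aggregate(b, meta_labels)
        meta_labels = np.arange(b.shape[0])
        first = False
    return Partition(nodes=supra.order, labels=mapping + 1).canonicalize()


def iterated_genlouvain(
    supra: SupraModularity, seed: int = 0, max_rounds: int = 100
) -> Partition:
    """Repeat genlouvain, seeding each round with the previous output,
    until the partition no longer changes (fixed point)."""
    rng = np.random.default_rng(seed)
    part = genlouvain(supra, seed=int(rng.integers(2**31 - 1)))
    for _ in range(max_rounds):
        nxt = genlouvain(supra, seed=int(rng.integers(2**31 - 1)), init=part)
        if nxt.same_assignment(part):
            return nxt
        part = nxt
    logger.warning("iterated genlouvain hit the %d-round cap", max_rounds)
    return part


def refine_partition(
    supra: SupraModularity, partition: Partition, seed: int = 0,
    max_rounds: int = 20,
) -> Partition:
    """Split-refinement of a converged partition.

    Greedy single-node moves cannot undo a bad multi-node merge: once two
    groups share a community, no individual node gains by leaving.  This
    pass re-clusters each community's induced sub-matrix from singletons
    and accepts the split whenever the total B weight between the resulting
    parts is negative (which raises global modularity by exactly minus that
    cross weight), then lets genlouvain re-converge from the refined
    labels.  Repeats until a fixed point; Q never decreases.
    """
    rng = np.random.default_rng(seed)
    part = partition.canonicalize()
    for _ in range(max_rounds):
        labels = part.labels.copy()
        next_label = labels.max() + 1
        changed = False
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if idx.size < 2:
                continue
            sub_b = supra.B[np.ix_(idx, idx)]
            sub = SupraModularity(
                order=[supra.order[i] for i in idx], B=sub_b,
                gamma=supra.gamma, c_norm=supra.c_norm,
            )
            sub_part = genlouvain(sub, seed=int(rng.integers(2**31 - 1)))
            if sub_part.n_communities < 2:
                continue
            # Cross weight between sub-parts: total minus within-part sums.
            within = sum(
                sub_b[np.ix_(np.flatnonzero(sub_part.labels == c),
                             np.flatnonzero(sub_part.labels == c))].sum()
                for c in np.unique(sub_part.labels)
            )
            if sub_b.sum() - within < -1e-12:
                for c in np.unique(sub_part.labels)[1:]:
                    labels[idx[sub_part.labels == c]] = next_label
                    next_label += 1
                changed = True
        if not changed:
            return part
        refined = Partition(nodes=supra.order, labels=labels).canonicalize()
        part = genlouvain(supra, seed=int(rng.integers(2**31 - 1)), init=refined)
    logger.warning("split refinement hit the %d-round cap", max_rounds)
    return part


def detect_communities(
    supra: SupraModularity, n_runs: int = 200, seed: int = 0,
) -> Partition:
    """Full detection at one resolution: consensus over refined iterated runs.

    Runs ``n_runs`` seeded iterated-genlouvain searches, applies split
    refinement to each, takes their consensus partition, and refines the
    consensus once more against the supra-modularity matrix (the consensus
    can glue together marginally co-assigned groups; the final refinement
    undoes any such merge that lowers Q).
    """
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_runs):
        p = iterated_genlouvain(supra, seed=int(rng.integers(2**31 - 1)))
        parts.append(refine_partition(supra, p, seed=int(rng.integers(2**31 - 1))))
    cons = consensus_partition(parts, supra, seed=int(rng.integers(2**31 - 1)))
    return refine_partition(supra, cons, seed=int(rng.integers(2**31 - 1)))


def _agreement(label_matrix: np.ndarray) -> np.ndarray:
    """Fraction of partitions co-assigning each node pair.

    ``label_matrix`` has one row per partition.
    """
    n_parts, n = label_matrix.shape
    agree = np.zeros((n, n))
    for row in label_matrix:
        agree += row[:, None] == row[None, :]
    return agree / n_parts


def consensus_partition(
    partitions, supra: SupraModularity | None = None, seed: int = 0,
    n_null_permutations: int = 100, n_cluster_runs: int = 10,
    max_rounds: int = 20,
) -> Partition:
    """Consensus over stochastic partitions via the agreement matrix.

    Builds the node x node co-assignment fraction, subtracts the mean
    agreement of the same partitions with labels randomly permuted across
    nodes (preserving community sizes), and clusters the residual matrix
    with genlouvain repeatedly until all runs agree.  Negative residual
    entries are kept and act as repulsion.

    When ``supra`` is given, the converged consensus is polished against it:
    single-node moves seeded by the consensus followed by split refinement,
    both of which only ever increase the original modularity.  Agreement
    clustering alone tracks the modal co-assignment pattern and can settle
    strictly below every input run when the ensemble is diverse; the polish
    restores local optimality with respect to the actual objective while
    keeping the consensus structure as the starting point.
    """
    partitions = list(partitions)
    if not partitions:
        raise ValueError("no partitions given")
    nodes = partitions[0].nodes
    for p in partitions[1:]:
        if p.nodes != nodes:
            raise ValueError("partitions cover different node sets")
    if len(partitions) == 1:
        return partitions[0].canonicalize()
    rng = np.random.default_rng(seed)
    labels = np.stack([p.labels for p in partitions])
    n = labels.shape[1]
    for _ in range(max_rounds):
        agree = _agreement(labels)
        null = np.zeros_like(agree)
        for _ in range(n_null_permutations):
            permuted = np.stack([row[rng.permutation(n)] for row in labels])
            null += _agreement(permuted)
        null /= n_null_permutations
        residual = agree - null
        np.fill_diagonal(residual, 0.0)
        sub = SupraModularity(
            order=nodes, B=residual, gamma=np.array([1.0]),
            c_norm=max(np.abs(residual).sum(), 1e-12),
        )
        runs = [
            genlouvain(sub, seed=int(rng.integers(2**31 - 1)))
            for _ in range(n_cluster_runs)
        ]
        if all(r.same_assignment(runs[0]) for r in runs[1:]):
            return _polish(runs[0], supra, rng)
        labels = np.stack([r.labels for r in runs])
    logger.warning("consensus did not stabilize in %d rounds", max_rounds)
    return _polish(runs[0], supra, rng)


def pillar_moves(supra: SupraModularity, partition: Partition,
                 max_sweeps: int = 20) -> Partition:
    """Coordinated moves of all replicas of one gene across layers.

    Single-node moves cannot relocate a gene whose layer replicas hold each
    other in place through their interlayer couplings: moving one replica
    alone severs the coupling and never gains.  This pass moves a gene's
    whole node set at once, to whichever existing (or fresh) community
    yields the largest exact modularity gain; Q is non-decreasing.
    """
    labels = partition.canonicalize().labels.copy()
    by_gene = {}
    for idx, (gene, _layer) in enumerate(partition.nodes):
        by_gene.setdefault(gene, []).append(idx)
    groups = [np.array(v) for v in by_gene.values()]
    b = supra.B

    def within(lab_vec, comms):
        total = 0.0
        for c in comms:
            idx = np.flatnonzero(lab_vec == c)
            total += b[np.ix_(idx, idx)].sum()
        return total

    for _ in range(max_sweeps):
        changed = False
        for grp in groups:
            old = set(labels[grp])
            fresh = labels.max() + 1
            candidates = set(np.unique(labels)) | {fresh}
            base = within(labels, old)
            best_gain, best_c = 1e-12, None
            for c in candidates:
                if old == {c}:
                    continue
                trial = labels.copy()
                trial[grp] = c
                gain = within(trial, old | {c}) - (
                    base if c in old else base + 0.0
                ) - (0.0 if c in old else within(labels, {c}))
                if gain > best_gain:
                    best_gain, best_c = gain, c
            if best_c is not None:
                labels[grp] = best_c
                changed = True
        if not changed:
            break
    return Partition(nodes=partition.nodes, labels=labels).canonicalize()


def _polish(part: Partition, supra: SupraModularity | None, rng,
            n_restarts: int = 5) -> Partition:
    """Restore local optimality of a consensus partition w.r.t. the original
    objective: several seeded descents from the consensus init, each a
    round of local moves, split refinement and coordinated pillar moves;
    the best by modularity wins."""
    if supra is None:
        return part
    n = supra.n_nodes

    def descend(start):
        cand = genlouvain(supra, seed=int(rng.integers(2**31 - 1)), init=start)
        cand = refine_partition(supra, cand, seed=int(rng.integers(2**31 - 1)))
        for _ in range(10):
            moved = pillar_moves(supra, cand)
            if moved.same_assignment(cand):
                break
            nxt = refine_partition(
                supra, genlouvain(
                    supra, seed=int(rng.integers(2**31 - 1)), init=moved
                ),
                seed=int(rng.integers(2**31 - 1)),
            )
            cand = nxt if modularity(nxt, supra) >= modularity(moved, supra) \
                else moved
        return cand

    best = descend(part)
    best_q = modularity(best, supra)
    # Basin hopping around the consensus: perturb a fraction of the labels,
    # descend again, keep the best. Escapes shallow local optima that the
    # seeded descents from the unperturbed consensus cannot leave.
    for _ in range(n_restarts):
        labels = best.labels.copy()
        flip = rng.random(n) < 0.3
        labels[flip] = rng.integers(1, labels.max() + 2, flip.sum())
        cand = descend(Partition(nodes=supra.order, labels=labels))
        q = modularity(cand, supra)
        if q > best_q:
            best, best_q = cand, q
    return best


def _set_partitions(n: int):
    """Iterate all set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)
    yield labels.copy()
    if n == 1:
        return
    maxima = np.zeros(n, dtype=int)
    while True:
        i = n - 1
        while i > 0 and labels[i] == maxima[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxima[i] = max(maxima[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxima[j] = maxima[i]
        yield labels.copy()


def brute_force_max_modularity(supra: SupraModularity, max_nodes: int = 10):
    """Exact modularity maximizer by enumeration of all set partitions.

    Test oracle only; Bell-number growth restricts it to ``max_nodes``.
    """
    n = supra.n_nodes
    if n > max_nodes:
        raise ValueError(f"exhaustive enumeration limited to {max_nodes} nodes")
    best_q, best_labels = -np.inf, None
    for labels in _set_partitions(n):
        q = modularity(Partition(nodes=supra.order, labels=labels + 1), supra)
        if q > best_q:
            best_q, best_labels = q, labels.copy()
    part = Partition(nodes=supra.order, labels=best_labels + 1).canonicalize()
    return part, float(best_q)
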