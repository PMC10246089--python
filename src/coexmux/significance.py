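"""Community significance under the configuration-model null.

The quality of a community is the total intralayer weight W: the sum of
empirical correlation entries over all within-layer gene pairs inside the
community (diagonal excluded, each unordered pair counted once).  Under the
null -- a sample covariance of L_a Gaussian observations drawn from the
fitted configuration-model correlation matrix of layer a -- the mean of W
is the corresponding sum of null entries, and its variance follows from the
Gaussian (Isserlis) fourth-moment identity:

    Var = sum_a (1/L_a) sum_{pairs (i>j)} sum_{pairs (k>r)}
              (C_ika C_jra + C_ira C_jka),

which scales exactly as 1/L_a.  The Z score (W - mu)/sigma is undefined for
communities without intralayer pairs or with zero variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CommunityNodeSet",
    "SignificanceRecord",
    "community_weight",
    "null_moments",
    "z_score",
    "mc_weight_moments",
    "significance_table",
]


@dataclass
class CommunityNodeSet:
    """A community as a set of (gene, layer) node keys."""

    label: int
    nodes: frozenset

    def __post_init__(self):
        self.nodes = frozenset(self.nodes)
        if not self.nodes:
            raise ValueError("community node set must be non-empty")

    def layer_members(self, mlc) -> dict:
        """Map layer name -> sorted gene row indices of members in that layer."""
        index = {g: i for i, g in enumerate(mlc.gene_ids)}
        out = {}
        for gene, layer in self.nodes:
            out.setdefault(layer, []).append(index[gene])
        return {layer: sorted(rows) for layer, rows in out.items()}


@dataclass
class SignificanceRecord:
    label: int
    n_nodes: int
    n_pairs: int
    W: float
    mu: float
    var: float
    z: float | None  # None when no intralayer pairs or zero variance


def community_weight(comm: CommunityNodeSet, mlc) -> float:
    """Total intralayer weight W: within-layer pair sums of empirical rho,
    diagonal excluded, each unordered pair counted once."""
    total = 0.0
    layer_index = {name: a for a, name in enumerate(mlc.layer_names)}
    for layer, rows in comm.layer_members(mlc).items():
        if len(rows) < 2:
            continue
        sub = mlc.rho[layer_index[layer]][np.ix_(rows, rows)]
        total += (sub.sum() - np.trace(sub)) / 2.0
    return float(total)


def _pair_indices(m: int):
    """Index arrays (i, j) over unordered pairs with i > j of range(m)."""
    i, j = np.tril_indices(m, k=-1)
    return i, j


def _layer_moments(c_sub: np.ndarray, l_obs: int):
    """(mu, var) of the within-layer pair sum for one layer's null submatrix."""
    m = c_sub.shape[0]
    if m < 2:
        return 0.0, 0.0
    i, j = _pair_indices(m)
    mu = float(c_sub[i, j].sum())
    # Var = (1/L) sum over pair pairs of (C_ik C_jr + C_ir C_jk), vectorized
    # as pair x pair Gram products.
    cik = c_sub[np.ix_(i, i)]
    cjr = c_sub[np.ix_(j, j)]
    cir = c_sub[np.ix_(i, j)]
    cjk = c_sub[np.ix_(j, i)]
    var = float((cik * cjr + cir * cjk).sum() / l_obs)
    return mu, var


def null_moments(comm: CommunityNodeSet, mlc, nulls, n_obs=None) -> tuple:
    """Closed-form mean and variance of W under the fitted nulls.

    ``nulls`` is the list of fitted NullLayer objects aligned with
    ``mlc.layer_names``; ``n_obs`` defaults to the per-layer sample counts
    used to estimate the empirical correlations.
    """
    if n_obs is None:
        n_obs = {name: int(s) for name, s in zip(mlc.layer_names, mlc.sample_counts)}
    layer_index = {name: a for a, name in enumerate(mlc.layer_names)}
    mu = 0.0
    var = 0.0
    for layer, rows in comm.layer_members(mlc).items():
        if len(rows) < 2:
            continue
        a = layer_index[layer]
        l_obs = int(n_obs[layer])
        if l_obs < 2:
            raise ValueError(f"layer {layer}: need n_obs >= 2, got {l_obs}")
        m, v = _layer_moments(nulls[a].null_rho[np.ix_(rows, rows)], l_obs)
        mu += m
        var += v
    return float(mu), float(var)


def z_score(x: float, mu: float, var: float):
    """(x - mu) / sqrt(var); None (undefined) when var == 0."""
    if var < 0:
        raise ValueError("variance must be non-negative")
    if var == 0:
        return None
    return float((x - mu) / np.sqrt(var))


def intralayer_pair_count(comm: CommunityNodeSet) -> int:
    by_layer = {}
    for gene, layer in comm.nodes:
        by_layer.setdefault(layer, []).append(gene)
    return sum(len(g) * (len(g) - 1) // 2 for g in by_layer.values())


def mc_weight_moments(
    comm: CommunityNodeSet, mlc, nulls, n_obs=None, n_rep: int = 1000, seed: int = 0
) -> tuple:
    """Monte-Carlo oracle for the closed-form moments.

    Re-draws ``n_rep`` sample covariances from each touched layer's fitted
    null and returns the empirical mean and variance of W recomputed on
    them.  The sample covariance uses the unbiased L-1 denominator, so the
    oracle matches the closed form to O(1/L).
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    if n_obs is None:
        n_obs = {name: int(s) for name, s in zip(mlc.layer_names, mlc.sample_counts)}
    layer_index = {name: a for a, name in enumerate(mlc.layer_names)}
    rng = np.random.default_rng(seed)
    members = comm.layer_members(mlc)
    w = np.zeros(n_rep)
    for layer, rows in members.items():
        if len(rows) < 2:
            continue
        a = layer_index[layer]
        null = nulls[a]
        sub_chol = np.linalg.cholesky(null.null_rho[np.ix_(rows, rows)])
        l_obs = int(n_obs[layer])
        i, j = _pair_indices(len(rows))
        for rep in range(n_rep):
            x = rng.standard_normal((l_obs, len(rows))) @ sub_chol.T
            x = x - x.mean(axis=0, keepdims=True)
            cov = (x.T @ x) / (l_obs - 1)
            w[rep] += cov[i, j].sum()
    return float(w.mean()), float(w.var(ddof=1))


def significance_table(partition, mlc, nulls, n_obs=None):
    """One SignificanceRecord per community, ordered by label.

    Communities without intralayer pairs (or with zero null variance) carry
    an undefined Z score.
    """
    records = []
    for label, nodes in sorted(partition.communities().items()):
        comm = CommunityNodeSet(label=label, nodes=frozenset(nodes))
        n_pairs = intralayer_pair_count(comm)
        w = community_weight(comm, mlc)
        mu, var = null_moments(comm, mlc, nulls, n_obs)
        z = z_score(w, mu, var) if n_pairs > 0 else None
        records.append(
            SignificanceRecord(
                label=int(label), n_nodes=len(nodes), n_pairs=n_pairs,
                W=w, mu=mu, var=var, z=z,
            )
        )
    return records
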