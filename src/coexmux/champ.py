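"""Resolution selection via the 1-D convex hull of admissible partitions.

For a fixed partition, multilayer correlation-matrix modularity is affine in
a shared resolution parameter: Q_p(gamma) = (a_p - gamma b_p) / C_norm,
where a_p collects the within-community empirical correlation and coupling
weight and b_p the within-community null weight.  Over a set of candidate
partitions the pointwise maximum of these lines (their upper envelope) tiles
the gamma axis into intervals, each owned by the partition that is optimal
there; wide intervals indicate robust partitions and supply representative
gamma values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Partition, SupraModularity, build_supra_modularity, iterated_genlouvain

__all__ = [
    "PartitionLine",
    "GammaDomains",
    "partition_line",
    "champ_1d",
    "gamma_sweep",
    "select_gamma",
]


@dataclass
class PartitionLine:
    """Affine-in-gamma modularity of one partition: Q = (a_p - gamma b_p)/C_norm."""

    partition_id: int
    a_p: float
    b_p: float
    c_norm: float = 1.0

    def value(self, gamma):
        return (self.a_p - np.asarray(gamma) * self.b_p) / self.c_norm


@dataclass
class GammaDomains:
    """Contiguous gamma intervals, each owned by one optimal partition."""

    intervals: list  # (gamma_low, gamma_high, partition_id), ordered
    at_lower_boundary: bool = False
    at_upper_boundary: bool = False

    def __post_init__(self):
        for (lo, hi, _pid) in self.intervals:
            if not hi > lo:
                raise ValueError("intervals must have positive width")
        for (_, hi, _), (lo, _, _) in zip(self.intervals, self.intervals[1:]):
            if abs(hi - lo) > 1e-12:
                raise ValueError("intervals must tile the range contiguously")

    @property
    def widest(self):
        """Intervals ordered by decreasing width; ties favor smaller gamma."""
        return sorted(self.intervals, key=lambda iv: (-(iv[1] - iv[0]), iv[0]))


def partition_line(partition: Partition, mlc, nulls) -> PartitionLine:
    """Decompose a partition's modularity into its line in the (gamma, Q) plane.

    Assumes a single resolution parameter shared by all layers.  a_p sums the
    within-community intralayer correlations (diagonal included) plus
    interlayer couplings; b_p sums the within-community null entries, so the
    direct modularity at any gamma equals (a_p - gamma b_p) / C_norm.
    """
    n, n_layers = mlc.n_genes, mlc.n_layers
    order = [(g, layer) for layer in mlc.layer_names for g in mlc.gene_ids]
    if partition.nodes != order:
        raise ValueError("partition nodes must be in layer-major multilayer order")
    labels = partition.labels
    a_p = 0.0
    b_p = 0.0
    # Intralayer sums per layer
    for a in range(n_layers):
        lab = labels[a * n:(a + 1) * n]
        for c in np.unique(lab):
            idx = np.flatnonzero(lab == c)
            a_p += mlc.rho[a][np.ix_(idx, idx)].sum()
            b_p += nulls[a].null_rho[np.ix_(idx, idx)].sum()
    # Interlayer couplings: same gene, co-assigned layers (double counted)
    for a in range(n_layers):
        for b in range(n_layers):
            if a == b:
                continue
            same = labels[a * n:(a + 1) * n] == labels[b * n:(b + 1) * n]
            a_p += mlc.omega[same, a, b].sum()
    c_norm = float(mlc.rho.sum() + mlc.omega.sum())
    return PartitionLine(partition_id=-1, a_p=float(a_p), b_p=float(b_p), c_norm=c_norm)


def champ_1d(lines, gamma_min: float, gamma_max: float, tol: float = 1e-12) -> GammaDomains:
    """Upper envelope of partition lines over [gamma_min, gamma_max].

    Returns the ordered gamma intervals in which each line dominates;
    dominated lines are discarded and coincident lines merged (first
    partition id kept).  Whether the envelope is clipped by the range
    boundary is flagged, since the winning partition may extend beyond it.
    """
    lines = list(lines)
    if not lines:
        raise ValueError("no partition lines given")
    if not gamma_max > gamma_min:
        raise ValueError("gamma_max must exceed gamma_min")

    # Deduplicate coincident lines, keeping the first id.
    unique = []
    for ln in lines:
        if not any(abs(ln.a_p - u.a_p) <= tol and abs(ln.b_p - u.b_p) <= tol
                   for u in unique):
            unique.append(ln)

    def value(ln, g):
        return ln.a_p - g * ln.b_p  # common positive 1/C_norm dropped

    intervals = []
    gamma = gamma_min
    # Best at gamma_min: highest value; among ties the shallowest slope in
    # -b (largest -b means growing fastest), i.e. smallest b_p, wins just
    # after gamma_min.
    current = max(unique, key=lambda ln: (value(ln, gamma_min), -ln.b_p))
    guard = 0
    while gamma < gamma_max and guard <= len(unique) + 2:
        guard += 1
        next_cross = gamma_max
        next_line = None
        for ln in unique:
            if ln is current:
                continue
            db = current.b_p - ln.b_p
            if db <= tol:
                continue  # ln never overtakes (not steeper downward than current)
            # cross solves a_cur - g b_cur = a_ln - g b_ln
            cross = (current.a_p - ln.a_p) / (current.b_p - ln.b_p)
            if gamma + tol < cross < next_cross - tol:
                next_cross = cross
                next_line = ln
            elif next_line is not None and abs(cross - next_cross) <= tol:
                # simultaneous crossing: prefer the line optimal furthest
                if ln.b_p < next_line.b_p:
                    next_line = ln
        intervals.append((gamma, next_cross, current.partition_id))
        gamma = next_cross
        if next_line is None:
            break
        current = next_line
    return GammaDomains(
        intervals=intervals,
        at_lower_boundary=True,
        at_upper_boundary=True,
    )


def gamma_sweep(mlc, nulls, grid, seed: int = 0):
    """One iterated-GenLouvain partition per resolution value on the grid.

    The default study grid is 15 evenly spaced values on [1, 4]; pass any
    non-empty iterable of gamma values.  Seeds for the per-gamma runs are
    derived deterministically from ``seed``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty gamma grid")
    rng = np.random.default_rng(seed)
    out = []
    for gamma in grid:
        supra = build_supra_modularity(mlc, nulls, gamma)
        part = iterated_genlouvain(supra, seed=int(rng.integers(2**31 - 1)))
        out.append((float(gamma), part))
    return out


def default_gamma_grid(gamma_min: float = 1.0, gamma_max: float = 4.0, n: int = 15):
    """Evenly spaced resolution grid; the study default is 15 points on [1, 4]."""
    return list(np.linspace(gamma_min, gamma_max, n))


def select_gamma(domains: GammaDomains, n_values: int = 2, pinned: dict | None = None):
    """Representative gamma per widest interval (two by default).

    The representative is the interval midpoint unless ``pinned`` maps the
    interval's partition id to an explicit value inside it.  Ties in width
    prefer the interval at smaller gamma.
    """
    chosen = domains.widest[:n_values]
    chosen.sort(key=lambda iv: iv[0])
    out = []
    for lo, hi, pid in chosen:
        if pinned and pid in pinned:
            g = float(pinned[pid])
            if not lo <= g <= hi:
                raise ValueError(
                    f"pinned gamma {g} outside interval [{lo}, {hi}] of partition {pid}"
                )
        else:
            g = (lo + hi) / 2.0
        out.append((g, pid))
    return out
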