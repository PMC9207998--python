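"""Topological measures of binary brain networks.

Degrees, shortest paths, triangles, global/local efficiency, clustering,
transitivity and modularity for binary directed and undirected graphs.  The
directed formulas sum over both edge orientations (so that undirected
graphs are the special case ``a_ij = a_ji``); infinite distances contribute
zero to efficiency sums; nodes with a zero clustering denominator
contribute zero to the mean and are excluded from transitivity.

All functions accept a :class:`~dcovnet.containers.BinaryNetwork` and
internally normalise its adjacency to the graph orientation
``a_ij = edge i -> j`` (FC-derived networks store the sink-row
orientation).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .containers import BinaryNetwork, TopologyReport

__all__ = [
    "degrees",
    "shortest_paths",
    "global_efficiency",
    "triangles",
    "clustering_transitivity",
    "local_efficiency",
    "modularity",
    "find_partition",
    "topology_report",
]


def _adj(net: BinaryNetwork) -> np.ndarray:
    return net.graph_adjacency().astype(float)


def degrees(net: BinaryNetwork) -> tuple[np.ndarray, np.ndarray]:
    """(out, in) degree vectors; identical for undirected networks."""
    a = _adj(net)
    out = a.sum(axis=1).astype(int)
    inn = a.sum(axis=0).astype(int)
    return out, inn


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """Unweighted all-pairs distances; ``inf`` marks unreachable pairs."""
    a = _adj(net)
    return _csgraph_shortest_path(a, method="D", directed=net.directed, unweighted=True)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over ordered node pairs; 1 on the
    complete graph, 0 on the empty graph."""
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return _efficiency_from_distances(shortest_paths(net))


def triangles(net: BinaryNetwork) -> np.ndarray:
    """Per-node triangle counts.

    Undirected: ``t_i = (1/2) sum_{j,h} a_ij a_ih a_jh``.  Directed: the
    orientation-summed count
    ``t_i = (1/2) sum_{j,h} (a_ij + a_ji)(a_ih + a_hi)(a_jh + a_hj)``.
    """
    a = _adj(net)
    b = a + a.T if net.directed else a
    return np.diag(np.linalg.matrix_power(b, 3)) / 2.0


def _clustering_denominator(net: BinaryNetwork) -> np.ndarray:
    a = _adj(net)
    if net.directed:
        ktot = a.sum(axis=1) + a.sum(axis=0)
        recip = np.diag(a @ a)
        return ktot * (ktot - 1) - 2.0 * recip
    k = a.sum(axis=1)
    return k * (k - 1)


def clustering_transitivity(net: BinaryNetwork) -> tuple[float, float]:
    """(clustering coefficient C, transitivity T).

    C averages each node's triangle density ``t_i / denom_i`` (zero for
    nodes with no possible triangle); T is the ratio of summed triangles to
    summed denominators, skipping zero-denominator nodes.  The undirected
    triangle count enters with the conventional factor two.
    """
    t = triangles(net)
    denom = _clustering_denominator(net)
    scale = 1.0 if net.directed else 2.0
    per_node = np.zeros_like(t, dtype=float)
    ok = denom > 0
    per_node[ok] = scale * t[ok] / denom[ok]
    C = float(per_node.mean())
    T = float(scale * t[ok].sum() / denom[ok].sum()) if np.any(ok) else 0.0
    return C, T


def local_efficiency(net: BinaryNetwork) -> float:
    """Efficiency of communication within each node's neighborhood.

    For node ``i`` the neighborhood is every node connected to ``i`` in
    either direction; path lengths are measured inside the induced
    subgraph.  Nodes with fewer than two neighbors contribute zero.
    """
    a = _adj(net)
    n = a.shape[0]
    denom = _clustering_denominator(net)
    total = 0.0
    for i in range(n):
        nbrs = np.where((a[i] > 0) | (a[:, i] > 0))[0]
        nbrs = nbrs[nbrs != i]
        if nbrs.size < 2 or denom[i] <= 0:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = _csgraph_shortest_path(sub, method="D", directed=net.directed, unweighted=True)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        np.fill_diagonal(inv, 0.0)
        if net.directed:
            w = a[i, nbrs] + a[nbrs, i]
            num = 0.5 * float((np.outer(w, w) * (inv + inv.T)).sum())
            total += num / denom[i]
        else:
            num = float((np.outer(a[i, nbrs], a[i, nbrs]) * inv).sum())
            total += num / denom[i]
    return total / n


def modularity(
    net: BinaryNetwork,
    partition: dict[str, int] | np.ndarray,
    printed_form: bool = False,
) -> float:
    """Newman modularity of a full node partition.

    ``e_uv`` is the proportion of all edges linking module ``u`` to module
    ``v``; ``Q = sum_u (e_uu - a_u^out a_u^in)`` with
    ``a_u^out = sum_v e_uv`` and ``a_u^in = sum_v e_vu`` (the two coincide
    for undirected networks).  ``printed_form=True`` instead squares the
    whole bracket, ``Q = sum_u (e_uu - sum_v e_uv)^2``, for auditing
    against sources that print that variant.
    """
    a = _adj(net)
    n = a.shape[0]
    membership = _as_membership(partition, net.labels, n)
    m = a.sum()
    if m == 0:
        return 0.0
    mods = np.unique(membership)
    k = mods.size
    relabel = {u: r for r, u in enumerate(mods)}
    e = np.zeros((k, k))
    for u in mods:
        for v in mods:
            e[relabel[u], relabel[v]] = a[np.ix_(membership == u, membership == v)].sum()
    e /= m
    a_out = e.sum(axis=1)
    a_in = e.sum(axis=0)
    if printed_form:
        return float(np.sum((np.diag(e) - a_out) ** 2))
    return float(np.sum(np.diag(e) - a_out * a_in))


def _as_membership(partition, labels: list[str], n: int) -> np.ndarray:
    if isinstance(partition, dict):
        missing = [lab for lab in labels if lab not in partition]
        if missing:
            raise ValueError(f"partition does not cover nodes: {missing}")
        membership = np.array([partition[lab] for lab in labels])
    else:
        membership = np.asarray(partition)
        if membership.shape != (n,):
            raise ValueError("partition array must have one entry per node")
    counts = np.bincount(membership - membership.min())
    if np.any(counts == 0):
        warnings.warn("partition contains empty module ids; they are ignored",
                      RuntimeWarning)
    return membership


def find_partition(net: BinaryNetwork, seed: int = 0) -> dict[str, int]:
    """Greedy agglomerative module search maximising modularity.

    Starts from singleton modules and repeatedly merges the pair of modules
    with the largest positive modularity gain (candidate order shuffled by
    ``seed``; ties resolved deterministically).  Never returns a partition
    worse than the single-module one (Q = 0).
    """
    a = _adj(net)
    n = a.shape[0]
    m = a.sum()
    labels = net.labels
    if m == 0:
        return {lab: 0 for lab in labels}

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    e = a[np.ix_(order, order)] / m  # module-pair link proportions
    alive = list(range(n))
    membership = {int(order[i]): i for i in range(n)}

    def gain(u: int, v: int) -> float:
        return (e[u, v] + e[v, u]
                - e[u].sum() * e[:, v].sum() - e[v].sum() * e[:, u].sum())

    while len(alive) > 1:
        best = None
        best_gain = 1e-12
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                u, v = alive[ai], alive[bi]
                g = gain(u, v)
                if g > best_gain:
                    best_gain = g
                    best = (u, v)
        if best is None:
            break
        u, v = best
        e[u, :] += e[v, :]
        e[:, u] += e[:, v]
        e[v, :] = 0.0
        e[:, v] = 0.0
        alive.remove(v)
        for node, mod in membership.items():
            if mod == v:
                membership[node] = u

    q = float(np.sum([e[u, u] - e[u].sum() * e[:, u].sum() for u in alive]))
    if q < 0.0:
        return {lab: 0 for lab in labels}
    remap = {mod: r for r, mod in enumerate(sorted(set(membership.values())))}
    return {labels[node]: remap[mod] for node, mod in membership.items()}


def topology_report(net: BinaryNetwork, seed: int = 0) -> TopologyReport:
    """All measures plus a searched module partition, in one report."""
    out_deg, in_deg = degrees(net)
    d = shortest_paths(net)
    t = triangles(net)
    C, T = clustering_transitivity(net)
    part = find_partition(net, seed=seed)
    return TopologyReport(
        out_degree=out_deg,
        in_degree=in_deg,
        distances=d,
        triangles=t,
        global_efficiency=_efficiency_from_distances(d),
        local_efficiency=local_efficiency(net),
        clustering=C,
        transitivity=T,
        modularity=modularity(net, part),
        partition=part,
    )
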