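"""Interactome connectivity statistics for a gene set.

Disease-associated genes tend to cluster on interaction networks.  Two
statistics quantify this for a candidate gene set: the size of the largest
connected component (LCC) of the induced subgraph, standardised against
random same-size node sets (permutation z-score), and the mean shortest
distance from each set member to its nearest other member.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


def _adjacency(net: nx.Graph) -> dict:
    return {n: set(net.neighbors(n)) for n in net.nodes}


def _lcc_of_set(adj: dict, nodes: set) -> int:
    """Largest connected component of the subgraph induced by ``nodes``."""
    best = 0
    seen: set = set()
    for start in nodes:
        if start in seen:
            continue
        size = 0
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            size += 1
            for v in adj.get(u, ()):
                if v in nodes and v not in seen:
                    seen.add(v)
                    stack.append(v)
        best = max(best, size)
    return best


def lcc_size(genes: set, net: nx.Graph) -> int:
    """Size of the largest connected component induced by
    ``genes ∩ net.nodes``; genes absent from the network are dropped."""
    present = set(genes) & set(net.nodes)
    dropped = len(set(genes)) - len(present)
    if dropped:
        logger.info("lcc_size: %d gene(s) absent from network", dropped)
    if not present:
        return 0
    return _lcc_of_set(_adjacency(net), present)


def lcc_zscore(genes: set, net: nx.Graph, n_perm: int = 100_000,
               seed: int = 0, null: str = "uniform") -> dict:
    """LCC z-score of a gene set against random same-size node sets.

    ``null='uniform'`` samples node sets uniformly; ``'degree_binned'``
    samples within log2-degree bins of the observed set, countering the
    hub-inflation of the uniform null.  Empirical p carries an add-one
    correction.  Returns dict with lcc, z (None if null SD is 0), p,
    null_mean, null_sd, dropped.
    """
    present = sorted(set(genes) & set(net.nodes))
    dropped = len(set(genes)) - len(present)
    if len(present) < 2:
        raise ValueError("need >= 2 genes present in the network")
    adj = _adjacency(net)
    observed = _lcc_of_set(adj, set(present))
    rng = np.random.default_rng(seed)
    all_nodes = np.array(sorted(net.nodes), dtype=object)
    k = len(present)
    if null == "degree_binned":
        degree = dict(net.degree())
        bins: dict[int, list] = {}
        for n in all_nodes:
            bins.setdefault(int(np.log2(degree[n] + 1)), []).append(n)
        set_bins = [int(np.log2(degree[g] + 1)) for g in present]
        null_sizes = np.empty(n_perm, dtype=np.int64)
        bin_arrays = {b: np.array(v, dtype=object) for b, v in bins.items()}
        for i in range(n_perm):
            draw = set()
            for b in set_bins:
                pool = bin_arrays[b]
                draw.add(pool[int(rng.integers(len(pool)))])
            null_sizes[i] = _lcc_of_set(adj, draw)
    elif null == "uniform":
        null_sizes = np.empty(n_perm, dtype=np.int64)
        for i in range(n_perm):
            idx = rng.choice(len(all_nodes), size=k, replace=False)
            null_sizes[i] = _lcc_of_set(adj, set(all_nodes[idx]))
    else:
        raise ValueError(f"unknown null {null!r}")
    mu = float(null_sizes.mean())
    sd = float(null_sizes.std(ddof=0))
    z = (observed - mu) / sd if sd > 0 else None
    p = (1 + int((null_sizes >= observed).sum())) / (1 + n_perm)
    return {"lcc": int(observed), "z": z, "p": float(p), "null_mean": mu,
            "null_sd": sd, "dropped": dropped, "null": null}


def mean_shortest_distance(genes: set, net: nx.Graph) -> dict:
    """Mean over set members of the BFS distance to the nearest other
    member; members unreachable from every other member are excluded from
    the mean (counted)."""
    present = sorted(set(genes) & set(net.nodes))
    if len(present) < 2:
        raise ValueError("need >= 2 genes present in the network")
    targets = set(present)
    adj = _adjacency(net)
    distances = []
    unreachable = 0
    for g in present:
        d = _bfs_nearest(adj, g, targets - {g})
        if d is None:
            unreachable += 1
        else:
            distances.append(d)
    if not distances:
        return {"d_s": None, "n_used": 0, "unreachable": unreachable}
    return {"d_s": float(np.mean(distances)), "n_used": len(distances),
            "unreachable": unreachable}


def _bfs_nearest(adj: dict, source, targets: set) -> int | None:
    if not targets:
        return None
    seen = {source}
    queue = deque([(source, 0)])
    while queue:
        u, d = queue.popleft()
        for v in adj.get(u, ()):
            if v in seen:
                continue
            if v in targets:
                return d + 1
            seen.add(v)
            queue.append((v, d + 1))
    return None
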