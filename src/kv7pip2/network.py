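"""Dynamical-network analysis over Calpha nodes.

Nodes are Calpha atoms (one per residue).  Two residues are connected when
they stay within a distance cutoff (default 4.5 A) for at least a fraction
of the frames (default 75%); each retained edge carries the Pearson
correlation C_ij of the two nodes' positional fluctuations and the
conventional dynamical-network edge length w_ij = -log|C_ij|.  Communities
are found by divisive edge-betweenness (Girvan-Newman) on the w-weighted
graph; among the partitions of the division sequence the one maximising
Newman-Girvan modularity computed with edge strength |C_ij| is returned,
with deterministic tie-breaking (fewest communities, then lexicographic node
order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import Selection, Topology, Trajectory

MIN_ABS_CORRELATION = 1e-6   # |C| clip for the -log edge-length transform


def correlation_matrix(traj: Trajectory, calpha_sel: Selection,
                       align: bool = True) -> np.ndarray:
    """Normalised fluctuation correlation C_ij of the selected nodes.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the deviation
    from the time-mean position.  With ``align`` every frame is first
    rigid-body superposed onto the mean structure (two iterations, all nodes,
    unit weights), which removes global translation/rotation.  Nodes with
    zero variance are flagged with a warning and their off-diagonal entries
    set to 0.
    """
    idx = calpha_sel.resolve(traj.topology)
    X = traj.coords[:, idx, :].astype(float).copy()   # (T, n, 3)
    T, n, _ = X.shape
    if T < 2 or n < 2:
        raise ValueError("need >= 2 frames and >= 2 nodes")
    if align:
        # superpose every frame onto frame 0 first, then iterate onto the
        # running mean structure.  Seeding from a single canonical frame
        # (rather than the mean of arbitrarily oriented frames) makes the
        # procedure equivariant: per-frame rigid motion only rotates the
        # final fixed point globally, which correlations cannot see.
        ref = X[0] - X[0].mean(axis=0)
        for f in range(T):
            frame_c = X[f] - X[f].mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, frame_c)
            X[f] = frame_c @ rot.as_matrix().T
        prev_mean = None
        for _ in range(100):
            mean = X.mean(axis=0)
            if prev_mean is not None and np.abs(mean - prev_mean).max() < 1e-12:
                break
            prev_mean = mean
            mean_c = mean - mean.mean(axis=0)
            for f in range(T):
                frame_c = X[f] - X[f].mean(axis=0)
                rot, _ = Rotation.align_vectors(mean_c, frame_c)
                X[f] = frame_c @ rot.as_matrix().T + mean.mean(axis=0)
    d = X - X.mean(axis=0)                            # (T, n, 3)
    cov = np.einsum("tia,tja->ij", d, d) / T
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance node(s); correlations set to 0",
                      RuntimeWarning, stacklevel=2)
        var[zero] = 1.0
    C = cov / np.sqrt(np.outer(var, var))
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def persistence_graph(traj: Trajectory, calpha_sel: Selection,
                      cutoff: float = 4.5, fraction: float = 0.75,
                      mode: str = "calpha",
                      exclude_neighbors: bool = False,
                      ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Contact-persistence matrix and the persistence-filtered edge set.

    persistence(i, j) is the fraction of frames with distance <= cutoff —
    Calpha-Calpha distance in ``calpha`` mode, or the minimum heavy-atom
    distance between the two residues in ``residue_heavy`` mode.  An edge
    exists iff persistence >= fraction.  ``exclude_neighbors`` drops
    sequence-adjacent pairs (same chain, |i - j| = 1).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if mode not in ("calpha", "residue_heavy"):
        raise ValueError(f"unknown mode {mode!r}")
    top = traj.topology
    idx = calpha_sel.resolve(top)
    n = idx.size
    T = traj.n_frames
    P = np.zeros((n, n))
    if mode == "calpha":
        for f in range(T):
            D = cdist(traj.coords[f, idx], traj.coords[f, idx])
            P += (D <= cutoff)
    else:
        heavy = top.heavy_mask()
        res_atoms = []
        for i in idx:
            mask = ((top.chain_id == top.chain_id[i])
                    & (top.residue_index == top.residue_index[i]) & heavy)
            res_atoms.append(np.nonzero(mask)[0])
        for f in range(T):
            xyz = traj.coords[f]
            for i, j in combinations(range(n), 2):
                dmin = cdist(xyz[res_atoms[i]], xyz[res_atoms[j]]).min()
                if dmin <= cutoff:
                    P[i, j] += 1
                    P[j, i] += 1
    P /= T
    np.fill_diagonal(P, 0.0)
    edges = []
    for i, j in combinations(range(n), 2):
        if P[i, j] >= fraction:
            if exclude_neighbors and (top.chain_id[idx[i]] == top.chain_id[idx[j]]
                                      and abs(int(top.residue_index[idx[i]])
                                              - int(top.residue_index[idx[j]])) == 1):
                continue
            edges.append((i, j))
    return P, edges


@dataclass
class CorrelationNetwork:
    """Correlation matrix + persistence-filtered weighted graph."""

    nodes: list[tuple[str, int, str]]        # (chain, resid, tag) per node
    C: np.ndarray
    persistence: np.ndarray
    edges: list[tuple[int, int]]
    graph: nx.Graph
    partition: Optional[dict[int, int]] = None   # node index -> community id
    modularity: Optional[float] = None

    def communities(self) -> list[set[int]]:
        if self.partition is None:
            raise ValueError("run detect_communities first")
        out: dict[int, set[int]] = {}
        for node, cid in self.partition.items():
            out.setdefault(cid, set()).add(node)
        return [out[k] for k in sorted(out)]


def build_network(traj: Trajectory, calpha_sel: Selection,
                  cutoff: float = 4.5, fraction: float = 0.75,
                  mode: str = "calpha", align: bool = True,
                  exclude_neighbors: bool = False) -> CorrelationNetwork:
    top = traj.topology
    idx = calpha_sel.resolve(top)
    C = correlation_matrix(traj, calpha_sel, align=align)
    P, edges = persistence_graph(traj, calpha_sel, cutoff=cutoff,
                                 fraction=fraction, mode=mode,
                                 exclude_neighbors=exclude_neighbors)
    nodes = [(str(top.chain_id[i]), int(top.residue_index[i]), str(top.tag[i]))
             for i in idx]
    G = nx.Graph()
    G.add_nodes_from(range(len(nodes)))
    for i, j in edges:
        strength = abs(float(C[i, j]))
        w = -np.log(max(strength, MIN_ABS_CORRELATION))
        G.add_edge(i, j, corr=float(C[i, j]), strength=strength,
                   distance=float(w), persistence=float(P[i, j]))
    return CorrelationNetwork(nodes=nodes, C=C, persistence=P, edges=edges,
                              graph=G)


def _modularity(G: nx.Graph, parts: Sequence[set[int]]) -> float:
    total = sum(d.get("strength", 0.0) for _, _, d in G.edges(data=True))
    weight = "strength" if total > 0 else None
    return nx.algorithms.community.modularity(G, parts, weight=weight)


def _heaviest_betweenness_edge(G: nx.Graph):
    bet = nx.edge_betweenness_centrality(G, weight="distance")

    # ties (common in dense graphs, where every pair uses its direct edge)
    # break toward the longest = weakest-correlation edge, then edge id
    def key(e):
        return (round(bet[e], 12), G.edges[e].get("distance", 0.0), e)

    return max(sorted(bet), key=key)


def _refine_partition(G: nx.Graph, parts: list[set[int]], q: float
                      ) -> tuple[list[set[int]], float]:
    """Deterministic greedy single-node refinement of a partition.

    Divisive edge-betweenness only reaches hierarchical splits; moving one
    node at a time between communities (or into a fresh singleton) while
    modularity improves recovers the optima such divisions miss.  Nodes are
    scanned in ascending order; the best improving move is applied each
    sweep until a fixed point.
    """
    parts = [set(p) for p in parts if p]
    improved = True
    while improved:
        improved = False
        for node in sorted(G.nodes):
            src = next(i for i, p in enumerate(parts) if node in p)
            best_move, best_gain = None, 1e-12
            targets = list(range(len(parts)))
            if len(parts[src]) > 1:
                targets.append(len(parts))      # fresh singleton
            for dst in targets:
                if dst == src:
                    continue
                trial = [set(p) for p in parts] + ([set()] if dst == len(parts) else [])
                trial[src].discard(node)
                trial[dst].add(node)
                trial = [p for p in trial if p]
                q_new = _modularity(G, trial)
                if q_new - q > best_gain:
                    best_gain, best_move = q_new - q, trial
            if best_move is not None:
                parts, q = best_move, q + best_gain
                improved = True
    return parts, q


def detect_communities(net: CorrelationNetwork
                       ) -> tuple[dict[int, int], float]:
    """Girvan-Newman division maximising strength-weighted modularity.

    Edge removal order follows betweenness computed with the -log|C| edge
    lengths.  The candidate partitions are the initial connected components
    plus every division level; ties on Q prefer fewer communities.  Isolated
    nodes always form singleton communities.  Community ids are assigned in
    order of each community's smallest node index.  Returns (partition, Q)
    and stores both on ``net``.
    """
    G = net.graph
    n = G.number_of_nodes()
    if G.number_of_edges() == 0:
        partition = {i: i for i in range(n)}
        net.partition, net.modularity = partition, 0.0
        return partition, 0.0

    def as_sets(comp) -> list[set[int]]:
        return [set(c) for c in comp]

    candidates = [as_sets(nx.connected_components(G))]
    gn = nx.algorithms.community.girvan_newman(
        G, most_valuable_edge=_heaviest_betweenness_edge)
    for level in gn:
        candidates.append(as_sets(level))
    # divisive sequences only reach hierarchical splits; add agglomerative
    # and Louvain candidates (fixed seeds) so the modularity scan is robust
    total = sum(d.get("strength", 0.0) for _, _, d in G.edges(data=True))
    w = "strength" if total > 0 else None
    candidates.append(as_sets(
        nx.algorithms.community.greedy_modularity_communities(G, weight=w)))
    for seed in range(8):
        candidates.append(as_sets(
            nx.algorithms.community.louvain_communities(G, weight=w, seed=seed)))

    best, best_q = None, -np.inf
    for parts in candidates:
        q = _modularity(G, parts)
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12
                                  and best is not None
                                  and len(parts) < len(best)):
            best, best_q = parts, q

    best, best_q = _refine_partition(G, best, best_q)
    best.sort(key=lambda s: min(s))
    partition = {node: cid for cid, comm in enumerate(best) for node in comm}
    net.partition, net.modularity = partition, float(best_q)
    return partition, float(best_q)


def community_report(net: CorrelationNetwork, topology: Topology
                     ) -> pd.DataFrame:
    """Per-domain-tag table of the community ids its residues occupy."""
    if net.partition is None:
        detect_communities(net)
    rows = []
    by_tag: dict[str, set[int]] = {}
    for i, (_, _, tag) in enumerate(net.nodes):
        by_tag.setdefault(tag, set()).add(net.partition[i])
    for tag in sorted(by_tag):
        cids = sorted(by_tag[tag])
        rows.append({"tag": tag, "communities": ",".join(map(str, cids)),
                     "n_communities": len(cids)})
    return pd.DataFrame(rows)


def covering_count(net: CorrelationNetwork, tags: Sequence[str]) -> int:
    """Number of distinct communities covering the residues of a tag set.

    This is the coupled-vs-decoupled observable: a single community covering
    {S4, S4-S5 linker, S6, pre-Helix-A} indicates correlated VSD-pore motion;
    several communities indicate decoupling.
    """
    if net.partition is None:
        detect_communities(net)
    tagset = set(tags)
    cids = {net.partition[i] for i, (_, _, tag) in enumerate(net.nodes)
            if tag in tagset}
    return len(cids)
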