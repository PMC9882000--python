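"""Degree-preserving hetnet permutation via XSwap.

XSwap repeatedly picks two edges (a, b) and (c, d) and exchanges their
endpoints to (a, d) and (c, b), rejecting any swap that would create a
self-loop or a duplicate edge. Every node keeps its exact degree, so permuted
networks retain degree effects while the specific pairings are randomized —
the null model against which observed DWPCs are compared. Applied to a hetnet,
XSwap runs independently on each metaedge's edge list.
"""

from __future__ import annotations

import zlib
from typing import Iterator

import numpy as np

from .hetnet_core import HetnetStore, Metaedge

__all__ = [
    "xswap_metaedge",
    "permute_store",
    "generate_permutations",
    "PermutedStore",
]


class PermutedStore(HetnetStore):
    """A permuted hetnet plus provenance of how it was generated."""

    def __init__(self, metagraph, provenance: dict):
        super().__init__(metagraph)
        self.provenance = provenance


def xswap_metaedge(
    edges: list[tuple[int, int]],
    seed: int,
    multiplier: float = 10.0,
    same_metanode: bool = False,
    directed: bool = False,
) -> tuple[list[tuple[int, int]], dict]:
    """XSwap one metaedge's edge list; returns (new edges, swap statistics).

    ``same_metanode`` marks edges whose endpoints share a metanode (self-loops
    forbidden); undirected same-metanode edges are handled on a canonical
    (min, max) representation so the mirrored matrix stays symmetric. The
    number of attempted swaps is ``multiplier * len(edges)``.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    undirected = same_metanode and not directed

    def canonical(pair: tuple[int, int]) -> tuple[int, int]:
        return (min(pair), max(pair)) if undirected else pair

    edge_list = [canonical(tuple(e)) for e in edges]
    edge_set = set(edge_list)
    if len(edge_set) != len(edge_list):
        raise ValueError("duplicate edges in input")
    if same_metanode and any(a == b for a, b in edge_list):
        raise ValueError("self-loops in input")

    n_edges = len(edge_list)
    attempts = int(round(multiplier * n_edges))
    accepted = 0
    if n_edges >= 2:
        rng = np.random.default_rng(seed)
        pair_idx = rng.integers(0, n_edges, size=(attempts, 2))
        for k in range(attempts):
            i, j = int(pair_idx[k, 0]), int(pair_idx[k, 1])
            if i == j:
                continue
            old1, old2 = edge_list[i], edge_list[j]
            a, b = old1
            c, d = old2
            if same_metanode and (a == d or c == b):
                continue
            new1, new2 = canonical((a, d)), canonical((c, b))
            if new1 == new2 or {new1, new2} == {old1, old2}:
                continue
            edge_set.discard(old1)
            edge_set.discard(old2)
            if new1 in edge_set or new2 in edge_set:
                edge_set.add(old1)
                edge_set.add(old2)
                continue
            edge_list[i], edge_list[j] = new1, new2
            edge_set.add(new1)
            edge_set.add(new2)
            accepted += 1
    stats = {"attempts": attempts, "accepted": accepted, "n_edges": n_edges}
    return edge_list, stats


def _metaedge_seed(base_seed: int, metaedge: Metaedge) -> int:
    """Stable per-metaedge seed so adding metaedges does not reshuffle others."""
    token = f"{base_seed}|{metaedge.full_abbreviation}".encode()
    return zlib.crc32(token) & 0x7FFFFFFF


def _edges_from_matrix(mat: np.ndarray, undirected_same: bool) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(mat)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    if undirected_same:
        pairs = [(i, j) for i, j in pairs if i < j]
    return pairs


def permute_store(
    store: HetnetStore, seed: int, multiplier: float = 10.0
) -> PermutedStore:
    """XSwap every metaedge of a store independently.

    Node tables are shared with the base store; per-node per-metaedge degrees
    are preserved exactly.
    """
    provenance = {
        "base_fingerprint": store.fingerprint(),
        "seed": seed,
        "multiplier": multiplier,
        "metaedges": {},
    }
    permuted = PermutedStore(store.metagraph, provenance)
    for mn in store.metagraph.metanodes:
        table = store.nodes(mn)
        permuted.set_nodes(mn, table["identifier"], table["name"])
    for me in store.metaedges_present():
        mat = np.asarray(store.adjacency(me))
        undirected_same = me.is_same_metanode and not me.directed
        edges = _edges_from_matrix(mat, undirected_same)
        new_edges, stats = xswap_metaedge(
            edges,
            seed=_metaedge_seed(seed, me),
            multiplier=multiplier,
            same_metanode=me.is_same_metanode,
            directed=me.directed,
        )
        new_mat = np.zeros_like(mat)
        for i, j in new_edges:
            new_mat[i, j] = 1
            if undirected_same:
                new_mat[j, i] = 1
        permuted.set_adjacency(me, new_mat)
        provenance["metaedges"][me.full_abbreviation] = stats
    return permuted


def generate_permutations(
    store: HetnetStore, count: int, base_seed: int, multiplier: float = 10.0
) -> Iterator[PermutedStore]:
    """Yield ``count`` independent permuted stores (seeds ``base_seed + i``)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    for index in range(count):
        yield permute_store(store, seed=base_seed + index, multiplier=multiplier)
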