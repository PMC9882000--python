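"""End-to-end connectivity search between two nodes.

For a query node pair, every metapath of bounded length between their
metanodes is scored: the DWPC is computed, compared to its degree-grouped
permutation null for a p-value, and Bonferroni-adjusted by the number of
same-length metapaths between the two metanodes. Individual paths are then
enumerated for connected metapaths; each path's degree product gives its
share of the DWPC, and the *path score* — that share times -log10 of the
metapath's p-value — ranks paths across metapaths.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dwpc import PathBudgetError, dwpc_matrix
from .hetnet_core import HetnetStore, Metanode, Metapath, degree_weighted_adjacency
from .metapaths import count_metapaths, enumerate_metapaths
from .null_model import NullCatalog, bonferroni_adjust, dwpc_pvalue

__all__ = [
    "path_degree_product",
    "enumerate_paths",
    "path_score",
    "storage_threshold",
    "connectivity_search",
    "PathRow",
    "METAPATH_COLUMNS",
    "PATH_COLUMNS",
]

METAPATH_COLUMNS = [
    "metapath",
    "path_count",
    "dwpc",
    "p_value",
    "adjusted_p_value",
    "source_degree",
    "target_degree",
    "n_dwpcs",
    "n_nonzero_dwpcs",
    "nonzero_mean",
    "nonzero_sd",
]
PATH_COLUMNS = ["path", "path_score", "percent_of_dwpc", "pdp"]

# -log10 cap used when an empirical p-value of exactly zero is scored
LOG10_P_CAP = 320.0


@dataclass
class PathRow:
    nodes: tuple[str, ...]
    metapath_abbreviation: str
    pdp: float
    percent_of_dwpc: float
    path_score: float | None = None

    @property
    def path(self) -> str:
        return "-".join(self.nodes)


def path_degree_product(
    store: HetnetStore, path: list[str], metapath: Metapath, w: float
) -> float:
    """Product over the path's edges of (source degree * target degree)**-w.

    ``path`` lists node identifiers, one per metapath position; nodes of the
    same metanode must be distinct and every consecutive pair must be joined
    by the corresponding metaedge.
    """
    metanodes = metapath.metanodes
    if len(path) != len(metanodes):
        raise ValueError(
            f"path has {len(path)} nodes but metapath {metapath.abbreviation} "
            f"has {len(metanodes)} positions"
        )
    seen: dict[str, set[str]] = {}
    positions = []
    for identifier, mn in zip(path, metanodes):
        used = seen.setdefault(mn.abbreviation, set())
        if identifier in used:
            raise ValueError(f"duplicate node {identifier!r} in path")
        used.add(identifier)
        positions.append(store.node_position(mn, identifier))
    pdp = 1.0
    for step, i, j in zip(metapath.steps, positions, positions[1:]):
        adj = store.step_adjacency(step)
        if not adj[i, j]:
            raise ValueError(
                f"no {step.metaedge} edge between {path[positions.index(i)]!r} "
                f"and the next node in the path"
            )
        src_deg, tgt_deg = store.step_degrees(step)
        pdp *= (src_deg[i] * tgt_deg[j]) ** -w
    return float(pdp)


def enumerate_paths(
    store: HetnetStore,
    source: str,
    target: str,
    metapath: Metapath,
    w: float,
    path_budget: int | None = 1_000_000,
) -> list[PathRow]:
    """All simple paths of a metapath between two nodes, with each path's
    degree product and share of the DWPC (shares sum to one)."""
    metanodes = metapath.metanodes
    start = store.node_position(metanodes[0], source)
    goal = store.node_position(metanodes[-1], target)
    mats = []
    for step in metapath.steps:
        damped = degree_weighted_adjacency(store, step.metaedge, w)
        mats.append(damped.matrix.T if step.inverted else damped.matrix)
    type_seq = [mn.abbreviation for mn in metanodes]
    id_tables = [store.nodes(mn)["identifier"].to_list() for mn in metanodes]
    found: list[tuple[tuple[str, ...], float]] = []
    budget = [0]

    def dfs(depth: int, node: int, weight: float, visited: dict, trail: list[int]):
        if path_budget is not None:
            budget[0] += 1
            if budget[0] > path_budget:
                raise PathBudgetError(
                    f"path enumeration exceeded budget of {path_budget} visits"
                )
        if depth == len(metapath.steps):
            if node == goal:
                nodes = tuple(
                    id_tables[k][trail[k]] for k in range(len(trail))
                )
                found.append((nodes, weight))
            return
        mn = type_seq[depth + 1]
        used = visited.get(mn, frozenset())
        row = mats[depth][node]
        for nxt in np.nonzero(row)[0]:
            nxt = int(nxt)
            if nxt in used:
                continue
            visited[mn] = used | {nxt}
            trail.append(nxt)
            dfs(depth + 1, nxt, weight * float(row[nxt]), visited, trail)
            trail.pop()
        visited[mn] = used

    dfs(0, start, 1.0, {type_seq[0]: frozenset({start})}, [start])
    total = sum(weight for _, weight in found)
    rows = [
        PathRow(
            nodes=nodes,
            metapath_abbreviation=metapath.abbreviation,
            pdp=weight,
            percent_of_dwpc=(weight / total) if total > 0 else 0.0,
        )
        for nodes, weight in found
    ]
    rows.sort(key=lambda r: (-r.pdp, r.nodes))
    return rows


def path_score(percent_of_dwpc: float, p_value: float) -> float:
    """Share of the DWPC times the magnitude (-log10) of its p-value.

    A p-value of exactly zero (empirical rule for an all-zero null) is capped
    so the score stays finite.
    """
    if not (0.0 <= percent_of_dwpc <= 1.0):
        raise ValueError("percent_of_dwpc must be in [0, 1]")
    if not (0.0 <= p_value <= 1.0):
        raise ValueError("p_value must be in [0, 1]")
    magnitude = LOG10_P_CAP if p_value == 0 else -math.log10(p_value)
    return percent_of_dwpc * min(magnitude, LOG10_P_CAP)


def storage_threshold(n_source: int, n_target: int, length: int) -> float | None:
    """Adjusted-p threshold for retaining a metapath's DWPCs in a database.

    Length-1 metapaths return None, the store-all-nonzero sentinel (direct
    edges are always kept); longer metapaths use ``5 * (n_source *
    n_target) ** -0.3``, penalizing metapaths with many possible node pairs.
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("node counts must be >= 1")
    if length == 1:
        return None
    return 5.0 * float(n_source * n_target) ** -0.3


def _locate_node(store: HetnetStore, identifier: str) -> tuple[Metanode, int]:
    candidates = []
    for mn in store.metagraph.metanodes:
        try:
            table = store.nodes(mn)
        except (KeyError, FileNotFoundError):
            continue
        match = table.index[table["identifier"] == identifier]
        if len(match):
            return mn, int(match[0])
        candidates.extend(table["identifier"].to_list())
    near = difflib.get_close_matches(identifier, candidates, n=3)
    raise LookupError(
        f"node {identifier!r} not found"
        + (f"; near matches: {', '.join(near)}" if near else "")
    )


def _oriented_metapaths_between(
    metagraph, mn_a: Metanode, mn_b: Metanode, max_length: int
) -> list[Metapath]:
    """Metapaths oriented from mn_a to mn_b, each oriented family once.

    For distinct endpoint metanodes this is one orientation per canonical
    metapath; when both endpoints share a metanode, a non-palindromic
    metapath and its reverse are genuinely different templates from a to b
    and both are returned (with reversed abbreviations), still counted once
    each.
    """
    out: list[Metapath] = []
    for mp in enumerate_metapaths(metagraph, max_length):
        if {mp.source, mp.target} != {mn_a, mn_b}:
            continue
        if mp.source == mn_a:
            out.append(mp)
        if mn_a == mn_b:
            rev = mp.reverse()
            if rev != mp:
                out.append(rev)
        elif mp.source != mn_a:
            out.append(mp.reverse())
    return out


def connectivity_search(
    store: HetnetStore,
    nulls: NullCatalog,
    node_a: str,
    node_b: str,
    max_length: int = 3,
    w: float | None = None,
    apply_storage_filter: bool = False,
    path_budget: int | None = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank metapaths between two nodes, then the paths that drive them.

    Returns (metapath rows, path rows): metapaths sorted by adjusted p-value
    (ties: DWPC descending, then abbreviation), paths merged across connected
    metapaths and sorted by path score descending. ``w`` defaults to the
    damping exponent the null catalog was built with.
    """
    if w is None:
        w = nulls.w
    mn_a, _ = _locate_node(store, node_a)
    mn_b, _ = _locate_node(store, node_b)
    metagraph = store.metagraph
    records = []
    path_rows: list[PathRow] = []
    for mp in _oriented_metapaths_between(metagraph, mn_a, mn_b, max_length):
        result = dwpc_matrix(store, mp, w=w)
        counts = dwpc_matrix(store, mp, w=0)
        i = store.node_position(mp.source, node_a)
        j = store.node_position(mp.target, node_b)
        dwpc = float(result.matrix[i, j])
        path_count = int(counts.matrix[i, j])
        src_deg, _ = store.step_degrees(mp.steps[0])
        _, tgt_deg = store.step_degrees(mp.steps[-1])
        d_s, d_t = int(src_deg[i]), int(tgt_deg[j])
        row = nulls.group_row(mp, d_s, d_t)
        if row is None:
            row = {
                "n_dwpcs": 0.0,
                "n_nonzero_dwpcs": 0.0,
                "sum": 0.0,
                "sum_of_squares": 0.0,
            }
        sig = dwpc_pvalue(dwpc, row)
        adjusted = bonferroni_adjust(
            sig.p_value, metagraph, mp.source, mp.target, mp.length
        )
        records.append(
            {
                "metapath": mp.abbreviation,
                "path_count": path_count,
                "dwpc": dwpc,
                "p_value": sig.p_value,
                "adjusted_p_value": adjusted,
                "source_degree": d_s,
                "target_degree": d_t,
                "n_dwpcs": int(row["n_dwpcs"]),
                "n_nonzero_dwpcs": int(row["n_nonzero_dwpcs"]),
                "nonzero_mean": sig.nonzero_mean,
                "nonzero_sd": sig.nonzero_sd,
                "_length": mp.length,
            }
        )
        if dwpc > 0:
            keep = True
            if apply_storage_filter:
                threshold = storage_threshold(
                    store.n_nodes(mp.source), store.n_nodes(mp.target), mp.length
                )
                keep = threshold is None or adjusted < threshold
            if keep:
                try:
                    rows = enumerate_paths(
                        store, node_a, node_b, mp, w, path_budget=path_budget
                    )
                except PathBudgetError:
                    rows = []
                for prow in rows:
                    prow.path_score = path_score(prow.percent_of_dwpc, sig.p_value)
                path_rows.extend(rows)
    metapath_frame = pd.DataFrame(records)
    if len(metapath_frame):
        metapath_frame = metapath_frame.sort_values(
            ["adjusted_p_value", "dwpc", "metapath"],
            ascending=[True, False, True],
            kind="stable",
        ).reset_index(drop=True)
        metapath_frame = metapath_frame[METAPATH_COLUMNS]
    else:
        metapath_frame = pd.DataFrame(columns=METAPATH_COLUMNS)
    path_frame = pd.DataFrame(
        [
            {
                "path": prow.path,
                "path_score": prow.path_score,
                "percent_of_dwpc": prow.percent_of_dwpc,
                "pdp": prow.pdp,
                "metapath": prow.metapath_abbreviation,
            }
            for prow in path_rows
        ]
    )
    if len(path_frame):
        path_frame = path_frame.sort_values(
            ["path_score", "path"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    else:
        path_frame = pd.DataFrame(columns=PATH_COLUMNS + ["metapath"])
    return metapath_frame, path_frame
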