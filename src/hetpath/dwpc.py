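"""Degree-weighted path counts (DWPCs) via corrected matrix multiplication.

The DWPC between a source and a target node along a metapath is the sum, over
all *simple* paths conforming to the metapath, of each path's degree product:
the product over traversed edges of ``(d_source * d_target) ** -w``, with
metaedge-specific degrees. With damping exponent ``w = 0`` the DWPC reduces to
the plain path count.

Chained products of damped adjacency matrices count walks, so repeated
metanodes require corrections that remove walks revisiting a node:

* a single metanode repeated two or three times (``XaXbX``): multiply the
  sub-segment DWPCs between consecutive occurrences and subtract the diagonal
  of each partial product (walks returning to an earlier node). Applying the
  correction recursively to sub-segments also covers nested ``BAAB`` patterns.
* an exact ``XYXY`` interleaving: inclusion-exclusion over the two possible
  coincidences, with a Hadamard term adding back doubly-coincident walks.
* anything else (four or more occurrences of one metanode, ``ABCABC``-style
  interleavings): no closed form is used; the segment is computed by explicit
  simple-path enumeration.

An approximate variant replaces the enumeration fallback with a correction of
only the first repeat, which never undercounts the exact DWPC.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from .hetnet_core import HetnetStore, Metapath, degree_weighted_adjacency
from .metapaths import (
    RepeatGroup,
    _group_kind,
    _shift_groups,
    masked_subsequence,
    repeat_groups,
)

__all__ = [
    "DwpcMatrix",
    "PathBudgetError",
    "dwpc_matrix",
    "dwpc_short_repeat",
    "dwpc_nested",
    "dwpc_overlapping",
    "dwpc_by_enumeration",
    "dwpc_approximate",
]


class PathBudgetError(RuntimeError):
    """Raised when path enumeration exceeds its configured budget."""


@dataclass
class DwpcMatrix:
    """A (source-metanode x target-metanode) matrix of path counts or DWPCs."""

    metapath: Metapath
    w: float
    matrix: np.ndarray
    kind: str  # "path-count" or "dwpc"
    method: str = "matrix"
    approximate: bool = False


def _finalize(metapath: Metapath, w: float, matrix: np.ndarray, method: str,
              approximate: bool = False) -> DwpcMatrix:
    # inclusion-exclusion corrections can leave -1e-17-scale round-off
    matrix = np.where((matrix < 0) & (matrix > -1e-8), 0.0, matrix)
    if w == 0:
        matrix = np.rint(matrix).astype(np.int64)
        kind = "path-count"
    else:
        kind = "dwpc"
    return DwpcMatrix(
        metapath=metapath, w=w, matrix=matrix, kind=kind,
        method=method, approximate=approximate,
    )


def _diag_removed(matrix: np.ndarray) -> np.ndarray:
    out = matrix.copy()
    np.fill_diagonal(out, 0.0)
    return out


def dwpc_short_repeat(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Correction for the ``XaXbX`` pattern: product minus its diagonal.

    ``d1`` and ``d2`` are DWPC matrices over the same metanode with zero
    diagonals (so the first and middle, and middle and last, occurrences are
    already distinct); subtracting the diagonal of the product removes walks
    whose first and last nodes coincide.
    """
    if d1.shape[0] != d1.shape[1] or d1.shape != d2.shape:
        raise ValueError(f"expected equal square matrices, got {d1.shape}, {d2.shape}")
    return _diag_removed(d1 @ d2)


def dwpc_nested(d_xy: np.ndarray, d_yy: np.ndarray, d_yx: np.ndarray) -> np.ndarray:
    """Correction for the nested ``XaYbYcX`` pattern.

    The inner Y repeat is excluded by ``d_yy``'s zero diagonal; subtracting the
    diagonal of the triple product removes walks whose outer X endpoints
    coincide.
    """
    if d_xy.shape[1] != d_yy.shape[0] or d_yy.shape[1] != d_yx.shape[0]:
        raise ValueError("shapes do not conform for nested-repeat correction")
    return _diag_removed(d_xy @ d_yy @ d_yx)


def dwpc_overlapping(
    d_xy: np.ndarray, d_yx: np.ndarray, d_xy2: np.ndarray
) -> np.ndarray:
    """Correction for the overlapping ``XaYbXcY`` pattern.

    Inclusion-exclusion over the coincidences x1 = x3 and y2 = y4: subtract
    walks where either pair coincides (the two diagonal terms), then add back
    walks where both coincide (the Hadamard term).
    """
    if (
        d_xy.shape != d_xy2.shape
        or d_yx.shape != (d_xy.shape[1], d_xy.shape[0])
    ):
        raise ValueError("shapes do not conform for overlapping-repeat correction")
    full = d_xy @ d_yx @ d_xy2
    corr_x = np.diag(np.diag(d_xy @ d_yx)) @ d_xy2
    corr_y = d_xy @ np.diag(np.diag(d_yx @ d_xy2))
    both = d_xy * d_yx.T * d_xy2
    return full - corr_x - corr_y + both


class _Computer:
    """Recursive DWPC evaluation over one metapath's damped step matrices."""

    def __init__(
        self,
        store: HetnetStore,
        metapath: Metapath,
        w: float,
        approximate: bool = False,
        path_budget: int | None = None,
        cache: "DwpcCache | None" = None,
    ):
        self.store = store
        self.metapath = metapath
        self.w = w
        self.approximate = approximate
        self.path_budget = path_budget
        self.cache = cache
        self.used_enumeration = False
        self.steps = metapath.steps
        self.types = [mn.abbreviation for mn in metapath.metanodes]
        self.mats: list[np.ndarray] = []
        for step in self.steps:
            damped = degree_weighted_adjacency(store, step.metaedge, w)
            mat = damped.matrix.T if step.inverted else damped.matrix
            self.mats.append(mat)

    def compute(self) -> np.ndarray:
        return self._rec(0, len(self.types) - 1, skip_endpoint_pair=False)

    # -- recursion -----------------------------------------------------------

    def _cache_key(self, lo: int, hi: int, skip: bool) -> tuple:
        abbrev = (
            "".join(s.abbreviation_part for s in self.steps[lo:hi])
            + self.steps[hi - 1].target.abbreviation
        )
        return (abbrev, self.w, skip, self.approximate)

    def _rec(self, lo: int, hi: int, skip_endpoint_pair: bool) -> np.ndarray:
        key = None
        if self.cache is not None:
            key = self._cache_key(lo, hi, skip_endpoint_pair)
            hit = self.cache.get(key)
            if hit is not None:
                return hit.copy()
        sub = masked_subsequence(self.types, lo, hi, skip_endpoint_pair)
        groups = _shift_groups(repeat_groups(sub), lo)
        if not groups:
            out = self._plain(lo, hi)
        else:
            out = None
            pos = lo
            for group in groups:
                if pos < group.start:
                    out = self._matmul(out, self._plain(pos, group.start))
                out = self._matmul(out, self._group(group))
                pos = group.end
            if pos < hi:
                out = self._matmul(out, self._plain(pos, hi))
        if self.cache is not None:
            self.cache.put(key, out.copy())
        return out

    def _plain(self, lo: int, hi: int) -> np.ndarray:
        out = self.mats[lo]
        for i in range(lo + 1, hi):
            out = out @ self.mats[i]
        return out

    @staticmethod
    def _matmul(left: np.ndarray | None, right: np.ndarray) -> np.ndarray:
        return right if left is None else left @ right

    def _group(self, group: RepeatGroup) -> np.ndarray:
        kind = _group_kind(group, self.types)
        occ = dict(group.occurrences)
        if kind == "short-repeat":
            anchors = list(occ[self.types[group.start]])
            out = None
            for a, b in zip(anchors, anchors[1:]):
                part = _diag_removed(self._rec(a, b, skip_endpoint_pair=True))
                if out is None:
                    out = part
                else:
                    out = _diag_removed(out @ part)
            return out
        if kind == "overlapping":
            p1, p3 = occ[self.types[group.start]]
            p2, p4 = occ[self.types[group.end]]
            f1 = self._rec(p1, p2, skip_endpoint_pair=False)
            f2 = self._rec(p2, p3, skip_endpoint_pair=False)
            f3 = self._rec(p3, p4, skip_endpoint_pair=False)
            return dwpc_overlapping(f1, f2, f3)
        # complex group
        if self.approximate:
            return self._first_repeat_only(group)
        self.used_enumeration = True
        return _enumerate_range(
            self.store, self.steps, self.mats, group.start, group.end,
            self.path_budget,
        )

    def _first_repeat_only(self, group: RepeatGroup) -> np.ndarray:
        """Correct only the first repeat of a complex group; walks through the
        remaining repeats are left uncorrected, so the result never falls
        below the exact DWPC."""
        occ = dict(group.occurrences)
        first = min(occ.items(), key=lambda item: item[1][0])
        q0, q1 = first[1][0], first[1][1]
        out = None
        if group.start < q0:
            out = self._plain(group.start, q0)
        mid = _diag_removed(self._plain(q0, q1))
        out = self._matmul(out, mid)
        if q1 < group.end:
            out = out @ self._plain(q1, group.end)
        return out


class DwpcCache:
    """LRU cache of segment DWPC matrices, keyed per store fingerprint.

    Caching is semantically invisible: entries are copied on the way in and
    out, and the key includes the segment abbreviation, damping exponent and
    correction mode.
    """

    def __init__(self, max_entries: int = 128):
        self.max_entries = max_entries
        self._data: OrderedDict[tuple, np.ndarray] = OrderedDict()

    def get(self, key: tuple) -> np.ndarray | None:
        if key in self._data:
            self._data.move_to_end(key)
            return self._data[key]
        return None

    def put(self, key: tuple, value: np.ndarray) -> None:
        self._data[key] = value
        self._data.move_to_end(key)
        while len(self._data) > self.max_entries:
            self._data.popitem(last=False)


_store_caches: dict[str, DwpcCache] = {}


def _cache_for(store: HetnetStore) -> DwpcCache:
    fp = store.fingerprint()
    if fp not in _store_caches:
        if len(_store_caches) > 16:
            _store_caches.clear()
        _store_caches[fp] = DwpcCache()
    return _store_caches[fp]


def dwpc_matrix(
    store: HetnetStore,
    metapath: Metapath,
    w: float = 0.5,
    method: str = "auto",
    path_budget: int | None = 2_000_000,
    use_cache: bool = False,
) -> DwpcMatrix:
    """DWPC matrix for a metapath over all source-target node pairs.

    ``method="auto"`` dispatches on the repeat pattern: closed-form matrix
    corrections where they exist, explicit enumeration for complex segments.
    ``method="enumeration"`` forces the exhaustive simple-path method (the
    oracle), and ``method="approximate"`` uses the first-repeat-only
    correction for complex segments.
    """
    if w < 0:
        raise ValueError("damping exponent must be non-negative")
    if method not in ("auto", "enumeration", "approximate"):
        raise ValueError(f"unknown method {method!r}")
    if method == "enumeration":
        return dwpc_by_enumeration(store, metapath, w, path_budget=path_budget)
    if method == "approximate":
        return dwpc_approximate(store, metapath, w, use_cache=use_cache)
    computer = _Computer(
        store, metapath, w,
        path_budget=path_budget,
        cache=_cache_for(store) if use_cache else None,
    )
    matrix = computer.compute()
    label = "matrix+enumeration" if computer.used_enumeration else "matrix"
    return _finalize(metapath, w, matrix, method=label)


def dwpc_approximate(
    store: HetnetStore, metapath: Metapath, w: float = 0.5, use_cache: bool = False
) -> DwpcMatrix:
    """Approximate DWPC: exact on segmentable patterns, first-repeat-only
    correction on complex ones (flagged ``approximate`` in the result)."""
    computer = _Computer(
        store, metapath, w, approximate=True,
        cache=_cache_for(store) if use_cache else None,
    )
    matrix = computer.compute()
    return _finalize(metapath, w, matrix, method="approximate", approximate=True)


def dwpc_by_enumeration(
    store: HetnetStore,
    metapath: Metapath,
    w: float = 0.5,
    path_budget: int | None = 2_000_000,
) -> DwpcMatrix:
    """Exact DWPC by exhaustive simple-path traversal.

    Valid for every repeat pattern; serves as the independent oracle for the
    matrix corrections. Cost grows with the number of walks, so a budget caps
    the traversal.
    """
    if w < 0:
        raise ValueError("damping exponent must be non-negative")
    computer = _Computer(store, metapath, w)
    matrix = _enumerate_range(
        store, metapath.steps, computer.mats, 0, len(metapath.steps), path_budget
    )
    return _finalize(metapath, w, matrix, method="enumeration")


def _enumerate_range(
    store: HetnetStore,
    steps,
    mats: list[np.ndarray],
    lo: int,
    hi: int,
    path_budget: int | None,
) -> np.ndarray:
    """Simple-path DFS over steps lo..hi-1 with damped edge weights.

    Nodes may not repeat within a metanode; nodes of different metanodes are
    always distinct. Returns the (source x target) accumulation matrix.
    """
    sub_steps = steps[lo:hi]
    sub_mats = mats[lo:hi]
    type_seq = [sub_steps[0].source.abbreviation] + [
        s.target.abbreviation for s in sub_steps
    ]
    n_src = sub_mats[0].shape[0]
    n_tgt = sub_mats[-1].shape[1]
    out = np.zeros((n_src, n_tgt))
    # adjacency lists of (neighbor, weight) per step
    neighbors: list[list[list[tuple[int, float]]]] = []
    for mat in sub_mats:
        rows = []
        for i in range(mat.shape[0]):
            nz = np.nonzero(mat[i])[0]
            rows.append([(int(j), float(mat[i, j])) for j in nz])
        neighbors.append(rows)
    budget = [0]

    def dfs(depth: int, node: int, weight: float, visited: dict, start: int):
        if path_budget is not None:
            budget[0] += 1
            if budget[0] > path_budget:
                raise PathBudgetError(
                    f"path enumeration exceeded budget of {path_budget} visits"
                )
        if depth == len(sub_steps):
            out[start, node] += weight
            return
        mn = type_seq[depth + 1]
        used = visited.get(mn, frozenset())
        for nxt, wgt in neighbors[depth][node]:
            if nxt in used:
                continue
            visited[mn] = used | {nxt}
            dfs(depth + 1, nxt, weight * wgt, visited, start)
        visited[mn] = used

    start_mn = type_seq[0]
    for start in range(n_src):
        dfs(0, start, 1.0, {start_mn: frozenset({start})}, start)
    return out
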