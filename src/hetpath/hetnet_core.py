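"""Core data model for heterogeneous networks ("hetnets").

A hetnet is a graph whose nodes and edges carry types. The type layer is the
*metagraph*: metanodes (node types) connected by metaedges (edge types). Each
metaedge is materialized as one biadjacency matrix whose rows index the source
metanode's nodes and whose columns index the target metanode's nodes. A
*metapath* is a composable sequence of metaedge traversals and is the template
along which paths between two nodes are counted.

Stores live on disk as a directory: a ``metagraph.json`` schema, one TSV node
table per metanode, and one matrix file per metaedge (dense ``.npy`` or sparse
``.sparse.npz``, chosen by density). Matrices are loaded lazily so large
networks need not fit in memory at once.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

__all__ = [
    "Metanode",
    "Metaedge",
    "Metagraph",
    "Metapath",
    "DampedAdjacency",
    "HetnetStore",
    "HetnetFormatError",
    "load_store",
    "save_store",
    "metaedge_degrees",
    "degree_weighted_adjacency",
    "store_from_edge_list",
]


class HetnetFormatError(ValueError):
    """A hetnet directory or matrix violates the storage invariants."""


@dataclass(frozen=True)
class Metanode:
    """A node type, e.g. Gene (abbreviated ``G``)."""

    identifier: str
    abbreviation: str

    def __post_init__(self) -> None:
        if not self.identifier or not self.abbreviation:
            raise ValueError("metanode identifier and abbreviation must be non-empty")

    def __str__(self) -> str:
        return self.identifier


@dataclass(frozen=True)
class Metaedge:
    """An edge type between two metanodes, e.g. Compound-binds-Gene (``CbG``).

    ``directed`` distinguishes metaedges such as Gene-regulates-Gene whose
    biadjacency matrix is asymmetric even though both endpoints share a
    metanode.
    """

    source: Metanode
    target: Metanode
    kind: str
    abbreviation: str
    directed: bool = False

    @property
    def full_abbreviation(self) -> str:
        """Abbreviation including endpoint metanodes, e.g. ``CbG`` or ``Gr>G``."""
        mark = ">" if self.directed else ""
        return f"{self.source.abbreviation}{self.abbreviation}{mark}{self.target.abbreviation}"

    @property
    def is_same_metanode(self) -> bool:
        return self.source == self.target

    def __str__(self) -> str:
        return self.full_abbreviation


@dataclass(frozen=True)
class MetapathStep:
    """One traversal of a metaedge, possibly against its stored orientation."""

    metaedge: Metaedge
    inverted: bool = False

    def __post_init__(self) -> None:
        # An undirected same-metanode metaedge has a single orientation.
        if self.inverted and self.metaedge.is_same_metanode and not self.metaedge.directed:
            object.__setattr__(self, "inverted", False)

    @property
    def source(self) -> Metanode:
        return self.metaedge.target if self.inverted else self.metaedge.source

    @property
    def target(self) -> Metanode:
        return self.metaedge.source if self.inverted else self.metaedge.target

    @property
    def abbreviation_part(self) -> str:
        """Source metanode plus edge-kind abbreviation with direction marks."""
        me = self.metaedge
        if not me.directed:
            return f"{self.source.abbreviation}{me.abbreviation}"
        if self.inverted:
            return f"{self.source.abbreviation}<{me.abbreviation}"
        return f"{self.source.abbreviation}{me.abbreviation}>"

    def reverse(self) -> "MetapathStep":
        return MetapathStep(self.metaedge, not self.inverted)


class Metapath:
    """An ordered, composable sequence of metaedge traversals."""

    __slots__ = ("steps", "_abbrev")

    def __init__(self, steps: Sequence[MetapathStep]):
        steps = tuple(steps)
        if not steps:
            raise ValueError("a metapath has at least one step")
        for a, b in zip(steps, steps[1:]):
            if a.target != b.source:
                raise ValueError(
                    f"steps {a.abbreviation_part} and {b.abbreviation_part} do not compose"
                )
        self.steps = steps
        self._abbrev = (
            "".join(s.abbreviation_part for s in steps) + steps[-1].target.abbreviation
        )

    @property
    def abbreviation(self) -> str:
        return self._abbrev

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def source(self) -> Metanode:
        return self.steps[0].source

    @property
    def target(self) -> Metanode:
        return self.steps[-1].target

    @property
    def metanodes(self) -> tuple[Metanode, ...]:
        """The metanode at each of the ``length + 1`` node positions."""
        return (self.steps[0].source,) + tuple(s.target for s in self.steps)

    def reverse(self) -> "Metapath":
        return Metapath(tuple(s.reverse() for s in reversed(self.steps)))

    def is_canonical(self) -> bool:
        return self.abbreviation <= self.reverse().abbreviation

    def canonical(self) -> "Metapath":
        rev = self.reverse()
        return self if self.abbreviation <= rev.abbreviation else rev

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Metapath) and self.abbreviation == other.abbreviation

    def __hash__(self) -> int:
        return hash(self.abbreviation)

    def __lt__(self, other: "Metapath") -> bool:
        return self.abbreviation < other.abbreviation

    def __repr__(self) -> str:
        return f"Metapath({self.abbreviation!r})"


class Metagraph:
    """The type schema: metanodes plus metaedges."""

    def __init__(self, metanodes: Iterable[Metanode], metaedges: Iterable[Metaedge]):
        self.metanodes: tuple[Metanode, ...] = tuple(metanodes)
        self.metaedges: tuple[Metaedge, ...] = tuple(metaedges)
        abbrevs = [mn.abbreviation for mn in self.metanodes]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("metanode abbreviations must be unique")
        self._metanode_by_abbrev = {mn.abbreviation: mn for mn in self.metanodes}
        self._metanode_by_id = {mn.identifier: mn for mn in self.metanodes}
        seen = set()
        for me in self.metaedges:
            key = (me.source, me.target, me.abbreviation)
            if key in seen:
                raise ValueError(f"duplicate metaedge abbreviation for {me}")
            seen.add(key)
        self._metaedge_by_full = {me.full_abbreviation: me for me in self.metaedges}

    def metanode(self, key: str) -> Metanode:
        """Look up a metanode by abbreviation or identifier."""
        if key in self._metanode_by_abbrev:
            return self._metanode_by_abbrev[key]
        if key in self._metanode_by_id:
            return self._metanode_by_id[key]
        raise KeyError(f"unknown metanode {key!r}")

    def metaedge(self, full_abbreviation: str) -> Metaedge:
        try:
            return self._metaedge_by_full[full_abbreviation]
        except KeyError:
            raise KeyError(f"unknown metaedge {full_abbreviation!r}") from None

    def steps_from(self, metanode: Metanode) -> list[MetapathStep]:
        """All oriented metaedge traversals leaving ``metanode``."""
        steps = []
        for me in self.metaedges:
            if me.source == metanode:
                steps.append(MetapathStep(me, inverted=False))
            if me.target == metanode:
                step = MetapathStep(me, inverted=True)
                if step not in steps:
                    steps.append(step)
        return steps

    def metapath_from_abbreviation(self, abbreviation: str) -> Metapath:
        """Parse a metapath abbreviation such as ``CbGpPWpG`` or ``G<rGr>G``."""
        mn_abbrevs = sorted(
            (mn.abbreviation for mn in self.metanodes), key=len, reverse=True
        )
        mn_pattern = "|".join(re.escape(a) for a in mn_abbrevs)
        token = re.compile(f"({mn_pattern})(<?)([a-z]+)(>?)")
        steps: list[MetapathStep] = []
        pos = 0
        while True:
            m = token.match(abbreviation, pos)
            if m is None:
                break
            pos = m.end()
            src = self._metanode_by_abbrev[m.group(1)]
            back, kind_abbrev, fwd = m.group(2), m.group(3), m.group(4)
            # target metanode is the next metanode abbreviation in the string
            nxt = re.compile(f"({mn_pattern})").match(abbreviation, pos)
            if nxt is None:
                raise ValueError(f"cannot parse metapath abbreviation {abbreviation!r}")
            tgt = self._metanode_by_abbrev[nxt.group(1)]
            found = None
            for me in self.metaedges:
                if me.abbreviation != kind_abbrev:
                    continue
                if back and me.directed and me.source == tgt and me.target == src:
                    found = MetapathStep(me, inverted=True)
                elif fwd and me.directed and me.source == src and me.target == tgt:
                    found = MetapathStep(me, inverted=False)
                elif not back and not fwd and not me.directed:
                    if me.source == src and me.target == tgt:
                        found = MetapathStep(me, inverted=False)
                    elif me.source == tgt and me.target == src:
                        found = MetapathStep(me, inverted=True)
                if found is not None:
                    break
            if found is None:
                raise ValueError(
                    f"no metaedge matches segment {m.group(0)!r}->{tgt.abbreviation}"
                    f" in {abbreviation!r}"
                )
            steps.append(found)
        if not steps or pos + len(steps[-1].target.abbreviation) != len(abbreviation):
            raise ValueError(f"cannot parse metapath abbreviation {abbreviation!r}")
        return Metapath(steps)

    def to_dict(self) -> dict:
        return {
            "metanodes": [
                {"identifier": mn.identifier, "abbreviation": mn.abbreviation}
                for mn in self.metanodes
            ],
            "metaedges": [
                {
                    "source": me.source.identifier,
                    "target": me.target.identifier,
                    "kind": me.kind,
                    "abbreviation": me.abbreviation,
                    "directed": me.directed,
                }
                for me in self.metaedges
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Metagraph":
        metanodes = [
            Metanode(d["identifier"], d["abbreviation"]) for d in data["metanodes"]
        ]
        by_id = {mn.identifier: mn for mn in metanodes}
        by_abbrev = {mn.abbreviation: mn for mn in metanodes}

        def resolve(key: str) -> Metanode:
            return by_id.get(key) or by_abbrev[key]

        metaedges = [
            Metaedge(
                source=resolve(d["source"]),
                target=resolve(d["target"]),
                kind=d["kind"],
                abbreviation=d["abbreviation"],
                directed=bool(d.get("directed", False)),
            )
            for d in data["metaedges"]
        ]
        return cls(metanodes, metaedges)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Metagraph) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"Metagraph({len(self.metanodes)} metanodes, {len(self.metaedges)} metaedges)"
        )


@dataclass
class DampedAdjacency:
    """Degree-weighted biadjacency for one metaedge.

    Entry (i, j) equals ``A_ij * (d_i * d_j) ** -w`` where the degrees are the
    metaedge-specific edge counts of node i (source side) and node j (target
    side). Entries where ``A_ij = 0`` are exactly zero, so isolated nodes never
    produce a division by zero, and ``w = 0`` recovers the boolean adjacency.
    """

    metaedge: Metaedge
    w: float
    matrix: np.ndarray
    source_degrees: np.ndarray
    target_degrees: np.ndarray


class HetnetStore:
    """Node tables plus one biadjacency matrix per metaedge.

    Node order within a metanode is fixed (sorted by identifier) at creation.
    When backed by a directory, matrices are read lazily on first access.
    """

    def __init__(
        self,
        metagraph: Metagraph,
        node_tables: Mapping[str, pd.DataFrame] | None = None,
        directory: str | Path | None = None,
    ):
        self.metagraph = metagraph
        self.directory = Path(directory) if directory is not None else None
        self._node_tables: dict[str, pd.DataFrame] = {}
        self._matrices: dict[str, scipy.sparse.spmatrix | np.ndarray] = {}
        if node_tables is not None:
            for abbrev, table in node_tables.items():
                self.set_nodes(self.metagraph.metanode(abbrev), table["identifier"],
                               table.get("name"))

    # -- node tables ---------------------------------------------------------

    def set_nodes(
        self,
        metanode: Metanode,
        identifiers: Iterable[str],
        names: Iterable[str] | None = None,
    ) -> None:
        identifiers = [str(i) for i in identifiers]
        if len(set(identifiers)) != len(identifiers):
            raise HetnetFormatError(
                f"duplicate node identifiers for metanode {metanode.identifier}"
            )
        if names is None:
            names = identifiers
        table = pd.DataFrame({"identifier": identifiers, "name": list(names)})
        table = table.sort_values("identifier", kind="stable").reset_index(drop=True)
        table.insert(0, "position", np.arange(len(table)))
        self._node_tables[metanode.abbreviation] = table

    def nodes(self, metanode: Metanode | str) -> pd.DataFrame:
        mn = self._as_metanode(metanode)
        if mn.abbreviation not in self._node_tables:
            if self.directory is not None:
                self._load_node_table(mn)
            else:
                raise KeyError(f"no node table for metanode {mn.identifier}")
        return self._node_tables[mn.abbreviation]

    def n_nodes(self, metanode: Metanode | str) -> int:
        return len(self.nodes(metanode))

    def node_position(self, metanode: Metanode | str, identifier: str) -> int:
        table = self.nodes(metanode)
        match = table.index[table["identifier"] == identifier]
        if len(match) == 0:
            raise KeyError(
                f"node {identifier!r} not found in metanode "
                f"{self._as_metanode(metanode).identifier}"
            )
        return int(match[0])

    # -- adjacency matrices --------------------------------------------------

    def set_adjacency(self, metaedge: Metaedge | str, matrix) -> None:
        me = self._as_metaedge(metaedge)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.tocsr().astype(np.uint8)
        else:
            matrix = np.asarray(matrix, dtype=np.uint8)
        self._validate_matrix(me, matrix)
        self._matrices[me.full_abbreviation] = matrix

    def adjacency(self, metaedge: Metaedge | str, dense: bool = True) -> np.ndarray:
        """Boolean biadjacency of a metaedge as a 0/1 array."""
        me = self._as_metaedge(metaedge)
        key = me.full_abbreviation
        if key not in self._matrices:
            if self.directory is not None:
                self._load_matrix(me)
            else:
                raise KeyError(f"no adjacency matrix for metaedge {key}")
        mat = self._matrices[key]
        if dense and scipy.sparse.issparse(mat):
            return np.asarray(mat.todense())
        return mat

    def step_adjacency(self, step: MetapathStep) -> np.ndarray:
        mat = self.adjacency(step.metaedge)
        return mat.T if step.inverted else mat

    def metaedges_present(self) -> list[Metaedge]:
        present = []
        for me in self.metagraph.metaedges:
            try:
                self.adjacency(me)
            except (KeyError, FileNotFoundError):
                continue
            present.append(me)
        return present

    # -- derived quantities --------------------------------------------------

    def degrees(self, metaedge: Metaedge | str) -> tuple[np.ndarray, np.ndarray]:
        mat = self.adjacency(metaedge)
        return (
            np.asarray(mat.sum(axis=1)).ravel().astype(np.int64),
            np.asarray(mat.sum(axis=0)).ravel().astype(np.int64),
        )

    def step_degrees(self, step: MetapathStep) -> tuple[np.ndarray, np.ndarray]:
        src, tgt = self.degrees(step.metaedge)
        return (tgt, src) if step.inverted else (src, tgt)

    def fingerprint(self) -> str:
        """Content hash over the metagraph, node tables and loaded matrices."""
        h = hashlib.sha1()
        h.update(json.dumps(self.metagraph.to_dict(), sort_keys=True).encode())
        for mn in self.metagraph.metanodes:
            try:
                table = self.nodes(mn)
            except (KeyError, FileNotFoundError):
                continue
            h.update(mn.abbreviation.encode())
            h.update("\x00".join(table["identifier"]).encode())
        for me in self.metaedges_present():
            h.update(me.full_abbreviation.encode())
            mat = self.adjacency(me)
            h.update(np.ascontiguousarray(mat, dtype=np.uint8).tobytes())
        return h.hexdigest()

    # -- internals -----------------------------------------------------------

    def _as_metanode(self, metanode: Metanode | str) -> Metanode:
        if isinstance(metanode, Metanode):
            return metanode
        return self.metagraph.metanode(metanode)

    def _as_metaedge(self, metaedge: Metaedge | str) -> Metaedge:
        if isinstance(metaedge, Metaedge):
            return metaedge
        return self.metagraph.metaedge(metaedge)

    def _validate_matrix(self, me: Metaedge, matrix) -> None:
        n_src = self.n_nodes(me.source)
        n_tgt = self.n_nodes(me.target)
        if matrix.shape != (n_src, n_tgt):
            raise HetnetFormatError(
                f"metaedge {me}: matrix shape {matrix.shape} does not match node "
                f"counts ({n_src}, {n_tgt})"
            )
        dense = np.asarray(matrix.todense()) if scipy.sparse.issparse(matrix) else matrix
        if not np.isin(dense, (0, 1)).all():
            raise HetnetFormatError(f"metaedge {me}: matrix entries must be 0 or 1")
        if me.is_same_metanode:
            if np.any(np.diag(dense) != 0):
                raise HetnetFormatError(f"metaedge {me}: self-loops are not allowed")
            if not me.directed and not np.array_equal(dense, dense.T):
                raise HetnetFormatError(
                    f"metaedge {me}: undirected same-metanode matrix must be symmetric"
                )

    def _load_node_table(self, mn: Metanode) -> None:
        path = _find_file(self.directory / "nodes", mn.identifier, (".tsv",))
        if path is None:
            raise HetnetFormatError(
                f"missing node table for metanode {mn.identifier} in {self.directory}"
            )
        table = pd.read_csv(path, sep="\t", dtype={"identifier": str, "name": str})
        expected = ["position", "identifier", "name"]
        if list(table.columns) != expected:
            raise HetnetFormatError(
                f"node table for {mn.identifier} must have columns {expected}"
            )
        ordered = table.sort_values("identifier", kind="stable")
        if not np.array_equal(ordered["position"].to_numpy(), table["position"].to_numpy()):
            raise HetnetFormatError(
                f"node table for {mn.identifier} is not sorted by identifier"
            )
        self._node_tables[mn.abbreviation] = table.reset_index(drop=True)

    def _load_matrix(self, me: Metaedge) -> None:
        name = me.full_abbreviation
        edges_dir = self.directory / "edges"
        sparse_path = _find_file(edges_dir, name, (".sparse.npz",))
        dense_path = _find_file(edges_dir, name, (".npy",))
        if sparse_path is not None:
            mat = scipy.sparse.load_npz(sparse_path).tocsr().astype(np.uint8)
        elif dense_path is not None:
            mat = np.load(dense_path).astype(np.uint8)
        else:
            raise HetnetFormatError(
                f"missing adjacency matrix for metaedge {name} in {edges_dir}"
            )
        self._validate_matrix(me, mat)
        self._matrices[name] = mat

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HetnetStore):
            return NotImplemented
        if self.metagraph != other.metagraph:
            return False
        for mn in self.metagraph.metanodes:
            if not self.nodes(mn).equals(other.nodes(mn)):
                return False
        for me in self.metagraph.metaedges:
            a = np.asarray(self.adjacency(me))
            b = np.asarray(other.adjacency(me))
            if not np.array_equal(a, b):
                return False
        return True


def _find_file(directory: Path, stem: str, suffixes: tuple[str, ...]) -> Path | None:
    if not directory.is_dir():
        return None
    compressions = ("", ".gz", ".bz2", ".xz", ".zip")
    for suffix in suffixes:
        for comp in compressions:
            path = directory / f"{stem}{suffix}{comp}"
            if path.exists():
                return path
    return None


# -- module-level operations --------------------------------------------------


def load_store(directory_path: str | Path) -> HetnetStore:
    """Open a hetnet directory as a lazily-loading store."""
    directory = Path(directory_path)
    metagraph_path = directory / "metagraph.json"
    if not metagraph_path.exists():
        raise HetnetFormatError(f"no metagraph.json in {directory}")
    with open(metagraph_path) as f:
        metagraph = Metagraph.from_dict(json.load(f))
    return HetnetStore(metagraph, directory=directory)


def save_store(
    store: HetnetStore,
    directory_path: str | Path,
    density_threshold: float = 0.7,
) -> Path:
    """Serialize a store: sparse format below the density threshold, else dense.

    Generated-data subdirectories already present at the target (for example
    ``permutations/`` or ``path-counts/``) are left untouched.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "metagraph.json", "w") as f:
        json.dump(store.metagraph.to_dict(), f, indent=2, sort_keys=True)
        f.write("\n")
    nodes_dir = directory / "nodes"
    nodes_dir.mkdir(exist_ok=True)
    for mn in store.metagraph.metanodes:
        try:
            table = store.nodes(mn)
        except (KeyError, HetnetFormatError):
            continue
        table.to_csv(nodes_dir / f"{mn.identifier}.tsv", sep="\t", index=False)
    edges_dir = directory / "edges"
    edges_dir.mkdir(exist_ok=True)
    for me in store.metaedges_present():
        mat = store.adjacency(me)
        density = mat.mean() if mat.size else 0.0
        name = me.full_abbreviation
        if density < density_threshold:
            scipy.sparse.save_npz(
                edges_dir / f"{name}.sparse.npz", scipy.sparse.csr_matrix(mat)
            )
        else:
            np.save(edges_dir / f"{name}.npy", np.asarray(mat, dtype=np.uint8))
    return directory


def metaedge_degrees(
    store: HetnetStore, metaedge: Metaedge | str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node edge counts (row sums, column sums) of one metaedge."""
    return store.degrees(metaedge)


def degree_weighted_adjacency(
    store: HetnetStore, metaedge: Metaedge | str, w: float
) -> DampedAdjacency:
    """Damped biadjacency with entries ``A_ij * (d_i * d_j) ** -w``."""
    if w < 0:
        raise ValueError(f"damping exponent must be non-negative, got {w}")
    me = store._as_metaedge(metaedge)
    adj = np.asarray(store.adjacency(me), dtype=np.float64)
    d_src, d_tgt = store.degrees(me)
    with np.errstate(divide="ignore"):
        row = np.where(d_src > 0, d_src.astype(float) ** -w, 0.0)
        col = np.where(d_tgt > 0, d_tgt.astype(float) ** -w, 0.0)
    matrix = adj * row[:, None] * col[None, :]
    return DampedAdjacency(
        metaedge=me, w=w, matrix=matrix, source_degrees=d_src, target_degrees=d_tgt
    )


def store_from_edge_list(
    metagraph: Metagraph,
    edges: pd.DataFrame,
    node_identifiers: Mapping[str, Iterable[str]] | None = None,
) -> HetnetStore:
    """Build a store from an edge-list frame.

    ``edges`` needs columns ``source_id``, ``metaedge``, ``target_id`` where
    ``metaedge`` is a full abbreviation such as ``CbG``. Node sets default to
    the identifiers observed in the edge list; pass ``node_identifiers`` (keyed
    by metanode abbreviation) to include isolated nodes.
    """
    ids: dict[str, set[str]] = {mn.abbreviation: set() for mn in metagraph.metanodes}
    if node_identifiers:
        for abbrev, identifiers in node_identifiers.items():
            ids[metagraph.metanode(abbrev).abbreviation].update(map(str, identifiers))
    parsed: list[tuple[Metaedge, str, str]] = []
    for row in edges.itertuples(index=False):
        me = metagraph.metaedge(str(row.metaedge))
        src, tgt = str(row.source_id), str(row.target_id)
        ids[me.source.abbreviation].add(src)
        ids[me.target.abbreviation].add(tgt)
        parsed.append((me, src, tgt))
    store = HetnetStore(metagraph)
    for mn in metagraph.metanodes:
        store.set_nodes(mn, sorted(ids[mn.abbreviation]))
    by_metaedge: dict[str, list[tuple[str, str]]] = {}
    for me, src, tgt in parsed:
        by_metaedge.setdefault(me.full_abbreviation, []).append((src, tgt))
    for me in metagraph.metaedges:
        pairs = by_metaedge.get(me.full_abbreviation, [])
        n_src = store.n_nodes(me.source)
        n_tgt = store.n_nodes(me.target)
        mat = np.zeros((n_src, n_tgt), dtype=np.uint8)
        seen: set[tuple[int, int]] = set()
        for src, tgt in pairs:
            i = store.node_position(me.source, src)
            j = store.node_position(me.target, tgt)
            if me.is_same_metanode and i == j:
                raise HetnetFormatError(f"metaedge {me}: self-loop on node {src!r}")
            key = (i, j)
            if key in seen or (
                not me.directed and me.is_same_metanode and (j, i) in seen
            ):
                raise HetnetFormatError(
                    f"metaedge {me}: duplicate edge {src!r}-{tgt!r}"
                )
            seen.add(key)
            mat[i, j] = 1
            if me.is_same_metanode and not me.directed:
                mat[j, i] = 1
        store.set_adjacency(me, mat)
    return store
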