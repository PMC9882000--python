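"""Deterministic synthetic hetnets for testing and calibration.

Every module of the package is exercised on networks generated here: a
user-specified metagraph, per-metanode node counts, and per-metaedge edge
densities or explicit degree sequences, realized by a seeded generator with no
self-loops and no duplicate edges. Also provides the small named toy networks
used throughout the documentation and the Hetionet v1.0 metagraph schema
(11 metanodes, 24 metaedges) bundled as a JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .hetnet_core import HetnetStore, Metaedge, Metagraph, Metanode
from .permutation import xswap_metaedge

__all__ = [
    "MetanodeSpec",
    "MetaedgeSpec",
    "FixtureSpec",
    "make_fixture",
    "toy_T1",
    "toy_T2",
    "toy_T2prime",
    "hetionet_metagraph",
    "hetionet_node_counts",
]


@dataclass(frozen=True)
class MetanodeSpec:
    identifier: str
    abbreviation: str
    count: int


@dataclass(frozen=True)
class MetaedgeSpec:
    source: str  # metanode abbreviation
    target: str
    kind: str
    abbreviation: str
    directed: bool = False
    density: float | None = None
    n_edges: int | None = None
    source_degrees: tuple[int, ...] | None = None
    target_degrees: tuple[int, ...] | None = None


@dataclass(frozen=True)
class FixtureSpec:
    metanodes: tuple[MetanodeSpec, ...]
    metaedges: tuple[MetaedgeSpec, ...]
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "FixtureSpec":
        metanodes = tuple(MetanodeSpec(**d) for d in data["metanodes"])
        metaedges = tuple(
            MetaedgeSpec(
                **{
                    **d,
                    "source_degrees": tuple(d["source_degrees"])
                    if d.get("source_degrees")
                    else None,
                    "target_degrees": tuple(d["target_degrees"])
                    if d.get("target_degrees")
                    else None,
                }
            )
            for d in data["metaedges"]
        )
        return cls(metanodes=metanodes, metaedges=metaedges, seed=data.get("seed", 0))


def _node_ids(abbrev: str, count: int) -> list[str]:
    width = max(3, len(str(count - 1))) if count else 3
    return [f"{abbrev.lower()}{i:0{width}d}" for i in range(count)]


def _allowed_pairs(n_src: int, n_tgt: int, same: bool, directed: bool):
    if not same:
        return [(i, j) for i in range(n_src) for j in range(n_tgt)]
    if directed:
        return [(i, j) for i in range(n_src) for j in range(n_tgt) if i != j]
    return [(i, j) for i in range(n_src) for j in range(i + 1, n_tgt)]


def _realize_degree_sequence(
    src_deg: tuple[int, ...],
    tgt_deg: tuple[int, ...],
    same: bool,
    directed: bool,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Greedy (Gale-Ryser style) realization followed by seeded XSwap to
    randomize which realization is returned; degree sequences are honored
    exactly or a ValueError is raised."""
    edges: list[tuple[int, int]] = []
    if same and not directed:
        # Havel-Hakimi: repeatedly connect the highest-residual node to the
        # next-highest residual nodes
        residual = list(src_deg)
        while True:
            order = sorted(range(len(residual)), key=lambda i: (-residual[i], i))
            i = order[0]
            if residual[i] == 0:
                break
            need = residual[i]
            residual[i] = 0
            partners = [j for j in order[1:] if residual[j] > 0][:need]
            if len(partners) < need:
                raise ValueError("degree sequence is not graphical")
            for j in partners:
                residual[j] -= 1
                edges.append((min(i, j), max(i, j)))
    else:
        # Gale-Ryser: each source takes the targets with highest residuals
        if sum(src_deg) != sum(tgt_deg):
            raise ValueError("source and target degree sums differ")
        residual = list(tgt_deg)
        for i in sorted(range(len(src_deg)), key=lambda i: (-src_deg[i], i)):
            need = src_deg[i]
            candidates = sorted(
                (
                    j
                    for j in range(len(residual))
                    if residual[j] > 0 and not (same and j == i)
                ),
                key=lambda j: (-residual[j], j),
            )[:need]
            if len(candidates) < need:
                raise ValueError("degree sequence is not realizable")
            for j in candidates:
                residual[j] -= 1
                edges.append((i, j))
        if any(residual):
            raise ValueError("degree sequence is not realizable")
    shuffled, _ = xswap_metaedge(
        edges,
        seed=int(rng.integers(0, 2**31 - 1)),
        multiplier=10,
        same_metanode=same,
        directed=directed,
    )
    return shuffled


def make_fixture(spec: FixtureSpec) -> HetnetStore:
    """Materialize a synthetic hetnet from its spec (pure in the spec)."""
    metanodes = [
        Metanode(s.identifier, s.abbreviation) for s in spec.metanodes
    ]
    by_abbrev = {mn.abbreviation: mn for mn in metanodes}
    counts = {s.abbreviation: s.count for s in spec.metanodes}
    metaedges = [
        Metaedge(
            source=by_abbrev[s.source],
            target=by_abbrev[s.target],
            kind=s.kind,
            abbreviation=s.abbreviation,
            directed=s.directed,
        )
        for s in spec.metaedges
    ]
    metagraph = Metagraph(metanodes, metaedges)
    store = HetnetStore(metagraph)
    for s in spec.metanodes:
        store.set_nodes(by_abbrev[s.abbreviation], _node_ids(s.abbreviation, s.count))
    rng = np.random.default_rng(spec.seed)
    for espec, me in zip(spec.metaedges, metaedges):
        n_src = counts[espec.source]
        n_tgt = counts[espec.target]
        same = espec.source == espec.target
        if espec.source_degrees is not None:
            if len(espec.source_degrees) != n_src:
                raise ValueError(f"metaedge {me}: source degree sequence length mismatch")
            tgt_deg = espec.target_degrees
            if same and not espec.directed:
                tgt_deg = espec.source_degrees
            if tgt_deg is None or len(tgt_deg) != n_tgt:
                raise ValueError(f"metaedge {me}: target degree sequence length mismatch")
            pairs = _realize_degree_sequence(
                espec.source_degrees, tgt_deg, same, espec.directed, rng
            )
        else:
            allowed = _allowed_pairs(n_src, n_tgt, same, espec.directed)
            if espec.n_edges is not None:
                n_edges = espec.n_edges
            elif espec.density is not None:
                if not (0.0 <= espec.density <= 1.0):
                    raise ValueError(f"metaedge {me}: density must be in [0, 1]")
                n_edges = int(round(espec.density * len(allowed)))
            else:
                raise ValueError(
                    f"metaedge {me}: specify density, n_edges or degree sequences"
                )
            if n_edges > len(allowed):
                raise ValueError(f"metaedge {me}: more edges requested than possible")
            idx = rng.choice(len(allowed), size=n_edges, replace=False)
            pairs = [allowed[i] for i in sorted(idx)]
        mat = np.zeros((n_src, n_tgt), dtype=np.uint8)
        for i, j in pairs:
            mat[i, j] = 1
            if same and not espec.directed:
                mat[j, i] = 1
        store.set_adjacency(me, mat)
    return store


def random_fixture_spec(
    seed: int,
    min_metanodes: int = 2,
    max_metanodes: int = 4,
    min_nodes: int = 3,
    max_nodes: int = 8,
    density_range: tuple[float, float] = (0.2, 0.6),
    allow_directed: bool = True,
) -> FixtureSpec:
    """A seeded random small metagraph and edge densities.

    Metaedges include bipartite, undirected same-metanode, and (optionally)
    directed same-metanode kinds so that every repeat-pattern family arises in
    the metapaths enumerated over the result.
    """
    rng = np.random.default_rng(seed)
    n_mn = int(rng.integers(min_metanodes, max_metanodes + 1))
    abbrevs = ["A", "B", "E", "F"][:n_mn]
    metanodes = tuple(
        MetanodeSpec(f"Type{a}", a, int(rng.integers(min_nodes, max_nodes + 1)))
        for a in abbrevs
    )
    n_me = int(rng.integers(2, n_mn + 3))
    kinds = "wxyzuv"
    metaedges = []
    used: set[tuple[str, str, str]] = set()
    for k in range(n_me):
        src, tgt = (str(a) for a in rng.choice(abbrevs, size=2, replace=True))
        directed = bool(src == tgt and allow_directed and rng.random() < 0.3)
        kind_abbrev = kinds[k]
        if (src, tgt, kind_abbrev) in used:
            continue
        used.add((src, tgt, kind_abbrev))
        density = float(rng.uniform(*density_range))
        metaedges.append(
            MetaedgeSpec(
                source=src,
                target=tgt,
                kind=f"kind_{kind_abbrev}",
                abbreviation=kind_abbrev,
                directed=directed,
                density=density,
            )
        )
    return FixtureSpec(
        metanodes=metanodes, metaedges=tuple(metaedges), seed=int(rng.integers(2**31))
    )


# -- named toy networks -------------------------------------------------------


def toy_T1() -> HetnetStore:
    """One metanode Gene with an interacts triangle g1-g2-g3 (all degrees 2)."""
    gene = Metanode("Gene", "G")
    gig = Metaedge(gene, gene, "interacts", "i")
    metagraph = Metagraph([gene], [gig])
    store = HetnetStore(metagraph)
    store.set_nodes(gene, ["g1", "g2", "g3"])
    store.set_adjacency(gig, np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]))
    return store


def toy_T2() -> HetnetStore:
    """Compound-binds-Gene with edges c1-g1, c1-g2, c2-g2."""
    compound = Metanode("Compound", "C")
    gene = Metanode("Gene", "G")
    cbg = Metaedge(compound, gene, "binds", "b")
    metagraph = Metagraph([compound, gene], [cbg])
    store = HetnetStore(metagraph)
    store.set_nodes(compound, ["c1", "c2"])
    store.set_nodes(gene, ["g1", "g2", "g3"])
    store.set_adjacency(cbg, np.array([[1, 1, 0], [0, 1, 0]]))
    return store


def toy_T2prime() -> HetnetStore:
    """Compound-treats-Disease with edges c1-d1, c1-d2, c2-d1."""
    compound = Metanode("Compound", "C")
    disease = Metanode("Disease", "D")
    ctd = Metaedge(compound, disease, "treats", "t")
    metagraph = Metagraph([compound, disease], [ctd])
    store = HetnetStore(metagraph)
    store.set_nodes(compound, ["c1", "c2"])
    store.set_nodes(disease, ["d1", "d2"])
    store.set_adjacency(ctd, np.array([[1, 1], [1, 0]]))
    return store


# -- Hetionet v1.0 schema -----------------------------------------------------


def _load_hetionet_json() -> dict:
    ref = resources.files("hetpath") / "data" / "hetionet-v1.0-metagraph.json"
    try:
        return json.loads(ref.read_text())
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            "the bundled Hetionet v1.0 metagraph file is missing; reinstall the "
            "package or place hetionet-v1.0-metagraph.json under hetpath/data/"
        ) from exc


def hetionet_metagraph() -> Metagraph:
    """The Hetionet v1.0 schema: 11 metanodes and 24 metaedges, with the
    Gene-regulates-Gene metaedge directed. Transcribed from the published
    schema description and bundled with the package."""
    return Metagraph.from_dict(_load_hetionet_json())


def hetionet_node_counts() -> dict[str, int]:
    """Published Hetionet v1.0 node counts per metanode identifier."""
    return dict(_load_hetionet_json()["node_counts"])
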