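"""Metapath enumeration, repeat-pattern classification, and segmentation.

Path counting by matrix multiplication counts walks, not paths: whenever a
metanode appears more than once in a metapath, products of adjacency matrices
include walks that revisit a node. The correction strategy depends on the
*pattern* of repeated metanodes, so metapaths are classified into categories
(no repeats, short single-metanode repeats like XaXbX, nested BAAB,
overlapping BABA, disjoint groups of the former, or complex patterns such as
ABCABC and repeats of four or more occurrences) and segmented into pieces for
which a closed-form correction exists. Complex leaves are the signal to fall
back to explicit path enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hetnet_core import Metagraph, Metanode, Metapath, MetapathStep

__all__ = [
    "enumerate_metapaths",
    "reverse",
    "categorize",
    "segment",
    "count_metapaths",
    "RepeatGroup",
    "Segment",
    "repeat_groups",
]

CATEGORIES = (
    "no-repeats",
    "short-repeat",
    "nested",
    "overlapping",
    "disjoint-groups",
    "complex",
)


def enumerate_metapaths(metagraph: Metagraph, max_length: int) -> list[Metapath]:
    """All composable metapaths of length 1..max_length, one orientation each.

    A metapath and its reverse describe the same type-level template, so only
    the canonical orientation (lexicographically smaller abbreviation) is kept.
    The result is sorted by (length, abbreviation) and therefore deterministic.
    """
    if max_length < 0:
        raise ValueError("max_length must be >= 0")
    found: set[Metapath] = set()
    frontier: list[tuple[MetapathStep, ...]] = []
    for mn in metagraph.metanodes:
        for step in metagraph.steps_from(mn):
            if step.source == mn:
                frontier.append((step,))
    # steps_from covers every orientation from every metanode, so the initial
    # frontier enumerates each oriented metaedge exactly once.
    frontier = list(dict.fromkeys(frontier))
    length = 1
    while frontier and length <= max_length:
        for steps in frontier:
            found.add(Metapath(steps).canonical())
        next_frontier = []
        for steps in frontier:
            tail = steps[-1].target
            for step in metagraph.steps_from(tail):
                next_frontier.append(steps + (step,))
        frontier = next_frontier
        length += 1
    return sorted(found, key=lambda m: (m.length, m.abbreviation))


def reverse(metapath: Metapath) -> Metapath:
    """The same template walked end-to-start (``GpPWpGaD`` <-> ``DaGpPWpG``)."""
    return metapath.reverse()


def count_metapaths(
    metagraph: Metagraph,
    metanode_a: Metanode | str,
    metanode_b: Metanode | str,
    length: int,
) -> int:
    """Number of distinct metapaths of exactly ``length`` between two metanodes.

    Uses the same one-orientation-per-metapath convention as
    :func:`enumerate_metapaths`; this is the Bonferroni multiplicity for
    adjusting p-values of a search between the two metanodes.
    """
    mn_a = metagraph.metanode(metanode_a) if isinstance(metanode_a, str) else metanode_a
    mn_b = metagraph.metanode(metanode_b) if isinstance(metanode_b, str) else metanode_b
    count = 0
    for mp in enumerate_metapaths(metagraph, length):
        if mp.length != length:
            continue
        if {mp.source, mp.target} == {mn_a, mn_b}:
            count += 1
    return count


@dataclass(frozen=True)
class RepeatGroup:
    """A maximal contiguous span of interleaved repeated metanodes.

    ``occurrences`` maps each repeated metanode abbreviation to its positions
    in the metapath's node sequence (positions run 0..length). Spans of
    repeated metanodes that overlap are merged into one group, because their
    duplicate-node corrections cannot be applied independently.
    """

    start: int
    end: int
    occurrences: tuple[tuple[str, tuple[int, ...]], ...]

    @property
    def metanode_abbrevs(self) -> tuple[str, ...]:
        return tuple(abbrev for abbrev, _ in self.occurrences)

    def occurrence_sequence(self) -> list[tuple[int, str]]:
        seq = [
            (pos, abbrev)
            for abbrev, positions in self.occurrences
            for pos in positions
        ]
        seq.sort()
        return seq


def repeat_groups(metanode_seq: list[str]) -> list[RepeatGroup]:
    """Merge the position spans of repeated metanodes into disjoint groups."""
    occ: dict[str, list[int]] = {}
    for pos, abbrev in enumerate(metanode_seq):
        occ.setdefault(abbrev, []).append(pos)
    repeated = {a: ps for a, ps in occ.items() if len(ps) >= 2}
    if not repeated:
        return []
    spans = sorted((ps[0], ps[-1], a) for a, ps in repeated.items())
    groups: list[list[str]] = []
    bounds: list[list[int]] = []
    for start, end, abbrev in spans:
        if bounds and start < bounds[-1][1]:
            bounds[-1][1] = max(bounds[-1][1], end)
            groups[-1].append(abbrev)
        else:
            bounds.append([start, end])
            groups.append([abbrev])
    result = []
    for (start, end), members in zip(bounds, groups):
        occurrences = tuple(
            (abbrev, tuple(repeated[abbrev])) for abbrev in sorted(members)
        )
        result.append(RepeatGroup(start=start, end=end, occurrences=occurrences))
    return result


def _confined(positions: tuple[int, ...], boundaries: list[int]) -> bool:
    """True if all positions fall strictly within one boundary interval."""
    for lo, hi in zip(boundaries, boundaries[1:]):
        if all(lo < p < hi for p in positions):
            return True
    return False


def _group_kind(group: RepeatGroup, metanode_seq: list[str]) -> str:
    """Classify a repeat group by the correction template that computes it.

    Returns one of ``short-repeat`` (single metanode at the group boundary,
    2-3 occurrences, everything else nested strictly inside the gaps — this
    subsumes the BAAB pattern), ``overlapping`` (exact XYXY interleaving), or
    ``complex`` (no closed-form correction; requires path enumeration).
    """
    occ = dict(group.occurrences)
    left = metanode_seq[group.start]
    right = metanode_seq[group.end]
    if left == right:
        anchors = occ[left]
        if len(anchors) <= 3:
            others_ok = all(
                _confined(positions, list(anchors))
                for abbrev, positions in occ.items()
                if abbrev != left
            )
            if others_ok:
                return "short-repeat"
        return "complex"
    x_pos, y_pos = occ[left], occ[right]
    if len(x_pos) == 2 and len(y_pos) == 2:
        p1, p3 = x_pos
        p2, p4 = y_pos
        if p1 < p2 < p3 < p4:
            boundaries = [p1, p2, p3, p4]
            others_ok = all(
                _confined(positions, boundaries)
                for abbrev, positions in occ.items()
                if abbrev not in (left, right)
            )
            if others_ok:
                return "overlapping"
    return "complex"


def _group_has_inner_repeats(group: RepeatGroup) -> bool:
    return len(group.occurrences) > 1


def categorize(metapath: Metapath) -> str:
    """Repeat-pattern category of a metapath.

    Metanodes occurring once need no correction and are ignored. The category
    is invariant under reversal because span merging and the group templates
    are symmetric under reversing the position sequence.
    """
    seq = [mn.abbreviation for mn in metapath.metanodes]
    groups = repeat_groups(seq)
    if not groups:
        return "no-repeats"
    kinds = [_group_kind(g, seq) for g in groups]
    if "complex" in kinds:
        return "complex"
    if len(groups) > 1:
        return "disjoint-groups"
    group, kind = groups[0], kinds[0]
    if kind == "overlapping":
        return "overlapping"
    # single-metanode template: plain short repeat, or nested if other
    # repeated metanodes sit inside the gaps (the BAAB family)
    return "nested" if _group_has_inner_repeats(group) else "short-repeat"


@dataclass
class Segment:
    """A node of the segmentation tree.

    ``start``/``end`` index the metapath's node positions; the segment covers
    steps ``start..end-1``. Leaves carry the pattern that computes them;
    internal group nodes list their sub-intervals in order, so concatenating
    the tree's leaves left-to-right reproduces the metapath.
    """

    start: int
    end: int
    pattern: str
    children: list["Segment"] = field(default_factory=list)

    def leaves(self) -> list["Segment"]:
        if not self.children:
            return [self]
        out: list[Segment] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


def segment(metapath: Metapath) -> Segment:
    """Hierarchical segmentation of a metapath by its repeat structure."""
    seq = [mn.abbreviation for mn in metapath.metanodes]
    return _segment_range(seq, 0, len(seq) - 1, skip_endpoint_pair=False)


def masked_subsequence(
    seq: list[str], lo: int, hi: int, skip_endpoint_pair: bool
) -> list[str]:
    """Metanode subsequence for positions lo..hi, optionally masking the
    endpoint pair so that an already-corrected outer repeat (the anchors of an
    enclosing short-repeat template) is not re-detected as a repeat."""
    sub = list(seq[lo : hi + 1])
    if (
        skip_endpoint_pair
        and hi > lo
        and sub[0] == sub[-1]
        and sub.count(sub[0]) == 2
    ):
        sub[0] = "\x00start"
        sub[-1] = "\x00end"
    return sub


def _shift_groups(groups: list[RepeatGroup], offset: int) -> list[RepeatGroup]:
    return [
        RepeatGroup(
            g.start + offset,
            g.end + offset,
            tuple((a, tuple(p + offset for p in ps)) for a, ps in g.occurrences),
        )
        for g in groups
    ]


def _segment_range(
    seq: list[str], lo: int, hi: int, skip_endpoint_pair: bool
) -> Segment:
    sub = masked_subsequence(seq, lo, hi, skip_endpoint_pair)
    groups = _shift_groups(repeat_groups(sub), lo)
    if not groups:
        return Segment(lo, hi, "no-repeats")
    children: list[Segment] = []
    pos = lo
    for group in groups:
        if pos < group.start:
            children.append(Segment(pos, group.start, "no-repeats"))
        children.append(_segment_group(seq, group))
        pos = group.end
    if pos < hi:
        children.append(Segment(pos, hi, "no-repeats"))
    if len(children) == 1 and children[0].start == lo and children[0].end == hi:
        return children[0]
    return Segment(lo, hi, "disjoint-groups", children)


def _segment_group(seq: list[str], group: RepeatGroup) -> Segment:
    kind = _group_kind(group, seq)
    occ = dict(group.occurrences)
    if kind == "complex":
        return Segment(group.start, group.end, "complex")
    if kind == "short-repeat":
        anchors = list(occ[seq[group.start]])
        pattern = "nested" if _group_has_inner_repeats(group) else "short-repeat"
        children = [
            _segment_range(seq, a, b, skip_endpoint_pair=True)
            for a, b in zip(anchors, anchors[1:])
        ]
        return Segment(group.start, group.end, pattern, _trim(children))
    # overlapping XYXY: three sub-intervals between the four anchors
    p1, p3 = occ[seq[group.start]]
    p2, p4 = occ[seq[group.end]]
    children = [
        _segment_range(seq, a, b, skip_endpoint_pair=False)
        for a, b in ((p1, p2), (p2, p3), (p3, p4))
    ]
    return Segment(group.start, group.end, "overlapping", _trim(children))


def _trim(children: list[Segment]) -> list[Segment]:
    """Collapse a group node to a leaf when its sub-intervals hold no further
    repeat structure (the pattern tag alone then describes the computation)."""
    if all(c.pattern == "no-repeats" and not c.children for c in children):
        return []
    return children
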