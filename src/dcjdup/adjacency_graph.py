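"""The adjacency graph, its decompositions, and candidate 4-cycles.

The adjacency graph of two (ghost-augmented, possibly capped) adjacency
sets is a bipartite multigraph: left vertices are the elements of
``S1' u T2``, right vertices those of ``S2' u T1``, and two elements are
joined by one edge per shared extremity.  Edges are never materialized;
instead a *decomposition* is stored directly as a label-preserving
bijection between left and right extremity slots, which is exactly a
choice of ``2n`` edges forming vertex-disjoint alternating cycles (and
paths, when telomeres are present).

A cycle of length ``l`` is *helpful* when at most ``l/2 - 1`` of its
vertices are ghost adjacencies and *unhelpful* when at least ``l/2`` are
(in which case exactly ``l/2`` are, all on one side, since T1 and T2 share
no extremities).  Only helpful cycles reduce the edit distance, and the
approximation algorithm packs vertex-disjoint helpful cycles of length 4.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .genome_model import AdjacencySet, Extremity, GraphElement
from .ghost_capping import CappedPair, GhostPair

__all__ = [
    "LEFT",
    "RIGHT",
    "Slot",
    "AdjacencyGraph",
    "Decomposition",
    "Component",
    "CandidateCycle",
    "build_graph",
    "build_uncapped_graph",
    "components_of",
    "classify_component",
    "enumerate_helpful_4cycles",
    "validate_decomposition",
]

LEFT = "left"
RIGHT = "right"

#: a slot reference: (element index on its side, slot position 0|1)
Slot = tuple[int, int]


class GraphBalanceError(ValueError):
    """Per-label slot counts differ between the two sides."""


def _element_sort_key(e: GraphElement):
    return (e.origin, e.slots)


@dataclass(frozen=True)
class AdjacencyGraph:
    """Bipartite multigraph over two ordered element lists.

    ``n`` is half the number of extremities on one side; for genomes with
    equal content and no duplicates it equals the gene count.
    """

    left: tuple[GraphElement, ...]   # S1' u T2
    right: tuple[GraphElement, ...]  # S2' u T1

    @property
    def n(self) -> int:
        ns = sum(len(e.slots) for e in self.left)
        if ns % 2:
            raise GraphBalanceError(f"odd extremity count {ns} on one side")
        return ns // 2

    def slots(self, side: str):
        elems = self.left if side == LEFT else self.right
        for eid, e in enumerate(elems):
            for pos in range(len(e.slots)):
                yield (eid, pos)

    def label_index(self, side: str) -> dict[Extremity, list[Slot]]:
        idx: dict[Extremity, list[Slot]] = defaultdict(list)
        elems = self.left if side == LEFT else self.right
        for eid, e in enumerate(elems):
            for pos, ext in enumerate(e.slots):
                idx[ext].append((eid, pos))
        return idx

    def element(self, side: str, eid: int) -> GraphElement:
        return (self.left if side == LEFT else self.right)[eid]


def _from_parts(left_parts, right_parts) -> AdjacencyGraph:
    left = tuple(sorted(left_parts, key=_element_sort_key))
    right = tuple(sorted(right_parts, key=_element_sort_key))
    g = AdjacencyGraph(left, right)
    lc = Counter(s for e in left for s in e.slots)
    rc = Counter(s for e in right for s in e.slots)
    if lc != rc:
        raise GraphBalanceError(
            "extremity labels unbalanced between sides: "
            f"{sorted((lc - rc).elements())!r} vs {sorted((rc - lc).elements())!r}"
        )
    return g


def build_graph(cp: CappedPair, gp: GhostPair) -> AdjacencyGraph:
    """Capped graph: left = S1' u T2, right = S2' u T1 (cycles only)."""
    return _from_parts(
        list(cp.s1_capped) + list(gp.t2), list(cp.s2_capped) + list(gp.t1)
    )


def build_uncapped_graph(
    s1: AdjacencySet, s2: AdjacencySet, gp: GhostPair
) -> AdjacencyGraph:
    """Uncapped graph with telomeres; decompositions contain paths."""
    return _from_parts(list(s1) + list(gp.t2), list(s2) + list(gp.t1))


@dataclass(frozen=True)
class Decomposition:
    """Total label-preserving bijection between left and right slots."""

    matching: dict[Slot, Slot]  # left slot -> right slot

    def inverse(self) -> dict[Slot, Slot]:
        return {r: l for l, r in self.matching.items()}


@dataclass(frozen=True)
class Component:
    """One alternating cycle or path of a decomposition.

    ``nodes`` alternate sides; ``labels[i]`` is the extremity shared by
    ``nodes[i]`` and ``nodes[i+1]`` (wrapping around for cycles).
    """

    kind: str  # "cycle" | "path"
    nodes: tuple[tuple[str, int], ...]   # (side, element id)
    labels: tuple[Extremity, ...]
    ghost_count: int

    @property
    def length(self) -> int:
        return len(self.labels)

    @property
    def classification(self) -> str:
        return classify_component(self)


def classify_component(c: Component) -> str:
    if c.kind == "cycle":
        return "helpful" if c.ghost_count <= c.length // 2 - 1 else "unhelpful"
    return "odd" if c.length % 2 else "even"


def validate_decomposition(
    graph: AdjacencyGraph, d: Decomposition
) -> list[str]:
    """Check totality, bijectivity and label preservation.

    Returns a list of violation messages; an empty list means the
    decomposition is valid.  Alternation is implied by slot-level matching
    (each slot carries exactly one edge).
    """
    violations: list[str] = []
    left_slots = set(graph.slots(LEFT))
    right_slots = set(graph.slots(RIGHT))
    matched_left = set(d.matching)
    matched_right = list(d.matching.values())
    for s in sorted(left_slots - matched_left):
        violations.append(f"left slot {s} unmatched")
    for s in sorted(matched_left - left_slots):
        violations.append(f"unknown left slot {s}")
    ctr = Counter(matched_right)
    for s, k in sorted(ctr.items()):
        if k > 1:
            violations.append(f"right slot {s} matched {k} times")
    for s in sorted(right_slots - set(matched_right)):
        violations.append(f"right slot {s} unmatched")
    for ls, rs in sorted(d.matching.items()):
        if ls in left_slots and rs in right_slots:
            ll = graph.left[ls[0]].slots[ls[1]]
            rl = graph.right[rs[0]].slots[rs[1]]
            if ll != rl:
                violations.append(
                    f"label mismatch: left {ls} carries {ll}, right {rs} carries {rl}"
                )
    return violations


def components_of(
    graph: AdjacencyGraph, d: Decomposition
) -> list[Component]:
    """Extract the alternating cycles and paths induced by a matching."""
    violations = validate_decomposition(graph, d)
    if violations:
        raise ValueError("invalid decomposition: " + "; ".join(violations))

    fwd = d.matching
    bwd = d.inverse()

    def partner(side: str, slot: Slot) -> Slot:
        return fwd[slot] if side == LEFT else bwd[slot]

    def other_side(side: str) -> str:
        return RIGHT if side == LEFT else LEFT

    visited: set[tuple[str, int]] = set()
    comps: list[Component] = []

    def ghost_count(nodes) -> int:
        return sum(1 for side, eid in nodes if graph.element(side, eid).is_ghost)

    def walk(side: str, slot: Slot, stop_at_start: bool):
        """Follow the matching from one slot; yields nodes and edge labels."""
        nodes = [(side, slot[0])]
        labels: list[Extremity] = []
        cur_side, cur = side, slot
        start = (side, slot)
        while True:
            labels.append(graph.element(cur_side, cur[0]).slots[cur[1]])
            nxt = partner(cur_side, cur)
            nxt_side = other_side(cur_side)
            elem = graph.element(nxt_side, nxt[0])
            if len(elem.slots) == 1:
                nodes.append((nxt_side, nxt[0]))
                return nodes, labels, False
            cont = (nxt[0], 1 - nxt[1])
            if (nxt_side, cont) == start:
                return nodes, labels, True  # cycle closed
            nodes.append((nxt_side, nxt[0]))
            cur_side, cur = nxt_side, cont

    # paths first: start from each telomere (1-slot element)
    for side in (LEFT, RIGHT):
        elems = graph.left if side == LEFT else graph.right
        for eid, e in enumerate(elems):
            if len(e.slots) == 1 and (side, eid) not in visited:
                nodes, labels, closed = walk(side, (eid, 0), stop_at_start=False)
                assert not closed
                visited.update(nodes)
                comps.append(
                    Component("path", tuple(nodes), tuple(labels), ghost_count(nodes))
                )

    # everything else lies on cycles
    for side in (LEFT, RIGHT):
        elems = graph.left if side == LEFT else graph.right
        for eid, e in enumerate(elems):
            if (side, eid) not in visited:
                nodes, labels, closed = walk(side, (eid, 0), stop_at_start=True)
                assert closed, "non-telomere element on an open walk"
                visited.update(nodes)
                comps.append(
                    Component("cycle", tuple(nodes), tuple(labels), ghost_count(nodes))
                )

    covered = sum(len(c.nodes) for c in comps)
    assert covered == len(graph.left) + len(graph.right)
    return comps


@dataclass(frozen=True)
class CandidateCycle:
    """A short alternating cycle (length 2 or 4) offered to the packer.

    ``pairs`` lists the matched (left slot, right slot) edges realizing the
    cycle; candidates covering the same element set are deduplicated.  Both
    lengths are packed together: short helpful cycles are the currency of
    the distance formula, and a maximum disjoint selection over sets of
    size 2 and 4 is what keeps the approximation within factor 1.5.
    """

    left_ids: tuple[int, ...]
    right_ids: tuple[int, ...]
    pairs: tuple[tuple[Slot, Slot], ...]
    ghost_count: int

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def helpful(self) -> bool:
        return self.ghost_count <= self.length // 2 - 1

    def covered(self) -> frozenset:
        return frozenset(
            [(LEFT, i) for i in self.left_ids]
            + [(RIGHT, i) for i in self.right_ids]
        )


def _try_4cycle(li, lj, rk, rl, ei, ej, ek, el):
    """Find one slot pairing forming the cycle L_i - R_k - L_j - R_l."""
    for sa in (0, 1):
        for pa in (0, 1):
            for ta in (0, 1):
                for qa in (0, 1):
                    if (
                        ei.slots[sa] == ek.slots[pa]
                        and ek.slots[1 - pa] == ej.slots[ta]
                        and ej.slots[1 - ta] == el.slots[qa]
                        and el.slots[1 - qa] == ei.slots[1 - sa]
                    ):
                        return (
                            ((li, sa), (rk, pa)),
                            ((lj, ta), (rk, 1 - pa)),
                            ((lj, 1 - ta), (rl, qa)),
                            ((li, 1 - sa), (rl, 1 - qa)),
                        )
    return None


def enumerate_helpful_2cycles(graph: AdjacencyGraph) -> list[CandidateCycle]:
    """All helpful 2-cycles: ghost-free left/right pairs of equal elements.

    A 2-cycle is a double edge, i.e. two elements sharing both extremities;
    it is helpful iff it contains no ghost.
    """
    rgroups: dict[tuple, list[int]] = defaultdict(list)
    for eid, e in enumerate(graph.right):
        if len(e.slots) == 2 and not e.is_ghost:
            rgroups[e.slots].append(eid)
    out: list[CandidateCycle] = []
    for lid, e in enumerate(graph.left):
        if len(e.slots) == 2 and not e.is_ghost:
            for rid in rgroups.get(e.slots, ()):
                out.append(
                    CandidateCycle(
                        (lid,),
                        (rid,),
                        (((lid, 0), (rid, 0)), ((lid, 1), (rid, 1))),
                        0,
                    )
                )
    return out


def enumerate_helpful_4cycles(graph: AdjacencyGraph) -> list[CandidateCycle]:
    """All helpful alternating 4-cycles, one representative per element set.

    Requires a capped graph (2-slot elements only).  The enumeration is a
    label-indexed scan of left pairs against right pairs, O(n^4) worst case
    but far smaller in practice.
    """
    ridx = graph.label_index(RIGHT)
    # right elements touching each left element
    touching: list[set[int]] = []
    for e in graph.left:
        t = set()
        for ext in e.slots:
            t.update(eid for eid, _ in ridx.get(ext, ()))
        touching.append(t)

    out: list[CandidateCycle] = []
    seen: set[tuple[int, int, int, int]] = set()
    nl = len(graph.left)
    for i in range(nl):
        ei = graph.left[i]
        for j in range(i + 1, nl):
            ej = graph.left[j]
            commons = sorted(touching[i] & touching[j])
            for a in range(len(commons)):
                for b in range(a + 1, len(commons)):
                    k, l = commons[a], commons[b]
                    key = (i, j, k, l)
                    if key in seen:
                        continue
                    ek, el = graph.right[k], graph.right[l]
                    ghosts = sum(e.is_ghost for e in (ei, ej, ek, el))
                    if ghosts > 1:
                        continue
                    pairs = _try_4cycle(i, j, k, l, ei, ej, ek, el)
                    if pairs is None:
                        # the two right roles are interchangeable only up to
                        # which one sits between i and j; try the swap
                        pairs = _try_4cycle(i, j, l, k, ei, ej, el, ek)
                    if pairs is not None:
                        seen.add(key)
                        out.append(
                            CandidateCycle((i, j), (k, l), pairs, ghosts)
                        )
    return out
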