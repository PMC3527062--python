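"""Edit-distance solvers: 4-cycle packing approximation and exact oracle.

The edit distance between two adjacency sets under unit-cost DCJ,
single-gene insertion and single-gene deletion equals

    d(S1, S2) = n - max_D (c_D + o_D / 2)

over all decompositions ``D`` of the adjacency graph, where ``c_D`` counts
helpful cycles and ``o_D`` odd-length paths.  Finding the maximum is
NP-hard, so two routes are provided:

* :func:`edit_distance` with ``method="approx"`` — the 4-step algorithm:
  cap telomeres, collect all helpful 4-cycles, pack a maximum
  vertex-disjoint subset (exact branch-and-bound or greedy + local
  search), complete the rest of the matching arbitrarily, then recover
  telomeres.  With exact packing the result is at most 1.5x optimal.

* ``method="exact"`` — a brute-force oracle enumerating all
  label-preserving slot bijections with branch-and-bound pruning; only
  feasible on small instances but exact, and used throughout the test
  suite as the ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import (
    AdjacencySet,
    Extremity,
    Genome,
    GraphElement,
    genome_to_adjacency_set,
    telomere,
)
from .ghost_capping import cap_telomeres, compute_ghosts
from .adjacency_graph import (
    LEFT,
    RIGHT,
    AdjacencyGraph,
    CandidateCycle,
    Component,
    Decomposition,
    build_graph,
    build_uncapped_graph,
    components_of,
    enumerate_helpful_2cycles,
    enumerate_helpful_4cycles,
)

__all__ = [
    "PackingResult",
    "DistanceReport",
    "CompSeq",
    "pack_cycles",
    "complete_decomposition",
    "exact_best_decomposition",
    "recover_uncapped",
    "distance_from_components",
    "edit_distance",
    "uncapped_oracle_distance",
    "OracleSizeError",
    "PackingSizeError",
]


class OracleSizeError(ValueError):
    """Instance exceeds the exact oracle's size cap."""


class PackingSizeError(ValueError):
    """Candidate collection exceeds the exact packing size cap."""


# ---------------------------------------------------------------------------
# k-set packing over candidate 4-cycles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PackingResult:
    selected: tuple[CandidateCycle, ...]
    mode: str

    def __post_init__(self) -> None:
        seen: set = set()
        for c in self.selected:
            cov = c.covered()
            if seen & cov:
                raise ValueError("packing is not element-disjoint")
            seen |= cov


def _conflict_masks(candidates: Sequence[CandidateCycle]) -> list[int]:
    """Bitmask of conflicting candidates (sharing an element) per candidate."""
    by_elem: dict = {}
    for i, c in enumerate(candidates):
        for el in c.covered():
            by_elem.setdefault(el, []).append(i)
    masks = [0] * len(candidates)
    for ids in by_elem.values():
        for i in ids:
            for j in ids:
                if i != j:
                    masks[i] |= 1 << j
    return masks


def _exact_packing(candidates: Sequence[CandidateCycle]) -> list[int]:
    """Maximum element-disjoint subset by branch and bound on the
    conflict graph (maximum independent set)."""
    masks = _conflict_masks(candidates)
    ncand = len(candidates)
    best: list[int] = []

    def dfs(avail: int, chosen: list[int]) -> None:
        nonlocal best
        if len(chosen) + avail.bit_count() <= len(best):
            return
        # absorb conflict-free candidates, find the most conflicted one
        taken: list[int] = []
        while True:
            v, vdeg = -1, -1
            m = avail
            while m:
                i = (m & -m).bit_length() - 1
                m &= m - 1
                deg = (masks[i] & avail).bit_count()
                if deg > vdeg:
                    v, vdeg = i, deg
            if v < 0 or vdeg > 0:
                break
            taken.append(v)
            avail &= ~(1 << v)
        chosen.extend(taken)
        if avail == 0 or v < 0:
            if len(chosen) > len(best):
                best = list(chosen)
        else:
            chosen.append(v)
            dfs(avail & ~(1 << v) & ~masks[v], chosen)
            chosen.pop()
            dfs(avail & ~(1 << v), chosen)
        del chosen[len(chosen) - len(taken):]

    dfs((1 << ncand) - 1, [])
    return sorted(best)


def _greedy_local_packing(
    candidates: Sequence[CandidateCycle], swap_radius: int, seed: int
) -> list[int]:
    """Greedy maximal packing improved by (1 -> many) local swaps."""
    rng = random.Random(seed)
    order = list(range(len(candidates)))
    rng.shuffle(order)
    # 2-cycles first: they tie up the fewest elements per unit gained
    order.sort(key=lambda i: candidates[i].length)
    covered: set = set()
    selected: list[int] = []
    for i in order:
        cov = candidates[i].covered()
        if not (cov & covered):
            selected.append(i)
            covered |= cov

    def try_improve() -> bool:
        nonlocal selected, covered
        for out in list(selected):
            base = covered - candidates[out].covered()
            pool = [
                i for i in range(len(candidates))
                if i not in selected and not (candidates[i].covered() & base)
            ]
            # find swap_radius-bounded sets of >= 2 mutually disjoint adds
            for a in range(len(pool)):
                ca = candidates[pool[a]].covered()
                for b in range(a + 1, len(pool)):
                    cb = candidates[pool[b]].covered()
                    if not (ca & cb):
                        selected.remove(out)
                        selected.extend([pool[a], pool[b]])
                        covered = base | ca | cb
                        return True
        return False

    if swap_radius >= 1:
        while try_improve():
            pass
    return sorted(selected)


def pack_cycles(
    candidates: Sequence[CandidateCycle],
    mode: str = "auto",
    swap_radius: int = 2,
    seed: int = 0,
    exact_limit: int = 512,
    auto_exact_threshold: int = 24,
) -> PackingResult:
    """Select a large element-disjoint subset of candidate 4-cycles.

    ``mode="exact"`` returns a maximum packing (branch and bound; refused
    above ``exact_limit`` candidates), ``mode="greedy_local"`` a greedy
    maximal packing improved by local swaps, and ``mode="auto"`` picks
    exact for small collections.
    """
    candidates = list(candidates)
    if mode == "auto":
        mode = "exact" if len(candidates) <= auto_exact_threshold else "greedy_local"
    if mode == "exact":
        if len(candidates) > exact_limit:
            raise PackingSizeError(
                f"{len(candidates)} candidates exceed exact packing cap "
                f"{exact_limit}; use greedy_local"
            )
        idx = _exact_packing(candidates)
    elif mode == "greedy_local":
        idx = _greedy_local_packing(candidates, swap_radius, seed)
    else:
        raise ValueError(f"unknown packing mode {mode!r}")
    return PackingResult(tuple(candidates[i] for i in idx), mode)


# ---------------------------------------------------------------------------
# completing a packing into a full decomposition
# ---------------------------------------------------------------------------

def complete_decomposition(
    graph: AdjacencyGraph, packing: PackingResult
) -> Decomposition:
    """Extend packed 4-cycles to a total label-preserving slot bijection.

    Remaining identical left/right element pairs are matched into length-2
    cycles first (preferring non-ghost pairs, which are helpful); all other
    slots are then matched label by label in sorted order.  Balance of the
    capped graph guarantees completability.
    """
    matching: dict = {}
    used_left: set[int] = set()
    used_right: set[int] = set()
    for cand in packing.selected:
        for ls, rs in cand.pairs:
            matching[ls] = rs
        used_left.update(cand.left_ids)
        used_right.update(cand.right_ids)

    # pair identical elements into 2-cycles (non-ghosts first on each side)
    def spare(elems, used):
        groups: dict[tuple, list[int]] = {}
        for eid, e in enumerate(elems):
            if eid not in used and len(e.slots) == 2:
                groups.setdefault(e.slots, []).append(eid)
        for ids in groups.values():
            ids.sort(key=lambda i: (elems[i].is_ghost, i))
        return groups

    lgroups = spare(graph.left, used_left)
    rgroups = spare(graph.right, used_right)
    for slots_key in sorted(lgroups):
        for l, r in zip(lgroups[slots_key], rgroups.get(slots_key, [])):
            matching[(l, 0)] = (r, 0)
            matching[(l, 1)] = (r, 1)
            used_left.add(l)
            used_right.add(r)

    # remaining slots: per-label sorted zip
    def open_slots(side, used):
        elems = graph.left if side == LEFT else graph.right
        idx: dict[Extremity, list] = {}
        for eid, e in enumerate(elems):
            if eid in used:
                continue
            for pos, ext in enumerate(e.slots):
                idx.setdefault(ext, []).append((eid, pos))
        return idx

    lopen = open_slots(LEFT, used_left)
    ropen = open_slots(RIGHT, used_right)
    for label in sorted(lopen):
        ls, rs = sorted(lopen[label]), sorted(ropen.get(label, []))
        if len(ls) != len(rs):
            raise ValueError(f"label {label} unbalanced during completion")
        for a, b in zip(ls, rs):
            matching[a] = b
    return Decomposition(matching)


# ---------------------------------------------------------------------------
# exact oracle: branch and bound over all label-preserving bijections
# ---------------------------------------------------------------------------

class _DSU:
    """Union-find with rollback, tracking per-component bookkeeping."""

    def __init__(self, n_elems, slots_per, ghosts, telomeres):
        self.parent = list(range(n_elems))
        self.size = [1] * n_elems
        self.free = list(slots_per)       # unmatched slots in component
        self.edges = [0] * n_elems
        self.ghosts = list(ghosts)
        self.tel = list(telomeres)
        self.trail: list[tuple] = []

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            x = self.parent[x]
        return x

    def snapshot(self) -> int:
        return len(self.trail)

    def rollback(self, mark: int) -> None:
        while len(self.trail) > mark:
            op = self.trail.pop()
            if op[0] == "union":
                _, child, root = op
                self.parent[child] = child
                self.size[root] -= self.size[child]
                self.free[root] -= self.free[child]
                self.edges[root] -= self.edges[child]
                self.ghosts[root] -= self.ghosts[child]
                self.tel[root] -= self.tel[child]
            else:  # ("edge", root)
                _, root = op
                self.free[root] += 2
                self.edges[root] -= 1

    def add_edge(self, u: int, v: int) -> tuple[int, bool]:
        """Join elements u, v by one matched slot pair.

        Returns (component root, completed) where completed means the
        component has no free slots left.
        """
        ru, rv = self.find(u), self.find(v)
        if ru != rv:
            if self.size[ru] < self.size[rv]:
                ru, rv = rv, ru
            self.parent[rv] = ru
            self.size[ru] += self.size[rv]
            self.free[ru] += self.free[rv]
            self.edges[ru] += self.edges[rv]
            self.ghosts[ru] += self.ghosts[rv]
            self.tel[ru] += self.tel[rv]
            self.trail.append(("union", rv, ru))
        self.free[ru] -= 2
        self.edges[ru] += 1
        self.trail.append(("edge", ru))
        return ru, self.free[ru] == 0


def exact_best_decomposition(
    graph: AdjacencyGraph, max_slots_per_side: int = 48
) -> Decomposition:
    """Exhaustive search for a decomposition maximizing ``c + o/2``.

    Enumerates label-preserving slot bijections depth-first, scoring
    components as they close, with two prunings: an upper bound of one
    future helpful cycle or odd path per still-open left element, and
    skipping isomorphic choices among untouched identical right elements.
    The search is seeded with the approximation algorithm's own
    decomposition, so it only explores branches that could beat it.
    """
    nl, nr = len(graph.left), len(graph.right)
    n_slots = sum(len(e.slots) for e in graph.left)
    if n_slots > max_slots_per_side:
        raise OracleSizeError(
            f"{n_slots} slots per side exceed oracle cap {max_slots_per_side}"
        )

    # global element ids: left 0..nl-1, right nl..nl+nr-1
    elems = list(graph.left) + list(graph.right)
    slots_per = [len(e.slots) for e in elems]
    ghosts = [1 if e.is_ghost else 0 for e in elems]
    tels = [1 if len(e.slots) == 1 else 0 for e in elems]

    ridx: dict[Extremity, list[tuple[int, int]]] = {}
    for eid, e in enumerate(graph.right):
        for pos, ext in enumerate(e.slots):
            ridx.setdefault(ext, []).append((eid, pos))

    # left slots, forced (rare) labels first for early pruning
    label_mult: dict[Extremity, int] = {k: len(v) for k, v in ridx.items()}
    order: list[tuple[int, int, Extremity]] = []
    for eid, e in enumerate(graph.left):
        for pos, ext in enumerate(e.slots):
            order.append((eid, pos, ext))
    order.sort(key=lambda t: (label_mult[t[2]], t[2], t[0], t[1]))

    right_used = [[False] * len(e.slots) for e in graph.right]
    right_free = [len(e.slots) for e in graph.right]

    dsu = _DSU(nl + nr, slots_per, ghosts, tels)
    open_left = nl  # left elements with at least one free slot
    left_free = [len(e.slots) for e in graph.left]

    # seed with the approximation algorithm's decomposition (2-cycle pairing
    # plus greedy packing where the graph is capped); the search then only
    # explores branches that could beat it
    all_two_slot = all(len(e.slots) == 2 for e in elems)
    cands = (
        enumerate_helpful_2cycles(graph) + enumerate_helpful_4cycles(graph)
        if all_two_slot
        else []
    )
    packing = pack_cycles(cands, mode="greedy_local", seed=0)
    seed_dec = complete_decomposition(graph, packing)
    best_score2 = _score2(components_of(graph, seed_dec))
    best_matching = dict(seed_dec.matching)

    matching: dict[tuple[int, int], tuple[int, int]] = {}
    score2 = 0

    def dfs(i: int) -> None:
        nonlocal score2, open_left, best_score2, best_matching
        if score2 + 2 * open_left <= best_score2:
            return
        if i == len(order):
            if score2 > best_score2:
                best_score2 = score2
                best_matching = dict(matching)
            return
        leid, lpos, label = order[i]
        seen_sig: set = set()
        for reid, rpos in ridx[label]:
            if right_used[reid][rpos]:
                continue
            e = graph.right[reid]
            if right_free[reid] == len(e.slots):
                sig = (e.slots, e.origin)
                if sig in seen_sig:
                    continue
                seen_sig.add(sig)
            # apply
            mark = dsu.snapshot()
            right_used[reid][rpos] = True
            right_free[reid] -= 1
            left_free[leid] -= 1
            dec_open = left_free[leid] == 0
            if dec_open:
                open_left -= 1
            root, completed = dsu.add_edge(leid, nl + reid)
            gained = 0
            if completed:
                length = dsu.edges[root]
                g = dsu.ghosts[root]
                if dsu.tel[root] == 0:
                    if g <= length // 2 - 1:
                        gained = 2  # helpful cycle
                elif length % 2 == 1:
                    gained = 1  # odd path
            score2 += gained
            matching[(leid, lpos)] = (reid, rpos)
            dfs(i + 1)
            # undo
            del matching[(leid, lpos)]
            score2 -= gained
            dsu.rollback(mark)
            if dec_open:
                open_left += 1
            left_free[leid] += 1
            right_free[reid] += 1
            right_used[reid][rpos] = False

    dfs(0)
    return Decomposition(best_matching)


def _score2(comps: Iterable[Component]) -> int:
    s = 0
    for c in comps:
        cls = c.classification
        if cls == "helpful":
            s += 2
        elif cls == "odd":
            s += 1
    return s


# ---------------------------------------------------------------------------
# telomere recovery and distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompSeq:
    """A component resolved to concrete element values (id-free).

    Same shape as :class:`Component` but nodes carry the elements
    themselves, which is what scenario construction consumes.
    """

    kind: str  # "cycle" | "path"
    nodes: tuple[tuple[str, GraphElement], ...]
    labels: tuple[Extremity, ...]

    @property
    def length(self) -> int:
        return len(self.labels)

    @property
    def ghost_count(self) -> int:
        return sum(1 for _, e in self.nodes if e.is_ghost)

    @property
    def classification(self) -> str:
        if self.kind == "cycle":
            return "helpful" if self.ghost_count <= self.length // 2 - 1 else "unhelpful"
        return "odd" if self.length % 2 else "even"


def recover_uncapped(
    graph: AdjacencyGraph, comps: Iterable[Component]
) -> list[CompSeq]:
    """Undo the capping inside a decomposition of the capped graph.

    Every matched edge whose shared label is the null extremity tau is
    removed; ``tau tau`` elements vanish and each capped element ``x tau``
    becomes the telomere ``x`` again.  A cycle with ``t`` tau edges splits
    into one path per surviving arc; tau-free cycles are unchanged.
    """
    out: list[CompSeq] = []
    for comp in comps:
        if comp.kind != "cycle":
            raise ValueError("recovery expects a capped (cycle-only) decomposition")
        m = len(comp.nodes)
        values = [graph.element(side, eid) for side, eid in comp.nodes]
        sides = [side for side, _ in comp.nodes]
        tau_pos = [i for i, lab in enumerate(comp.labels) if lab.is_tau]
        if not tau_pos:
            assert not any(v.has_tau() for v in values)
            out.append(
                CompSeq("cycle", tuple(zip(sides, values)), comp.labels)
            )
            continue
        t = len(tau_pos)
        for r in range(t):
            start = (tau_pos[r] + 1) % m
            end = tau_pos[(r + 1) % t]  # label index of the next cut
            idxs = [start]
            while idxs[-1] != end:
                idxs.append((idxs[-1] + 1) % m)
            seg_vals = [values[i] for i in idxs]
            seg_labels = [comp.labels[i] for i in idxs[:-1]] if len(idxs) > 1 else []
            if len(idxs) == 1:
                v = seg_vals[0]
                assert all(s.is_tau for s in v.slots), "lone arc must be tau tau"
                continue  # null adjacency vanishes
            # endpoints regain telomere status
            for endpoint in (0, -1):
                v = seg_vals[endpoint]
                real = [s for s in v.slots if not s.is_tau]
                assert len(real) == 1, f"cap endpoint {v} is not x-tau"
                seg_vals[endpoint] = telomere(real[0])  # original telomere again
            out.append(
                CompSeq(
                    "path",
                    tuple((sides[i], seg_vals[j]) for j, i in enumerate(idxs)),
                    tuple(seg_labels),
                )
            )
    return out


def distance_from_components(n: int, comps: Iterable) -> tuple[int, int, int]:
    """Evaluate ``n - c - o/2``; returns (distance, c, o).

    ``comps`` may be Component or CompSeq instances; ``c`` counts helpful
    cycles only and ``o`` odd paths (always even in number).
    """
    c = o = 0
    for comp in comps:
        cls = comp.classification
        if cls == "helpful":
            c += 1
        elif cls == "odd":
            o += 1
    if o % 2:
        raise ValueError(f"odd number of odd paths ({o}); component bug")
    return n - c - o // 2, c, o


# ---------------------------------------------------------------------------
# top-level distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceReport:
    """Distance plus the witnessing decomposition and its statistics.

    ``n``, ``c``, ``o`` refer to the recovered (uncapped) decomposition, so
    ``distance == n - c - o/2`` always holds; ``n_capped``/``c_capped``
    echo the telomere-free view used during the search.
    """

    distance: int
    method: str
    n: int
    c: int
    o: int
    n_capped: int
    c_capped: int
    t1_size: int
    t2_size: int
    k1: int
    k2: int
    seed: int
    packing_mode: str
    swap_radius: int
    s1: AdjacencySet
    s2: AdjacencySet
    components: tuple[CompSeq, ...]
    decomposition: Decomposition

    def summary(self) -> dict:
        return {
            "distance": self.distance,
            "method": self.method,
            "n": self.n,
            "c": self.c,
            "o": self.o,
            "n_capped": self.n_capped,
            "c_capped": self.c_capped,
            "t1": self.t1_size,
            "t2": self.t2_size,
            "k1": self.k1,
            "k2": self.k2,
            "seed": self.seed,
            "packing_mode": self.packing_mode,
            "swap_radius": self.swap_radius,
        }


def _pipeline(a: Genome, b: Genome):
    s1 = genome_to_adjacency_set(a)
    s2 = genome_to_adjacency_set(b)
    gp = compute_ghosts(s1, s2)
    cp = cap_telomeres(s1, s2)
    graph = build_graph(cp, gp)
    return s1, s2, gp, cp, graph


def edit_distance(
    a: Genome,
    b: Genome,
    method: str = "approx",
    packing_mode: str = "auto",
    swap_radius: int = 2,
    seed: int = 0,
    oracle_max_slots: int = 48,
) -> DistanceReport:
    """Approximate (default) or exact edit distance between two genomes.

    The full pipeline: ghosts -> capping -> adjacency graph -> helpful
    4-cycle packing (or exhaustive search for ``method="exact"``) ->
    completion -> telomere recovery -> ``n - c - o/2`` over the recovered
    decomposition, which also witnesses an explicit operation scenario.
    """
    s1, s2, gp, cp, graph = _pipeline(a, b)
    if method == "approx":
        candidates = enumerate_helpful_2cycles(graph) + enumerate_helpful_4cycles(graph)
        packing = pack_cycles(
            candidates, mode=packing_mode, swap_radius=swap_radius, seed=seed
        )
        dec = complete_decomposition(graph, packing)
        used_mode = packing.mode
    elif method == "exact":
        dec = exact_best_decomposition(graph, max_slots_per_side=oracle_max_slots)
        used_mode = "oracle"
    else:
        raise ValueError(f"unknown method {method!r}")

    capped_comps = components_of(graph, dec)
    _, c_capped, _ = distance_from_components(graph.n, capped_comps)
    recovered = recover_uncapped(graph, capped_comps)
    n_unc = build_uncapped_graph(s1, s2, gp).n
    distance, c, o = distance_from_components(n_unc, recovered)
    return DistanceReport(
        distance=distance,
        method=method,
        n=n_unc,
        c=c,
        o=o,
        n_capped=graph.n,
        c_capped=c_capped,
        t1_size=len(gp.t1),
        t2_size=len(gp.t2),
        k1=cp.k1,
        k2=cp.k2,
        seed=seed,
        packing_mode=used_mode,
        swap_radius=swap_radius,
        s1=s1,
        s2=s2,
        components=tuple(
            sorted(recovered, key=lambda cs: (cs.kind, cs.nodes))
        ),
        decomposition=dec,
    )


def uncapped_oracle_distance(
    a: Genome, b: Genome, max_slots_per_side: int = 48
) -> int:
    """Exact distance via path-aware search on the *uncapped* graph.

    Independent of the capping route: decompositions here contain genuine
    paths through telomeres.  Used to check that capping preserves the
    distance.
    """
    s1 = genome_to_adjacency_set(a)
    s2 = genome_to_adjacency_set(b)
    gp = compute_ghosts(s1, s2)
    graph = build_uncapped_graph(s1, s2, gp)
    dec = exact_best_decomposition(graph, max_slots_per_side=max_slots_per_side)
    comps = components_of(graph, dec)
    distance, _, _ = distance_from_components(graph.n, comps)
    return distance
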