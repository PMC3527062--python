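"""Explicit operation scenarios: transform S1 into S2, component by component.

Each component of the recovered decomposition is sorted locally:

* every ghost on the right side (surplus of genome 1) costs one deletion,
* every ghost on the left side (surplus of genome 2) costs one insertion,
* the ghost-free remainder is resolved by DCJ operations, splitting off one
  matched length-2 cycle (or length-1 path) at a time.

A helpful cycle of length ``l`` with ``d`` ghosts in T1 and ``i`` in T2
therefore costs ``d`` deletions + ``i`` insertions + ``l/2 - d - i - 1``
DCJs; an unhelpful cycle costs ``l/2`` deletions (T1 side) or ``l/2``
insertions (T2 side, bootstrapped by inserting a first gene from nothing);
paths cost ``(l-1)/2`` (odd) or ``l/2`` (even) operations.  Summed over a
decomposition with ``c`` helpful cycles and ``o`` odd paths this is exactly
``n - c - o/2`` operations, of which ``|T1|`` are deletions and ``|T2|``
insertions.

Every emitted operation is one of the set-level rewrite schemas:

* DCJ:  {pq, rs} -> {pr, qs} | {ps, qr};  {pq, r} -> {pr, q} | {p, qr};
        {p, q} -> {pq};  {pq} -> {p, q}
* INS g: {pq} -> {p gt, gh q};  {p} -> {p gt, gh};  {} -> {gt gh};
         {} -> {gt, gh}
* DEL g: the reverse of the insertion schemas.

Scenarios are replayable: :func:`verify_scenario` folds
:func:`apply_operation` over the operations and checks both the final
multiset and the deletion/insertion count law.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome_model import (
    REGULAR,
    AdjacencySet,
    Extremity,
    GraphElement,
    adjacency,
    telomere,
)
from .ghost_capping import compute_ghosts
from .adjacency_graph import LEFT, RIGHT
from .solver import CompSeq, DistanceReport

__all__ = [
    "EditOperation",
    "Scenario",
    "component_operations",
    "build_scenario",
    "apply_operation",
    "verify_scenario",
    "matches_schema",
    "VerifyResult",
    "ScenarioReplayError",
]


class ScenarioReplayError(ValueError):
    """An operation consumed elements absent from the current set."""


@dataclass(frozen=True)
class EditOperation:
    kind: str  # "DCJ" | "INS" | "DEL"
    consumed: tuple[GraphElement, ...]
    produced: tuple[GraphElement, ...]
    gene: str | None = None  # family label, INS/DEL only

    def __str__(self) -> str:  # pragma: no cover
        c = ", ".join(map(str, self.consumed)) or "{}"
        p = ", ".join(map(str, self.produced)) or "{}"
        g = f" [{self.gene}]" if self.gene else ""
        return f"{self.kind}{g}: {c} -> {p}"


@dataclass(frozen=True)
class Scenario:
    ops: tuple[EditOperation, ...]

    @property
    def counts(self) -> Counter:
        return Counter(op.kind for op in self.ops)

    def __len__(self) -> int:
        return len(self.ops)


def matches_schema(op: EditOperation) -> bool:
    """Does the rewrite match one of the set-level operation schemas?"""
    cons = Counter(s for e in op.consumed for s in e.slots)
    prod = Counter(s for e in op.produced for s in e.slots)
    if any(len(e.slots) not in (1, 2) for e in op.consumed + op.produced):
        return False
    if op.kind == "DCJ":
        if op.gene is not None or cons != prod:
            return False
        nc, np = len(op.consumed), len(op.produced)
        if not (1 <= nc <= 2 and 1 <= np <= 2):
            return False
        # a single element rewritten into itself is not an operation
        if nc == 1 and np == 1 and op.consumed[0].slots == op.produced[0].slots:
            return False
        return sum(cons.values()) <= 4
    if op.kind in ("INS", "DEL"):
        if op.gene is None:
            return False
        pair = Counter(
            (Extremity(op.gene, "t"), Extremity(op.gene, "h"))
        )
        if op.kind == "INS":
            return (
                len(op.consumed) <= 1
                and len(op.produced) <= 2
                and prod - cons == pair
                and not (cons - prod)
            )
        return (
            len(op.produced) <= 1
            and len(op.consumed) <= 2
            and cons - prod == pair
            and not (prod - cons)
        )
    return False


# ---------------------------------------------------------------------------
# per-component construction
# ---------------------------------------------------------------------------

def _rot(nodes, labels, k):
    return nodes[k:] + nodes[:k], labels[k:] + labels[:k]


def _is_right_ghost(node) -> bool:
    return node[0] == RIGHT and node[1].is_ghost


def _is_left_ghost(node) -> bool:
    return node[0] == LEFT and node[1].is_ghost


def _sort_cycle(nodes, labels) -> list[EditOperation]:
    ops: list[EditOperation] = []

    # deletions: one per ghost in T1 (right side)
    while nodes:
        m = len(nodes)
        jr = next((j for j in range(m) if _is_right_ghost(nodes[j])), None)
        if jr is None:
            break
        gene = nodes[jr][1].slots[0].gene
        nodes, labels = _rot(nodes, labels, (jr - 1) % m)  # A, ghost, B, ...
        if m == 2:
            ops.append(EditOperation("DEL", (nodes[0][1],), (), gene))
            nodes, labels = [], []
            continue
        A, B = nodes[0][1], nodes[2][1]
        merged = adjacency(labels[-1], labels[2])
        ops.append(EditOperation("DEL", (A, B), (merged,), gene))
        nodes = [(LEFT, merged)] + nodes[3:]
        labels = labels[2:]

    # insertions: one per ghost in T2 (left side)
    while nodes:
        m = len(nodes)
        ghost_idx = [j for j in range(m) if _is_left_ghost(nodes[j])]
        if not ghost_idx:
            break
        if m == 2:
            g = nodes[ghost_idx[0]][1]
            new = adjacency(g.slots[0], g.slots[1])
            assert new.slots == nodes[1 - ghost_idx[0]][1].slots
            ops.append(EditOperation("INS", (), (new,), g.slots[0].gene))
            nodes, labels = [], []
            continue
        progressed = False
        for j in ghost_idx:
            nd, lb = _rot(nodes, labels, j)  # ghost at 0
            if not nd[2][1].is_ghost:
                pass  # resolve forward
            elif not nd[m - 2][1].is_ghost:
                nd = [nd[0]] + nd[1:][::-1]  # reverse the ring, then forward
                lb = lb[::-1]
            else:
                continue
            gene = nd[0][1].slots[0].gene
            alpha, beta = lb[-1], lb[0]
            matched = adjacency(beta, lb[1])
            assert matched.slots == nd[1][1].slots
            carry = adjacency(alpha, lb[2])
            ops.append(EditOperation("INS", (nd[2][1],), (matched, carry), gene))
            nodes = [(LEFT, carry)] + nd[3:]
            labels = lb[2:]
            progressed = True
            break
        if not progressed:
            # every left element is a ghost (unhelpful T2 cycle): insert a
            # first gene from nothing as the initial operand
            j = ghost_idx[0]
            g = nodes[j][1]
            new = adjacency(g.slots[0], g.slots[1])
            ops.append(EditOperation("INS", (), (new,), g.slots[0].gene))
            nodes[j] = (LEFT, new)

    # DCJs: split off one length-2 cycle per operation
    while len(nodes) > 2:
        m = len(nodes)
        # prefer a rotation whose rewrite changes the multiset (with
        # duplicates some cuts rejoin into equal adjacencies; those are
        # legal DCJs but we avoid them when a real move exists)
        choice = 0
        for r in range(0, m, 2):
            nd, lb = _rot(nodes, labels, r)
            if Counter((nd[0][1].slots, nd[2][1].slots)) != Counter(
                (nd[1][1].slots, adjacency(lb[-1], lb[2]).slots)
            ):
                choice = r
                break
        nodes, labels = _rot(nodes, labels, choice)
        A, R, B = nodes[0][1], nodes[1][1], nodes[2][1]
        matched = adjacency(labels[0], labels[1])
        assert matched.slots == R.slots
        carry = adjacency(labels[-1], labels[2])
        ops.append(EditOperation("DCJ", (A, B), (matched, carry), None))
        nodes = [(LEFT, carry)] + nodes[3:]
        labels = labels[2:]
    if nodes:
        assert nodes[0][1].slots == nodes[1][1].slots
    return ops


def _sort_path(nodes, labels) -> list[EditOperation]:
    ops: list[EditOperation] = []

    # deletions
    while nodes:
        m = len(nodes)
        i = next((j for j in range(m) if _is_right_ghost(nodes[j])), None)
        if i is None:
            break
        gene = nodes[i][1].slots[0].gene
        A, B = nodes[i - 1][1], nodes[i + 1][1]
        a_tel, b_tel = len(A.slots) == 1, len(B.slots) == 1
        if a_tel and b_tel:
            assert m == 3
            ops.append(EditOperation("DEL", (A, B), (), gene))
            nodes, labels = [], []
        elif a_tel:
            new = telomere(labels[i + 1])
            ops.append(EditOperation("DEL", (A, B), (new,), gene))
            nodes = [(LEFT, new)] + nodes[i + 2:]
            labels = labels[i + 1:]
        elif b_tel:
            new = telomere(labels[i - 2])
            ops.append(EditOperation("DEL", (A, B), (new,), gene))
            nodes = nodes[: i - 1] + [(LEFT, new)]
            labels = labels[: i - 1]
        else:
            new = adjacency(labels[i - 2], labels[i + 1])
            ops.append(EditOperation("DEL", (A, B), (new,), gene))
            nodes = nodes[: i - 1] + [(LEFT, new)] + nodes[i + 2:]
            labels = labels[: i - 1] + labels[i + 1:]

    # insertions
    while nodes:
        m = len(nodes)
        ghost_idx = [j for j in range(m) if _is_left_ghost(nodes[j])]
        if not ghost_idx:
            break
        progressed = False
        for i in ghost_idx:
            g = nodes[i][1]
            gene = g.slots[0].gene
            alpha, beta = labels[i - 1], labels[i]
            Rp, Rn = nodes[i - 1][1], nodes[i + 1][1]
            if len(Rn.slots) == 2 and not nodes[i + 2][1].is_ghost:
                Ln, v = nodes[i + 2][1], labels[i + 1]
                matched = adjacency(beta, v)
                assert matched.slots == Rn.slots
                if len(Ln.slots) == 1:
                    new = telomere(alpha)
                    ops.append(EditOperation("INS", (Ln,), (matched, new), gene))
                    nodes = nodes[:i] + [(LEFT, new)]
                    labels = labels[:i]
                else:
                    new = adjacency(alpha, labels[i + 2])
                    ops.append(EditOperation("INS", (Ln,), (matched, new), gene))
                    nodes = nodes[:i] + [(LEFT, new)] + nodes[i + 3:]
                    labels = labels[:i] + labels[i + 2:]
            elif len(Rp.slots) == 2 and not nodes[i - 2][1].is_ghost:
                Lp, u = nodes[i - 2][1], labels[i - 2]
                matched = adjacency(u, alpha)
                assert matched.slots == Rp.slots
                if len(Lp.slots) == 1:
                    new = telomere(beta)
                    ops.append(EditOperation("INS", (Lp,), (matched, new), gene))
                    nodes = [(LEFT, new)] + nodes[i + 1:]
                    labels = labels[i:]
                else:
                    new = adjacency(labels[i - 3], beta)
                    ops.append(EditOperation("INS", (Lp,), (matched, new), gene))
                    nodes = nodes[: i - 2] + [(LEFT, new)] + nodes[i + 1:]
                    labels = labels[: i - 2] + labels[i:]
            else:
                continue
            progressed = True
            break
        if not progressed:
            # every interior resolution is blocked by further ghosts: the
            # ghost chain reaches a path end; insert the gene as a telomere
            # pair against that end (schema {} -> {gt, gh})
            for i in ghost_idx:
                g = nodes[i][1]
                gene = g.slots[0].gene
                alpha, beta = labels[i - 1], labels[i]
                Rp, Rn = nodes[i - 1][1], nodes[i + 1][1]
                if len(Rn.slots) == 1:
                    new = telomere(alpha)
                    assert telomere(beta).slots == Rn.slots
                    ops.append(
                        EditOperation("INS", (), (telomere(beta), new), gene)
                    )
                    nodes = nodes[:i] + [(LEFT, new)]
                    labels = labels[:i]
                elif len(Rp.slots) == 1:
                    new = telomere(beta)
                    assert telomere(alpha).slots == Rp.slots
                    ops.append(
                        EditOperation("INS", (), (telomere(alpha), new), gene)
                    )
                    nodes = [(LEFT, new)] + nodes[i + 1:]
                    labels = labels[i:]
                else:
                    continue
                progressed = True
                break
        assert progressed, "unresolvable ghost chain in path"

    # DCJs
    while len(nodes) > 2:
        if nodes[0][0] != LEFT and nodes[-1][0] == LEFT:
            nodes = nodes[::-1]
            labels = labels[::-1]
        if nodes[0][0] == LEFT:
            A, R, B = nodes[0][1], nodes[1][1], nodes[2][1]
            matched = adjacency(labels[0], labels[1])
            assert matched.slots == R.slots
            if len(B.slots) == 1:
                assert len(nodes) == 3
                ops.append(EditOperation("DCJ", (A, B), (matched,), None))
                nodes, labels = [], []
            else:
                new = telomere(labels[2])
                ops.append(EditOperation("DCJ", (A, B), (matched, new), None))
                nodes = [(LEFT, new)] + nodes[3:]
                labels = labels[2:]
        else:
            # both endpoints are right telomeres: split an adjacency
            Rt, L = nodes[0][1], nodes[1][1]
            t1, t2 = telomere(labels[0]), telomere(labels[1])
            assert t1.slots == Rt.slots
            ops.append(EditOperation("DCJ", (L,), (t1, t2), None))
            nodes = [(LEFT, t2)] + nodes[2:]
            labels = labels[1:]
    if len(nodes) == 2:
        assert nodes[0][1].slots == nodes[1][1].slots
    return ops


def component_operations(comp: CompSeq) -> list[EditOperation]:
    """Operations sorting one component (deletions, insertions, then DCJs)."""
    nodes, labels = list(comp.nodes), list(comp.labels)
    if comp.kind == "cycle":
        return _sort_cycle(nodes, labels)
    return _sort_path(nodes, labels)


def build_scenario(report: DistanceReport) -> Scenario:
    """Concatenate component operations in deterministic component order."""
    ops: list[EditOperation] = []
    for comp in report.components:
        ops.extend(component_operations(comp))
    return Scenario(tuple(ops))


# ---------------------------------------------------------------------------
# replay
# ---------------------------------------------------------------------------

def apply_operation(s: AdjacencySet, op: EditOperation) -> AdjacencySet:
    """Apply one rewrite; consumed elements must be present (multiset)."""
    ctr = Counter(e.slots for e in s)
    for e in op.consumed:
        if ctr[e.slots] <= 0:
            raise ScenarioReplayError(f"missing element {e} for {op}")
        ctr[e.slots] -= 1
    remaining = Counter(e.slots for e in op.consumed)
    elems = []
    for e in s:
        if remaining.get(e.slots, 0) > 0:
            remaining[e.slots] -= 1
            continue
        elems.append(e)
    elems.extend(GraphElement(e.slots, REGULAR) for e in op.produced)
    return AdjacencySet(elems)


@dataclass(frozen=True)
class VerifyResult:
    ok: bool
    message: str = ""

    def __bool__(self) -> bool:  # pragma: no cover
        return self.ok


def verify_scenario(
    s1: AdjacencySet,
    sc: Scenario,
    s2: AdjacencySet,
    expected_distance: int | None = None,
) -> VerifyResult:
    """Replay a scenario and check the count law.

    ok iff every step applies, every operation matches a rewrite schema,
    the final multiset equals ``s2``, and the counts satisfy
    DEL = |T1|, INS = |T2| (and total = expected_distance when given).
    """
    gp = compute_ghosts(s1, s2)
    cur = s1
    for step, op in enumerate(sc.ops):
        if not matches_schema(op):
            return VerifyResult(False, f"step {step}: {op} matches no schema")
        try:
            cur = apply_operation(cur, op)
        except ScenarioReplayError as exc:
            return VerifyResult(False, f"step {step}: {exc}")
    if Counter(e.slots for e in cur) != Counter(e.slots for e in s2):
        return VerifyResult(False, "final adjacency set differs from target")
    counts = sc.counts
    if counts.get("DEL", 0) != len(gp.t1):
        return VerifyResult(
            False, f"{counts.get('DEL', 0)} deletions, expected {len(gp.t1)}"
        )
    if counts.get("INS", 0) != len(gp.t2):
        return VerifyResult(
            False, f"{counts.get('INS', 0)} insertions, expected {len(gp.t2)}"
        )
    if expected_distance is not None and len(sc.ops) != expected_distance:
        return VerifyResult(
            False, f"{len(sc.ops)} operations, reported distance {expected_distance}"
        )
    return VerifyResult(True, "ok")
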