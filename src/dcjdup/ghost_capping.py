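"""Ghost adjacencies and telomere capping.

Two preprocessing steps turn a pair of adjacency sets into a balanced,
telomere-free instance:

* *Ghosts*: for every gene family the copy-number surplus of one genome over
  the other is represented by ghost adjacencies ``g_h g_t`` (one per surplus
  copy).  ``T1`` holds the surplus of genome 1 (genes that must be deleted),
  ``T2`` the surplus of genome 2 (genes that must be inserted).  Surplus
  extremities are paired head-with-tail within their own family, matching the
  single-gene insertion/deletion operations that will consume them.

* *Capping*: every telomere ``x`` is replaced by the adjacency ``x tau``
  with the null extremity tau, and ``|k2 - k1|`` null adjacencies ``tau tau``
  are added to the side with fewer telomeres (``2*k_i`` telomeres on side
  ``i``).  Afterwards both sides expose the same multiset of extremity
  labels and the adjacency graph decomposes into cycles only; the edit
  distance is unchanged by this transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import (
    GHOST,
    HEAD,
    NULL_CAP,
    TAIL,
    TAU,
    AdjacencySet,
    Extremity,
    GraphElement,
    InconsistentAdjacencySetError,
    adjacency,
)

__all__ = ["GhostPair", "CappedPair", "compute_ghosts", "cap_telomeres"]


@dataclass(frozen=True)
class GhostPair:
    """Ghost adjacencies for both directions of content difference."""

    t1: tuple[GraphElement, ...]  # surplus of genome 1 -> deletions
    t2: tuple[GraphElement, ...]  # surplus of genome 2 -> insertions


@dataclass(frozen=True)
class CappedPair:
    """Telomere-free adjacency sets plus the original telomere half-counts."""

    s1_capped: AdjacencySet
    s2_capped: AdjacencySet
    k1: int
    k2: int


def _ghost(gene: str) -> GraphElement:
    return adjacency(Extremity(gene, HEAD), Extremity(gene, TAIL), origin=GHOST)


def compute_ghosts(s1: AdjacencySet, s2: AdjacencySet) -> GhostPair:
    """Pair surplus extremities into per-family ghost adjacencies."""
    c1, c2 = s1.copy_numbers(), s2.copy_numbers()
    t1: list[GraphElement] = []
    t2: list[GraphElement] = []
    for fam in sorted(set(c1) | set(c2)):
        surplus = c1[fam] - c2[fam]
        if surplus > 0:
            t1.extend(_ghost(fam) for _ in range(surplus))
        elif surplus < 0:
            t2.extend(_ghost(fam) for _ in range(-surplus))
    return GhostPair(tuple(t1), tuple(t2))


def _cap_one(s: AdjacencySet) -> tuple[list[GraphElement], int]:
    out: list[GraphElement] = []
    n_tel = 0
    for e in s:
        if e.is_telomere:
            n_tel += 1
            out.append(adjacency(e.slots[0], TAU, origin=NULL_CAP))
        else:
            out.append(e)
    if n_tel % 2:
        raise InconsistentAdjacencySetError(
            f"odd telomere count {n_tel} (no genome has an odd number)"
        )
    return out, n_tel // 2


def cap_telomeres(s1: AdjacencySet, s2: AdjacencySet) -> CappedPair:
    """Replace telomeres by ``x tau`` caps and balance with ``tau tau``.

    Idempotent: sets without telomeres are returned unchanged (no
    ``tau tau`` is added when ``k1 == k2``).
    """
    e1, k1 = _cap_one(s1)
    e2, k2 = _cap_one(s2)
    null_adj = adjacency(TAU, TAU, origin=NULL_CAP)
    if k1 < k2:
        e1.extend(null_adj for _ in range(k2 - k1))
    elif k2 < k1:
        e2.extend(null_adj for _ in range(k1 - k2))
    return CappedPair(AdjacencySet(e1), AdjacencySet(e2), k1, k2)
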