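"""Genomes as signed gene orders, and their adjacency-set representation.

A gene ``g`` has two extremities, the tail ``g_t`` and the head ``g_h``.
Written in forward orientation (``+g``) a gene exposes its tail on the left
and its head on the right; ``-g`` is the reverse.  Two consecutive genes on
a chromosome are connected by an *adjacency* (an unordered pair of
extremities); each end of a linear chromosome is a *telomere* (a single
extremity).  The adjacencies and telomeres of a genome form a multiset, the
*adjacency set*, which is the level at which the edit distance is defined.

Duplicate genes are allowed: the same family label may occur many times, so
an adjacency set is a true multiset and may admit several distinct genome
structures (:func:`realize_genome` returns one deterministic realization).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "Extremity",
    "TAU",
    "GraphElement",
    "Chromosome",
    "Genome",
    "AdjacencySet",
    "REGULAR",
    "GHOST",
    "NULL_CAP",
    "adjacency",
    "telomere",
    "parse_genomes",
    "write_genomes",
    "genome_to_adjacency_set",
    "realize_genome",
    "GenomeFormatError",
    "InconsistentAdjacencySetError",
]

HEAD = "h"
TAIL = "t"

#: element origins
REGULAR = "regular"
GHOST = "ghost"
NULL_CAP = "null-cap"

RESERVED_TOKENS = {"TAU", "|", ")", ">"}


class GenomeFormatError(ValueError):
    """Raised on malformed gene-order documents."""


class InconsistentAdjacencySetError(ValueError):
    """Raised when a multiset of adjacencies/telomeres admits no genome."""


class Extremity(NamedTuple):
    """One end of a gene: ``(family, 'h'|'t')``; the null extremity is TAU."""

    gene: str
    end: str

    @property
    def is_tau(self) -> bool:
        return self.gene == ""

    def opposite(self) -> "Extremity":
        if self.is_tau:
            raise ValueError("the null extremity has no opposite end")
        return Extremity(self.gene, TAIL if self.end == HEAD else HEAD)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return "tau" if self.is_tau else f"{self.gene}{self.end}"


#: the null extremity used to cap telomeres; never present in parsed genomes
TAU = Extremity("", "")


class GraphElement(NamedTuple):
    """An adjacency (2 slots) or telomere (1 slot) with an origin tag.

    Two-slot elements are unordered pairs; slots are kept sorted so value
    equality matches the mathematical definition (``pq == qp``).
    """

    slots: tuple[Extremity, ...]
    origin: str = REGULAR

    @property
    def is_telomere(self) -> bool:
        return len(self.slots) == 1

    @property
    def is_ghost(self) -> bool:
        return self.origin == GHOST

    def has_tau(self) -> bool:
        return any(s.is_tau for s in self.slots)

    def other_slot(self, pos: int) -> Extremity:
        return self.slots[1 - pos]

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return "(" + " ".join(str(s) for s in self.slots) + ")"


def adjacency(a: Extremity, b: Extremity, origin: str = REGULAR) -> GraphElement:
    """Unordered 2-slot element; slots stored in canonical (sorted) order."""
    return GraphElement(tuple(sorted((a, b))), origin)


def telomere(a: Extremity, origin: str = REGULAR) -> GraphElement:
    if a.is_tau:
        raise ValueError("a telomere cannot be the null extremity")
    return GraphElement((a,), origin)


@dataclass(frozen=True)
class Chromosome:
    """Ordered signed genes plus a topology flag."""

    genes: tuple[tuple[str, int], ...]  # (family label, +1|-1)
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("chromosome must contain at least one gene")
        for g, s in self.genes:
            if s not in (+1, -1):
                raise ValueError(f"bad orientation {s!r} for gene {g!r}")


@dataclass(frozen=True)
class Genome:
    name: str
    chromosomes: tuple[Chromosome, ...] = ()

    def gene_count(self) -> int:
        return sum(len(c.genes) for c in self.chromosomes)

    def family_counts(self) -> Counter:
        return Counter(g for c in self.chromosomes for g, _ in c.genes)


class AdjacencySet:
    """Multiset of :class:`GraphElement` (adjacencies and telomeres)."""

    __slots__ = ("elements",)

    def __init__(self, elements: Iterable[GraphElement] = ()):
        self.elements: tuple[GraphElement, ...] = tuple(elements)

    def __iter__(self) -> Iterator[GraphElement]:
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AdjacencySet):
            return NotImplemented
        return Counter(self.elements) == Counter(other.elements)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AdjacencySet({sorted(self.elements)!r})"

    def counter(self) -> Counter:
        return Counter(self.elements)

    def slot_counter(self) -> Counter:
        """Multiplicity of every extremity label over all slots."""
        return Counter(s for e in self.elements for s in e.slots)

    def telomere_count(self) -> int:
        return sum(1 for e in self.elements if e.is_telomere)

    def copy_numbers(self) -> Counter:
        """Gene-family copy numbers implied by head occurrences."""
        c = Counter()
        for e in self.elements:
            for s in e.slots:
                if not s.is_tau and s.end == HEAD:
                    c[s.gene] += 1
        return c


# ---------------------------------------------------------------------------
# gene-order document I/O
# ---------------------------------------------------------------------------

def _check_gene_token(tok: str) -> str:
    if tok in RESERVED_TOKENS or tok.startswith("-") or tok.startswith(">"):
        raise GenomeFormatError(f"reserved or malformed gene token {tok!r}")
    return tok


def parse_genomes(text: str) -> list[Genome]:
    """Parse a gene-order document.

    Lines starting with ``>`` open a genome; subsequent whitespace-separated
    signed gene tokens accumulate into chromosomes terminated by ``|``
    (linear) or ``)`` (circular).  ``#`` starts a comment.
    """
    genomes: list[Genome] = []
    name: str | None = None
    chroms: list[Chromosome] = []
    pending: list[tuple[str, int]] = []

    def flush_genome() -> None:
        nonlocal name, chroms, pending
        if name is None:
            return
        if pending:
            raise GenomeFormatError(
                f"genome {name!r}: chromosome without terminator ('|' or ')')"
            )
        genomes.append(Genome(name, tuple(chroms)))
        name, chroms = None, []

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush_genome()
            name = line[1:].strip()
            if not name:
                raise GenomeFormatError("empty genome name after '>'")
            continue
        if name is None:
            raise GenomeFormatError(f"gene data before any '>' header: {line!r}")
        for tok in line.split():
            if tok in ("|", ")"):
                if not pending:
                    raise GenomeFormatError(
                        f"genome {name!r}: empty chromosome before {tok!r}"
                    )
                chroms.append(Chromosome(tuple(pending), circular=(tok == ")")))
                pending = []
            elif tok.startswith("-"):
                pending.append((_check_gene_token(tok[1:]), -1))
            else:
                pending.append((_check_gene_token(tok), +1))
    flush_genome()
    return genomes


def write_genomes(genomes: Iterable[Genome]) -> str:
    """Inverse of :func:`parse_genomes` on canonical documents."""
    lines: list[str] = []
    for g in genomes:
        lines.append(f">{g.name}")
        for c in g.chromosomes:
            toks = [(lbl if s > 0 else f"-{lbl}") for lbl, s in c.genes]
            toks.append(")" if c.circular else "|")
            lines.append(" ".join(toks))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# genome <-> adjacency set
# ---------------------------------------------------------------------------

def _left_ext(gene: str, sign: int) -> Extremity:
    return Extremity(gene, TAIL if sign > 0 else HEAD)


def _right_ext(gene: str, sign: int) -> Extremity:
    return Extremity(gene, HEAD if sign > 0 else TAIL)


def genome_to_adjacency_set(g: Genome) -> AdjacencySet:
    """One adjacency per consecutive gene pair, one telomere per linear end."""
    out: list[GraphElement] = []
    for chrom in g.chromosomes:
        genes = chrom.genes
        for (ga, sa), (gb, sb) in zip(genes, genes[1:]):
            out.append(adjacency(_right_ext(ga, sa), _left_ext(gb, sb)))
        if chrom.circular:
            out.append(
                adjacency(_right_ext(*genes[-1]), _left_ext(*genes[0]))
            )
        else:
            out.append(telomere(_left_ext(*genes[0])))
            out.append(telomere(_right_ext(*genes[-1])))
    return AdjacencySet(out)


def realize_genome(s: AdjacencySet, name: str = "realized") -> Genome:
    """Return one genome whose adjacency set equals ``s``.

    With duplicate genes several structures can share the same adjacency
    set; a deterministic one is produced by pairing, family by family, the
    sorted head slots with the sorted tail slots (each pair is one gene
    copy), then reading off the resulting paths (linear chromosomes, started
    from the smallest telomere) and cycles (circular chromosomes, started
    from the smallest element).
    """
    elements = sorted(s.elements)
    # collect slots per extremity label
    by_label: dict[Extremity, list[tuple[int, int]]] = defaultdict(list)
    for eid, e in enumerate(elements):
        for pos, ext in enumerate(e.slots):
            if ext.is_tau:
                raise InconsistentAdjacencySetError(
                    "null extremities cannot be realized as a genome"
                )
            by_label[ext].append((eid, pos))

    # one gene copy joins a head slot to a tail slot of the same family
    partner: dict[tuple[int, int], tuple[int, int]] = {}
    families = {ext.gene for ext in by_label}
    for fam in sorted(families):
        heads = by_label.get(Extremity(fam, HEAD), [])
        tails = by_label.get(Extremity(fam, TAIL), [])
        if len(heads) != len(tails):
            raise InconsistentAdjacencySetError(
                f"family {fam!r}: {len(heads)} heads vs {len(tails)} tails"
            )
        for hs, ts in zip(heads, tails):
            partner[hs] = ts
            partner[ts] = hs

    if s.telomere_count() % 2:
        raise InconsistentAdjacencySetError("odd number of telomeres")

    used = [False] * len(elements)
    chroms: list[Chromosome] = []

    def walk(start_slot: tuple[int, int], circular: bool) -> Chromosome:
        genes: list[tuple[str, int]] = []
        slot = start_slot
        start_eid = start_slot[0]
        while True:
            eid, pos = slot
            used[eid] = True
            left = elements[eid].slots[pos]
            genes.append((left.gene, +1 if left.end == TAIL else -1))
            nxt_eid, nxt_pos = partner[slot]
            if circular and nxt_eid == start_eid:
                break
            used[nxt_eid] = True
            if elements[nxt_eid].is_telomere:
                break
            slot = (nxt_eid, 1 - nxt_pos)
        return Chromosome(tuple(genes), circular=circular)

    # linear chromosomes first, from the smallest unused telomere
    for eid, e in enumerate(elements):
        if e.is_telomere and not used[eid]:
            used[eid] = True
            chroms.append(walk((eid, 0), circular=False))
    # remaining elements belong to circular chromosomes
    for eid, e in enumerate(elements):
        if not used[eid]:
            chroms.append(walk((eid, 0), circular=True))

    g = Genome(name, tuple(chroms))
    if genome_to_adjacency_set(g) != s:
        raise InconsistentAdjacencySetError(
            "multiset admits no genome realization"
        )
    return g
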