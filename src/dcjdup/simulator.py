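"""Random genomes and randomized operation histories for testing.

Instances are generated the way the model sees them: a random genome with
duplicate genes is built first, then a history of DCJ / insertion /
deletion operations is sampled directly on its adjacency set (each step a
valid rewrite schema) and the result is realized back into a genome.  The
history length is therefore an upper bound on the true edit distance of
the generated pair, which makes simulated pairs useful ground-truth-free
test cases.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .genome_model import (
    HEAD,
    TAIL,
    AdjacencySet,
    Chromosome,
    Extremity,
    Genome,
    GraphElement,
    adjacency,
    genome_to_adjacency_set,
    realize_genome,
    telomere,
)
from .scenario import EditOperation, apply_operation

__all__ = ["SimulationConfig", "random_genome", "apply_random_operations"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for instance generation.

    ``copy_rate`` is the expected number of extra copies per gene family
    (truncated geometric, at most ``max_extra_copies`` so the copy number
    stays small enough for the exact oracle); ``weights`` are the sampling
    probabilities of (DCJ, INS, DEL) in a history of ``ops`` steps.
    """

    families: int = 6
    copy_rate: float = 0.3
    max_extra_copies: int = 2
    chromosomes: int = 2
    circular_fraction: float = 0.5
    ops: int = 3
    weights: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("operation weights must sum to 1")
        if self.families < 1 or self.chromosomes < 1 or self.ops < 0:
            raise ValueError("counts must be positive")


def random_genome(cfg: SimulationConfig, name: str = "sim") -> Genome:
    """Random genome: family copy numbers, order, signs and topologies."""
    rng = random.Random(f"{cfg.seed}:genome")
    p = cfg.copy_rate / (1.0 + cfg.copy_rate) if cfg.copy_rate > 0 else 0.0
    tokens: list[str] = []
    for i in range(cfg.families):
        fam = f"g{i + 1}"
        copies = 1
        while copies <= cfg.max_extra_copies and rng.random() < p:
            copies += 1
        tokens.extend([fam] * copies)
    rng.shuffle(tokens)
    n_chrom = min(cfg.chromosomes, len(tokens))
    # cut points splitting the token list into non-empty chromosomes
    cuts = sorted(rng.sample(range(1, len(tokens)), n_chrom - 1)) if n_chrom > 1 else []
    bounds = [0] + cuts + [len(tokens)]
    chroms = []
    for lo, hi in zip(bounds, bounds[1:]):
        genes = tuple((t, rng.choice((1, -1))) for t in tokens[lo:hi])
        chroms.append(
            Chromosome(genes, circular=rng.random() < cfg.circular_fraction)
        )
    return Genome(name, tuple(chroms))


def _slot_occurrences(s: AdjacencySet, ext: Extremity):
    return [
        (i, pos)
        for i, e in enumerate(s.elements)
        for pos, x in enumerate(e.slots)
        if x == ext
    ]


def _join(p: Extremity | None, q: Extremity | None) -> tuple[GraphElement, ...]:
    if p is not None and q is not None:
        return (adjacency(p, q),)
    if p is not None:
        return (telomere(p),)
    if q is not None:
        return (telomere(q),)
    return ()


def _sample_dcj(cur: AdjacencySet, rng: random.Random) -> EditOperation | None:
    elems = list(cur.elements)
    if not elems:
        return None
    two_slot = [e for e in elems if len(e.slots) == 2]
    if len(elems) >= 2 and (rng.random() < 0.85 or not two_slot):
        i, j = rng.sample(range(len(elems)), 2)
        a, b = elems[i], elems[j]
        a1 = a.slots[0]
        a2 = a.slots[1] if len(a.slots) == 2 else None
        b1 = b.slots[0]
        b2 = b.slots[1] if len(b.slots) == 2 else None
        if rng.random() < 0.5:
            b1, b2 = b2, b1
        produced = _join(a1, b1) + _join(a2, b2)
        return EditOperation("DCJ", (a, b), produced, None)
    if not two_slot:
        return None
    e = rng.choice(two_slot)
    return EditOperation(
        "DCJ", (e,), (telomere(e.slots[0]), telomere(e.slots[1])), None
    )


def _sample_ins(
    cur: AdjacencySet, rng: random.Random, labels: set[str], fresh: list[int]
) -> EditOperation:
    if labels and rng.random() < 0.5:
        fam = rng.choice(sorted(labels))  # duplication of an existing family
    else:
        fresh[0] += 1
        while f"n{fresh[0]}" in labels:
            fresh[0] += 1
        fam = f"n{fresh[0]}"
    gt, gh = Extremity(fam, TAIL), Extremity(fam, HEAD)
    r = rng.random()
    if cur.elements and r < 0.7:
        e = rng.choice(cur.elements)
        left, right = (gt, gh) if rng.random() < 0.5 else (gh, gt)
        if len(e.slots) == 2:
            p, q = e.slots
            return EditOperation(
                "INS", (e,), (adjacency(p, left), adjacency(right, q)), fam
            )
        return EditOperation(
            "INS", (e,), (adjacency(e.slots[0], left), telomere(right)), fam
        )
    if r < 0.85:
        return EditOperation("INS", (), (adjacency(gt, gh),), fam)
    return EditOperation("INS", (), (telomere(gt), telomere(gh)), fam)


def _sample_del(cur: AdjacencySet, rng: random.Random) -> EditOperation | None:
    fams = sorted(cur.copy_numbers())
    if not fams:
        return None
    fam = rng.choice(fams)
    gt, gh = Extremity(fam, TAIL), Extremity(fam, HEAD)
    t_i, t_pos = rng.choice(_slot_occurrences(cur, gt))
    h_i, h_pos = rng.choice(_slot_occurrences(cur, gh))
    et, eh = cur.elements[t_i], cur.elements[h_i]
    if t_i == h_i:
        # one element holding both extremities is exactly {gt gh}
        return EditOperation("DEL", (et,), (), fam)
    p = et.other_slot(t_pos) if len(et.slots) == 2 else None
    q = eh.other_slot(h_pos) if len(eh.slots) == 2 else None
    return EditOperation("DEL", (et, eh), _join(p, q), fam)


def apply_random_operations(
    g: Genome, cfg: SimulationConfig, name: str = "derived"
) -> tuple[Genome, list[EditOperation]]:
    """Sample ``cfg.ops`` weighted operations on the adjacency set of ``g``.

    Returns the realized result genome and the operation log; the log
    length bounds the edit distance between input and output from above.
    An operation kind with no applicable operands is resampled.
    """
    rng = random.Random(f"{cfg.seed}:ops")
    cur = genome_to_adjacency_set(g)
    labels = {fam for fam in g.family_counts()}
    fresh = [0]
    log: list[EditOperation] = []
    kinds = ("DCJ", "INS", "DEL")
    for _ in range(cfg.ops):
        op = None
        for _attempt in range(50):
            kind = rng.choices(kinds, weights=cfg.weights)[0]
            if kind == "DCJ":
                op = _sample_dcj(cur, rng)
            elif kind == "INS":
                op = _sample_ins(cur, rng, labels, fresh)
            else:
                op = _sample_del(cur, rng)
            if op is not None:
                break
        if op is None:  # pragma: no cover - empty genome corner
            break
        if op.kind == "INS":
            labels.add(op.gene)
        cur = apply_operation(cur, op)
        log.append(op)
    if not log:
        return Genome(name, g.chromosomes), log
    return realize_genome(cur, name=name), log
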