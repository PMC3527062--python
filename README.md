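# dcjdup

Edit distance between genomes **with duplicate genes** under unit-cost
**DCJ** (double-cut-and-join), single-gene **insertion** and single-gene
**deletion** — for researchers in genome rearrangement and comparative
genomics who need a distance, a certificate, and an explicit mutation
scenario when gene content is unequal and families have several copies.

## The model

Each gene `g` has a tail `g_t` and a head `g_h`. A genome is encoded by its
**adjacency set**: the multiset of adjacencies (unordered extremity pairs of
consecutive genes) and telomeres (single extremities at linear chromosome
ends). The edit distance `d(S1, S2)` is the minimum number of operations
transforming one adjacency set into the other, where one operation is a DCJ
(`{pq, rs} -> {pr, qs}` and its telomere variants), an insertion of one gene
(`{pq} -> {p g_t, g_h q}`, ...), or a deletion (the reverse).

Content differences are materialized as **ghost adjacencies**: one
`g_h g_t` pair per surplus copy of a family (set `T1` for genome 1's
surplus, `T2` for genome 2's). On the bipartite **adjacency graph** of
`S1 ∪ T2` versus `S2 ∪ T1`, with `n` half the number of extremities,

```
d(S1, S2) = n - max_D ( c_D + o_D / 2 )
```

over all decompositions `D` into vertex-disjoint alternating cycles and
paths, where `c_D` counts **helpful** cycles (length `l` with at most
`l/2 - 1` ghosts) and `o_D` odd-length paths. Finding the maximum is
NP-hard; with duplicates the graph has vertices of degree above two and
exponentially many decompositions.

`dcjdup` provides:

* **approximate distance** — telomeres are capped with null extremities
  `τ` so the graph decomposes into cycles only, all helpful cycles of
  length 2 and 4 are collected, a maximum element-disjoint subset is packed
  (exact branch-and-bound, or greedy + local search on large inputs), the
  matching is completed arbitrarily, and the caps are removed again. With
  exact packing the result is at most **1.5×** the optimal distance.
* **exact distance** — a brute-force oracle enumerating label-preserving
  slot matchings with pruning; practical up to a few dozen extremities per
  genome.
* **scenarios** — an ordered, replayable list of concrete operations whose
  length equals the reported distance, with exactly `|T1|` deletions and
  `|T2|` insertions.
* **a simulator** — random genomes with duplicate families evolved by
  sampled operations, so every instance ships with a distance upper bound.

## Worked example

`A.txt` and `B.txt` in UniMoG-style gene-order format (`|` ends a linear
chromosome, `)` a circular one, `-` flips orientation):

```
>lineage_A            >lineage_B
a b -c d |            a c d |
e )                   d -b |
```

```console
$ dcjdup distance A.txt B.txt --method exact
{ "distance": 4, "n": 6, "c": 1, "o": 2, "t1": 1, "t2": 1, ... }
```

Four operations separate the two genomes: genome B lacks `e` and carries an
extra copy of `d`, so any optimal scenario has exactly one deletion and one
insertion (`t1`, `t2`), plus two DCJs; `n - c - o/2 = 6 - 1 - 1 = 4`. The
scenario subcommand prints the operations and verifies them by replay:

```console
$ dcjdup scenario A.txt B.txt --method exact
step  kind  gene  consumed         produced
0     INS   d     (bh ch)          (bh dh),(ch dt)
1     DEL   e     (eh et)
2     DCJ         (ah bt)          (bt),(ah)
3     DCJ         (ah),(ct dt)     (ah ct),(dt)
```

Replace `--method exact` with the default approximation for genomes beyond
oracle size; `oracle` and `simulate` subcommands complete the interface.

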