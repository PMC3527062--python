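"""Packing, completion, the exact oracle, recovery, and distances."""

import itertools

import pytest

from dcjdup.genome_model import (
    genome_to_adjacency_set,
    parse_genomes,
)
from dcjdup.ghost_capping import cap_telomeres, compute_ghosts
from dcjdup.adjacency_graph import (
    CandidateCycle,
    build_graph,
    components_of,
    enumerate_helpful_4cycles,
    validate_decomposition,
)
from dcjdup.solver import (
    OracleSizeError,
    PackingSizeError,
    complete_decomposition,
    distance_from_components,
    edit_distance,
    exact_best_decomposition,
    pack_cycles,
    recover_uncapped,
    uncapped_oracle_distance,
)


def pair(text_a, text_b):
    a, b = parse_genomes(f">A\n{text_a}\n>B\n{text_b}")
    return a, b


def capped(text_a, text_b):
    a, b = pair(text_a, text_b)
    s1, s2 = genome_to_adjacency_set(a), genome_to_adjacency_set(b)
    gp = compute_ghosts(s1, s2)
    return build_graph(cap_telomeres(s1, s2), gp)


def chain_candidate(lo: int) -> CandidateCycle:
    """Dummy candidate covering left/right elements lo, lo+1."""
    return CandidateCycle(
        (lo, lo + 1),
        (lo, lo + 1),
        (((lo, 0), (lo, 0)),),
        0,
    )


class TestPacking:
    def test_disjoint_candidates_all_selected(self):
        cands = [chain_candidate(0), chain_candidate(2), chain_candidate(4)]
        res = pack_cycles(cands, mode="exact")
        assert len(res.selected) == 3

    def test_exact_picks_outer_pair_of_conflicting_chain(self):
        # coverage {0,1},{1,2},{2,3}: brute force over all subsets says the
        # maximum disjoint selection has size 2 (the outer candidates)
        cands = [chain_candidate(0), chain_candidate(1), chain_candidate(2)]
        best = max(
            (
                sub
                for r in range(4)
                for sub in itertools.combinations(range(3), r)
                if not any(
                    cands[i].covered() & cands[j].covered()
                    for i, j in itertools.combinations(sub, 2)
                )
            ),
            key=len,
        )
        res = pack_cycles(cands, mode="exact")
        assert len(res.selected) == len(best) == 2

    def test_empty_candidates(self):
        assert pack_cycles([], mode="exact").selected == ()

    def test_exact_refused_above_cap(self):
        cands = [chain_candidate(2 * i) for i in range(10)]
        with pytest.raises(PackingSizeError):
            pack_cycles(cands, mode="exact", exact_limit=5)

    def test_greedy_local_matches_exact_on_random_conflicts(self):
        import random

        rng = random.Random(7)
        for _ in range(20):
            cands = [chain_candidate(rng.randrange(8)) for _ in range(8)]
            exact = pack_cycles(cands, mode="exact")
            greedy = pack_cycles(cands, mode="greedy_local", seed=1)
            assert len(greedy.selected) <= len(exact.selected)
            # greedy is at least maximal: no candidate fits beside it
            cov = set().union(*(c.covered() for c in greedy.selected)) if greedy.selected else set()
            assert all(c.covered() & cov for c in cands if c not in greedy.selected)


class TestCompletion:
    def test_packed_inversion_cycle_extends_to_full_matching(self):
        g = capped("a b )", "a -b )")
        packing = pack_cycles(enumerate_helpful_4cycles(g), mode="exact")
        dec = complete_decomposition(g, packing)
        assert validate_decomposition(g, dec) == []
        assert len(components_of(g, dec)) == 1

    def test_empty_packing_pairs_identical_elements(self):
        g = capped("a b |", "a b |")
        dec = complete_decomposition(g, pack_cycles([], mode="exact"))
        comps = components_of(g, dec)
        assert sorted(c.length for c in comps) == [2, 2, 2]

    def test_completion_always_valid(self):
        g = capped("a a b |", "b a )")
        dec = complete_decomposition(g, pack_cycles([], mode="exact"))
        assert validate_decomposition(g, dec) == []


class TestOracle:
    @pytest.mark.parametrize(
        "ta,tb,expected",
        [
            ("a b )", "a -b )", 1),   # one inversion-equivalent DCJ
            ("a b |", "a b |", 0),    # identical
            ("a |", "a a |", 1),      # one insertion
            ("a )", "a |", 1),        # circularization
            ("a b c |", "c b a |", 2),
        ],
    )
    def test_known_distances(self, ta, tb, expected):
        a, b = pair(ta, tb)
        assert edit_distance(a, b, method="exact").distance == expected

    def test_oracle_maximizes_helpful_cycles(self):
        g = capped("a |", "a a |")
        dec = exact_best_decomposition(g)
        _, c, _ = distance_from_components(
            g.n, components_of(g, dec)
        )
        assert (g.n, c) == (3, 2)  # ghost 2-cycle stays unhelpful

    def test_size_cap(self):
        g = capped("a b )", "a -b )")
        with pytest.raises(OracleSizeError):
            exact_best_decomposition(g, max_slots_per_side=2)

    def test_oracle_beats_exhaustive_bijection_scan(self):
        # tiny instance: compare against a straight product-of-permutations
        # enumeration of every label-preserving bijection
        import itertools as it

        g = capped("a a )", "a -a )")
        ridx = g.label_index("right")
        lidx = g.label_index("left")
        labels = sorted(ridx)
        best = -1
        choices = [list(it.permutations(ridx[lab])) for lab in labels]
        for combo in it.product(*choices):
            matching = {}
            for lab, perm in zip(labels, combo):
                for ls, rs in zip(lidx[lab], perm):
                    matching[ls] = rs
            from dcjdup.adjacency_graph import Decomposition

            comps = components_of(g, Decomposition(matching))
            _, c, o = distance_from_components(g.n, comps)
            best = max(best, 2 * c + o)
        dec = exact_best_decomposition(g)
        _, c, o = distance_from_components(g.n, components_of(g, dec))
        assert 2 * c + o == best


class TestRecovery:
    def test_cap_2cycle_becomes_odd_path(self):
        g = capped("a |", "a |")
        dec = exact_best_decomposition(g)
        recovered = recover_uncapped(g, components_of(g, dec))
        assert sorted(c.classification for c in recovered) == ["odd", "odd"]
        assert all(c.length == 1 for c in recovered)

    def test_null_adjacency_cycle_becomes_even_path(self):
        g = capped("a )", "a |")
        dec = exact_best_decomposition(g)
        recovered = recover_uncapped(g, components_of(g, dec))
        assert [c.classification for c in recovered] == ["even"]
        assert recovered[0].length == 2

    def test_tau_free_cycles_unchanged(self):
        g = capped("a b )", "a -b )")
        dec = exact_best_decomposition(g)
        comps = components_of(g, dec)
        recovered = recover_uncapped(g, comps)
        assert [(c.kind, c.length) for c in recovered] == [
            (c.kind, c.length) for c in comps
        ]


class TestDistanceFormula:
    def test_formula_values(self):
        a, b = pair("a b )", "a -b )")
        rep = edit_distance(a, b, method="exact")
        assert (rep.n, rep.c, rep.o, rep.distance) == (2, 1, 0, 1)

    def test_identical_genomes_zero(self):
        a, b = pair("a b c | d )", "a b c | d )")
        rep = edit_distance(a, b)
        assert rep.distance == 0

    def test_two_odd_paths(self):
        # identical single linear gene: n=1, c=0, o=2 -> distance 0
        a, b = pair("a |", "a |")
        rep = edit_distance(a, b, method="exact")
        assert (rep.n, rep.c, rep.o, rep.distance) == (1, 0, 2, 0)

    def test_insertion_distance_report(self):
        a, b = pair("a |", "a a |")
        rep = edit_distance(a, b, method="exact")
        assert rep.distance == 1
        assert (rep.t1_size, rep.t2_size) == (0, 1)
        assert rep.distance == rep.n - rep.c - rep.o // 2

    def test_capped_equals_uncapped_oracle(self):
        for ta, tb in [
            ("a b |", "b a |"),
            ("a b c |", "-b a -c |"),
            ("a )", "a |"),
            ("a a b |", "a b )"),
        ]:
            a, b = pair(ta, tb)
            assert (
                edit_distance(a, b, method="exact").distance
                == uncapped_oracle_distance(a, b)
            )
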