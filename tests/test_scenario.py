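"""Operation schemas, per-component costs, and scenario replay."""

import pytest

from dcjdup.genome_model import (
    GHOST,
    AdjacencySet,
    Extremity,
    adjacency,
    genome_to_adjacency_set,
    parse_genomes,
    telomere,
)
from dcjdup.adjacency_graph import LEFT, RIGHT
from dcjdup.solver import CompSeq, edit_distance
from dcjdup.scenario import (
    EditOperation,
    Scenario,
    apply_operation,
    build_scenario,
    component_operations,
    matches_schema,
    verify_scenario,
)
from dcjdup.simulator import SimulationConfig, apply_random_operations, random_genome

at, ah = Extremity("a", "t"), Extremity("a", "h")
bt, bh = Extremity("b", "t"), Extremity("b", "h")


def pair(ta, tb):
    a, b = parse_genomes(f">A\n{ta}\n>B\n{tb}")
    return a, b


class TestSchemas:
    def test_dcj_two_adjacencies(self):
        op = EditOperation(
            "DCJ",
            (adjacency(ah, bt), adjacency(bh, at)),
            (adjacency(ah, bh), adjacency(bt, at)),
        )
        assert matches_schema(op)

    def test_dcj_join_and_split(self):
        assert matches_schema(
            EditOperation("DCJ", (telomere(at), telomere(ah)), (adjacency(at, ah),))
        )
        assert matches_schema(
            EditOperation("DCJ", (adjacency(at, ah),), (telomere(at), telomere(ah)))
        )

    def test_dcj_must_preserve_extremities(self):
        assert not matches_schema(
            EditOperation("DCJ", (adjacency(ah, bt),), (adjacency(ah, bh),))
        )

    def test_single_element_identity_is_not_an_operation(self):
        assert not matches_schema(
            EditOperation("DCJ", (adjacency(ah, bt),), (adjacency(bt, ah),))
        )

    def test_insertion_schemas(self):
        assert matches_schema(
            EditOperation(
                "INS",
                (adjacency(bh, bt),),
                (adjacency(bh, at), adjacency(ah, bt)),
                "a",
            )
        )
        assert matches_schema(
            EditOperation("INS", (), (adjacency(at, ah),), "a")
        )
        assert matches_schema(
            EditOperation("INS", (), (telomere(at), telomere(ah)), "a")
        )
        assert not matches_schema(
            EditOperation("INS", (), (adjacency(at, bh),), "a")
        )

    def test_deletion_schemas(self):
        assert matches_schema(EditOperation("DEL", (adjacency(at, ah),), (), "a"))
        assert matches_schema(
            EditOperation(
                "DEL",
                (adjacency(bh, at), adjacency(ah, bt)),
                (adjacency(bh, bt),),
                "a",
            )
        )


def cycle_seq(*nodes_labels):
    nodes, labels = zip(*nodes_labels)
    return CompSeq("cycle", tuple(nodes), tuple(labels))


class TestComponentCosts:
    def test_ghost_free_2cycle_costs_nothing(self):
        comp = cycle_seq(
            ((LEFT, adjacency(ah, bt)), ah),
            ((RIGHT, adjacency(ah, bt)), bt),
        )
        assert component_operations(comp) == []

    def test_unhelpful_t1_2cycle_costs_one_deletion(self):
        comp = cycle_seq(
            ((LEFT, adjacency(at, ah)), at),
            ((RIGHT, adjacency(at, ah, origin=GHOST)), ah),
        )
        ops = component_operations(comp)
        assert [op.kind for op in ops] == ["DEL"]

    def test_unhelpful_t2_2cycle_costs_one_insertion(self):
        comp = cycle_seq(
            ((LEFT, adjacency(at, ah, origin=GHOST)), at),
            ((RIGHT, adjacency(at, ah)), ah),
        )
        ops = component_operations(comp)
        assert [op.kind for op in ops] == ["INS"]

    def test_helpful_ghost_free_4cycle_costs_one_dcj(self):
        comp = cycle_seq(
            ((LEFT, adjacency(ah, bt)), ah),
            ((RIGHT, adjacency(ah, bh)), bh),
            ((LEFT, adjacency(bh, at)), at),
            ((RIGHT, adjacency(bt, at)), bt),
        )
        ops = component_operations(comp)
        assert [op.kind for op in ops] == ["DCJ"]

    @pytest.mark.parametrize("length", [2, 4, 6, 8])
    def test_lemma_costs_on_simulated_components(self, length):
        """Cost law d + i + DCJs per component, across simulated pairs."""
        # exercised thoroughly via the pipelines below; here check the
        # helpful-cycle formula l/2 - 1 on ghost-free cycles of given length
        genes = "abcd"[: length // 2]
        fwd = " ".join(genes)
        rev = " ".join(f"-{g}" for g in reversed(genes))
        a, b = pair(f"{fwd} )", f"{rev} )")
        rep = edit_distance(a, b, method="exact")
        for comp in rep.components:
            if comp.kind == "cycle" and comp.ghost_count == 0:
                assert (
                    len(component_operations(comp)) == comp.length // 2 - 1
                )


class TestApply:
    def test_dcj_rewrite(self):
        s = AdjacencySet([adjacency(ah, bt), adjacency(bh, at)])
        op = EditOperation(
            "DCJ",
            (adjacency(ah, bt), adjacency(bh, at)),
            (adjacency(ah, bh), adjacency(bt, at)),
        )
        assert apply_operation(s, op) == AdjacencySet(
            [adjacency(ah, bh), adjacency(bt, at)]
        )

    def test_insertion_into_telomere(self):
        s = AdjacencySet([telomere(ah)])
        op = EditOperation(
            "INS", (telomere(ah),), (adjacency(ah, at), telomere(ah)), "a"
        )
        assert apply_operation(s, op) == AdjacencySet(
            [adjacency(ah, at), telomere(ah)]
        )

    def test_deletion_to_empty(self):
        s = AdjacencySet([adjacency(at, ah)])
        op = EditOperation("DEL", (adjacency(at, ah),), (), "a")
        assert apply_operation(s, op) == AdjacencySet([])

    def test_missing_consumed_rejected(self):
        from dcjdup.scenario import ScenarioReplayError

        with pytest.raises(ScenarioReplayError):
            apply_operation(
                AdjacencySet([]), EditOperation("DEL", (adjacency(at, ah),), (), "a")
            )


class TestBuildAndVerify:
    def test_identical_genomes_empty_scenario(self):
        a, b = pair("a b | c )", "a b | c )")
        rep = edit_distance(a, b)
        sc = build_scenario(rep)
        assert len(sc) == 0
        assert verify_scenario(rep.s1, sc, rep.s2, 0).ok

    def test_single_insertion_scenario(self):
        a, b = pair("a |", "a a |")
        rep = edit_distance(a, b, method="exact")
        sc = build_scenario(rep)
        assert [op.kind for op in sc.ops] == ["INS"]
        assert verify_scenario(rep.s1, sc, rep.s2, rep.distance).ok

    def test_single_dcj_scenario(self):
        a, b = pair("a b )", "a -b )")
        rep = edit_distance(a, b, method="exact")
        sc = build_scenario(rep)
        assert [op.kind for op in sc.ops] == ["DCJ"]
        assert verify_scenario(rep.s1, sc, rep.s2, rep.distance).ok

    def test_spurious_extra_operation_fails_count_law(self):
        a, b = pair("a b )", "a -b )")
        rep = edit_distance(a, b, method="exact")
        sc = build_scenario(rep)
        padded = Scenario(
            sc.ops
            + (
                EditOperation(
                    "DCJ",
                    (adjacency(ah, bh),),
                    (telomere(ah), telomere(bh)),
                ),
                EditOperation(
                    "DCJ",
                    (telomere(ah), telomere(bh)),
                    (adjacency(ah, bh),),
                ),
            )
        )
        res = verify_scenario(rep.s1, padded, rep.s2, rep.distance)
        assert not res.ok and "operations" in res.message

    def test_wrong_target_detected(self):
        a, b = pair("a b )", "a -b )")
        c = parse_genomes(">C\na b )")[0]
        rep = edit_distance(a, b, method="exact")
        sc = build_scenario(rep)
        res = verify_scenario(rep.s1, sc, genome_to_adjacency_set(c), rep.distance)
        assert not res.ok

    @pytest.mark.parametrize("seed", range(25))
    def test_replay_and_count_law_on_simulated_pairs(self, seed):
        """DEL = |T1|, INS = |T2|, total = distance, final set = S2."""
        cfg = SimulationConfig(
            families=2 + seed % 5,
            copy_rate=0.5,
            chromosomes=1 + seed % 2,
            circular_fraction=0.5,
            ops=1 + seed % 5,
            seed=seed,
        )
        anc = random_genome(cfg)
        der, _ = apply_random_operations(anc, cfg)
        for method in ("approx", "exact"):
            rep = edit_distance(anc, der, method=method)
            sc = build_scenario(rep)
            res = verify_scenario(rep.s1, sc, rep.s2, rep.distance)
            assert res.ok, res.message
            counts = sc.counts
            assert counts.get("DEL", 0) == rep.t1_size
            assert counts.get("INS", 0) == rep.t2_size
            assert all(matches_schema(op) for op in sc.ops)
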