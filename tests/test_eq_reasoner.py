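"""Structural EQ subsumption, classification, and class-expression queries."""

import random

import pytest

from phenoforge import (
    EQDefinition,
    PhenotypeClass,
    Relation,
    SupportOntology,
    SupportSet,
    TermId,
    build_unified,
    classify,
    query,
    subsumes,
)
from phenoforge import fixtures as fx
from phenoforge.fixtures import (
    gen_random_eq_classes,
    gen_random_supports,
    mini_cl,
    mini_go,
    mini_pato,
    mini_uberon,
)

from oracles import naive_ancestors, naive_subsumes, naive_transitive_reduction

COPO = Relation.characteristic_of_part_of
CO = Relation.characteristic_of


def supports_without_edge(drop):
    """Rebuild the fixture supports with one edge removed."""
    def filtered(ont, role):
        return SupportOntology(
            ont.classes.values(),
            [e for e in ont.edges if e != drop],
            role=role,
        )

    return SupportSet(
        filtered(mini_pato(), "quality"),
        [filtered(mini_uberon(), "entity"), mini_go(), mini_cl()],
    )


class TestSubsumes:
    def test_valve_thickness_under_heart_morphology(self, supports):
        general = EQDefinition(fx.MORPHOLOGY, fx.HEART, COPO)
        specific = EQDefinition(fx.INCREASED_THICKNESS, fx.AORTIC_VALVE_LEAFLET, COPO)
        assert subsumes(general, specific, supports)
        assert not subsumes(specific, general, supports)

    def test_removing_quality_edge_breaks_inference(self, supports):
        general = EQDefinition(fx.MORPHOLOGY, fx.HEART, COPO)
        specific = EQDefinition(fx.THICKNESS, fx.AORTIC_VALVE_LEAFLET, COPO)
        assert subsumes(general, specific, supports)
        broken = supports_without_edge((fx.THICKNESS, Relation.is_a, fx.MORPHOLOGY))
        assert not subsumes(general, specific, broken)

    def test_removing_parthood_edge_breaks_inference(self, supports):
        general = EQDefinition(fx.MORPHOLOGY, fx.HEART, COPO)
        specific = EQDefinition(fx.THICKNESS, fx.AORTIC_VALVE, COPO)
        broken = supports_without_edge((fx.AORTIC_VALVE, Relation.part_of, fx.HEART))
        assert not subsumes(general, specific, broken)

    def test_strict_bearer_mode_ignores_parthood(self, supports):
        general = EQDefinition(fx.MORPHOLOGY, fx.HEART, CO)
        specific = EQDefinition(fx.THICKNESS, fx.AORTIC_VALVE, CO)
        assert not subsumes(general, specific, supports)

    def test_reflexive(self, supports):
        eq = EQDefinition(fx.INCREASED_SIZE, fx.HEART, COPO, towards=fx.EYE)
        assert subsumes(eq, eq, supports)

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_ancestor_set_oracle(self, seed):
        sup = gen_random_supports(seed)
        classes = gen_random_eq_classes(sup, 8, seed=seed + 1000)
        edges = [e for ont in (sup.quality, *sup.entities) for e in ont.edges]
        for ca in classes:
            for cb in classes:
                assert subsumes(ca.eq, cb.eq, sup) == naive_subsumes(ca.eq, cb.eq, edges)

    @pytest.mark.parametrize("seed", range(0, 100, 1))
    def test_preorder(self, seed):
        sup = gen_random_supports(seed)
        classes = gen_random_eq_classes(sup, 6, seed=seed + 2000)
        eqs = [c.eq for c in classes]
        for a in eqs:
            assert subsumes(a, a, sup)
        for a in eqs:
            for b in eqs:
                for c in eqs:
                    if subsumes(a, b, sup) and subsumes(b, c, sup):
                        assert subsumes(a, c, sup)

    def test_quality_coarsening_is_monotone(self, supports):
        general = EQDefinition(fx.SIZE, fx.HEART, COPO)
        specific = EQDefinition(fx.INCREASED_SIZE, fx.HEART, COPO)
        assert subsumes(general, specific, supports)
        for coarser_quality in (fx.MORPHOLOGY, fx.QUALITY):
            coarser = EQDefinition(coarser_quality, fx.HEART, COPO)
            assert subsumes(coarser, specific, supports)


class TestClassify:
    def test_species_heart_classes_group_under_generated(self, unified):
        generated_inc_size = next(
            t for t, c in unified.classes.items()
            if c.label == "increased size of the heart"
        )
        size_grouping = next(
            t for t, c in unified.classes.items()
            if c.label == "size of heart phenotype"
        )
        for curie in ("HP:0001640", "MP:0000274", "ZP:0000532"):
            anc = unified.ancestors(TermId.parse(curie))
            assert generated_inc_size in anc
            assert size_grouping in anc

    def test_single_class_no_edges(self, supports):
        cls = PhenotypeClass(
            TermId.parse("HP:0001640"),
            "Cardiomegaly",
            EQDefinition(fx.INCREASED_SIZE, fx.HEART, COPO),
        )
        ont = classify([cls], supports)
        assert ont.direct_edges == []

    def test_order_invariance(self, templates, filler_tables, species, supports):
        base = build_unified(templates, filler_tables, list(species.values()), supports)
        shuffled_species = [list(v) for v in species.values()]
        rng = random.Random(5)
        for lst in shuffled_species:
            rng.shuffle(lst)
        shuffled_species.reverse()
        other = build_unified(
            list(reversed(templates)), list(reversed(filler_tables)),
            shuffled_species, supports,
        )
        assert base.direct_edges == other.direct_edges
        assert base.canonical == other.canonical

    @pytest.mark.parametrize("seed", range(20))
    def test_direct_edges_are_oracle_transitive_reduction(self, seed):
        sup = gen_random_supports(seed)
        classes = gen_random_eq_classes(sup, 10, seed=seed + 3000)
        edges = [e for ont in (sup.quality, *sup.entities) for e in ont.edges]
        ont = classify(classes, sup)
        # oracle: full subsumption matrix between representatives
        reps = sorted(set(ont.canonical.values()))
        eq_of = {c.id: c.eq for c in classes}
        reach = {
            r: {
                p for p in reps
                if p != r and naive_subsumes(eq_of[p], eq_of[r], edges)
            }
            for r in reps
        }
        expected = naive_transitive_reduction(reps, reach)
        assert set(ont.direct_edges) == expected

    def test_equivalents_merge_to_smallest_rep(self, unified):
        group = unified.equivalents(TermId.parse("HP:0001640"))
        assert {t.curie for t in group} >= {"HP:0001640", "MP:0000274", "ZP:0000532"}
        assert unified.canonical[TermId.parse("MP:0000274")] == min(group)


class TestQuery:
    def test_heart_morphology_query_equals_grouping_descendants(self, unified, supports):
        expr = EQDefinition(fx.MORPHOLOGY, fx.HEART, COPO)
        got = {c.id for c in query(expr, unified, supports)}
        grouping = next(
            t for t, c in unified.classes.items()
            if c.label == "heart morphology phenotype"
        )
        assert got == unified.descendants(grouping)

    def test_top_query_returns_all(self, unified, supports):
        expr = EQDefinition(fx.QUALITY, fx.ANATOMICAL_ENTITY, COPO)
        got = {c.id for c in query(expr, unified, supports)}
        anatomical = {
            t for t, c in unified.classes.items()
            if c.eq is not None
            and fx.ANATOMICAL_ENTITY in supports.ancestors(
                c.eq.bearer, (Relation.is_a, Relation.part_of)
            )
        }
        assert got == anatomical

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_linear_scan(self, seed):
        sup = gen_random_supports(seed)
        classes = gen_random_eq_classes(sup, 12, seed=seed + 4000)
        ont = classify(classes, sup)
        probes = [c.eq for c in classes[:4]]
        for expr in probes:
            got = {c.id for c in query(expr, ont, sup)}
            expected = {c.id for c in classes if subsumes(expr, c.eq, sup)}
            assert got == expected


class TestBuildUnified:
    def test_every_species_heart_class_has_neutral_ancestor(self, unified):
        for curie in ("HP:0001640", "MP:0000274", "ZP:0000532", "ZP:0100001"):
            anc = unified.ancestors(TermId.parse(curie), include_self=False)
            assert any(t.prefix == "PHF" for t in anc), curie

    def test_without_species_only_groupings(self, templates, filler_tables, supports):
        ont = build_unified(templates, filler_tables, [], supports)
        assert all(t.prefix == "PHF" for t in ont.classes)
        assert len(ont) > 0
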