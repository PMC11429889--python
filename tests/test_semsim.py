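"""Jaccard, information content and PhenoDigm-style similarity."""

import math
import random

import pytest

from phenoforge import (
    ClassifiedOntology,
    ICStrategy,
    PhenotypeClass,
    Profile,
    TermId,
    UsageError,
    information_content,
    jaccard,
    phenodigm,
    profile_similarity,
    write_similarity_table,
)
from phenoforge import fixtures as fx
from phenoforge.fixtures import (
    RandomOntologySpec,
    gen_random_ontology,
    gen_random_profiles,
    toy_chain,
)
from phenoforge.model import Relation

from oracles import naive_ic_corpus, naive_jaccard, naive_mica


def random_hierarchy(seed, n=15):
    """A random classified hierarchy built from a random DAG's is_a edges."""
    ont = gen_random_ontology(RandomOntologySpec(n, 0.25, 0.0, seed=seed), prefix="H")
    classes = [PhenotypeClass(t, c.label) for t, c in ont.classes.items()]
    edges = [(s, o) for s, rel, o in ont.edges if rel is Relation.is_a]
    return ClassifiedOntology.from_edges(classes, edges)


class TestJaccard:
    def test_self_similarity_is_one(self, unified):
        for t in unified.classes:
            assert jaccard(unified, t, t) == 1.0

    def test_toy_chain_half(self):
        ont, _ = toy_chain()
        a, b = TermId.parse("TOY:0000003"), TermId.parse("TOY:0000004")
        assert jaccard(ont, a, b) == 0.5

    def test_symmetric(self, unified):
        ids = sorted(unified.classes)[:8]
        for a in ids:
            for b in ids:
                assert jaccard(unified, a, b) == jaccard(unified, b, a)

    def test_siblings_outrank_root_only_pairs(self, unified):
        roots = set(unified.roots())
        sibling_scores, distant_scores = [], []
        reps = sorted(unified.groups)
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                common = unified.ancestors(a) & unified.ancestors(b)
                common_reps = {unified.canonical[t] for t in common}
                share_parent = bool(
                    set(unified._parents.get(a, ())) & set(unified._parents.get(b, ()))
                )
                related = a in unified.ancestors(b) or b in unified.ancestors(a)
                score = jaccard(unified, a, b)
                if share_parent:
                    sibling_scores.append(score)
                elif not related and common_reps <= roots:
                    distant_scores.append(score)
        assert sibling_scores and distant_scores
        assert min(sibling_scores) > max(distant_scores)


class TestInformationContent:
    def test_root_annotating_everything_has_zero_ic(self):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        assert ic[TermId.parse("TOY:0000001")] == 0.0

    def test_one_of_four_profiles_is_two_bits(self):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        assert ic[TermId.parse("TOY:0000002")] == 2.0

    def test_unseen_term_gets_add_one_value(self):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        assert ic[TermId.parse("TOY:0000004")] == pytest.approx(math.log2(5))

    def test_empty_corpus_rejected(self):
        ont, _ = toy_chain()
        with pytest.raises(UsageError):
            information_content(ont, [], ICStrategy.corpus)

    def test_topology_strategy_root_zero_when_single_root(self):
        ont, _ = toy_chain()
        ic = information_content(ont, strategy=ICStrategy.topology)
        assert ic[TermId.parse("TOY:0000001")] == 0.0
        assert ic[TermId.parse("TOY:0000003")] == math.log2(4)

    @pytest.mark.parametrize("seed", range(50))
    def test_monotone_along_is_a_random_corpora(self, seed):
        ont = random_hierarchy(seed)
        terms = sorted(ont.classes)
        profiles = gen_random_profiles(terms, n_profiles=5, seed=seed + 77)
        ic = information_content(ont, profiles)
        for child, parent in ont.direct_edges:
            assert ic[child] >= ic[parent] - 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        ont = random_hierarchy(seed)
        terms = sorted(ont.classes)
        profiles = gen_random_profiles(terms, n_profiles=6, seed=seed + 99)
        ic = information_content(ont, profiles)
        anc = {t: ont.ancestors(t) for t in terms}
        expected = naive_ic_corpus(profiles, anc, terms)
        for t in terms:
            assert ic[t] == pytest.approx(expected[t])


class TestPhenoDigm:
    def test_root_only_common_ancestor_scores_zero(self):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        root, x = TermId.parse("TOY:0000001"), TermId.parse("TOY:0000002")
        # pair whose only common ancestor is the IC-0 root
        extra = PhenotypeClass(TermId.parse("TOY:0000005"), "toy leaf c")
        ont2 = ClassifiedOntology.from_edges(
            list(ont.classes.values()) + [extra],
            ont.direct_edges + [(extra.id, root)],
        )
        ic2 = information_content(ont2, profiles)
        r = phenodigm(ont2, ic2, TermId.parse("TOY:0000003"), extra.id)
        assert r.phenodigm == 0.0 and r.mica == root

    def test_toy_chain_value_one(self):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        r = phenodigm(ont, ic, TermId.parse("TOY:0000003"), TermId.parse("TOY:0000004"))
        assert r.mica == TermId.parse("TOY:0000002")
        assert r.ic_mica == 2.0
        assert r.phenodigm == pytest.approx(1.0)

    def test_self_score_is_sqrt_ic(self):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        a = TermId.parse("TOY:0000003")
        assert phenodigm(ont, ic, a, a).phenodigm == pytest.approx(math.sqrt(ic[a]))

    @pytest.mark.parametrize("seed", range(25))
    def test_mica_matches_exhaustive_oracle(self, seed):
        ont = random_hierarchy(seed)
        terms = sorted(ont.classes)
        profiles = gen_random_profiles(terms, n_profiles=5, seed=seed + 55)
        ic = information_content(ont, profiles)
        for a in terms[:8]:
            for b in terms[:8]:
                r = phenodigm(ont, ic, a, b)
                exp_mica, exp_ic = naive_mica(ont.ancestors(a), ont.ancestors(b), ic.ic)
                exp_jac = naive_jaccard(ont.ancestors(a), ont.ancestors(b))
                assert r.mica == exp_mica
                assert r.ic_mica == pytest.approx(exp_ic)
                assert r.jaccard == pytest.approx(exp_jac)
                assert r.phenodigm == pytest.approx(math.sqrt(exp_jac * exp_ic))


class TestProfileSimilarity:
    def test_self_combined_is_hundred(self):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        p = profiles[0]
        assert profile_similarity(ont, ic, p, p, "combined") == pytest.approx(100.0)

    def test_disjoint_under_zero_ic_root_is_zero(self):
        ont, profiles = toy_chain()
        root = TermId.parse("TOY:0000001")
        extra = PhenotypeClass(TermId.parse("TOY:0000005"), "toy leaf c")
        ont2 = ClassifiedOntology.from_edges(
            list(ont.classes.values()) + [extra],
            ont.direct_edges + [(extra.id, root)],
        )
        ic = information_content(ont2, profiles)
        p1 = Profile("q", frozenset({TermId.parse("TOY:0000003")}))
        p2 = Profile("t", frozenset({extra.id}))
        for mode in ("max", "avg", "combined"):
            assert profile_similarity(ont2, ic, p1, p2, mode) == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_avg_equals_double_loop(self, seed):
        ont = random_hierarchy(seed, n=10)
        terms = sorted(ont.classes)
        profiles = gen_random_profiles(terms, n_profiles=4, seed=seed + 11)
        ic = information_content(ont, profiles)
        p1, p2 = profiles[0], profiles[1]
        scores = []
        for t1 in p1.terms:
            scores.append(max(phenodigm(ont, ic, t1, t2).phenodigm for t2 in p2.terms))
        for t2 in p2.terms:
            scores.append(max(phenodigm(ont, ic, t2, t1).phenodigm for t1 in p1.terms))
        expected = sum(scores) / len(scores)
        assert profile_similarity(ont, ic, p1, p2, "avg") == pytest.approx(expected)

    def test_symmetric_for_avg_and_max(self, unified):
        corpus = fx.fixture_corpus()
        ic = information_content(unified, corpus)
        p1, p2 = corpus[0], corpus[1]
        for mode in ("avg", "max"):
            assert profile_similarity(unified, ic, p1, p2, mode) == pytest.approx(
                profile_similarity(unified, ic, p2, p1, mode)
            )

    def test_empty_profile_rejected(self):
        with pytest.raises(UsageError):
            Profile("empty", frozenset())


class TestSimilarityTable:
    def test_single_result_single_row(self, tmp_path):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        r = phenodigm(ont, ic, TermId.parse("TOY:0000003"), TermId.parse("TOY:0000004"))
        path = tmp_path / "sim.tsv"
        write_similarity_table([r], path, ont=ont)
        lines = path.read_text().splitlines()
        assert len(lines) == 2

    def test_homologous_heart_pair_ranks_above_nonhomologous(self, unified, tmp_path):
        corpus = fx.fixture_corpus()
        ic = information_content(unified, corpus)
        hp_heart = TermId.parse("HP:0001640")
        zp_heart = TermId.parse("ZP:0000532")
        mp_tail = TermId.parse("MP:0011999")
        results = [
            phenodigm(unified, ic, hp_heart, zp_heart),
            phenodigm(unified, ic, hp_heart, mp_tail),
        ]
        path = tmp_path / "rank.tsv"
        write_similarity_table(results, path, ont=unified)
        rows = path.read_text().splitlines()[1:]
        assert rows[0].startswith("HP:0001640\tCardiomegaly\tZP:0000532")

    def test_sort_order_matches_comparator_oracle(self, tmp_path):
        ont, profiles = toy_chain()
        ic = information_content(ont, profiles)
        terms = sorted(ont.classes)
        results = [
            phenodigm(ont, ic, a, b) for i, a in enumerate(terms) for b in terms[i:]
        ]
        path = tmp_path / "sorted.tsv"
        write_similarity_table(results, path, ont=ont)
        rows = path.read_text().splitlines()[1:]
        scores = [float(r.split("\t")[7]) for r in rows]
        subjects = [r.split("\t")[0] for r in rows]
        expected = sorted(
            zip(scores, subjects), key=lambda t: (-t[0], t[1])
        )
        assert [s for s, _ in expected] == scores
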