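"""Deterministic fixture suite and random-input generators.

The fixture suite is a self-contained miniature of the cross-species
phenotype-integration setting: a small quality hierarchy (PATO-like), small
anatomy/process/component hierarchies (Uberon/GO/CL-like), seven pattern
templates with filler tables, three mini species phenotype ontologies
(HP/MP/ZP-style), post-composed annotation rows and a six-profile
annotation corpus.  Identifiers and labels reuse the real ontologies'
published CURIEs wherever those exist (HP:0001640 "Cardiomegaly",
UBERON:0002386 "forelimb zeugopod", ...); the handful of extra terms that
have no published counterpart use clearly local ids (``PHF``-minted ids,
``ZP:0100001``, ``TOY:*``) and are synthetic.

Everything here is pure-function deterministic: regenerating the suite
with the same seed is byte-identical (the seed only feeds the random
generators used by property tests; the worked-example content is fixed).
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import random
from dataclasses import dataclass
from typing import Optional, Union

import yaml

from .model import (
    OntologyClass,
    Relation,
    SupportOntology,
    SupportSet,
    TermId,
)
from .obo import write_obo, write_phenotype_obo
from .patterns import FillerTable, PatternTemplate, parse_pattern, serialize_pattern
from .reasoner import EQDefinition, ClassifiedOntology, PhenotypeClass
from .semsim import Profile

__all__ = [
    "FixtureSuite",
    "RandomOntologySpec",
    "mini_pato",
    "mini_uberon",
    "mini_go",
    "mini_cl",
    "fixture_supports",
    "fixture_templates",
    "fixture_filler_tables",
    "fixture_species",
    "fixture_postcomposed_rows",
    "fixture_corpus",
    "toy_chain",
    "make_fixture_suite",
    "gen_random_ontology",
    "gen_random_supports",
    "gen_random_eq_classes",
    "gen_random_profiles",
]

T = TermId.parse

# quality hierarchy ids (PATO)
QUALITY = T("PATO:0000001")
MORPHOLOGY = T("PATO:0000051")
SIZE = T("PATO:0000117")
INCREASED_SIZE = T("PATO:0000586")
THICKNESS = T("PATO:0000915")
INCREASED_THICKNESS = T("PATO:0000600")
LENGTH = T("PATO:0000122")
CURVATURE = T("PATO:0001591")
PROCESS_QUALITY = T("PATO:0001236")
DECREASED_PROCESS_QUALITY = T("PATO:0002302")
DECREASED_RATE = T("PATO:0000911")
RATE = T("PATO:0000161")
AMOUNT = T("PATO:0000070")
DECREASED_AMOUNT = T("PATO:0001997")
ABNORMAL = T("PATO:0000460")

# entity hierarchy ids (Uberon / GO / CL)
ANATOMICAL_ENTITY = T("UBERON:0001062")
HEART = T("UBERON:0000948")
AORTIC_VALVE = T("UBERON:0002137")
AORTIC_VALVE_LEAFLET = T("UBERON:0011742")
FORELIMB_ZEUGOPOD = T("UBERON:0002386")
TAIL = T("UBERON:0002415")
CORPUS_CALLOSUM = T("UBERON:0002336")
EYE = T("UBERON:0000970")
MANUAL_DIGIT = T("UBERON:0002389")
BIOLOGICAL_PROCESS = T("GO:0008150")
RETINAL_BV_MORPHOGENESIS = T("GO:0061304")
CELLULAR_COMPONENT = T("GO:0005575")
MITOCHONDRION = T("GO:0005739")
CELL = T("CL:0000000")
NEURON = T("CL:0000540")


def _ont(role, terms, edges):
    classes = [OntologyClass(tid, label) for tid, label in terms]
    return SupportOntology(classes, edges, role=role)


def mini_pato() -> SupportOntology:
    """Miniature quality hierarchy."""
    isa = Relation.is_a
    terms = [
        (QUALITY, "quality"),
        (MORPHOLOGY, "morphology"),
        (SIZE, "size"),
        (INCREASED_SIZE, "increased size"),
        (THICKNESS, "thickness"),
        (INCREASED_THICKNESS, "increased thickness"),
        (LENGTH, "length"),
        (CURVATURE, "curvature"),
        (PROCESS_QUALITY, "process quality"),
        (DECREASED_PROCESS_QUALITY, "decreased process quality"),
        (DECREASED_RATE, "decreased rate"),
        (RATE, "rate"),
        (AMOUNT, "amount"),
        (DECREASED_AMOUNT, "decreased amount"),
        (ABNORMAL, "abnormal"),
    ]
    edges = [
        (MORPHOLOGY, isa, QUALITY),
        (SIZE, isa, MORPHOLOGY),
        (INCREASED_SIZE, isa, SIZE),
        (THICKNESS, isa, MORPHOLOGY),
        (INCREASED_THICKNESS, isa, THICKNESS),
        (LENGTH, isa, MORPHOLOGY),
        (CURVATURE, isa, MORPHOLOGY),
        (PROCESS_QUALITY, isa, QUALITY),
        (DECREASED_PROCESS_QUALITY, isa, PROCESS_QUALITY),
        (RATE, isa, PROCESS_QUALITY),
        (DECREASED_RATE, isa, DECREASED_PROCESS_QUALITY),
        (DECREASED_RATE, isa, RATE),
        (AMOUNT, isa, QUALITY),
        (DECREASED_AMOUNT, isa, AMOUNT),
        (ABNORMAL, isa, QUALITY),
    ]
    return _ont("quality", terms, edges)


def mini_uberon() -> SupportOntology:
    """Miniature anatomy hierarchy; the aortic valve sits inside the heart."""
    isa, part = Relation.is_a, Relation.part_of
    terms = [
        (ANATOMICAL_ENTITY, "anatomical entity"),
        (HEART, "heart"),
        (AORTIC_VALVE, "aortic valve"),
        (AORTIC_VALVE_LEAFLET, "aortic valve leaflet"),
        (FORELIMB_ZEUGOPOD, "forelimb zeugopod"),
        (TAIL, "tail"),
        (CORPUS_CALLOSUM, "corpus callosum"),
        (EYE, "eye"),
        (MANUAL_DIGIT, "manual digit"),
    ]
    edges = [
        (HEART, isa, ANATOMICAL_ENTITY),
        (AORTIC_VALVE, isa, ANATOMICAL_ENTITY),
        (AORTIC_VALVE, part, HEART),
        (AORTIC_VALVE_LEAFLET, isa, ANATOMICAL_ENTITY),
        (AORTIC_VALVE_LEAFLET, part, AORTIC_VALVE),
        (FORELIMB_ZEUGOPOD, isa, ANATOMICAL_ENTITY),
        (TAIL, isa, ANATOMICAL_ENTITY),
        (CORPUS_CALLOSUM, isa, ANATOMICAL_ENTITY),
        (EYE, isa, ANATOMICAL_ENTITY),
        (MANUAL_DIGIT, isa, ANATOMICAL_ENTITY),
    ]
    return _ont("entity", terms, edges)


def mini_go() -> SupportOntology:
    isa = Relation.is_a
    terms = [
        (BIOLOGICAL_PROCESS, "biological process"),
        (RETINAL_BV_MORPHOGENESIS, "retinal blood vessel morphogenesis"),
        (CELLULAR_COMPONENT, "cellular component"),
        (MITOCHONDRION, "mitochondrion"),
    ]
    edges = [
        (RETINAL_BV_MORPHOGENESIS, isa, BIOLOGICAL_PROCESS),
        (MITOCHONDRION, isa, CELLULAR_COMPONENT),
    ]
    return _ont("entity", terms, edges)


def mini_cl() -> SupportOntology:
    return _ont(
        "entity",
        [(CELL, "cell"), (NEURON, "neuron")],
        [(NEURON, Relation.is_a, CELL)],
    )


def fixture_supports() -> SupportSet:
    return SupportSet(mini_pato(), [mini_uberon(), mini_go(), mini_cl()])


# ---------------------------------------------------------------------------
# Pattern templates

_PATTERN_IRI_BASE = "https://example.org/phenoforge/patterns/"
_ORCID = "https://orcid.org/0000-0002-0000-0000"  # synthetic contributor

_ANAT_RELATIONS = {
    "has part": "BFO:0000051",
    "characteristic of part of": "RO:0002314",
    "has modifier": "RO:0002573",
}
_PROC_RELATIONS = {
    "has part": "BFO:0000051",
    "characteristic of": "RO:0000052",
    "has modifier": "RO:0002573",
}


def _template_doc(
    pattern_name: str,
    quality_name: str,
    quality: TermId,
    name_text: str,
    def_text: str,
    *,
    mode: str = "characteristic of part of",
    range_name: str = "anatomical entity",
    range_id: TermId = ANATOMICAL_ENTITY,
    var: str = "anatomical_entity",
) -> dict:
    relations = _ANAT_RELATIONS if mode == "characteristic of part of" else _PROC_RELATIONS
    return {
        "pattern_name": pattern_name,
        "pattern_iri": f"{_PATTERN_IRI_BASE}{pattern_name}.yaml",
        "description": def_text.replace("%s", "an entity"),
        "contributors": [_ORCID],
        "classes": {
            quality_name: quality.curie,
            "abnormal": ABNORMAL.curie,
            range_name: range_id.curie,
        },
        "relations": dict(relations),
        "vars": {var: f"'{range_name}'"},
        "name": {"text": name_text, "vars": [var]},
        "def": {"text": def_text, "vars": [var]},
        "equivalentTo": {
            "text": (
                f"'has part' some ('{quality_name}'"
                f" and ('{mode}' some %s)"
                f" and ('has modifier' some 'abnormal'))"
            ),
            "vars": [var],
        },
    }


def fixture_template_docs() -> list[dict]:
    return [
        _template_doc(
            "abnormalAnatomicalEntity", "quality", QUALITY,
            "abnormal %s", "Any abnormality of the %s.",
        ),
        _template_doc(
            "increasedSizeOfAnatomicalEntity", "increased size", INCREASED_SIZE,
            "increased size of the %s", "Increased size of the %s.",
        ),
        _template_doc(
            "abnormalSizeOfAnatomicalEntity", "size", SIZE,
            "size of %s phenotype", "Abnormal size of the %s.",
        ),
        _template_doc(
            "abnormalAnatomicalEntityMorphology", "morphology", MORPHOLOGY,
            "%s morphology phenotype", "Abnormal morphology of the %s.",
        ),
        _template_doc(
            "abnormalLengthOfAnatomicalEntity", "length", LENGTH,
            "abnormal %s length", "Abnormal length of the %s.",
        ),
        _template_doc(
            "abnormallyDecreasedRateOfContinuousBiologicalProcess",
            "decreased process quality", DECREASED_PROCESS_QUALITY,
            "abnormally decreased rate of %s", "Decreased rate of %s.",
            mode="characteristic of",
            range_name="biological process", range_id=BIOLOGICAL_PROCESS,
            var="biological_process",
        ),
        _template_doc(
            "abnormallyDecreasedNumberOfCellularComponent",
            "decreased amount", DECREASED_AMOUNT,
            "abnormally decreased number of %s", "Decreased number of %s.",
            mode="characteristic of",
            range_name="cellular component", range_id=CELLULAR_COMPONENT,
            var="cellular_component",
        ),
    ]


def fixture_templates(supports: Optional[SupportSet] = None) -> list[PatternTemplate]:
    supports = supports or fixture_supports()
    return [
        parse_pattern(yaml.safe_dump(doc, sort_keys=False), supports)
        for doc in fixture_template_docs()
    ]


def fixture_filler_tables() -> list[FillerTable]:
    def tbl(name, var, terms):
        return FillerTable.from_rows(name, [{var: t} for t in terms])

    return [
        tbl("abnormalAnatomicalEntity", "anatomical_entity", [HEART, EYE, TAIL]),
        tbl("increasedSizeOfAnatomicalEntity", "anatomical_entity", [HEART, EYE]),
        tbl("abnormalSizeOfAnatomicalEntity", "anatomical_entity", [HEART, EYE]),
        tbl(
            "abnormalAnatomicalEntityMorphology",
            "anatomical_entity",
            [HEART, AORTIC_VALVE, FORELIMB_ZEUGOPOD, EYE, MANUAL_DIGIT],
        ),
        tbl("abnormalLengthOfAnatomicalEntity", "anatomical_entity", [TAIL, CORPUS_CALLOSUM]),
        tbl(
            "abnormallyDecreasedRateOfContinuousBiologicalProcess",
            "biological_process",
            [RETINAL_BV_MORPHOGENESIS],
        ),
        tbl(
            "abnormallyDecreasedNumberOfCellularComponent",
            "cellular_component",
            [MITOCHONDRION],
        ),
    ]


# ---------------------------------------------------------------------------
# Mini species phenotype ontologies

COPO = Relation.characteristic_of_part_of


def fixture_species() -> dict[str, list[PhenotypeClass]]:
    """HP/MP/ZP-style mini ontologies with EQ logical definitions.

    All ids and labels are the published ones except ZP:0100001, which is a
    synthetic stand-in for a zebrafish valve-thickness term.
    """
    hp = [
        PhenotypeClass(T("HP:0001640"), "Cardiomegaly", EQDefinition(INCREASED_SIZE, HEART, COPO)),
        PhenotypeClass(
            T("HP:0002973"), "Abnormal forearm morphology",
            EQDefinition(MORPHOLOGY, FORELIMB_ZEUGOPOD, COPO),
        ),
        PhenotypeClass(T("HP:0100490"), "Camptodactyly", EQDefinition(CURVATURE, MANUAL_DIGIT, COPO)),
        PhenotypeClass(
            T("HP:0200011"), "Abnormal length of corpus callosum",
            EQDefinition(LENGTH, CORPUS_CALLOSUM, COPO),
        ),
    ]
    mp = [
        PhenotypeClass(T("MP:0000274"), "enlarged heart", EQDefinition(INCREASED_SIZE, HEART, COPO)),
        PhenotypeClass(
            T("MP:0003855"), "abnormal forelimb zeugopod morphology",
            EQDefinition(MORPHOLOGY, FORELIMB_ZEUGOPOD, COPO),
        ),
        PhenotypeClass(T("MP:0011999"), "abnormal tail length", EQDefinition(LENGTH, TAIL, COPO)),
        PhenotypeClass(T("MP:0003807"), "camptodactyly", EQDefinition(CURVATURE, MANUAL_DIGIT, COPO)),
    ]
    zp = [
        PhenotypeClass(
            T("ZP:0000532"), "heart increased size, abnormal",
            EQDefinition(INCREASED_SIZE, HEART, COPO),
        ),
        PhenotypeClass(  # synthetic id
            T("ZP:0100001"), "aortic valve leaflet increased thickness, abnormal",
            EQDefinition(INCREASED_THICKNESS, AORTIC_VALVE_LEAFLET, COPO),
        ),
    ]
    return {"hp": hp, "mp": mp, "zp": zp}


def fixture_postcomposed_rows() -> list[tuple[TermId, TermId]]:
    """Post-composed (entity, quality) annotation rows, ZFIN/SGD style.

    The neuron/morphology row has no admitting template (cells are outside
    every fixture range) and exercises the rejection path.
    """
    return [
        (RETINAL_BV_MORPHOGENESIS, DECREASED_PROCESS_QUALITY),
        (TAIL, LENGTH),
        (NEURON, MORPHOLOGY),
    ]


def fixture_corpus() -> list[Profile]:
    """Six gene profiles annotated with species phenotype terms."""
    pairs = [
        ("gene:G1", T("HP:0001640")),
        ("gene:G1", T("HP:0002973")),
        ("gene:G2", T("MP:0000274")),
        ("gene:G2", T("MP:0011999")),
        ("gene:G3", T("ZP:0000532")),
        ("gene:G4", T("HP:0100490")),
        ("gene:G5", T("MP:0003807")),
        ("gene:G5", T("MP:0003855")),
        ("gene:G6", T("HP:0200011")),
    ]
    return Profile.from_pairs(pairs)


def toy_chain() -> tuple[ClassifiedOntology, list[Profile]]:
    """The hand-checkable chain root -> x -> {a, b} with a 4-profile corpus.

    One profile is annotated to ``a`` and the other three to the root, so
    ``x`` covers exactly 1 of 4 profiles: IC(x) = 2 bits.
    """
    root, x, a, b = (T(f"TOY:000000{i}") for i in range(1, 5))
    classes = [
        PhenotypeClass(root, "toy root"),
        PhenotypeClass(x, "toy intermediate"),
        PhenotypeClass(a, "toy leaf a"),
        PhenotypeClass(b, "toy leaf b"),
    ]
    ont = ClassifiedOntology.from_edges(classes, [(x, root), (a, x), (b, x)])
    profiles = [
        Profile("p1", frozenset({a})),
        Profile("p2", frozenset({root})),
        Profile("p3", frozenset({root})),
        Profile("p4", frozenset({root})),
    ]
    return ont, profiles


# ---------------------------------------------------------------------------
# Suite on disk

@dataclass(frozen=True)
class FixtureSuite:
    root_dir: pathlib.Path
    manifest: dict[str, str]
    seed: int


def make_fixture_suite(out_dir: Union[str, pathlib.Path], seed: int = 42) -> FixtureSuite:
    """Write the whole fixture suite under ``out_dir`` and hash every file."""
    root = pathlib.Path(out_dir)
    supports = fixture_supports()
    labels = {}
    for ont in (mini_pato(), mini_uberon(), mini_go(), mini_cl()):
        labels.update({tid: c.label for tid, c in ont.classes.items()})

    for sub in ("supports", "patterns", "fillers", "species"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    write_obo(mini_pato(), root / "supports" / "pato.obo")
    write_obo(mini_uberon(), root / "supports" / "uberon.obo")
    write_obo(mini_go(), root / "supports" / "go.obo")
    write_obo(mini_cl(), root / "supports" / "cl.obo")

    templates = fixture_templates(supports)
    for tpl in templates:
        (root / "patterns" / f"{tpl.pattern_name}.yaml").write_text(
            serialize_pattern(tpl), encoding="utf-8"
        )
    var_orders = {t.pattern_name: list(t.name_template.vars) for t in templates}
    for tbl in fixture_filler_tables():
        tbl.write_tsv(root / "fillers" / f"{tbl.pattern_name}.tsv", var_orders[tbl.pattern_name])

    for name, classes in fixture_species().items():
        write_phenotype_obo(classes, root / "species" / f"{name}.obo", labels)

    post = ["entity_id\tquality_id"]
    post += [f"{e.curie}\t{q.curie}" for e, q in fixture_postcomposed_rows()]
    (root / "postcomposed.tsv").write_text("\n".join(post) + "\n", encoding="utf-8")

    corp = ["entity_id\tterm_id"]
    for profile in fixture_corpus():
        corp += [f"{profile.entity_id}\t{t.curie}" for t in sorted(profile.terms)]
    (root / "corpus.tsv").write_text("\n".join(corp) + "\n", encoding="utf-8")

    manifest: dict[str, str] = {}
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            rel = path.relative_to(root).as_posix()
            manifest[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    (root / "manifest.json").write_text(
        json.dumps({"seed": seed, "files": manifest}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return FixtureSuite(root, manifest, seed)


# ---------------------------------------------------------------------------
# Random generators (property-test support)

@dataclass(frozen=True)
class RandomOntologySpec:
    n_terms: int
    edge_prob: float = 0.3
    part_of_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be positive")
        if not 0.0 <= self.edge_prob <= 1.0 or not 0.0 <= self.part_of_frac <= 1.0:
            raise ValueError("edge_prob and part_of_frac must lie in [0, 1]")


def gen_random_ontology(
    spec: RandomOntologySpec, prefix: str = "R", role: str = "entity"
) -> SupportOntology:
    """Random DAG by topological-order edge sampling (acyclic by construction)."""
    rng = random.Random(spec.seed)
    ids = [TermId(prefix, str(i).zfill(4)) for i in range(1, spec.n_terms + 1)]
    classes = [OntologyClass(tid, f"{prefix.lower()} term {tid.local_id}") for tid in ids]
    edges = []
    for j in range(1, len(ids)):
        for i in range(j):
            if rng.random() < spec.edge_prob:
                rel = Relation.part_of if rng.random() < spec.part_of_frac else Relation.is_a
                edges.append((ids[j], rel, ids[i]))
    return SupportOntology(classes, edges, role=role)


def gen_random_supports(
    seed: int, n_quality: int = 8, n_entity: int = 12
) -> SupportSet:
    quality = gen_random_ontology(
        RandomOntologySpec(n_quality, 0.35, 0.0, seed=seed * 3 + 1), prefix="Q", role="quality"
    )
    entity = gen_random_ontology(
        RandomOntologySpec(n_entity, 0.3, 0.3, seed=seed * 3 + 2), prefix="E", role="entity"
    )
    return SupportSet(quality, [entity])


def gen_random_eq_classes(
    supports: SupportSet,
    n: int,
    seed: int,
    prefix: str = "XX",
    p_towards: float = 0.2,
    p_occurs_in: float = 0.2,
) -> list[PhenotypeClass]:
    """Random phenotype classes over the given supports, seeded."""
    rng = random.Random(seed)
    qualities = sorted(supports.quality.classes)
    entities = sorted(t for ont in supports.entities for t in ont.classes)
    out = []
    for k in range(1, n + 1):
        eq = EQDefinition(
            quality=rng.choice(qualities),
            bearer=rng.choice(entities),
            bearer_mode=rng.choice(
                [Relation.characteristic_of, Relation.characteristic_of_part_of]
            ),
            towards=rng.choice(entities) if rng.random() < p_towards else None,
            occurs_in=rng.choice(entities) if rng.random() < p_occurs_in else None,
        )
        tid = TermId(prefix, str(k).zfill(4))
        out.append(PhenotypeClass(tid, f"{prefix.lower()} phenotype {k}", eq))
    return out


def gen_random_profiles(
    terms: list[TermId], n_profiles: int, seed: int, max_terms: int = 3
) -> list[Profile]:
    rng = random.Random(seed)
    out = []
    for k in range(1, n_profiles + 1):
        size = rng.randint(1, min(max_terms, len(terms)))
        out.append(Profile(f"p{k}", frozenset(rng.sample(sorted(terms), size))))
    return out
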