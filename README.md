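# pheno-forge

A desk-scale engine for cross-species computational phenomics. It
implements the entity–quality (EQ) approach to phenotype representation:
every phenotype class is logically defined as a quality (from a PATO-like
hierarchy) borne by an entity (an anatomical structure, biological process
or cellular component), always carrying an `abnormal` modifier:

```
has_part some (Q and characteristic_of[_part_of] some E
               [and towards some T] [and occurs_in some O]
               and has_modifier some abnormal)
```

Because every class follows this shape, subsumption between phenotype
classes reduces to component-wise closure checks against the support
ontologies — a structural, EL-style reasoner rather than a full OWL one.
`characteristic_of_part_of` absorbs parthood on the bearer side, which is
what lets "increased thickness of the aortic valve leaflet" classify under
"heart morphology phenotype": thickness `is_a` morphology, and the valve
leaflet is `part_of*` the heart.

On top of the reasoner the package provides:

- **Pattern templates** (DOSDP-style YAML) with `%s` slots for labels,
  text definitions and the logical axiom; filler tables (TSV) compile into
  generated phenotype classes with deterministic content-hashed ids.
- **Classification** of species-specific (HP/MP/ZP-style) and
  species-neutral terms into one hierarchy, with equivalence-group merging
  and transitive reduction, plus EQ class-expression queries.
- **Post-composed conversion**: (entity, quality) annotation pairs, as
  curated by ZFIN- or SGD-style databases, are matched to the most
  specific admitting template and pre-composed into classes.
- **Cross-species mappings** by logical and lexical matching, serialized
  as SSSOM TSV with `semapv:crossSpeciesExactMatch` / `skos:exactMatch`
  predicates and justification metadata.
- **Semantic similarity**: Jaccard over ancestor sets, corpus- or
  topology-based information content, and a PhenoDigm-style score
  `sqrt(jaccard × IC(MICA))` at term and profile level.

It is aimed at ontology engineers and comparative-phenomics developers who
want the whole pipeline — template instantiation through similarity
tables — runnable and testable on a laptop against miniature fixtures.

## Worked example

```python
from phenoforge import fixtures as fx
from phenoforge import build_unified, logical_match, information_content, phenodigm, TermId

supports = fx.fixture_supports()                 # mini PATO/Uberon/GO/CL
templates = fx.fixture_templates(supports)       # 7 pattern templates
tables = fx.fixture_filler_tables()
species = fx.fixture_species()                   # mini HP / MP / ZP

unified = build_unified(templates, tables, list(species.values()), supports)
print(f"{len(unified)} classes, {len(unified.direct_edges)} inferred direct edges")

cardio = TermId.parse("HP:0001640")
for anc in sorted(unified.ancestors(cardio)):
    print(f"  {anc}  {unified.label(anc)}")
```

prints

```
26 classes, 10 inferred direct edges
  HP:0001640  Cardiomegaly
  MP:0000274  enlarged heart
  PHF:1800734  increased size of the heart
  PHF:2675845  abnormal heart
  PHF:4146263  heart morphology phenotype
  PHF:8298044  size of heart phenotype
  ZP:0000532  heart increased size, abnormal
```

Human Cardiomegaly, mouse enlarged heart and the zebrafish heart-size term
share one logical definition, so they merge into an equivalence group with
the template-generated "increased size of the heart" (`PHF:*` ids are the
engine's minted species-neutral classes), which is in turn inferred under
the size, morphology and top-level heart groupings. Continuing:

```python
for m in logical_match(species["mp"], species["hp"], supports):
    print(f"{m.subject_id} -> {m.object_id}  {m.predicate.value}")

ic = information_content(unified, fx.fixture_corpus())
r = phenodigm(unified, ic, cardio, TermId.parse("ZP:0000532"))
print(f"jaccard={r.jaccard:.2f} IC(MICA)={r.ic_mica:.2f} phenodigm={r.phenodigm:.2f}")
```

```
MP:0000274 -> HP:0001640  semapv:crossSpeciesExactMatch
MP:0003807 -> HP:0100490  semapv:crossSpeciesExactMatch
MP:0003855 -> HP:0002973  semapv:crossSpeciesExactMatch
jaccard=1.00 IC(MICA)=1.00 phenodigm=1.00
```

The mouse "abnormal forelimb zeugopod morphology" maps to the human
"Abnormal forearm morphology" because both are defined on the same
anatomical term (UBERON:0002386); the HP/ZP heart pair scores jaccard 1
(identical inferred ancestry) and IC 1 bit (half of the six-gene corpus is
annotated to the heart-size group, −log₂ ½ = 1).

## Command line

```sh
pheno-forge fixtures --out suite/            # write the fixture suite
pheno-forge validate suite/supports/uberon.obo
pheno-forge generate --pattern suite/patterns/increasedSizeOfAnatomicalEntity.yaml \
    --table suite/fillers/increasedSizeOfAnatomicalEntity.tsv \
    --supports suite/supports -o generated.obo
pheno-forge classify suite/species/*.obo generated.obo \
    --supports suite/supports -o classified.obo --edges edges.tsv
pheno-forge query --quality PATO:0000051 --bearer UBERON:0000948 \
    --supports suite/supports suite/species/*.obo
pheno-forge map --left suite/species/mp.obo --right suite/species/hp.obo \
    --supports suite/supports -o mappings.sssom.tsv
pheno-forge sim --ontology suite/species/hp.obo --ontology suite/species/zp.obo \
    --supports suite/supports --corpus suite/corpus.tsv -o sim.tsv
```

Exit codes: 0 success, 1 usage error, 2 data error.

## Layout

- `src/phenoforge/model.py` — CURIE term ids, support-ontology DAGs, closures
- `src/phenoforge/obo.py` — OBO-subset reader/writer (incl. EQ blocks)
- `src/phenoforge/patterns.py` — template parsing, instantiation, precomposition
- `src/phenoforge/reasoner.py` — structural EQ subsumption, classification, queries
- `src/phenoforge/mapping.py` — logical/lexical matching, SSSOM TSV
- `src/phenoforge/semsim.py` — Jaccard, information content, PhenoDigm-style scores
- `src/phenoforge/fixtures.py` — deterministic fixture suite, random generators
- `src/phenoforge/cli.py` — the `pheno-forge` command

See `docs/methods.md` for the model, its assumptions and the numerical
conventions.
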