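# Methods

## The EQ model and its scope

A phenotype class is represented by a normalized logical definition with
six components: a **quality** `Q` from the quality hierarchy, a **bearer**
`E` from an entity hierarchy, a **bearer mode** (`characteristic_of` or
`characteristic_of_part_of`), an optional **towards** filler (the second
entity of a relational quality), an optional **occurs_in** location (for
processes localized to an anatomical site), and a **modifier**, fixed to
`abnormal` in this version: the engine models deviations from a reference
state only, never "normal" phenotypes, comparators or effect sizes.

Composite bearers are limited to one `towards` and one `occurs_in` filler.
Deeper nesting (e.g. a chemical playing a role in a location) is encoded
by treating the role term as the bearer and the location as `occurs_in`.
Negation, cardinality and disjointness are out of scope, as are phenotype
classes that have no EQ decomposition at all; those can only enter the
hierarchy through the (shipped but unused) manual-edge injection hook.

## Structural subsumption

`subsumes(general, specific)` holds iff all of:

1. `specific.Q is_a* general.Q` (quality hierarchy only);
2. bearer compatibility — under `characteristic_of_part_of` the general
   bearer must be reachable from the specific bearer through the combined
   `is_a`/`part_of` closure; under `characteristic_of` both classes must
   use the strict mode and only `is_a` counts;
3. a general `towards`, when present, must be matched by a specific
   `towards` inside its `is_a` closure (absent means unconstrained);
4. likewise for `occurs_in`, with parthood admitted (a process occurring
   in the aortic valve occurs in the heart);
5. modifiers agree.

Each clause is a closure membership, so the relation is reflexive and
transitive by construction. Treating `characteristic_of_part_of` as
absorbing parthood composition is the engine's fixed reading of the
property-chain semantics attached to that relation; the exact chain axioms
admit more than one formalization, and this one is documented here as the
contract. It is what makes a valve-leaflet thickness phenotype a heart
morphology phenotype.

Classification computes the full pairwise subsumption preorder, merges
mutually subsuming classes into equivalence groups (canonical
representative: lexicographically smallest id), and emits the transitive
reduction of the condensed DAG. Cross-namespace equivalences are expected,
not errors — a species term whose definition coincides with a generated
grouping joins its group, and the mapping layer reports the pair as an
exact match; consumers preferring a subclass-only view can read the
groups out of `ClassifiedOntology.groups`. Class-expression queries walk
the classified hierarchy top-down and stop testing below the first
subsumed group, which is sound because the hierarchy encodes the
(transitive) subsumption relation.

## Pattern templates and id minting

Templates are YAML documents with `classes`/`relations`/`vars` maps, text
templates (`name`, `def`) using printf-style `%s` slots filled in declared
var order, and an `equivalentTo` axiom template in a Manchester-like
conjunction syntax. Filler values are range-checked by strict `is_a`
subsumption against the var's range class. Label casing is template data:
species conventions differ (HP capitalizes, MP does not), so the engine
never recases anything.

Generated ids are content hashes: SHA-256 of `(pattern_iri, sorted
bindings)` reduced into a 7-digit `PHF:` numeric space. This makes every
generated class fully re-derivable from its provenance pair and keeps ids
independent of batch composition; collisions are detected and raised
(at fixture scale the probability is negligible). A batch-rank scheme was
considered and rejected because it would make ids depend on what else was
in the table.

Post-composed (entity, quality) rows are converted to pre-composed classes
by matching each row against all single-variable templates whose range
admits the entity (`is_a`) and whose fixed quality subsumes the row's
quality (`is_a`). The most specific template wins, where specificity is
the quality's depth (longest `is_a` chain from its root); ties break on
pattern name. Unmatched rows are returned as data with a reason, never as
errors — real post-composed corpora always contain combinations no
template covers.

## Mappings

Logical matching emits `crossSpeciesExactMatch` only for *identical*
normalized definitions (identical characteristics of the same pre-aligned
structure) and downgrades mutually-subsuming-but-not-identical pairs to
`exactMatch`. Lexical matching joins on casefolded, punctuation-stripped,
whitespace-collapsed labels and selected synonym scopes. Confidence values
(1.0 logical, 0.9 label–label, 0.8 synonym-involving) are package
conventions for downstream filtering, not calibrated probabilities. When
logical and lexical matching both fire for a pair, both rows are emitted
with their justifications; no precedence is imposed. Species bearer terms
are assumed pre-aligned to the species-neutral entity ontologies; no
bridge-axiom inference is attempted.

SSSOM files carry a `# `-prefixed YAML header (mapping set id, license,
date, curie map) and eight fixed columns; reading back a written file
reproduces the document exactly.

## Similarity

- **Jaccard** uses reflexive `is_a` ancestor sets of the classified
  hierarchy, expanded over equivalence groups. Parthood affects similarity
  only through classification, never directly.
- **Information content** is in bits (log base 2). Corpus strategy:
  annotations propagate to ancestors and `IC(t) = −log2(hits/N)`; terms
  with zero hits get the add-one value `log2(N+1)` rather than infinity.
  Topology strategy: `p(t) = (|descendants(t)|+1)/|classes|`, for use when
  no annotation corpus exists. Which strategy a published similarity table
  should use is genuinely open; both are implemented and the CLI exposes
  the choice (`--ic corpus|topology`, default corpus).
- **PhenoDigm-style score**: `sqrt(jaccard × IC(MICA))`, the geometric
  mean of positional and information-theoretic similarity, with the MICA
  chosen as the common ancestor of maximal IC (ties: smallest id). The
  profile-level `combined` mode normalizes best-match max and average by
  the query profile's self-comparison and scales to 0–100. The formula is
  isolated behind one function so an alternative normalization can be
  substituted without touching callers.

## Fixture suite

The fixture suite emulates the cross-species integration setting at desk
scale: ~15-term quality and ~9-term anatomy hierarchies, process/component
stubs, seven templates, three mini species ontologies whose ids and labels
are the published ones wherever a published counterpart exists, three
post-composed rows (including one deliberately unmatched), and a six-gene
annotation corpus. What it does **not** emulate: ontology size (real
phenotype ontologies have 10³–10⁴ terms), bridge alignments between
species anatomy ontologies (fixture species terms are defined directly on
species-neutral entities), annotation sparsity and bias, synonym richness,
and logically undefinable classes. Passing tests therefore demonstrate
correctness of the algorithms under the stated semantics, not coverage
behavior on full-scale released ontologies.

Property tests run against random DAGs produced by topological-order edge
sampling (acyclic by construction) and random EQ sets over random
supports, with all randomness flowing from explicit integer seeds. Oracle
sweeps use a few thousand brute-force comparisons per run (e.g. 100 seeds
× all pairs of 8×8 EQ classes over 20-term supports); these sizes keep the
whole suite in the seconds range while exercising every closure branch.

## Numerical and degenerate-input conventions

- All orderings (stanzas, edges, mappings, table rows) are total and
  deterministic; repeated runs and permuted inputs are byte-identical.
- Empty inputs are identities where meaningful (empty OBO file, empty
  filler table) and errors where meaningless (empty corpus with corpus IC,
  empty profile).
- Obsolete terms are dropped at load together with their edges — the
  simplest behavior that cannot create dangling references.
- Cycles in `is_a ∪ part_of` are rejected at load, naming a cycle member.
- Floating-point comparisons in tests use exact equality only where the
  arithmetic is exact (powers of two); everything else uses relative
  tolerance.

## Known limitations

- One quality, one bearer, at most one `towards`/`occurs_in` per
  definition; no qualifier algebra beyond the fixed `abnormal`.
- The reasoner is deliberately incomplete relative to OWL EL: it never
  invents classes, so a query can only return classes that exist.
- Lexical matching is exact-string after normalization; no stemming,
  embeddings or fuzzy matching.
- `part_of` is the only mereological relation; `has_part` on the entity
  side and population-level relations are extension points, not features.
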