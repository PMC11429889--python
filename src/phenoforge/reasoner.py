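"""Structural subsumption over entity–quality phenotype definitions.

A phenotype class is logically defined by an EQ expression of the shape::

    has_part some (Q
                   and characteristic_of[_part_of] some E
                   [and towards some T]
                   [and occurs_in some O]
                   and has_modifier some abnormal)

where ``Q`` is a quality (PATO-like hierarchy) and ``E``/``T``/``O`` are
entity terms (anatomy, process, cellular-component hierarchies).  Because
every class follows this shape, subsumption between two phenotype classes
reduces to component-wise closure checks against the support ontologies —
no general OWL reasoner is required.  The semantics implemented here:

* the quality of the specific class must be an ``is_a`` descendant of the
  general quality;
* ``characteristic_of_part_of`` absorbs parthood on the bearer side (the
  bearer of the specific class may be the general bearer, a subclass of it,
  or a part of it), while plain ``characteristic_of`` is strict ``is_a``;
* a general class without ``towards``/``occurs_in`` constrains nothing; when
  present, the specific class must fill the slot with a term inside the
  corresponding closure (``is_a`` for towards, ``is_a``/``part_of`` for
  occurs-in);
* modifiers must agree (only ``abnormal`` exists in this version).

The relation is a preorder; mutually subsuming classes are merged into
equivalence groups during classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import UsageError
from .model import Relation, SupportSet, TermId

__all__ = [
    "EQDefinition",
    "PhenotypeClass",
    "ClassifiedOntology",
    "subsumes",
    "classify",
    "query",
    "build_unified",
]

#: bearer modes admissible in an EQ definition
BEARER_MODES = (Relation.characteristic_of, Relation.characteristic_of_part_of)

ISA = frozenset({Relation.is_a})
ISA_PART = frozenset({Relation.is_a, Relation.part_of})


@dataclass(frozen=True)
class EQDefinition:
    """Normalized logical definition of a phenotype class.

    ``quality`` lives in the quality support ontology; ``bearer``,
    ``towards`` and ``occurs_in`` in the entity support ontologies.  The
    ``modifier`` is fixed to ``"abnormal"`` — every phenotype here is a
    deviation from the reference state.
    """

    quality: TermId
    bearer: TermId
    bearer_mode: Relation = Relation.characteristic_of_part_of
    towards: Optional[TermId] = None
    occurs_in: Optional[TermId] = None
    modifier: str = "abnormal"

    def __post_init__(self) -> None:
        if self.bearer_mode not in BEARER_MODES:
            raise ValueError(
                f"bearer_mode must be characteristic_of or characteristic_of_part_of,"
                f" got {self.bearer_mode.value}"
            )
        if self.modifier != "abnormal":
            raise ValueError(f"only the 'abnormal' modifier is supported, got {self.modifier!r}")

    def validate(self, supports: SupportSet) -> None:
        """Raise if any component term is undeclared or misplaced."""
        if not supports.is_quality(self.quality):
            supports[self.quality]  # not-found error wins over misplacement
            raise UsageError(f"quality {self.quality} is not in the quality ontology")
        for t in (self.bearer, self.towards, self.occurs_in):
            if t is not None:
                supports[t]


@dataclass(frozen=True)
class PhenotypeClass:
    """A named phenotype term, species-specific (HP/MP/ZP...) or neutral."""

    id: TermId
    label: str
    eq: Optional[EQDefinition] = None

    @property
    def namespace(self) -> str:
        return self.id.prefix


def subsumes(general: EQDefinition, specific: EQDefinition, supports: SupportSet) -> bool:
    """True iff every instance of ``specific`` is an instance of ``general``.

    Reflexive and transitive by construction (each check is a closure
    membership, and closures compose).
    """
    # (i) quality along is_a
    if general.quality not in supports.ancestors(specific.quality, ISA):
        return False
    # (ii) bearer, with parthood absorbed only by characteristic_of_part_of
    if general.bearer_mode is Relation.characteristic_of_part_of:
        if general.bearer not in supports.ancestors(specific.bearer, ISA_PART):
            return False
    else:
        if specific.bearer_mode is not Relation.characteristic_of:
            return False
        if general.bearer not in supports.ancestors(specific.bearer, ISA):
            return False
    # (iii) towards: absent means unconstrained
    if general.towards is not None:
        if specific.towards is None:
            return False
        if general.towards not in supports.ancestors(specific.towards, ISA):
            return False
    # (iv) occurs_in: location may be reached through parthood
    if general.occurs_in is not None:
        if specific.occurs_in is None:
            return False
        if general.occurs_in not in supports.ancestors(specific.occurs_in, ISA_PART):
            return False
    # (v) modifier
    return general.modifier == specific.modifier


class ClassifiedOntology:
    """The inferred phenotype hierarchy.

    Mutually subsuming classes form equivalence groups; ``direct_edges`` is
    the transitive reduction of the inferred subsumption preorder, expressed
    between group representatives (lexicographically smallest member id).
    """

    def __init__(
        self,
        classes: dict[TermId, PhenotypeClass],
        canonical: dict[TermId, TermId],
        direct_edges: list[tuple[TermId, TermId]],
    ) -> None:
        self.classes = classes
        self.canonical = canonical  # member id -> representative id
        self.direct_edges = direct_edges  # (child rep, parent rep), sorted
        self.groups: dict[TermId, frozenset[TermId]] = {}
        by_rep: dict[TermId, set[TermId]] = {}
        for member, rep in canonical.items():
            by_rep.setdefault(rep, set()).add(member)
        self.groups = {rep: frozenset(m) for rep, m in by_rep.items()}
        self._parents: dict[TermId, list[TermId]] = {}
        self._children: dict[TermId, list[TermId]] = {}
        for child, parent in direct_edges:
            self._parents.setdefault(child, []).append(parent)
            self._children.setdefault(parent, []).append(child)

    @classmethod
    def from_edges(
        cls,
        classes: Iterable[PhenotypeClass],
        edges: Iterable[tuple[TermId, TermId]],
    ) -> "ClassifiedOntology":
        """Build a hierarchy from asserted (child, parent) is_a edges.

        Convenience for similarity computations over hierarchies that were
        not produced by :func:`classify` (no equivalence groups inferred).
        """
        cmap = {c.id: c for c in classes}
        g = nx.DiGraph()
        g.add_nodes_from(cmap)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise UsageError("asserted is_a edges contain a cycle")
        reduced = nx.transitive_reduction(g)
        return cls(
            cmap,
            {t: t for t in cmap},
            sorted(reduced.edges()),
        )

    def __contains__(self, term: TermId) -> bool:
        return term in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, term: TermId) -> PhenotypeClass:
        from .errors import TermNotFoundError

        try:
            return self.classes[term]
        except KeyError:
            raise TermNotFoundError(f"term {term} not in classified ontology") from None

    def label(self, term: TermId) -> str:
        return self[term].label

    def equivalents(self, term: TermId) -> frozenset[TermId]:
        self[term]
        return self.groups[self.canonical[term]]

    def _rep_closure(self, rep: TermId, adj: dict[TermId, list[TermId]]) -> set[TermId]:
        seen: set[TermId] = {rep}
        stack = [rep]
        while stack:
            for nb in adj.get(stack.pop(), ()):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    def ancestors(self, term: TermId, include_self: bool = True) -> set[TermId]:
        """All classes subsuming ``term`` (expanded over equivalence groups)."""
        self[term]
        reps = self._rep_closure(self.canonical[term], self._parents)
        out: set[TermId] = set()
        for rep in reps:
            out |= self.groups[rep]
        if not include_self:
            out.discard(term)
        elif term not in out:  # pragma: no cover - term always in own group
            out.add(term)
        return out

    def descendants(self, term: TermId, include_self: bool = True) -> set[TermId]:
        self[term]
        reps = self._rep_closure(self.canonical[term], self._children)
        out: set[TermId] = set()
        for rep in reps:
            out |= self.groups[rep]
        if not include_self:
            out.discard(term)
        return out

    def roots(self) -> list[TermId]:
        return sorted(rep for rep in self.groups if rep not in self._parents)


def classify(classes: Sequence[PhenotypeClass], supports: SupportSet) -> ClassifiedOntology:
    """Compute the full subsumption hierarchy over ``classes``.

    Pairwise structural subsumption, condensation of mutual subsumption into
    equivalence groups, then transitive reduction.  Output is independent of
    input order: representatives and edges are chosen by id sort.
    """
    cmap: dict[TermId, PhenotypeClass] = {}
    for c in sorted(classes, key=lambda c: c.id):
        if c.eq is None:
            raise UsageError(f"class {c.id} has no logical definition; cannot classify")
        if c.id in cmap:
            raise UsageError(f"duplicate class id {c.id}")
        c.eq.validate(supports)
        cmap[c.id] = c
    ids = sorted(cmap)
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    for child in ids:
        for parent in ids:
            if child is not parent and subsumes(cmap[parent].eq, cmap[child].eq, supports):
                g.add_edge(child, parent)
    # condense mutual subsumption into equivalence groups
    canonical: dict[TermId, TermId] = {}
    for comp in nx.strongly_connected_components(g):
        rep = min(comp)
        for member in comp:
            canonical[member] = rep
    cond = nx.DiGraph()
    cond.add_nodes_from(set(canonical.values()))
    for child, parent in g.edges():
        cr, pr = canonical[child], canonical[parent]
        if cr != pr:
            cond.add_edge(cr, pr)
    reduced = nx.transitive_reduction(cond)
    return ClassifiedOntology(cmap, canonical, sorted(reduced.edges()))


def query(
    expr: EQDefinition,
    ont: ClassifiedOntology,
    supports: SupportSet,
) -> set[PhenotypeClass]:
    """All classes whose definition is subsumed by the query expression.

    Walks the classified hierarchy top-down: once a group's definition is
    subsumed, all its descendants are included without further checks
    (subsumption is transitive and the hierarchy encodes it), so only the
    frontier of non-matching groups is tested.
    """
    expr.validate(supports)
    hits: set[TermId] = set()
    seen: set[TermId] = set()
    stack = list(ont.roots())
    while stack:
        rep = stack.pop()
        if rep in seen or rep in hits:
            continue
        seen.add(rep)
        eq = ont[rep].eq
        if eq is not None and subsumes(expr, eq, supports):
            hits |= {ont.canonical[d] for d in ont.descendants(rep)}
        else:
            stack.extend(ont._children.get(rep, ()))
    out: set[PhenotypeClass] = set()
    for rep in hits:
        out.update(ont[m] for m in ont.groups[rep])
    return out


def build_unified(
    templates: Sequence,
    filler_tables: Sequence,
    species_onts: Sequence[Sequence[PhenotypeClass]],
    supports: SupportSet,
) -> ClassifiedOntology:
    """Compile species-neutral grouping classes and classify everything.

    ``templates`` and ``filler_tables`` are matched by pattern name; each
    pair yields generated grouping classes which are merged with the species
    phenotype classes and classified together, so every species class with a
    compatible definition acquires at least one species-neutral ancestor.
    """
    from .patterns import compile_table  # local import avoids a module cycle

    by_name = {t.pattern_name: t for t in templates}
    generated = []
    for tbl in filler_tables:
        tpl = by_name.get(tbl.pattern_name)
        if tpl is None:
            raise UsageError(f"no template named {tbl.pattern_name!r} for filler table")
        generated.extend(compile_table(tpl, tbl, supports))
    merged: list[PhenotypeClass] = [
        PhenotypeClass(id=g.id, label=g.label, eq=g.eq) for g in generated
    ]
    for ont in species_onts:
        merged.extend(ont)
    return classify(merged, supports)
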