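"""Core ontology data types and closure operations.

The engine works over *support ontologies*: a quality hierarchy (PATO-like)
and one or more entity hierarchies (Uberon/GO/CL-like).  Support ontologies
are plain DAGs whose edges carry only ``is_a`` and ``part_of``; every other
relation of the EQ model (``characteristic_of``, ``towards``, ...) appears
exclusively inside logical definitions, never as a graph edge.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Iterator, Optional

import networkx as nx

from .errors import ReferentialError, StructuralError, TermNotFoundError

__all__ = [
    "TermId",
    "Relation",
    "SynonymScope",
    "OntologyClass",
    "SupportOntology",
    "SupportSet",
    "ancestors",
    "is_subclass_or_part",
]


@total_ordering
@dataclass(frozen=True)
class TermId:
    """A CURIE-identified term, e.g. ``UBERON:0000948``.

    ``prefix`` is the namespace token (``UBERON``), ``local_id`` the local
    part (``0000948``).  Identifiers are case-sensitive; parsing followed by
    serialization is the identity.
    """

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        for part, name in ((self.prefix, "prefix"), (self.local_id, "local_id")):
            if not part:
                raise ValueError(f"TermId {name} must be nonempty")
            if ":" in part or any(c.isspace() for c in part):
                raise ValueError(f"TermId {name} {part!r} contains whitespace or ':'")

    @classmethod
    def parse(cls, curie: str) -> "TermId":
        prefix, sep, local = curie.partition(":")
        if not sep:
            raise ValueError(f"not a CURIE (missing ':'): {curie!r}")
        return cls(prefix, local)

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __str__(self) -> str:
        return self.curie

    def __lt__(self, other: "TermId") -> bool:
        return self.curie < other.curie


class Relation(enum.Enum):
    """Relations of the EQ model.

    Only ``is_a`` and ``part_of`` may label support-ontology edges; the rest
    connect the pieces of a logical phenotype definition.
    """

    is_a = "is_a"
    part_of = "part_of"
    has_part = "has_part"
    characteristic_of = "characteristic_of"
    characteristic_of_part_of = "characteristic_of_part_of"
    towards = "towards"
    has_modifier = "has_modifier"
    occurs_in = "occurs_in"


#: relations admissible as support-ontology edges
EDGE_RELATIONS = frozenset({Relation.is_a, Relation.part_of})


class SynonymScope(enum.Enum):
    exact = "EXACT"
    broad = "BROAD"
    narrow = "NARROW"
    related = "RELATED"


@dataclass(frozen=True)
class OntologyClass:
    """A named class in a support ontology."""

    id: TermId
    label: str
    definition: Optional[str] = None
    synonyms: tuple[tuple[str, SynonymScope], ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"class {self.id} has an empty label")

    @property
    def namespace(self) -> str:
        return self.id.prefix


class SupportOntology:
    """A validated DAG of classes over ``is_a`` and ``part_of`` edges.

    ``role`` records whether the ontology supplies qualities (PATO-like) or
    entities (anatomy/process/component hierarchies).

    Parameters
    ----------
    classes:
        The declared classes.
    edges:
        ``(subject, relation, object)`` triples meaning *subject relation
        object* (child -> parent direction).
    role:
        ``"quality"`` or ``"entity"``.
    """

    def __init__(
        self,
        classes: Iterable[OntologyClass],
        edges: Iterable[tuple[TermId, Relation, TermId]],
        role: str = "entity",
    ) -> None:
        if role not in ("quality", "entity"):
            raise ValueError(f"role must be 'quality' or 'entity', got {role!r}")
        self.role = role
        self.classes: dict[TermId, OntologyClass] = {}
        for cls in classes:
            if cls.id in self.classes:
                raise StructuralError(f"duplicate class id {cls.id}")
            self.classes[cls.id] = cls
        self.edges: list[tuple[TermId, Relation, TermId]] = []
        seen: set[tuple[TermId, Relation, TermId]] = set()
        for subj, rel, obj in edges:
            if rel not in EDGE_RELATIONS:
                raise StructuralError(
                    f"relation {rel.value} is not admissible as an ontology edge"
                )
            for end in (subj, obj):
                if end not in self.classes:
                    raise ReferentialError(
                        f"edge ({subj} {rel.value} {obj}) references undeclared term {end}"
                    )
            triple = (subj, rel, obj)
            if triple not in seen:
                seen.add(triple)
                self.edges.append(triple)
        self._check_acyclic()
        # child -> parents adjacency per relation, for closure traversal
        self._parents: dict[Relation, dict[TermId, list[TermId]]] = {
            Relation.is_a: {},
            Relation.part_of: {},
        }
        for subj, rel, obj in self.edges:
            self._parents[rel].setdefault(subj, []).append(obj)

    def _check_acyclic(self) -> None:
        # combined (is_a | part_of) acyclicity implies acyclicity of each
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        g.add_edges_from((s, o) for s, _, o in self.edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        member = cycle[0][0]
        raise StructuralError(f"cycle in is_a/part_of graph involving {member}")

    def __contains__(self, term: TermId) -> bool:
        return term in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self) -> Iterator[TermId]:
        return iter(self.classes)

    def label(self, term: TermId) -> str:
        return self[term].label

    def __getitem__(self, term: TermId) -> OntologyClass:
        try:
            return self.classes[term]
        except KeyError:
            raise TermNotFoundError(f"term {term} not declared") from None

    def parents(self, term: TermId, rels: frozenset[Relation]) -> set[TermId]:
        self[term]
        out: set[TermId] = set()
        for rel in rels:
            out.update(self._parents[rel].get(term, ()))
        return out


def ancestors(
    ont: "SupportOntology | SupportSet",
    term: TermId,
    rels: Iterable[Relation] = (Relation.is_a,),
    include_self: bool = True,
) -> set[TermId]:
    """Reflexive-optional transitive closure of ``term`` over ``rels`` edges.

    Deterministic and order-independent: the result is a plain set reached by
    breadth-first traversal in the child -> parent direction.
    """
    rels = frozenset(rels)
    if not rels <= EDGE_RELATIONS:
        bad = ", ".join(sorted(r.value for r in rels - EDGE_RELATIONS))
        raise ValueError(f"ancestors only traverses is_a/part_of, got {bad}")
    closed: set[TermId] = set()
    frontier = [term]
    ont[term]  # raise TermNotFoundError early
    while frontier:
        nxt: list[TermId] = []
        for t in frontier:
            for p in ont.parents(t, rels):
                if p not in closed and p != term:
                    closed.add(p)
                    nxt.append(p)
        frontier = nxt
    if include_self:
        closed.add(term)
    else:
        closed.discard(term)
    return closed


def is_subclass_or_part(
    ont: "SupportOntology | SupportSet",
    a: TermId,
    b: TermId,
    use_part_of: bool = False,
) -> bool:
    """True iff ``a`` is ``b`` or reaches ``b`` via is_a (and part_of if asked)."""
    ont[b]
    rels = {Relation.is_a} | ({Relation.part_of} if use_part_of else set())
    return b in ancestors(ont, a, rels, include_self=True)


class SupportSet:
    """The union of the quality ontology and the entity ontologies.

    Phenotype logical definitions draw their quality from one hierarchy and
    their bearer/towards/occurs-in fillers from the entity hierarchies; the
    reasoner needs a single lookup surface over all of them.  Namespaces are
    expected to be disjoint across member ontologies.
    """

    def __init__(self, quality: SupportOntology, entities: Iterable[SupportOntology]):
        self.quality = quality
        self.entities = list(entities)
        self._members = [quality, *self.entities]
        self._home: dict[TermId, SupportOntology] = {}
        for ont in self._members:
            for tid in ont.classes:
                if tid in self._home:
                    raise StructuralError(f"term {tid} declared in two support ontologies")
                self._home[tid] = ont
        self._closure_cache: dict[tuple[TermId, frozenset[Relation]], frozenset[TermId]] = {}

    def __contains__(self, term: TermId) -> bool:
        return term in self._home

    def __getitem__(self, term: TermId) -> OntologyClass:
        ont = self._home.get(term)
        if ont is None:
            raise TermNotFoundError(f"term {term} not declared in any support ontology")
        return ont[term]

    def label(self, term: TermId) -> str:
        return self[term].label

    def home(self, term: TermId) -> SupportOntology:
        self[term]
        return self._home[term]

    def parents(self, term: TermId, rels: frozenset[Relation]) -> set[TermId]:
        return self.home(term).parents(term, rels)

    def ancestors(
        self,
        term: TermId,
        rels: Iterable[Relation] = (Relation.is_a,),
        include_self: bool = True,
    ) -> frozenset[TermId]:
        """Memoized closure; the cache makes pairwise classification cheap."""
        key = (term, frozenset(rels))
        hit = self._closure_cache.get(key)
        if hit is None:
            hit = frozenset(ancestors(self, term, key[1], include_self=True))
            self._closure_cache[key] = hit
        return hit if include_self else hit - {term}

    def is_quality(self, term: TermId) -> bool:
        return term in self.quality

    def depth(self, term: TermId) -> int:
        """Length of the longest is_a chain above ``term`` (root depth 0)."""
        memo: dict[TermId, int] = {}

        def rec(t: TermId) -> int:
            if t in memo:
                return memo[t]
            ps = self.parents(t, frozenset({Relation.is_a}))
            memo[t] = 0 if not ps else 1 + max(rec(p) for p in ps)
            return memo[t]

        return rec(term)
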