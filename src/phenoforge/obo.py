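"""Reader/writer for a small OBO-format subset.

Supported tags in ``[Term]`` stanzas: ``id``, ``name``, ``def``,
``synonym`` (with scope), ``is_a``, ``relationship: part_of``,
``is_obsolete`` and — for phenotype files — an ``intersection_of`` block
carrying the EQ logical definition::

    [Term]
    id: HP:0001640
    name: Cardiomegaly
    intersection_of: PATO:0000586 ! increased size
    intersection_of: characteristic_of_part_of UBERON:0000948 ! heart
    intersection_of: has_modifier abnormal

The first ``intersection_of`` line is the primary quality (the genus); the
rest are ``relation filler`` pairs.  All other tags are ignored with a
logged warning.  Obsolete terms and their edges are dropped at load.  The
writer emits a canonical form (stanzas and tags sorted), so loading and
re-writing any file is idempotent and byte-stable.
"""

from __future__ import annotations

import logging
import pathlib
import re
from typing import Iterable, Optional, Sequence, TextIO, Union

from .errors import StructuralError, TemplateError
from .model import (
    OntologyClass,
    Relation,
    SupportOntology,
    SynonymScope,
    TermId,
)
from .reasoner import EQDefinition, PhenotypeClass

__all__ = [
    "load_obo",
    "write_obo",
    "load_phenotype_obo",
    "write_phenotype_obo",
    "write_edges_tsv",
]

log = logging.getLogger(__name__)

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s+(?P<scope>EXACT|BROAD|NARROW|RELATED)\b')
_DEF_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')

_KNOWN_TAGS = {
    "id", "name", "def", "synonym", "is_a", "relationship",
    "is_obsolete", "intersection_of",
}


def _strip_comment(value: str) -> str:
    # OBO trailing comments: " ! label"
    return value.split(" !", 1)[0].strip()


def _parse_stanzas(text: str) -> list[dict]:
    stanzas: list[dict] = []
    current: Optional[dict] = None
    warned: set[str] = set()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            current = {"_type": line.strip("[]"), "_tags": []}
            stanzas.append(current)
            continue
        if current is None:
            continue  # header tags (format-version etc.) are irrelevant here
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag not in _KNOWN_TAGS:
            if tag not in warned:
                warned.add(tag)
                log.warning("ignoring unsupported OBO tag %r", tag)
            continue
        current["_tags"].append((tag, value))
    return [s for s in stanzas if s["_type"] == "Term"]


def _parse_term(stanza: dict):
    tid = name = definition = None
    synonyms: list[tuple[str, SynonymScope]] = []
    is_a: list[TermId] = []
    part_of: list[TermId] = []
    intersections: list[tuple[Optional[str], str]] = []
    obsolete = False
    for tag, value in stanza["_tags"]:
        if tag == "id":
            tid = TermId.parse(_strip_comment(value))
        elif tag == "name":
            name = value
        elif tag == "def":
            m = _DEF_RE.match(value)
            definition = m.group("text").replace('\\"', '"') if m else value
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if m:
                synonyms.append(
                    (m.group("text").replace('\\"', '"'), SynonymScope(m.group("scope")))
                )
            else:
                log.warning("unparseable synonym line %r", value)
        elif tag == "is_a":
            is_a.append(TermId.parse(_strip_comment(value)))
        elif tag == "relationship":
            rel, _, target = _strip_comment(value).partition(" ")
            if rel == "part_of":
                part_of.append(TermId.parse(target.strip()))
            else:
                log.warning("ignoring unsupported relationship %r", rel)
        elif tag == "intersection_of":
            body = _strip_comment(value)
            head, _, rest = body.partition(" ")
            if rest:
                intersections.append((head, rest.strip()))
            else:
                intersections.append((None, head))
        elif tag == "is_obsolete":
            obsolete = value.lower() == "true"
    if tid is None:
        raise StructuralError("[Term] stanza without an id")
    return tid, name, definition, synonyms, is_a, part_of, intersections, obsolete


def load_obo(path: Union[str, pathlib.Path], role: str = "entity") -> SupportOntology:
    """Load a support ontology from an OBO-subset file.

    Raises ``StructuralError`` on cycles and ``ReferentialError`` on edges
    to undeclared terms (both via ``SupportOntology`` validation).
    """
    text = pathlib.Path(path).read_text(encoding="utf-8")
    classes: list[OntologyClass] = []
    edges: list[tuple[TermId, Relation, TermId]] = []
    dropped: set[TermId] = set()
    for stanza in _parse_stanzas(text):
        tid, name, definition, synonyms, is_a, part_of, _, obsolete = _parse_term(stanza)
        if obsolete:
            dropped.add(tid)
            continue
        classes.append(
            OntologyClass(tid, name or tid.curie, definition, tuple(synonyms))
        )
        for parent in is_a:
            edges.append((tid, Relation.is_a, parent))
        for whole in part_of:
            edges.append((tid, Relation.part_of, whole))
    edges = [e for e in edges if e[0] not in dropped and e[2] not in dropped]
    return SupportOntology(classes, edges, role=role)


def _fmt_def(text: str) -> str:
    return '"%s" []' % text.replace('"', '\\"')


def write_obo(
    ont: SupportOntology,
    dest: Union[str, pathlib.Path, TextIO],
) -> None:
    """Write the canonical OBO-subset form: stanzas sorted by id, fixed tag order."""
    parents_isa: dict[TermId, list[TermId]] = {}
    parents_part: dict[TermId, list[TermId]] = {}
    for s, rel, o in ont.edges:
        (parents_isa if rel is Relation.is_a else parents_part).setdefault(s, []).append(o)
    lines = ["format-version: 1.2", ""]
    for tid in sorted(ont.classes):
        cls = ont.classes[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid.curie}")
        lines.append(f"name: {cls.label}")
        if cls.definition:
            lines.append(f"def: {_fmt_def(cls.definition)}")
        for text, scope in sorted(cls.synonyms):
            lines.append('synonym: "%s" %s []' % (text.replace('"', '\\"'), scope.value))
        for p in sorted(parents_isa.get(tid, ())):
            lines.append(f"is_a: {p.curie} ! {ont.label(p)}")
        for p in sorted(parents_part.get(tid, ())):
            lines.append(f"relationship: part_of {p.curie} ! {ont.label(p)}")
        lines.append("")
    _write_lines(dest, lines)


def _write_lines(dest, lines: list[str]) -> None:
    payload = "\n".join(lines).rstrip("\n") + "\n"
    if hasattr(dest, "write"):
        dest.write(payload)
    else:
        pathlib.Path(dest).write_text(payload, encoding="utf-8")


# ---------------------------------------------------------------------------
# Phenotype files (terms with EQ logical definitions)

def _eq_from_intersections(
    tid: TermId, intersections: Sequence[tuple[Optional[str], str]]
) -> EQDefinition:
    quality = bearer = towards = occurs_in = None
    bearer_mode = None
    modifier = None
    for rel_name, filler in intersections:
        if rel_name is None:
            if quality is not None:
                raise TemplateError(f"{tid}: more than one primary quality in intersection_of")
            quality = TermId.parse(filler)
            continue
        try:
            rel = Relation(rel_name)
        except ValueError:
            raise TemplateError(f"{tid}: unknown intersection_of relation {rel_name!r}") from None
        if rel in (Relation.characteristic_of, Relation.characteristic_of_part_of):
            bearer, bearer_mode = TermId.parse(filler), rel
        elif rel is Relation.towards:
            towards = TermId.parse(filler)
        elif rel is Relation.occurs_in:
            occurs_in = TermId.parse(filler)
        elif rel is Relation.has_modifier:
            modifier = filler
        else:
            raise TemplateError(f"{tid}: relation {rel.value} not allowed in an EQ block")
    if quality is None or bearer is None:
        raise TemplateError(f"{tid}: EQ block must declare a quality and a bearer")
    if modifier is None:
        raise TemplateError(f"{tid}: EQ block lacks has_modifier")
    return EQDefinition(quality, bearer, bearer_mode, towards, occurs_in, modifier)


def load_phenotype_obo(path: Union[str, pathlib.Path]) -> list[PhenotypeClass]:
    """Load phenotype classes (with EQ blocks) from an OBO-subset file."""
    text = pathlib.Path(path).read_text(encoding="utf-8")
    out: list[PhenotypeClass] = []
    for stanza in _parse_stanzas(text):
        tid, name, _, _, _, _, intersections, obsolete = _parse_term(stanza)
        if obsolete:
            continue
        eq = _eq_from_intersections(tid, intersections) if intersections else None
        out.append(PhenotypeClass(tid, name or tid.curie, eq))
    return out


def write_phenotype_obo(
    classes: Iterable[PhenotypeClass],
    dest: Union[str, pathlib.Path, TextIO],
    labels: Optional[dict[TermId, str]] = None,
) -> None:
    """Canonical phenotype-file form; ``labels`` resolves filler comments."""

    def comment(t: TermId) -> str:
        if labels and t in labels:
            return f" ! {labels[t]}"
        return ""

    lines = ["format-version: 1.2", ""]
    for cls in sorted(classes, key=lambda c: c.id):
        lines.append("[Term]")
        lines.append(f"id: {cls.id.curie}")
        lines.append(f"name: {cls.label}")
        if cls.eq is not None:
            eq = cls.eq
            lines.append(f"intersection_of: {eq.quality.curie}{comment(eq.quality)}")
            lines.append(
                f"intersection_of: {eq.bearer_mode.value} {eq.bearer.curie}{comment(eq.bearer)}"
            )
            if eq.towards is not None:
                lines.append(f"intersection_of: towards {eq.towards.curie}{comment(eq.towards)}")
            if eq.occurs_in is not None:
                lines.append(
                    f"intersection_of: occurs_in {eq.occurs_in.curie}{comment(eq.occurs_in)}"
                )
            lines.append(f"intersection_of: has_modifier {eq.modifier}")
        lines.append("")
    _write_lines(dest, lines)


def write_edges_tsv(edges: Iterable[tuple[TermId, TermId]], dest) -> None:
    """(child, parent) inferred-subsumption edge list as two-column TSV."""
    lines = ["child\tparent"]
    for child, parent in edges:
        lines.append(f"{child.curie}\t{parent.curie}")
    _write_lines(dest, lines)
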