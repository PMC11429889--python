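"""Cross-species phenotype mappings and SSSOM TSV serialization.

Two matchers are provided.  The *logical* matcher compares normalized EQ
definitions: identical definitions across namespaces assert identical
phenotypic characteristics of the same (homologous, pre-aligned) structure
and get ``semapv:crossSpeciesExactMatch``; definitions that subsume each
other without being identical get ``skos:exactMatch``.  The *lexical*
matcher joins on normalized labels and synonyms.  Both justifications are
recorded per SSSOM conventions and neither suppresses the other.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pathlib

import yaml

from .errors import SerializationError, TermNotFoundError, UsageError
from .model import SynonymScope, TermId
from .reasoner import ClassifiedOntology, PhenotypeClass, SupportSet, subsumes

__all__ = [
    "MappingPredicate",
    "MappingJustification",
    "Mapping",
    "SSSOMDocument",
    "logical_match",
    "lexical_match",
    "species_neutral_links",
    "write_sssom",
    "read_sssom",
]

TOOL_NAME = "pheno-forge"

#: default curie map for SSSOM headers; term prefixes are added as needed
BASE_CURIE_MAP = {
    "semapv": "https://w3id.org/semapv/vocab/",
    "skos": "http://www.w3.org/2004/02/skos/core#",
}

_PREFIX_IRI = "https://example.org/phenoforge/"


class MappingPredicate(enum.Enum):
    crossSpeciesExactMatch = "semapv:crossSpeciesExactMatch"
    exactMatch = "skos:exactMatch"
    closeMatch = "skos:closeMatch"


class MappingJustification(enum.Enum):
    LogicalMatching = "semapv:LogicalMatching"
    LexicalMatching = "semapv:LexicalMatching"
    ManualMappingCuration = "semapv:ManualMappingCuration"


@dataclass(frozen=True)
class Mapping:
    subject_id: TermId
    object_id: TermId
    subject_label: str
    object_label: str
    predicate: MappingPredicate
    justification: MappingJustification
    confidence: float = 1.0
    tool: str = TOOL_NAME

    @property
    def sort_key(self):
        return (self.subject_id, self.object_id, self.predicate.value, self.justification.value)

    def __post_init__(self) -> None:
        if self.subject_id.prefix == self.object_id.prefix:
            raise UsageError(
                f"mapping within one namespace: {self.subject_id} -> {self.object_id}"
            )
        if self.predicate is MappingPredicate.crossSpeciesExactMatch and (
            self.justification is MappingJustification.LexicalMatching
        ):
            raise UsageError(
                "crossSpeciesExactMatch requires logical matching or manual curation"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise UsageError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class SSSOMDocument:
    """A mapping set: YAML metadata header plus sorted mapping rows."""

    mappings: list[Mapping]
    mapping_set_id: str = _PREFIX_IRI + "mappings/default"
    license: str = "https://creativecommons.org/publicdomain/zero/1.0/"
    mapping_date: str = "2025-01-01"
    curie_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mappings = sorted(self.mappings, key=lambda m: m.sort_key)
        cmap = dict(BASE_CURIE_MAP)
        cmap.update(self.curie_map)
        for m in self.mappings:
            for prefix in (m.subject_id.prefix, m.object_id.prefix):
                cmap.setdefault(prefix, f"{_PREFIX_IRI}{prefix}_")
        self.curie_map = cmap

    def validate(self) -> None:
        for m in self.mappings:
            for prefix in (m.subject_id.prefix, m.object_id.prefix):
                if prefix not in self.curie_map:
                    raise SerializationError(f"prefix {prefix!r} missing from curie_map")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SSSOMDocument):
            return NotImplemented
        return (
            self.mappings == other.mappings
            and self.mapping_set_id == other.mapping_set_id
            and self.license == other.license
            and self.mapping_date == other.mapping_date
            and self.curie_map == other.curie_map
        )


def logical_match(
    a: Sequence[PhenotypeClass],
    b: Sequence[PhenotypeClass],
    supports: SupportSet,
) -> list[Mapping]:
    """Match by logical definition.

    Identical EQs -> crossSpeciesExactMatch (confidence 1.0); mutual
    subsumption without identity -> exactMatch.  Same-namespace pairs and
    classes without definitions are skipped.  Output is sorted, hence
    deterministic and symmetric up to the subject/object swap.
    """
    out: list[Mapping] = []
    for ca in a:
        if ca.eq is None:
            continue
        for cb in b:
            if cb.eq is None or ca.namespace == cb.namespace:
                continue
            if ca.eq == cb.eq:
                pred = MappingPredicate.crossSpeciesExactMatch
            elif subsumes(ca.eq, cb.eq, supports) and subsumes(cb.eq, ca.eq, supports):
                pred = MappingPredicate.exactMatch
            else:
                continue
            out.append(
                Mapping(
                    subject_id=ca.id,
                    object_id=cb.id,
                    subject_label=ca.label,
                    object_label=cb.label,
                    predicate=pred,
                    justification=MappingJustification.LogicalMatching,
                    confidence=1.0,
                )
            )
    return sorted(out, key=lambda m: m.sort_key)


_PUNCT = re.compile(r"[^\w\s]", flags=re.UNICODE)


def normalize_label(text: str) -> str:
    """Casefold, strip punctuation, collapse whitespace."""
    text = unicodedata.normalize("NFKC", text).casefold()
    text = _PUNCT.sub(" ", text)
    return " ".join(text.split())


def lexical_match(
    a: Sequence[PhenotypeClass],
    b: Sequence[PhenotypeClass],
    synonym_scopes: Iterable[SynonymScope] = (SynonymScope.exact,),
    synonyms: Optional[dict[TermId, Sequence[tuple[str, SynonymScope]]]] = None,
) -> list[Mapping]:
    """Match by normalized label/synonym string equality.

    Label-label agreement scores 0.9; anything involving a synonym 0.8.
    ``synonyms`` supplies per-term synonym lists (phenotype classes carry
    only labels).
    """
    scopes = set(synonym_scopes)
    synonyms = synonyms or {}

    def keys(cls: PhenotypeClass) -> list[tuple[str, bool]]:
        out = [(normalize_label(cls.label), False)]
        for text, scope in synonyms.get(cls.id, ()):
            if scope in scopes:
                out.append((normalize_label(text), True))
        return out

    index: dict[str, list[tuple[PhenotypeClass, bool]]] = {}
    for cb in b:
        for key, from_syn in keys(cb):
            index.setdefault(key, []).append((cb, from_syn))

    out: list[Mapping] = []
    seen: set[tuple[TermId, TermId]] = set()
    for ca in a:
        for key, a_syn in keys(ca):
            for cb, b_syn in index.get(key, ()):
                if ca.namespace == cb.namespace or (ca.id, cb.id) in seen:
                    continue
                seen.add((ca.id, cb.id))
                out.append(
                    Mapping(
                        subject_id=ca.id,
                        object_id=cb.id,
                        subject_label=ca.label,
                        object_label=cb.label,
                        predicate=MappingPredicate.exactMatch,
                        justification=MappingJustification.LexicalMatching,
                        confidence=0.8 if (a_syn or b_syn) else 0.9,
                    )
                )
    return sorted(out, key=lambda m: m.sort_key)


def species_neutral_links(
    species: Sequence[PhenotypeClass],
    unified: ClassifiedOntology,
    neutral_prefix: str = "PHF",
) -> tuple[list[Mapping], list[PhenotypeClass]]:
    """Link each species class to its nearest species-neutral ancestor(s).

    Equivalent (same inferred group) -> exactMatch; otherwise the
    species-neutral classes at minimal upward distance in the inferred
    hierarchy -> closeMatch.  Species classes with no species-neutral
    ancestor are returned in the orphans list.
    """
    mappings: list[Mapping] = []
    orphans: list[PhenotypeClass] = []
    for cls in species:
        if cls.id not in unified:
            raise TermNotFoundError(f"species class {cls.id} not in the unified ontology")
        neutral_eq = [
            t for t in unified.equivalents(cls.id)
            if t.prefix == neutral_prefix and t != cls.id
        ]
        if neutral_eq:
            targets = [(t, MappingPredicate.exactMatch, 1.0) for t in neutral_eq]
        else:
            targets = []
            frontier = {unified.canonical[cls.id]}
            visited = set(frontier)
            while frontier and not targets:
                nxt: set[TermId] = set()
                for rep in frontier:
                    for parent in unified._parents.get(rep, ()):
                        if parent in visited:
                            continue
                        visited.add(parent)
                        nxt.add(parent)
                        hits = [t for t in unified.groups[parent] if t.prefix == neutral_prefix]
                        targets.extend((t, MappingPredicate.closeMatch, 0.9) for t in hits)
                frontier = nxt
        if not targets:
            orphans.append(cls)
            continue
        for target, pred, conf in sorted(targets, key=lambda x: (x[0], x[1].value)):
            mappings.append(
                Mapping(
                    subject_id=cls.id,
                    object_id=target,
                    subject_label=cls.label,
                    object_label=unified.label(target),
                    predicate=pred,
                    justification=MappingJustification.LogicalMatching,
                    confidence=conf,
                )
            )
    return sorted(mappings, key=lambda m: m.sort_key), orphans


# ---------------------------------------------------------------------------
# SSSOM TSV

_COLUMNS = (
    "subject_id",
    "subject_label",
    "predicate_id",
    "object_id",
    "object_label",
    "mapping_justification",
    "confidence",
    "mapping_tool",
)


def write_sssom(doc: SSSOMDocument, dest: Union[str, pathlib.Path]) -> None:
    """SSSOM TSV: '# '-prefixed YAML metadata block, then the mapping rows."""
    doc.validate()
    header = {
        "mapping_set_id": doc.mapping_set_id,
        "license": doc.license,
        "mapping_date": doc.mapping_date,
        "curie_map": dict(sorted(doc.curie_map.items())),
    }
    meta = yaml.safe_dump(header, sort_keys=False, allow_unicode=True).rstrip("\n")
    lines = [f"# {ln}" if ln else "#" for ln in meta.splitlines()]
    lines.append("\t".join(_COLUMNS))
    for m in doc.mappings:
        lines.append(
            "\t".join(
                (
                    m.subject_id.curie,
                    m.subject_label,
                    m.predicate.value,
                    m.object_id.curie,
                    m.object_label,
                    m.justification.value,
                    repr(m.confidence),
                    m.tool,
                )
            )
        )
    pathlib.Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sssom(path: Union[str, pathlib.Path]) -> SSSOMDocument:
    text = pathlib.Path(path).read_text(encoding="utf-8")
    meta_lines: list[str] = []
    rows: list[str] = []
    for ln in text.splitlines():
        if ln.startswith("#"):
            meta_lines.append(ln[2:] if ln.startswith("# ") else ln[1:])
        elif ln.strip():
            rows.append(ln)
    meta = yaml.safe_load("\n".join(meta_lines)) or {}
    if not rows:
        raise SerializationError("SSSOM file has no column header")
    header = tuple(rows[0].split("\t"))
    if header != _COLUMNS:
        raise SerializationError(f"unexpected SSSOM columns: {header}")
    by_value_pred = {p.value: p for p in MappingPredicate}
    by_value_just = {j.value: j for j in MappingJustification}
    mappings = []
    for row in rows[1:]:
        cells = row.split("\t")
        if len(cells) != len(_COLUMNS):
            raise SerializationError(f"SSSOM row has {len(cells)} cells: {row!r}")
        rec = dict(zip(_COLUMNS, cells))
        mappings.append(
            Mapping(
                subject_id=TermId.parse(rec["subject_id"]),
                object_id=TermId.parse(rec["object_id"]),
                subject_label=rec["subject_label"],
                object_label=rec["object_label"],
                predicate=by_value_pred[rec["predicate_id"]],
                justification=by_value_just[rec["mapping_justification"]],
                confidence=float(rec["confidence"]),
                tool=rec["mapping_tool"],
            )
        )
    return SSSOMDocument(
        mappings=mappings,
        mapping_set_id=meta.get("mapping_set_id", ""),
        license=meta.get("license", ""),
        mapping_date=str(meta.get("mapping_date", "")),
        curie_map=meta.get("curie_map", {}),
    )
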