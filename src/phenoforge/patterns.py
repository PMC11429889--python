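"""DOSDP-style phenotype pattern templates and their instantiation.

A pattern template is a YAML document that fixes the logical shape of a
family of phenotype classes (the ``equivalentTo`` axiom template) together
with label and text-definition templates whose ``%s`` slots are filled from
variable bindings.  Filler tables (TSV, one column per variable) supply the
bindings; compiling a table yields one generated phenotype class per
distinct row, each with a deterministic content-addressed id.

The axiom template dialect is a Manchester-syntax-like conjunction::

    'has_part' some ('increased size'
        and ('characteristic_of_part_of' some %s)
        and ('has_modifier' some abnormal))

Quoted names resolve through the template's ``classes``/``relations`` maps;
``%s`` slots are bound positionally via the declared var order.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import yaml

from .errors import RangeError, ReferentialError, TemplateError
from .model import Relation, SupportSet, TermId, is_subclass_or_part
from .reasoner import BEARER_MODES, EQDefinition

__all__ = [
    "VarSlot",
    "EQSkeleton",
    "TextTemplate",
    "PatternTemplate",
    "FillerTable",
    "GeneratedClass",
    "parse_pattern",
    "serialize_pattern",
    "hash_minter",
    "instantiate",
    "compile_table",
    "precompose",
]

#: default prefix for minted (generated species-neutral) class ids
GENERATED_PREFIX = "PHF"


@dataclass(frozen=True)
class VarSlot:
    """A yet-unbound variable inside an axiom skeleton."""

    name: str


Filler = "TermId | VarSlot"


@dataclass(frozen=True)
class EQSkeleton:
    """An EQ definition whose slots may still be variables."""

    quality: TermId | VarSlot
    bearer: TermId | VarSlot
    bearer_mode: Relation
    towards: Optional[TermId | VarSlot] = None
    occurs_in: Optional[TermId | VarSlot] = None
    modifier: str = "abnormal"

    def substitute(self, bindings: Mapping[str, TermId]) -> EQDefinition:
        def sub(x):
            if isinstance(x, VarSlot):
                return bindings[x.name]
            return x

        return EQDefinition(
            quality=sub(self.quality),
            bearer=sub(self.bearer),
            bearer_mode=self.bearer_mode,
            towards=sub(self.towards) if self.towards is not None else None,
            occurs_in=sub(self.occurs_in) if self.occurs_in is not None else None,
            modifier=self.modifier,
        )

    def variables(self) -> set[str]:
        out = set()
        for x in (self.quality, self.bearer, self.towards, self.occurs_in):
            if isinstance(x, VarSlot):
                out.add(x.name)
        return out


@dataclass(frozen=True)
class TextTemplate:
    """A printf-style text template with a declared variable order."""

    text: str
    vars: tuple[str, ...]

    def fill(self, values: Sequence[str]) -> str:
        if self.text.count("%s") != len(values):
            raise TemplateError(
                f"template {self.text!r} expects {self.text.count('%s')} slots,"
                f" got {len(values)} values"
            )
        out = self.text
        for v in values:
            out = out.replace("%s", v, 1)
        return out


@dataclass(frozen=True)
class PatternTemplate:
    pattern_name: str
    pattern_iri: str
    description: str
    contributors: tuple[str, ...]
    classes: tuple[tuple[str, TermId], ...]  # display name -> term
    relations: tuple[tuple[str, Relation], ...]
    vars: tuple[tuple[str, TermId], ...]  # var name -> range class
    name_template: TextTemplate
    def_template: TextTemplate
    equivalent_to_text: str
    skeleton: EQSkeleton
    extra: tuple[tuple[str, str], ...] = ()  # unknown top-level keys, opaque

    @property
    def var_ranges(self) -> dict[str, TermId]:
        return dict(self.vars)

    @property
    def class_map(self) -> dict[str, TermId]:
        return dict(self.classes)


@dataclass(frozen=True)
class FillerTable:
    pattern_name: str
    rows: tuple[tuple[tuple[str, TermId], ...], ...]  # each row: var -> term

    @classmethod
    def from_rows(cls, pattern_name: str, rows: Sequence[Mapping[str, TermId]]) -> "FillerTable":
        return cls(pattern_name, tuple(tuple(sorted(r.items())) for r in rows))

    @classmethod
    def read_tsv(cls, path, pattern_name: Optional[str] = None) -> "FillerTable":
        """Header row = var names; cells = CURIEs; pattern name defaults to the file stem."""
        import pathlib

        p = pathlib.Path(path)
        lines = [ln for ln in p.read_text(encoding="utf-8").splitlines() if ln.strip()]
        if not lines:
            return cls(pattern_name or p.stem, ())
        header = lines[0].split("\t")
        rows = []
        for ln in lines[1:]:
            cells = ln.split("\t")
            if len(cells) != len(header):
                raise TemplateError(f"filler row has {len(cells)} cells, header has {len(header)}")
            rows.append({h: TermId.parse(c) for h, c in zip(header, cells)})
        return cls.from_rows(pattern_name or p.stem, rows)

    def write_tsv(self, path, var_order: Sequence[str]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(var_order) + "\n")
            for row in self.rows:
                d = dict(row)
                fh.write("\t".join(d[v].curie for v in var_order) + "\n")


@dataclass(frozen=True)
class GeneratedClass:
    """A phenotype class produced by template instantiation.

    Fully re-derivable from its provenance: the id is a content hash of
    ``(pattern_iri, sorted bindings)``, and label/definition/EQ follow from
    the template alone.
    """

    id: TermId
    label: str
    definition: str
    eq: EQDefinition
    pattern_iri: str
    bindings: tuple[tuple[str, TermId], ...]


# ---------------------------------------------------------------------------
# YAML parsing

_REQUIRED_KEYS = ("pattern_name", "pattern_iri", "vars", "name", "equivalentTo")
_KNOWN_KEYS = {
    "pattern_name",
    "pattern_iri",
    "description",
    "contributors",
    "classes",
    "relations",
    "vars",
    "name",
    "def",
    "equivalentTo",
}

_QUOTED = re.compile(r"'([^']*)'")


def _norm_rel(name: str) -> Optional[Relation]:
    key = name.strip().strip("'").replace(" ", "_")
    try:
        return Relation(key)
    except ValueError:
        return None


def _resolve_name(
    token: str,
    class_map: Mapping[str, TermId],
) -> TermId:
    token = token.strip()
    m = _QUOTED.fullmatch(token)
    name = m.group(1) if m else token
    if name in class_map:
        return class_map[name]
    try:
        return TermId.parse(name)
    except ValueError:
        raise TemplateError(f"name {name!r} is neither a declared class nor a CURIE") from None


def _split_top_level_and(text: str) -> list[str]:
    parts, depth, cur = [], 0, []
    tokens = re.split(r"(\(|\)|\s+and\s+)", text)
    for tok in tokens:
        if tok == "(":
            depth += 1
            cur.append(tok)
        elif tok == ")":
            depth -= 1
            cur.append(tok)
        elif tok.strip() == "and" and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(tok)
    parts.append("".join(cur))
    return [p.strip() for p in parts if p.strip()]


def _strip_outer_parens(s: str) -> str:
    s = s.strip()
    while s.startswith("(") and s.endswith(")"):
        depth = 0
        ok = True
        for i, c in enumerate(s):
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth == 0 and i != len(s) - 1:
                    ok = False
                    break
        if not ok:
            break
        s = s[1:-1].strip()
    return s


def _parse_skeleton(
    text: str,
    var_order: Sequence[str],
    class_map: Mapping[str, TermId],
    relation_names: Mapping[str, Relation],
) -> EQSkeleton:
    """Parse the equivalentTo axiom text into an EQ skeleton."""
    work = text
    slots: list[VarSlot] = []
    idx = 0
    while "%s" in work:
        if idx >= len(var_order):
            raise TemplateError("more %s slots in equivalentTo than declared vars")
        token = f"?v{idx}?"
        work = work.replace("%s", token, 1)
        slots.append(VarSlot(var_order[idx]))
        idx += 1

    def resolve_filler(tok: str):
        tok = tok.strip()
        m = re.fullmatch(r"\?v(\d+)\?", tok)
        if m:
            return slots[int(m.group(1))]
        return _resolve_name(tok, class_map)

    def resolve_rel(tok: str) -> Relation:
        key = tok.strip().strip("'")
        if key in relation_names:
            return relation_names[key]
        rel = _norm_rel(key)
        if rel is None:
            raise TemplateError(f"unknown relation {tok!r} in equivalentTo")
        return rel

    outer = re.match(r"\s*('[^']+'|\S+)\s+some\s+(.*)$", work, flags=re.S)
    if not outer:
        raise TemplateError("equivalentTo must have the shape '<rel> some (<conjunction>)'")
    if resolve_rel(outer.group(1)) is not Relation.has_part:
        raise TemplateError("equivalentTo must be wrapped in 'has_part some (...)'")
    body = _strip_outer_parens(outer.group(2))

    quality = bearer = None
    bearer_mode: Optional[Relation] = None
    towards = occurs_in = None
    modifier_seen = False
    for conj in _split_top_level_and(body):
        conj = _strip_outer_parens(conj)
        m = re.match(r"('[^']+'|\S+)\s+some\s+(.*)$", conj, flags=re.S)
        if not m:
            if quality is not None:
                raise TemplateError("equivalentTo declares more than one primary quality")
            quality = resolve_filler(conj)
            continue
        rel = resolve_rel(m.group(1))
        filler = _strip_outer_parens(m.group(2))
        if rel in BEARER_MODES:
            if bearer is not None:
                raise TemplateError("equivalentTo declares more than one bearer")
            bearer, bearer_mode = resolve_filler(filler), rel
        elif rel is Relation.towards:
            towards = resolve_filler(filler)
        elif rel is Relation.occurs_in:
            occurs_in = resolve_filler(filler)
        elif rel is Relation.has_modifier:
            modifier_seen = True  # only 'abnormal' exists in this version
        else:
            raise TemplateError(f"relation {rel.value} not allowed inside an EQ conjunction")
    if quality is None:
        raise TemplateError("equivalentTo lacks a primary quality conjunct")
    if bearer is None or bearer_mode is None:
        raise TemplateError("equivalentTo lacks a characteristic_of[_part_of] bearer conjunct")
    if not modifier_seen:
        raise TemplateError("equivalentTo lacks the has_modifier some abnormal conjunct")
    return EQSkeleton(quality, bearer, bearer_mode, towards, occurs_in, "abnormal")


def _text_template(node, key: str) -> TextTemplate:
    if not isinstance(node, dict) or "text" not in node:
        raise TemplateError(f"field {key!r} must be a mapping with 'text' (and 'vars')")
    return TextTemplate(str(node["text"]), tuple(node.get("vars", ())))


def parse_pattern(text: str, supports: Optional[SupportSet] = None) -> PatternTemplate:
    """Parse a YAML pattern document.

    When ``supports`` is given, var range classes are checked for existence
    (referential validation); otherwise ranges are taken on faith.
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise TemplateError("pattern document must be a YAML mapping")
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise TemplateError(f"pattern is missing required field {key!r}")

    class_map = {
        str(k): TermId.parse(str(v)) for k, v in (doc.get("classes") or {}).items()
    }
    relation_names: dict[str, Relation] = {}
    for k in (doc.get("relations") or {}):
        rel = _norm_rel(str(k))
        if rel is None:
            raise TemplateError(f"relation name {k!r} is not a recognized EQ relation")
        relation_names[str(k)] = rel

    var_ranges: dict[str, TermId] = {}
    for vname, vrange in (doc.get("vars") or {}).items():
        var_ranges[str(vname)] = _resolve_name(str(vrange), class_map)
    if supports is not None:
        for vname, rng in var_ranges.items():
            if rng not in supports:
                raise ReferentialError(f"range {rng} of var {vname!r} is not a known term")

    name_tpl = _text_template(doc["name"], "name")
    def_tpl = _text_template(doc.get("def", {"text": "", "vars": []}), "def")

    eq_node = doc["equivalentTo"]
    eq_text = str(eq_node["text"]) if isinstance(eq_node, dict) else str(eq_node)
    eq_vars = tuple(eq_node.get("vars", ())) if isinstance(eq_node, dict) else ()
    skeleton = _parse_skeleton(eq_text, eq_vars, class_map, relation_names)

    for tpl_vars in (name_tpl.vars, def_tpl.vars, eq_vars):
        for v in tpl_vars:
            if v not in var_ranges:
                raise TemplateError(f"var {v!r} used in a template but not declared in vars")

    extra = tuple(
        sorted((str(k), yaml.safe_dump(v, default_flow_style=True).strip())
               for k, v in doc.items() if k not in _KNOWN_KEYS)
    )
    return PatternTemplate(
        pattern_name=str(doc["pattern_name"]),
        pattern_iri=str(doc["pattern_iri"]),
        description=str(doc.get("description", "")),
        contributors=tuple(doc.get("contributors") or ()),
        classes=tuple(sorted(class_map.items())),
        relations=tuple(sorted(relation_names.items(), key=lambda kv: kv[0])),
        vars=tuple(sorted(var_ranges.items())),
        name_template=name_tpl,
        def_template=def_tpl,
        equivalent_to_text=eq_text,
        skeleton=skeleton,
        extra=extra,
    )


def serialize_pattern(tpl: PatternTemplate) -> str:
    """Emit the canonical YAML form; ``parse_pattern`` inverts it."""
    doc: dict = {
        "pattern_name": tpl.pattern_name,
        "pattern_iri": tpl.pattern_iri,
        "description": tpl.description,
        "contributors": list(tpl.contributors),
        "classes": {k: v.curie for k, v in tpl.classes},
        "relations": {k: r.value for k, r in tpl.relations},
        "vars": {k: v.curie for k, v in tpl.vars},
        "name": {"text": tpl.name_template.text, "vars": list(tpl.name_template.vars)},
        "def": {"text": tpl.def_template.text, "vars": list(tpl.def_template.vars)},
        "equivalentTo": {
            "text": tpl.equivalent_to_text,
            "vars": list(v for v in dict(tpl.vars) if VarSlot(v) in _skeleton_slots(tpl)),
        },
    }
    # recover declared eq var order from the skeleton slot order in the text
    doc["equivalentTo"]["vars"] = _eq_var_order(tpl)
    for k, v in tpl.extra:
        doc[k] = yaml.safe_load(v)
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def _skeleton_slots(tpl: PatternTemplate) -> set[VarSlot]:
    return {VarSlot(v) for v in tpl.skeleton.variables()}


def _eq_var_order(tpl: PatternTemplate) -> list[str]:
    order = []
    for x in (tpl.skeleton.quality, tpl.skeleton.bearer, tpl.skeleton.towards, tpl.skeleton.occurs_in):
        if isinstance(x, VarSlot) and x.name not in order:
            order.append(x.name)
    return order


# ---------------------------------------------------------------------------
# Instantiation

def hash_minter(prefix: str = GENERATED_PREFIX, digits: int = 7) -> Callable:
    """Content-addressed id minting.

    The numeric id is the SHA-256 of ``pattern_iri`` plus the sorted
    bindings, reduced into the ``10**digits`` space — so a generated class
    is fully determined by (pattern, bindings) and batch composition never
    changes ids.
    """

    def mint(pattern_iri: str, bindings: tuple[tuple[str, TermId], ...]) -> TermId:
        payload = pattern_iri + "|" + ";".join(f"{k}={v.curie}" for k, v in sorted(bindings))
        h = hashlib.sha256(payload.encode("utf-8")).hexdigest()
        num = int(h, 16) % (10 ** digits)
        return TermId(prefix, str(num).zfill(digits))

    return mint


def instantiate(
    tpl: PatternTemplate,
    row: Mapping[str, TermId],
    supports: SupportSet,
    id_minter: Optional[Callable] = None,
) -> GeneratedClass:
    """Fill one binding row into a template.

    Range checking is strict ``is_a``: each bound term must be a subclass of
    its variable's range.  Labels and definitions substitute the bound
    terms' labels into the text templates in declared var order.
    """
    mint = id_minter or hash_minter()
    ranges = tpl.var_ranges
    missing = set(ranges) - set(row)
    if missing:
        raise TemplateError(f"row lacks bindings for vars: {sorted(missing)}")
    for var, term in row.items():
        if var not in ranges:
            raise TemplateError(f"row binds undeclared var {var!r}")
        rng = ranges[var]
        if not is_subclass_or_part(supports, term, rng, use_part_of=False):
            raise RangeError(
                f"var {var!r}: term {term} ({supports.label(term)!r}) is outside"
                f" range {rng} ({supports.label(rng)!r})"
            )
    bindings = tuple(sorted(row.items()))
    label = tpl.name_template.fill([supports.label(row[v]) for v in tpl.name_template.vars])
    definition = tpl.def_template.fill([supports.label(row[v]) for v in tpl.def_template.vars])
    eq = tpl.skeleton.substitute(row)
    return GeneratedClass(
        id=mint(tpl.pattern_iri, bindings),
        label=label,
        definition=definition,
        eq=eq,
        pattern_iri=tpl.pattern_iri,
        bindings=bindings,
    )


def compile_table(
    tpl: PatternTemplate,
    tbl: FillerTable,
    supports: SupportSet,
    id_minter: Optional[Callable] = None,
) -> list[GeneratedClass]:
    """One generated class per distinct row, sorted by minted id."""
    if tbl.pattern_name != tpl.pattern_name:
        raise TemplateError(
            f"filler table is for {tbl.pattern_name!r}, template is {tpl.pattern_name!r}"
        )
    out: dict[tuple, GeneratedClass] = {}
    for i, row in enumerate(tbl.rows):
        if row in out:
            continue
        try:
            out[row] = instantiate(tpl, dict(row), supports, id_minter)
        except Exception as exc:
            raise type(exc)(f"row {i}: {exc}") from exc
    return sorted(out.values(), key=lambda g: g.id)


def precompose(
    rows: Sequence[tuple[TermId, TermId]],
    tpls: Sequence[PatternTemplate],
    supports: SupportSet,
    id_minter: Optional[Callable] = None,
) -> tuple[list[GeneratedClass], list[tuple[tuple[TermId, TermId], str]]]:
    """Convert post-composed (entity, quality) annotation rows into classes.

    Each row is matched to the most specific single-variable template whose
    var range admits the entity (is_a) and whose fixed quality subsumes the
    row's quality (is_a).  Specificity is quality depth in the quality
    hierarchy; ties break on pattern name.  Unmatched rows come back in a
    rejection list with a reason — they are data, not errors.
    """
    candidates = []
    for tpl in tpls:
        ranges = tpl.var_ranges
        if len(ranges) != 1 or isinstance(tpl.skeleton.quality, VarSlot):
            continue  # only single-var fixed-quality templates can absorb an E-Q pair
        (var, rng), = ranges.items()
        candidates.append((tpl, var, rng, tpl.skeleton.quality))

    accepted: list[GeneratedClass] = []
    rejected: list[tuple[tuple[TermId, TermId], str]] = []
    for entity, quality in rows:
        best = None
        for tpl, var, rng, tpl_quality in candidates:
            if entity not in supports or rng not in supports:
                continue
            if not is_subclass_or_part(supports, entity, rng, use_part_of=False):
                continue
            if not is_subclass_or_part(supports, quality, tpl_quality, use_part_of=False):
                continue
            key = (-supports.depth(tpl_quality), tpl.pattern_name)
            if best is None or key < best[0]:
                best = (key, tpl, var)
        if best is None:
            rejected.append(
                ((entity, quality), "no template admits this entity/quality combination")
            )
        else:
            _, tpl, var = best
            accepted.append(instantiate(tpl, {var: entity}, supports, id_minter))
    return accepted, rejected
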