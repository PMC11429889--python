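"""Semantic similarity over a classified phenotype hierarchy.

Three layers:

* **Jaccard** — overlap of reflexive ``is_a`` ancestor sets; sibling terms
  share most of their ancestry and score close to 1, terms related only
  through the root score near 0.
* **Information content (IC)** — ``-log2 p(t)`` where ``p(t)`` is the
  fraction of annotated profiles hitting ``t`` or any descendant (corpus
  strategy), or a topology-based fallback using descendant counts.  IC is
  monotone non-decreasing from root to leaves.
* **PhenoDigm-style score** — ``sqrt(jaccard * IC(MICA))``, the geometric
  mean of positional similarity and the informativeness of the most
  informative common ancestor; profile-level comparison uses best-match
  max/avg with optional self-normalization to a 0–100 scale.

Similarity reads only the ``is_a`` edges of the classified hierarchy;
parthood influences similarity indirectly, through classification.
"""

from __future__ import annotations

import enum
import math
import pathlib
from dataclasses import dataclass
from statistics import mean
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import TermNotFoundError, UsageError
from .model import TermId
from .reasoner import ClassifiedOntology

__all__ = [
    "ICStrategy",
    "ICTable",
    "Profile",
    "SimilarityResult",
    "jaccard",
    "information_content",
    "phenodigm",
    "profile_similarity",
    "write_similarity_table",
]


class ICStrategy(enum.Enum):
    corpus = "corpus"
    topology = "topology"


@dataclass(frozen=True)
class ICTable:
    """Per-term information content in bits."""

    ic: Mapping[TermId, float]
    corpus_size: int

    def __getitem__(self, term: TermId) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise TermNotFoundError(f"no information content for {term}") from None


@dataclass(frozen=True)
class Profile:
    """An annotated entity (gene, genotype, disease) and its phenotype terms."""

    entity_id: str
    terms: frozenset[TermId]

    def __post_init__(self) -> None:
        if not self.terms:
            raise UsageError(f"profile {self.entity_id!r} has no terms")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, TermId]]) -> list["Profile"]:
        by_entity: dict[str, set[TermId]] = {}
        for entity, term in pairs:
            by_entity.setdefault(entity, set()).add(term)
        return [cls(e, frozenset(ts)) for e, ts in sorted(by_entity.items())]

    @classmethod
    def read_tsv(cls, path: Union[str, pathlib.Path]) -> list["Profile"]:
        """TSV with columns entity_id, term_id; one row per annotation."""
        pairs = []
        for ln in pathlib.Path(path).read_text(encoding="utf-8").splitlines():
            if not ln.strip() or ln.startswith("entity_id"):
                continue
            entity, term = ln.split("\t")[:2]
            pairs.append((entity, TermId.parse(term)))
        return cls.from_pairs(pairs)


@dataclass(frozen=True)
class SimilarityResult:
    a: TermId
    b: TermId
    jaccard: float
    ic_mica: float
    mica: Optional[TermId]
    phenodigm: float


def jaccard(ont: ClassifiedOntology, a: TermId, b: TermId) -> float:
    """|A ∩ B| / |A ∪ B| over reflexive is_a ancestor sets."""
    sa = ont.ancestors(a)
    sb = ont.ancestors(b)
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


def information_content(
    ont: ClassifiedOntology,
    corpus: Optional[Sequence[Profile]] = None,
    strategy: ICStrategy = ICStrategy.corpus,
) -> ICTable:
    """Annotation-frequency (or topology) information content, in bits.

    Corpus strategy: annotations propagate to all ancestors, so a term's
    frequency counts every profile annotated to it *or any descendant*;
    terms never hit get the add-one value ``log2(corpus_size + 1)``.
    Topology strategy: ``p(t) = (|descendants(t)| + 1) / |ont|`` with
    exclusive descendant counts — no corpus needed.
    """
    ic: dict[TermId, float] = {}
    if strategy is ICStrategy.corpus:
        if not corpus:
            raise UsageError("corpus IC strategy requires a nonempty corpus")
        n = len(corpus)
        counts: dict[TermId, int] = {t: 0 for t in ont.classes}
        for profile in corpus:
            hit: set[TermId] = set()
            for term in profile.terms:
                hit |= ont.ancestors(term)
            for t in hit:
                counts[t] += 1
        unseen = math.log2(n + 1)
        for t, c in counts.items():
            ic[t] = -math.log2(c / n) if c else unseen
    else:
        total = len(ont)
        for t in ont.classes:
            p = (len(ont.descendants(t, include_self=False)) + 1) / total
            ic[t] = -math.log2(p)
        corpus = corpus or ()
    return ICTable(ic=ic, corpus_size=len(corpus) if corpus else 0)


def phenodigm(
    ont: ClassifiedOntology,
    ic: ICTable,
    a: TermId,
    b: TermId,
) -> SimilarityResult:
    """Jaccard, MICA and the PhenoDigm-style geometric-mean score for a pair.

    The MICA is the common ancestor with maximal IC; ties break to the
    lexicographically smallest id, so results are fully deterministic.
    """
    jac = jaccard(ont, a, b)
    common = ont.ancestors(a) & ont.ancestors(b)
    if not common:
        return SimilarityResult(a, b, jac, 0.0, None, 0.0)
    mica = min(common, key=lambda t: (-ic[t], t))
    ic_mica = ic[mica]
    return SimilarityResult(a, b, jac, ic_mica, mica, math.sqrt(jac * ic_mica))


class ProfileMode(enum.Enum):
    max = "max"
    avg = "avg"
    combined = "combined"


def _best_match_scores(
    ont: ClassifiedOntology, ic: ICTable, p: Profile, q: Profile
) -> list[float]:
    return [
        max(phenodigm(ont, ic, t1, t2).phenodigm for t2 in sorted(q.terms))
        for t1 in sorted(p.terms)
    ]


def profile_similarity(
    ont: ClassifiedOntology,
    ic: ICTable,
    p1: Profile,
    p2: Profile,
    mode: Union[ProfileMode, str] = ProfileMode.avg,
) -> float:
    """Best-match profile comparison.

    ``avg``: mean of best-match scores in both directions; ``max``: single
    best pair; ``combined``: mean of (max, avg) each normalized by the
    query profile's self-comparison, scaled to 0–100 (so a profile against
    itself scores 100).
    """
    mode = ProfileMode(mode) if isinstance(mode, str) else mode
    scores = _best_match_scores(ont, ic, p1, p2) + _best_match_scores(ont, ic, p2, p1)
    if mode is ProfileMode.max:
        return max(scores)
    if mode is ProfileMode.avg:
        return mean(scores)
    self_scores = _best_match_scores(ont, ic, p1, p1) * 2
    max_self, avg_self = max(self_scores), mean(self_scores)
    max_ratio = max(scores) / max_self if max_self > 0 else 0.0
    avg_ratio = mean(scores) / avg_self if avg_self > 0 else 0.0
    return mean((max_ratio, avg_ratio)) * 100.0


def write_similarity_table(
    results: Sequence[SimilarityResult],
    dest: Union[str, pathlib.Path],
    labels: Optional[Mapping[TermId, str]] = None,
    ont: Optional[ClassifiedOntology] = None,
) -> None:
    """TSV sorted by descending PhenoDigm score, then subject id."""

    def label(t: Optional[TermId]) -> str:
        if t is None:
            return ""
        if labels is not None and t in labels:
            return labels[t]
        if ont is not None and t in ont:
            return ont.label(t)
        return ""

    lines = [
        "subject_id\tsubject_label\tobject_id\tobject_label\tjaccard\tic_mica\tmica_id\tphenodigm"
    ]
    for r in sorted(results, key=lambda r: (-r.phenodigm, r.a, r.b)):
        lines.append(
            "\t".join(
                (
                    r.a.curie,
                    label(r.a),
                    r.b.curie,
                    label(r.b),
                    f"{r.jaccard:.6g}",
                    f"{r.ic_mica:.6g}",
                    r.mica.curie if r.mica else "",
                    f"{r.phenodigm:.6g}",
                )
            )
        )
    pathlib.Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")
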