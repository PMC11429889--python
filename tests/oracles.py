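"""Independent brute-force oracles used to cross-check the implementation.

Everything here works directly on raw edge triples / ancestor sets with
naive enumeration, deliberately sharing no traversal code with the package.
"""

from __future__ import annotations

import math

from phenoforge.model import Relation


def naive_ancestors(edges, term, rels, include_self=True):
    """Transitive closure by repeated full passes over the raw edge list."""
    closed = {term}
    changed = True
    while changed:
        changed = False
        for s, rel, o in edges:
            if rel in rels and s in closed and o not in closed:
                closed.add(o)
                changed = True
    if not include_self:
        closed.discard(term)
    return closed


def naive_subsumes(general, specific, edges):
    """Re-derive EQ subsumption from first principles over raw edges."""
    isa = {Relation.is_a}
    both = {Relation.is_a, Relation.part_of}
    if general.quality not in naive_ancestors(edges, specific.quality, isa):
        return False
    if general.bearer_mode is Relation.characteristic_of_part_of:
        if general.bearer not in naive_ancestors(edges, specific.bearer, both):
            return False
    else:
        if specific.bearer_mode is not Relation.characteristic_of:
            return False
        if general.bearer not in naive_ancestors(edges, specific.bearer, isa):
            return False
    if general.towards is not None and (
        specific.towards is None
        or general.towards not in naive_ancestors(edges, specific.towards, isa)
    ):
        return False
    if general.occurs_in is not None and (
        specific.occurs_in is None
        or general.occurs_in not in naive_ancestors(edges, specific.occurs_in, both)
    ):
        return False
    return general.modifier == specific.modifier


def naive_transitive_reduction(nodes, reachable):
    """Minimal edge set from a full (child -> set of proper ancestors) map."""
    edges = set()
    for child in nodes:
        for parent in reachable[child]:
            # parent is direct unless some intermediate node sits between
            if not any(
                parent in reachable[mid]
                for mid in reachable[child]
                if mid != parent
            ):
                edges.add((child, parent))
    return edges


def naive_jaccard(anc_a, anc_b):
    union = anc_a | anc_b
    return len(anc_a & anc_b) / len(union) if union else 0.0


def naive_mica(anc_a, anc_b, ic):
    common = anc_a & anc_b
    if not common:
        return None, 0.0
    best = sorted(common, key=lambda t: (-ic[t], t))[0]
    return best, ic[best]


def naive_ic_corpus(profiles, ancestor_sets, all_terms):
    """Annotation-propagation IC computed with a plain double loop."""
    n = len(profiles)
    ic = {}
    for t in all_terms:
        hits = sum(
            1
            for p in profiles
            if any(t in ancestor_sets[term] for term in p.terms)
        )
        ic[t] = -math.log2(hits / n) if hits else math.log2(n + 1)
    return ic
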