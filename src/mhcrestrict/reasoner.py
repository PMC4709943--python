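"""Materialize the inferred subsumption hierarchy.

The logical fragment used by every branch design pattern is EL-like:
atomic classes, conjunction and existential restriction over six
relations, with told subclass axioms and definitional equivalences.
Classification normalizes each axiom (naming nested subexpressions with
internal terms) and saturates completion rules to a fixpoint:

* CR1  A ∈ S(X), A ⊑ B           ⟹  B ∈ S(X)
* CR2  A1..Ak ∈ S(X), ⨅Ai ⊑ B    ⟹  B ∈ S(X)
* CR3  A ∈ S(X), A ⊑ ∃r.B        ⟹  (X,B) ∈ R(r)
* CR4  (X,Y) ∈ R(r), A ∈ S(Y), ∃r.A ⊑ B  ⟹  B ∈ S(X)

This is sound and complete for the fragment, terminates after polynomially
many rule applications, and replaces a general OWL-DL reasoner for the
patterns this toolkit generates.  Internal normalization names never leak
into results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .errors import UnknownTermError, UnsupportedConstructError, ValidationError
from .model import (
    Atom,
    ClassExpression,
    Conjunction,
    EquivalentTo,
    Existential,
    INTERNAL_PREFIX,
    Ontology,
    Relation,
    SubClassOf,
    TermId,
    expression_key,
    is_internal,
)


@dataclass
class InferredHierarchy:
    """Materialized subsumption DAG over the declared classes.

    ``subsumptions`` is reflexive and transitive; ``direct_parents`` is its
    transitive reduction (computed on the quotient by equivalence, so
    declared-equivalent classes share one node represented by the
    lexicographically smallest term id).
    """

    subsumptions: frozenset[tuple[TermId, TermId]]
    direct_parents: dict[TermId, frozenset[TermId]]
    equivalents: dict[TermId, frozenset[TermId]]
    stats: dict[str, int]
    _implied: dict[TermId, set[TermId]] = field(repr=False, default_factory=dict)
    _role_pairs: dict[Relation, set[tuple[TermId, TermId]]] = field(
        repr=False, default_factory=dict
    )
    _declared: frozenset[TermId] = frozenset()

    # -- low-level helpers used by the query engine ------------------------

    def implied_superclasses(self, t: TermId) -> set[TermId]:
        """All Y (possibly internal) with t ⊑ Y."""
        return self._implied.get(t, {t})

    def related_to(self, x: TermId, rel: Relation, target: TermId) -> bool:
        """True iff x ⊑ ∃rel.target follows (target may subsume the filler)."""
        for (a, y) in self._role_pairs.get(rel, ()):
            if a == x and target in self._implied.get(y, {y}):
                return True
        return False

    def role_pairs(self, rel: Relation) -> set[tuple[TermId, TermId]]:
        return self._role_pairs.get(rel, set())

    def successors(self, x: TermId, rel: Relation) -> set[TermId]:
        """Declared fillers y with x ⊑ ∃rel.y."""
        out = set()
        for (a, y) in self._role_pairs.get(rel, ()):
            if a == x:
                if y in self._declared:
                    out.add(y)
                out |= {
                    s for s in self._implied.get(y, {y}) if s in self._declared
                }
        return out

    def descendants(self, t: TermId) -> set[TermId]:
        return {a for (a, b) in self.subsumptions if b == t}


def classify(o: Ontology) -> InferredHierarchy:
    """Normalize, saturate and read off the inferred hierarchy.

    Precondition: ``o.validate()`` is empty (raises
    :class:`ValidationError` otherwise).
    """
    diags = o.validate()
    if diags:
        raise ValidationError(diags)

    declared = frozenset(t for t in o.ids())
    naming = _Naming()
    nf = _normalize(o, naming)

    # indexes over normal-form axioms
    atomic_sub: dict[TermId, list[TermId]] = {}
    conj_index: dict[TermId, list[tuple[tuple[TermId, ...], TermId]]] = {}
    ex_right: dict[TermId, list[tuple[Relation, TermId]]] = {}
    ex_left: dict[tuple[Relation, TermId], list[TermId]] = {}
    for form in nf:
        kind = form[0]
        if kind == "sub":
            _, a, b = form
            atomic_sub.setdefault(a, []).append(b)
        elif kind == "conj":
            _, conjs, b = form
            for c in set(conjs):
                conj_index.setdefault(c, []).append((conjs, b))
        elif kind == "exr":
            _, a, r, b = form
            ex_right.setdefault(a, []).append((r, b))
        elif kind == "exl":
            _, r, a, b = form
            ex_left.setdefault((r, a), []).append(b)

    atoms = set(declared) | naming.internal_ids()
    S: dict[TermId, set[TermId]] = {x: {x} for x in atoms}
    R: dict[Relation, set[tuple[TermId, TermId]]] = {r: set() for r in Relation}
    preds: dict[TermId, set[tuple[Relation, TermId]]] = {}
    stats = {"s_additions": 0, "r_additions": 0, "firings": 0}

    queue: list[tuple] = [("s", x, x) for x in sorted(atoms)]

    def add_s(x: TermId, a: TermId):
        if a not in S[x]:
            S[x].add(a)
            stats["s_additions"] += 1
            queue.append(("s", x, a))

    def add_r(r: Relation, x: TermId, y: TermId):
        if (x, y) not in R[r]:
            R[r].add((x, y))
            preds.setdefault(y, set()).add((r, x))
            stats["r_additions"] += 1
            queue.append(("r", r, x, y))

    while queue:
        item = queue.pop()
        if item[0] == "s":
            _, x, a = item
            for b in atomic_sub.get(a, ()):
                stats["firings"] += 1
                add_s(x, b)
            for conjs, b in conj_index.get(a, ()):
                stats["firings"] += 1
                if all(c in S[x] for c in conjs):
                    add_s(x, b)
            for r, b in ex_right.get(a, ()):
                stats["firings"] += 1
                add_r(r, x, b)
            # x gained a: revisit incoming edges (CR4)
            for r, w in preds.get(x, set()).copy():
                for b in ex_left.get((r, a), ()):
                    stats["firings"] += 1
                    add_s(w, b)
        else:
            _, r, x, y = item
            for a in S[y].copy():
                for b in ex_left.get((r, a), ()):
                    stats["firings"] += 1
                    add_s(x, b)

    subs = frozenset(
        (x, a) for x in declared for a in S[x] if a in declared
    )
    implied = {x: set(S[x]) for x in atoms}
    role_pairs = {r: set(p) for r, p in R.items() if p}

    equivalents, direct = _reduce(declared, subs)
    return InferredHierarchy(
        subsumptions=subs,
        direct_parents=direct,
        equivalents=equivalents,
        stats=stats,
        _implied=implied,
        _role_pairs=role_pairs,
        _declared=declared,
    )


class _Naming:
    """Assigns stable internal names to complex subexpressions."""

    def __init__(self):
        self._by_expr: dict[ClassExpression, TermId] = {}

    def name_of(self, e: ClassExpression) -> TermId:
        if isinstance(e, Atom):
            return e.term
        t = self._by_expr.get(e)
        if t is None:
            t = TermId(INTERNAL_PREFIX, f"{len(self._by_expr) + 1:07d}")
            self._by_expr[e] = t
        return t

    def internal_ids(self) -> set[TermId]:
        return set(self._by_expr.values())


def _normalize(o: Ontology, naming: _Naming) -> list[tuple]:
    """Flatten axioms into normal forms over atoms.

    Every complex subexpression E gets an internal name n(E) defined in
    both directions (n(E) ≡ E), which keeps the translation equivalence-
    preserving.
    """
    nf: list[tuple] = []
    done: set[ClassExpression] = set()

    def define(e: ClassExpression) -> TermId:
        n = naming.name_of(e)
        if isinstance(e, Atom) or e in done:
            return n
        done.add(e)
        if isinstance(e, Existential):
            f = define(e.filler)
            nf.append(("exr", n, e.relation, f))
            nf.append(("exl", e.relation, f, n))
        elif isinstance(e, Conjunction):
            parts = tuple(define(c) for c in e.conjuncts)
            for p in parts:
                nf.append(("sub", n, p))
            nf.append(("conj", parts, n))
        else:
            raise UnsupportedConstructError(f"unsupported expression: {e!r}")
        return n

    for ax in sorted(
        (a for a in o.logical_axioms()),
        key=lambda a: (
            a.__class__.__name__,
            str(a.sub if isinstance(a, SubClassOf) else a.term),
            expression_key(a.sup if isinstance(a, SubClassOf) else a.expr),
        ),
    ):
        if isinstance(ax, SubClassOf):
            nf.append(("sub", ax.sub, define(ax.sup)))
        elif isinstance(ax, EquivalentTo):
            n = define(ax.expr)
            nf.append(("sub", ax.term, n))
            nf.append(("sub", n, ax.term))
    return nf


def _reduce(
    declared: frozenset[TermId], subs: frozenset[tuple[TermId, TermId]]
) -> tuple[dict[TermId, frozenset[TermId]], dict[TermId, frozenset[TermId]]]:
    """Equivalence groups + transitive reduction on the quotient DAG."""
    pairs = set(subs)
    equiv: dict[TermId, frozenset[TermId]] = {}
    canon: dict[TermId, TermId] = {}
    for t in sorted(declared):
        group = frozenset(
            u for u in declared if (t, u) in pairs and (u, t) in pairs
        )
        equiv[t] = group
        canon[t] = min(group)

    g = nx.DiGraph()
    g.add_nodes_from(sorted(set(canon.values())))
    for (a, b) in pairs:
        ca, cb = canon[a], canon[b]
        if ca != cb:
            g.add_edge(ca, cb)
    red = nx.transitive_reduction(g)
    direct: dict[TermId, frozenset[TermId]] = {}
    for t in declared:
        direct[t] = frozenset(red.successors(canon[t]))
    return equiv, direct


# ---------------------------------------------------------------------------
# point queries
# ---------------------------------------------------------------------------


def is_subsumed(a: TermId, b: TermId, h: InferredHierarchy) -> bool:
    """True iff a ⊑ b in the materialized hierarchy."""
    for t in (a, b):
        if t not in h._declared:
            raise UnknownTermError(f"term not declared: {t}")
    return (a, b) in h.subsumptions


def direct_parents(a: TermId, h: InferredHierarchy) -> frozenset[TermId]:
    """Minimal strict superclasses of ``a`` (transitive-reduction row)."""
    if a not in h._declared:
        raise UnknownTermError(f"term not declared: {a}")
    return h.direct_parents[a]
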