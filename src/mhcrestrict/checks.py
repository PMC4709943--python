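"""Slow reference classifier used to cross-validate the reasoner.

Instead of normalizing axioms, this works directly on the lattice of all
subexpressions occurring in the ontology and naively re-applies four rules
until nothing changes:

* reflexivity and transitivity of ⊑,
* conjunction decomposition and composition,
* monotonicity of existentials (A ⊑ B ⟹ ∃r.A ⊑ ∃r.B),
* told axioms (equivalences contribute both directions).

No indexing, no worklist — every pass re-scans everything.  It is far too
slow for real ontologies but is an independent code path against which
:func:`mhcrestrict.reasoner.classify` is checked on many small random
ontologies.
"""

from __future__ import annotations

from .model import (
    Atom,
    ClassExpression,
    Conjunction,
    EquivalentTo,
    Existential,
    Ontology,
    SubClassOf,
    TermId,
)


def _subexpressions(e: ClassExpression) -> set[ClassExpression]:
    out = {e}
    if isinstance(e, Conjunction):
        for c in e.conjuncts:
            out |= _subexpressions(c)
    elif isinstance(e, Existential):
        out |= _subexpressions(e.filler)
    return out


def naive_classify(o: Ontology) -> frozenset[tuple[TermId, TermId]]:
    """All subsumption pairs among declared classes, by brute force."""
    exprs: set[ClassExpression] = {Atom(t) for t in o.ids()}
    told: list[tuple[ClassExpression, ClassExpression]] = []
    for ax in o.logical_axioms():
        if isinstance(ax, SubClassOf):
            lhs, rhs = Atom(ax.sub), ax.sup
            told.append((lhs, rhs))
        elif isinstance(ax, EquivalentTo):
            lhs, rhs = Atom(ax.term), ax.expr
            told.append((lhs, rhs))
            told.append((rhs, lhs))
        exprs |= _subexpressions(ax.sup if isinstance(ax, SubClassOf) else ax.expr)

    expr_list = list(exprs)
    sup: dict[ClassExpression, set[ClassExpression]] = {e: {e} for e in expr_list}
    for lhs, rhs in told:
        sup[lhs].add(rhs)
    for e in expr_list:
        if isinstance(e, Conjunction):
            sup[e].update(e.conjuncts)

    conjunctions = [e for e in expr_list if isinstance(e, Conjunction)]
    existentials = [e for e in expr_list if isinstance(e, Existential)]

    changed = True
    while changed:
        changed = False
        # transitivity
        for e in expr_list:
            extra: set[ClassExpression] = set()
            for s in sup[e]:
                extra |= sup[s]
            if not extra <= sup[e]:
                sup[e] |= extra
                changed = True
        # conjunction composition
        for a in conjunctions:
            for x in expr_list:
                if a not in sup[x] and all(c in sup[x] for c in a.conjuncts):
                    sup[x].add(a)
                    changed = True
        # existential monotonicity
        for e1 in existentials:
            for e2 in existentials:
                if (
                    e1 is not e2
                    and e1.relation is e2.relation
                    and e2 not in sup[e1]
                    and e2.filler in sup[e1.filler]
                ):
                    sup[e1].add(e2)
                    changed = True

    declared = set(o.ids())
    return frozenset(
        (a, b.term)
        for a in declared
        for b in sup[Atom(a)]
        if isinstance(b, Atom) and b.term in declared
    )
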