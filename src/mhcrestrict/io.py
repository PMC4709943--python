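"""Read and write the ontology and browse trees in standard formats.

OBO 1.4 flat files are the authoritative round-trip format (single
parser); OWL 2 functional-style syntax is write-only; browse trees export
as JSON.  All writers are deterministic: identical input (and id
registry) yields byte-identical output.

OBO mapping of the model:

* told atomic superclass       → ``is_a:``
* told existential superclass  → ``relationship: <rel> <id>``
* definitional equivalence     → ``intersection_of:`` lines
  (equivalence to a single atom → ``equivalent_to:``)
* branch / fully-specified     → ``subset:`` values
* definition / comment / other annotations → ``def:`` / ``comment:`` /
  ``property_value:``
"""

from __future__ import annotations

import json
from typing import TextIO

from .errors import ExportError, OboParseError
from .model import (
    Annotation,
    Atom,
    Branch,
    ClassExpression,
    Conjunction,
    EquivalentTo,
    Existential,
    OntClass,
    Ontology,
    Relation,
    SubClassOf,
    TermId,
    expression_key,
)
from .query import Tree, TreeNode

_SUBSET_PREFIX = "branch_"
_FULLY = "fully_specified"


# ---------------------------------------------------------------------------
# OBO writer
# ---------------------------------------------------------------------------


def write_obo(o: Ontology, stream: TextIO) -> None:
    """Serialize to an OBO 1.4 flat file (deterministic byte output).

    Raises :class:`ExportError` for expressions outside the OBO subset
    (nested fillers, conjunctions on the right of a told subclass,
    equivalence to a bare existential).
    """
    w = stream.write
    w("format-version: 1.4\n")
    w(f"ontology: {o.name}\n")
    used_subsets = sorted(
        {_SUBSET_PREFIX + c.branch.value for c in o.classes()}
        | ({_FULLY} if any(c.fully_specified for c in o.classes()) else set())
    )
    for s in used_subsets:
        w(f'subsetdef: {s} "{s}"\n')

    by_term: dict[TermId, dict[str, list]] = {}
    for t in o.ids():
        by_term[t] = {"is_a": [], "rel": [], "inter": [], "equiv": [], "ann": []}
    for ax in o.axioms:
        if isinstance(ax, SubClassOf):
            slot = by_term[ax.sub]
            if isinstance(ax.sup, Atom):
                slot["is_a"].append(ax.sup.term)
            elif isinstance(ax.sup, Existential) and isinstance(ax.sup.filler, Atom):
                slot["rel"].append((ax.sup.relation, ax.sup.filler.term))
            else:
                raise ExportError(
                    f"superclass of {ax.sub} not expressible in OBO: {ax.sup}"
                )
        elif isinstance(ax, EquivalentTo):
            slot = by_term[ax.term]
            if isinstance(ax.expr, Atom):
                slot["equiv"].append(ax.expr.term)
            elif isinstance(ax.expr, Conjunction):
                slot["inter"].append(_conjuncts_for_obo(ax.term, ax.expr))
            else:
                raise ExportError(
                    f"definition of {ax.term} not expressible in OBO: {ax.expr}"
                )
        elif isinstance(ax, Annotation):
            by_term[ax.term]["ann"].append((ax.key, ax.value))

    for t in o.ids():
        c = o[t]
        slot = by_term[t]
        w("\n[Term]\n")
        w(f"id: {t}\n")
        w(f"name: {c.label}\n")
        anns = sorted(slot["ann"])
        for key, value in anns:
            if key == "definition":
                w(f'def: "{_escape(value)}" []\n')
        for key, value in anns:
            if key == "comment":
                w(f"comment: {value}\n")
        w(f"subset: {_SUBSET_PREFIX}{c.branch.value}\n")
        if c.fully_specified:
            w(f"subset: {_FULLY}\n")
        for s in sorted(c.synonyms):
            w(f'synonym: "{_escape(s)}" EXACT []\n')
        for sup in sorted(slot["is_a"]):
            w(f"is_a: {sup} ! {o.label_of(sup)}\n")
        if len(slot["inter"]) > 1:
            raise ExportError(f"{t} has more than one definition")
        for conjuncts in slot["inter"]:
            for item in conjuncts:
                if isinstance(item, TermId):
                    w(f"intersection_of: {item} ! {o.label_of(item)}\n")
                else:
                    rel, filler = item
                    w(
                        f"intersection_of: {rel.obo_id} {filler} "
                        f"! {o.label_of(filler)}\n"
                    )
        for eq in sorted(slot["equiv"]):
            w(f"equivalent_to: {eq} ! {o.label_of(eq)}\n")
        for rel, filler in sorted(slot["rel"], key=lambda p: (p[0].obo_id, p[1])):
            w(f"relationship: {rel.obo_id} {filler} ! {o.label_of(filler)}\n")
        for key, value in anns:
            if key not in ("definition", "comment"):
                w(f'property_value: {key} "{_escape(value)}" xsd:string\n')

    for rel in sorted(Relation, key=lambda r: r.obo_id):
        w("\n[Typedef]\n")
        w(f"id: {rel.obo_id}\n")
        w(f"name: {rel.value}\n")


def _conjuncts_for_obo(t: TermId, e: Conjunction):
    out = []
    for c in e.conjuncts:
        if isinstance(c, Atom):
            out.append(c.term)
        elif isinstance(c, Existential) and isinstance(c.filler, Atom):
            out.append((c.relation, c.filler.term))
        else:
            raise ExportError(f"conjunct of {t} not expressible in OBO: {c}")
    # atoms first, then existentials by (relation, filler)
    return sorted(
        out,
        key=lambda i: (0, str(i), "") if isinstance(i, TermId) else (1, i[0].obo_id, str(i[1])),
    )


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _unescape(s: str) -> str:
    out, i = [], 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            out.append(s[i + 1])
            i += 2
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# OBO parser
# ---------------------------------------------------------------------------


def parse_obo(stream: TextIO) -> Ontology:
    """Parse the OBO subset written by :func:`write_obo`.

    Unknown tags are preserved as opaque annotations.  Malformed stanzas
    raise :class:`OboParseError` with a line number.
    """
    name = "mhc-restriction"
    classes: list[tuple[int, dict]] = []
    current: dict | None = None
    current_line = 0
    in_typedef = False

    lines = stream.read().split("\n")
    for ln, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line or line.startswith("!"):
            continue
        if line == "[Term]":
            current = {"tags": []}
            current_line = ln
            classes.append((ln, current))
            in_typedef = False
            continue
        if line == "[Typedef]":
            current = None
            in_typedef = True
            continue
        if line.startswith("["):
            raise OboParseError(f"unknown stanza {line!r}", ln)
        tag, sep, value = line.partition(": ")
        if not sep:
            tag, sep, value = line.partition(":")
            if not sep:
                raise OboParseError(f"malformed line {line!r}", ln)
        value = value.split(" ! ")[0].strip()
        if in_typedef:
            continue
        if current is None:
            if tag == "ontology":
                name = value
            continue
        current["tags"].append((ln, tag, value))

    o = Ontology(name=name)
    pending: list[tuple[TermId, list]] = []
    for stanza_ln, stanza in classes:
        tid = None
        label = None
        branch = Branch.OTHER
        fully = False
        synonyms: list[str] = []
        body: list = []
        for ln, tag, value in stanza["tags"]:
            if tag == "id":
                tid = TermId.parse(value)
            elif tag == "name":
                label = value
            elif tag == "subset":
                if value == _FULLY:
                    fully = True
                elif value.startswith(_SUBSET_PREFIX):
                    try:
                        branch = Branch(value[len(_SUBSET_PREFIX):])
                    except ValueError:
                        raise OboParseError(f"unknown branch subset {value!r}", ln)
            elif tag == "synonym":
                synonyms.append(_parse_quoted(value, ln))
            else:
                body.append((ln, tag, value))
        if tid is None:
            raise OboParseError("stanza missing id", stanza_ln)
        if label is None:
            raise OboParseError(f"stanza {tid} missing name", stanza_ln)
        fully_val = (fully if branch is Branch.MOLECULE else None)
        o.add_class(
            OntClass(
                id=tid,
                label=label,
                branch=branch,
                synonyms=tuple(synonyms),
                fully_specified=fully_val,
            )
        )
        pending.append((tid, body, stanza_ln))

    for tid, body, stanza_ln in pending:
        conjuncts: list[ClassExpression] = []
        for ln, tag, value in body:
            if tag == "is_a":
                o.add_axiom(SubClassOf(tid, Atom(TermId.parse(value))))
            elif tag == "relationship":
                rel_s, _, target = value.partition(" ")
                o.add_axiom(
                    SubClassOf(
                        tid,
                        Existential(
                            Relation.from_obo_id(rel_s), Atom(TermId.parse(target))
                        ),
                    )
                )
            elif tag == "intersection_of":
                first, _, second = value.partition(" ")
                if second:
                    conjuncts.append(
                        Existential(
                            Relation.from_obo_id(first), Atom(TermId.parse(second))
                        )
                    )
                else:
                    conjuncts.append(Atom(TermId.parse(first)))
            elif tag == "equivalent_to":
                o.add_axiom(EquivalentTo(tid, Atom(TermId.parse(value))))
            elif tag == "def":
                o.add_axiom(Annotation(tid, "definition", _parse_quoted(value, ln)))
            elif tag == "comment":
                o.add_axiom(Annotation(tid, "comment", value))
            elif tag == "property_value":
                key, _, rest = value.partition(" ")
                o.add_axiom(Annotation(tid, key, _parse_quoted(rest, ln)))
            else:
                o.add_axiom(Annotation(tid, f"obo-{tag}", value))
        if len(conjuncts) == 1:
            raise OboParseError(
                f"{tid}: a single intersection_of line is not a definition",
                stanza_ln,
            )
        if conjuncts:
            o.add_axiom(EquivalentTo(tid, Conjunction(tuple(conjuncts))))
    return o


def _parse_quoted(value: str, ln: int) -> str:
    if not value.startswith('"'):
        raise OboParseError(f"expected quoted string in {value!r}", ln)
    out, i = [], 1
    while i < len(value):
        ch = value[i]
        if ch == "\\" and i + 1 < len(value):
            out.append(value[i + 1])
            i += 2
            continue
        if ch == '"':
            return "".join(out)
        out.append(ch)
        i += 1
    raise OboParseError(f"unterminated quoted string in {value!r}", ln)


# ---------------------------------------------------------------------------
# OWL functional-style writer
# ---------------------------------------------------------------------------

_BASE = "https://example.org/mhcrestrict/"


def _iri(t: TermId) -> str:
    return f":{t.prefix}_{t.local}"


def _render_expr(e: ClassExpression) -> str:
    if isinstance(e, Atom):
        return _iri(e.term)
    if isinstance(e, Existential):
        return f"ObjectSomeValuesFrom(:{e.relation.obo_id} {_render_expr(e.filler)})"
    if isinstance(e, Conjunction):
        inner = " ".join(_render_expr(c) for c in e.conjuncts)
        return f"ObjectIntersectionOf({inner})"
    raise ExportError(f"not renderable: {e!r}")


def write_owl_functional(o: Ontology, stream: TextIO) -> None:
    """Serialize to OWL 2 functional-style syntax (write-only subset)."""
    w = stream.write
    w(f"Prefix(:=<{_BASE}>)\n")
    w("Prefix(owl:=<http://www.w3.org/2002/07/owl#>)\n")
    w("Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)\n")
    w("Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)\n")
    w("Prefix(oboInOwl:=<http://www.geneontology.org/formats/oboInOwl#>)\n")
    w(f"Ontology(<{_BASE}{o.name}.owl>\n")
    for rel in sorted(Relation, key=lambda r: r.obo_id):
        w(f"Declaration(ObjectProperty(:{rel.obo_id}))\n")
    for t in o.ids():
        w(f"Declaration(Class({_iri(t)}))\n")
    for t in o.ids():
        c = o[t]
        w(f'AnnotationAssertion(rdfs:label {_iri(t)} "{_escape(c.label)}")\n')
        for s in sorted(c.synonyms):
            w(
                f"AnnotationAssertion(oboInOwl:hasExactSynonym "
                f'{_iri(t)} "{_escape(s)}")\n'
            )
    logical = []
    for ax in o.axioms:
        if isinstance(ax, SubClassOf):
            logical.append(f"SubClassOf({_iri(ax.sub)} {_render_expr(ax.sup)})")
        elif isinstance(ax, EquivalentTo):
            logical.append(
                f"EquivalentClasses({_iri(ax.term)} {_render_expr(ax.expr)})"
            )
        elif isinstance(ax, Annotation):
            logical.append(
                f"AnnotationAssertion(:{_ann_key(ax.key)} {_iri(ax.term)} "
                f'"{_escape(ax.value)}")'
            )
    for line in sorted(logical):
        w(line + "\n")
    w(")\n")


def _ann_key(key: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in key)


# ---------------------------------------------------------------------------
# tree JSON
# ---------------------------------------------------------------------------


def _node_obj(n: TreeNode) -> dict:
    return {
        "id": str(n.id),
        "label": n.label,
        "children": [_node_obj(c) for c in n.children],
    }


def write_tree_json(t: Tree, stream: TextIO) -> None:
    """Write a browse tree as JSON with stable key and child order.

    A single root serializes as one object, multiple roots as an array.
    """
    roots = [_node_obj(r) for r in t.roots]
    obj = roots[0] if len(roots) == 1 else roots
    json.dump(obj, stream, indent=2, ensure_ascii=False)
    stream.write("\n")
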