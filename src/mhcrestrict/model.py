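"""Core ontology data structures.

Terms, the six object relations, a small class-expression language (atomic
class, conjunction, existential restriction — the fragment all of the MHC
design patterns live in), axioms, and the :class:`Ontology` container.

MHC molecules are modeled as protein complexes with two chains: a class I
molecule is an alpha chain plus the invariant beta-2 microglobulin, a class
II molecule an alpha plus a beta chain.  Chains are gene products of genetic
loci, may carry serotypes (treated as information entities, since serotype
assignment depends on the antibody panel used) and may belong to haplotypes.
Engineered molecules point at their naturally occurring counterpart via a
dedicated relation instead of being subclasses of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Union

from .errors import (
    DuplicateLabelError,
    DuplicateTermError,
    UnknownTermError,
)

# ---------------------------------------------------------------------------
# identifiers and relations
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class TermId:
    """A CURIE-style identifier, rendered ``PREFIX:LOCAL``."""

    prefix: str
    local: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local}"

    @classmethod
    def parse(cls, curie: str) -> "TermId":
        prefix, sep, local = curie.partition(":")
        if not sep or not prefix or not local:
            raise UnknownTermError(f"not a CURIE: {curie!r}")
        return cls(prefix, local)


#: prefix used for internal names the reasoner introduces during
#: normalization; such terms never appear in query results or exports.
INTERNAL_PREFIX = "_NORM"


def is_internal(t: TermId) -> bool:
    return t.prefix == INTERNAL_PREFIX


class Relation(Enum):
    """The six object relations the design patterns use.

    ``has part``, ``in taxon`` and ``gene product of`` are reused from the
    Relation Ontology; the other three are defined by this artifact.
    """

    HAS_PART = "has part"
    GENE_PRODUCT_OF = "gene product of"
    IN_TAXON = "in taxon"
    HAS_SEROTYPE = "has serotype"
    PART_OF_HAPLOTYPE = "part of haplotype"
    MUTANT_OF = "mutant of"

    @property
    def obo_id(self) -> str:
        return self.name.lower()

    @classmethod
    def from_obo_id(cls, s: str) -> "Relation":
        try:
            return cls[s.upper()]
        except KeyError:
            raise UnknownTermError(f"unknown relation: {s!r}") from None


IMPORTED_RELATIONS = frozenset(
    {Relation.HAS_PART, Relation.GENE_PRODUCT_OF, Relation.IN_TAXON}
)


# ---------------------------------------------------------------------------
# class expressions
# ---------------------------------------------------------------------------


class ClassExpression:
    """Marker base class; see :class:`Atom`, :class:`Conjunction`,
    :class:`Existential`."""

    __slots__ = ()


@dataclass(frozen=True)
class Atom(ClassExpression):
    term: TermId

    def __str__(self) -> str:
        return str(self.term)


@dataclass(frozen=True)
class Conjunction(ClassExpression):
    """Intersection of two or more expressions; conjuncts are kept in a
    canonical sort order so logically equal conjunctions compare equal."""

    conjuncts: tuple[ClassExpression, ...]

    def __post_init__(self):
        if len(self.conjuncts) < 2:
            raise ValueError("conjunction needs at least 2 conjuncts")
        object.__setattr__(
            self, "conjuncts", tuple(sorted(self.conjuncts, key=expression_key))
        )

    def __str__(self) -> str:
        return "(" + " and ".join(str(c) for c in self.conjuncts) + ")"


@dataclass(frozen=True)
class Existential(ClassExpression):
    relation: Relation
    filler: ClassExpression

    def __str__(self) -> str:
        return f"('{self.relation.value}' some {self.filler})"


def expression_key(e: ClassExpression):
    """Total order on expressions, used for canonical sorting."""
    if isinstance(e, Atom):
        return (0, e.term.prefix, e.term.local)
    if isinstance(e, Existential):
        return (1, e.relation.name, expression_key(e.filler))
    if isinstance(e, Conjunction):
        return (2, tuple(expression_key(c) for c in e.conjuncts))
    raise TypeError(f"not a class expression: {e!r}")


def conj(*exprs: ClassExpression) -> ClassExpression:
    """Build a (flattened) conjunction; a single argument passes through."""
    flat: list[ClassExpression] = []
    for e in exprs:
        if isinstance(e, Conjunction):
            flat.extend(e.conjuncts)
        else:
            flat.append(e)
    if len(flat) == 1:
        return flat[0]
    return Conjunction(tuple(flat))


def referenced_terms(e: ClassExpression) -> set[TermId]:
    """Exactly the atomic term ids occurring in ``e``."""
    if isinstance(e, Atom):
        return {e.term}
    if isinstance(e, Existential):
        return referenced_terms(e.filler)
    if isinstance(e, Conjunction):
        out: set[TermId] = set()
        for c in e.conjuncts:
            out |= referenced_terms(c)
        return out
    raise TypeError(f"not a class expression: {e!r}")


# ---------------------------------------------------------------------------
# axioms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubClassOf:
    sub: TermId
    sup: ClassExpression

    def __str__(self) -> str:
        return f"{self.sub} SubClassOf {self.sup}"


@dataclass(frozen=True)
class EquivalentTo:
    term: TermId
    expr: ClassExpression

    def __str__(self) -> str:
        return f"{self.term} EquivalentTo {self.expr}"


@dataclass(frozen=True)
class Annotation:
    term: TermId
    key: str
    value: str


Axiom = Union[SubClassOf, EquivalentTo, Annotation]
LogicalAxiom = Union[SubClassOf, EquivalentTo]


# ---------------------------------------------------------------------------
# classes and the ontology container
# ---------------------------------------------------------------------------


class Branch(Enum):
    TAXON = "taxon"
    LOCUS = "locus"
    CHAIN = "chain"
    MOLECULE = "molecule"
    HAPLOTYPE = "haplotype"
    SEROTYPE = "serotype"
    EVIDENCE = "evidence"
    OTHER = "other"


@dataclass
class OntClass:
    """One ontology class: id, label, synonyms and branch membership.

    ``fully_specified`` is meaningful for molecule-branch classes only: a
    molecule whose definition uses a generic (locus-level) chain is not
    fully specified.  It is ``None`` outside the molecule branch.
    """

    id: TermId
    label: str
    branch: Branch = Branch.OTHER
    synonyms: tuple[str, ...] = ()
    fully_specified: Optional[bool] = None

    def __post_init__(self):
        self.synonyms = tuple(self.synonyms)


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: the violated invariant and the offender."""

    invariant: str
    term: Optional[TermId]
    message: str

    def __str__(self) -> str:
        where = f" [{self.term}]" if self.term else ""
        return f"{self.invariant}{where}: {self.message}"


# labels used by convention for the three top-level molecule categories;
# the tree builder and the evidence engine locate them by these labels.
CLASS_I_LABEL = "MHC class I protein complex"
CLASS_II_LABEL = "MHC class II protein complex"
NON_CLASSICAL_LABEL = "non-classical MHC protein complex"
CATEGORY_LABELS = (CLASS_I_LABEL, CLASS_II_LABEL, NON_CLASSICAL_LABEL)


class Ontology:
    """Registry of classes plus an ordered list of axioms.

    Axiom order is preserved for reproducible serialization but carries no
    meaning: all downstream inference treats the axiom list as a set.
    """

    def __init__(self, name: str = "mhc-restriction"):
        self.name = name
        self._classes: dict[TermId, OntClass] = {}
        self._by_branch_label: dict[tuple[Branch, str], TermId] = {}
        self._by_label: dict[str, list[TermId]] = {}
        self.axioms: list[Axiom] = []

    # -- registry ----------------------------------------------------------

    def add_class(self, c: OntClass) -> None:
        key = (c.branch, c.label)
        if key in self._by_branch_label:
            raise DuplicateLabelError(
                f"label {c.label!r} already used in branch {c.branch.value}"
            )
        if c.id in self._classes:
            raise DuplicateTermError(f"term already declared: {c.id} ({c.label!r})")
        self._classes[c.id] = c
        self._by_branch_label[key] = c.id
        self._by_label.setdefault(c.label, []).append(c.id)

    def add_axiom(self, ax: Axiom) -> None:
        self.axioms.append(ax)

    def __contains__(self, t: TermId) -> bool:
        return t in self._classes

    def __getitem__(self, t: TermId) -> OntClass:
        try:
            return self._classes[t]
        except KeyError:
            raise UnknownTermError(f"term not declared: {t}") from None

    def __len__(self) -> int:
        return len(self._classes)

    def classes(self) -> Iterator[OntClass]:
        """All classes, sorted by id for deterministic iteration."""
        for t in sorted(self._classes):
            yield self._classes[t]

    def ids(self) -> list[TermId]:
        return sorted(self._classes)

    def label_of(self, t: TermId) -> str:
        return self[t].label

    def get_by_label(self, label: str, branch: Optional[Branch] = None) -> OntClass:
        if branch is not None:
            t = self._by_branch_label.get((branch, label))
            if t is None:
                raise UnknownTermError(
                    f"no class labelled {label!r} in branch {branch.value}"
                )
            return self._classes[t]
        hits = self._by_label.get(label, [])
        if not hits:
            raise UnknownTermError(f"no class labelled {label!r}")
        if len(hits) > 1:
            raise UnknownTermError(
                f"label {label!r} is ambiguous across branches: "
                + ", ".join(str(h) for h in hits)
            )
        return self._classes[hits[0]]

    def has_label(self, label: str) -> bool:
        return len(self._by_label.get(label, [])) == 1

    def branch_ids(self, branch: Branch) -> list[TermId]:
        return sorted(t for t, c in self._classes.items() if c.branch is branch)

    def molecule_ids(self) -> list[TermId]:
        return self.branch_ids(Branch.MOLECULE)

    def logical_axioms(self) -> list[LogicalAxiom]:
        return [a for a in self.axioms if isinstance(a, (SubClassOf, EquivalentTo))]

    def annotations_of(self, t: TermId) -> list[Annotation]:
        return [a for a in self.axioms if isinstance(a, Annotation) and a.term == t]

    # -- validation --------------------------------------------------------

    def validate(self) -> list[Diagnostic]:
        """Check the container invariants; empty list means valid.

        Checked: referential closure of every axiom; serotype-branch classes
        never used as ``has part`` fillers (serotypes are information
        entities, not physical parts); no subclass cycles among distinct
        classes unless covered by declared equivalences.
        """
        out: list[Diagnostic] = []
        for ax in self.axioms:
            if isinstance(ax, (SubClassOf, EquivalentTo)):
                subject = ax.sub if isinstance(ax, SubClassOf) else ax.term
                expr = ax.sup if isinstance(ax, SubClassOf) else ax.expr
                refs = referenced_terms(expr) | {subject}
                for t in refs:
                    if t not in self._classes:
                        out.append(
                            Diagnostic(
                                "referential closure",
                                t,
                                f"undeclared term referenced by axiom: {ax}",
                            )
                        )
                for t in _has_part_fillers(expr):
                    c = self._classes.get(t)
                    if c is not None and c.branch is Branch.SEROTYPE:
                        out.append(
                            Diagnostic(
                                "serotype not a physical part",
                                t,
                                f"serotype used as 'has part' filler in: {ax}",
                            )
                        )
            elif isinstance(ax, Annotation):
                if ax.term not in self._classes:
                    out.append(
                        Diagnostic(
                            "referential closure",
                            ax.term,
                            f"annotation on undeclared term: {ax.key}",
                        )
                    )
        out.extend(self._told_cycles())
        return out

    def _told_cycles(self) -> list[Diagnostic]:
        # cycles in the told atomic-subclass graph are only legal when every
        # edge pair in the cycle is covered by a declared equivalence
        edges: dict[TermId, set[TermId]] = {}
        declared_eq: set[frozenset[TermId]] = set()
        for ax in self.axioms:
            if isinstance(ax, SubClassOf) and isinstance(ax.sup, Atom):
                edges.setdefault(ax.sub, set()).add(ax.sup.term)
            elif isinstance(ax, EquivalentTo) and isinstance(ax.expr, Atom):
                edges.setdefault(ax.term, set()).add(ax.expr.term)
                edges.setdefault(ax.expr.term, set()).add(ax.term)
                declared_eq.add(frozenset({ax.term, ax.expr.term}))
        out = []
        for comp in _sccs(edges):
            if len(comp) > 1:
                pairs = {
                    frozenset({a, b}) for a in comp for b in comp if a != b
                }
                if not pairs <= declared_eq:
                    names = ", ".join(str(t) for t in sorted(comp))
                    out.append(
                        Diagnostic(
                            "acyclic told hierarchy",
                            min(comp),
                            f"undeclared subclass cycle among: {names}",
                        )
                    )
        return out

    # -- equality ----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        if set(self._classes) != set(other._classes):
            return False
        for t, c in self._classes.items():
            d = other._classes[t]
            if (
                c.label != d.label
                or c.branch != d.branch
                or sorted(c.synonyms) != sorted(d.synonyms)
                or bool(c.fully_specified) != bool(d.fully_specified)
            ):
                return False
        return set(self.axioms) == set(other.axioms)

    def __repr__(self) -> str:
        return f"<Ontology {self.name!r}: {len(self)} classes, {len(self.axioms)} axioms>"


def _has_part_fillers(e: ClassExpression) -> set[TermId]:
    if isinstance(e, Atom):
        return set()
    if isinstance(e, Existential):
        out = _has_part_fillers(e.filler)
        if e.relation is Relation.HAS_PART:
            out |= referenced_terms(e.filler)
        return out
    if isinstance(e, Conjunction):
        out = set()
        for c in e.conjuncts:
            out |= _has_part_fillers(c)
        return out
    return set()


def _sccs(edges: dict[TermId, set[TermId]]) -> list[set[TermId]]:
    """Strongly connected components (iterative Tarjan)."""
    index: dict[TermId, int] = {}
    low: dict[TermId, int] = {}
    on_stack: set[TermId] = set()
    stack: list[TermId] = []
    out: list[set[TermId]] = []
    counter = [0]
    nodes = set(edges)
    for vs in edges.values():
        nodes |= vs

    for root in sorted(nodes):
        if root in index:
            continue
        work = [(root, iter(sorted(edges.get(root, ()))))]
        index[root] = low[root] = counter[0]
        counter[0] += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            v, it = work[-1]
            advanced = False
            for w in it:
                if w not in index:
                    index[w] = low[w] = counter[0]
                    counter[0] += 1
                    stack.append(w)
                    on_stack.add(w)
                    work.append((w, iter(sorted(edges.get(w, ())))))
                    advanced = True
                    break
                elif w in on_stack:
                    low[v] = min(low[v], index[w])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                low[parent] = min(low[parent], low[v])
            if low[v] == index[v]:
                comp = set()
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.add(w)
                    if w == v:
                        break
                out.append(comp)
    return out


# -- module-level operation aliases (functional surface) --------------------


def add_class(o: Ontology, c: OntClass) -> Ontology:
    o.add_class(c)
    return o


def validate(o: Ontology) -> list[Diagnostic]:
    return o.validate()
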