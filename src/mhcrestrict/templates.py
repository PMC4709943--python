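"""Compile per-branch tabular templates into ontology classes and axioms.

Each branch of the hierarchy (loci, chains, molecules, haplotypes,
serotypes, mutant molecules, evidence codes, taxa) is maintained as one
tab-separated table: a header row naming the columns, a second row of
template patterns, then one data row per class.  Compiling a table applies
the same pattern to every row, which enforces a uniform design pattern per
branch.

Pattern mini-language (one pattern per column):

=====================  ====================================================
``ID``                 term id cell (CURIE); blank = assign from registry
``LABEL``              class label (required, unique within the branch)
``SYNONYMS``           ``|``-separated exact synonyms
``BRANCH``             per-row branch override (else the table's name)
``FULLY SPECIFIED``    ``true``/``false`` for molecule rows
``SC %``               told superclass (cell resolved label → term)
``SC 'rel' some %``    told existential superclass
``EC %``               equivalence conjunct, atomic
``EC 'rel' some %``    equivalence conjunct, existential
``A key``              annotation with the given key
=====================  ====================================================

All ``EC`` cells of a row together form one definitional equivalence
(a conjunction when there are two or more conjuncts).  Empty cells are
skipped.  Cell values resolve against class labels, falling back to MHC
name normalization so tables may use spelling variants of allele names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from . import nomenclature
from .errors import (
    TemplateFormatError,
    TemplateSchemaError,
    UnknownTermError,
    ValidationError,
)
from .model import (
    Annotation,
    Atom,
    Axiom,
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
    conj,
)

_EXISTENTIAL_RE = re.compile(r"^(SC|EC) '([^']+)' some %$")


@dataclass(frozen=True)
class _Pattern:
    op: str  # id | label | synonyms | branch | fully | sc | ec | sc_some | ec_some | ann
    relation: Optional[Relation] = None
    key: Optional[str] = None


def _parse_pattern(raw: str) -> _Pattern:
    p = raw.strip()
    if p == "ID":
        return _Pattern("id")
    if p == "LABEL":
        return _Pattern("label")
    if p == "SYNONYMS":
        return _Pattern("synonyms")
    if p == "BRANCH":
        return _Pattern("branch")
    if p == "FULLY SPECIFIED":
        return _Pattern("fully")
    if p == "SC %":
        return _Pattern("sc")
    if p == "EC %":
        return _Pattern("ec")
    m = _EXISTENTIAL_RE.match(p)
    if m:
        op = "sc_some" if m.group(1) == "SC" else "ec_some"
        try:
            rel = Relation(m.group(2))
        except ValueError:
            raise TemplateSchemaError(f"unknown relation in pattern: {raw!r}") from None
        return _Pattern(op, relation=rel)
    if p.startswith("A ") and len(p) > 2:
        return _Pattern("ann", key=p[2:].strip())
    raise TemplateSchemaError(f"unrecognized template pattern: {raw!r}")


@dataclass
class BranchTable:
    """One branch template: header, per-column patterns, data rows."""

    name: str
    header: tuple[str, ...]
    patterns: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        if len(self.patterns) != len(self.header):
            raise TemplateSchemaError(
                f"{self.name}: {len(self.header)} columns but "
                f"{len(self.patterns)} patterns"
            )
        parsed = [_parse_pattern(p) for p in self.patterns]
        for op in ("id", "label"):
            n = sum(1 for p in parsed if p.op == op)
            if n != 1:
                raise TemplateSchemaError(
                    f"{self.name}: exactly one {op.upper()} column required, found {n}"
                )
        for i, row in enumerate(self.rows):
            if len(row) != len(self.header):
                raise TemplateFormatError(
                    f"{len(row)} cells under {len(self.header)} columns",
                    row=i + 3,  # 1-based file line: header=1, patterns=2
                )
        self._parsed = tuple(parsed)

    def column(self, op: str) -> int:
        for i, p in enumerate(self._parsed):
            if p.op == op:
                return i
        raise TemplateSchemaError(f"{self.name}: no {op!r} column")


def read_branch_table(stream: Union[TextIO, str], name: str = "branch") -> BranchTable:
    """Parse one TSV template (header row, pattern row, data rows)."""
    text = stream if isinstance(stream, str) else stream.read()
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if len(lines) < 2:
        raise TemplateSchemaError(f"{name}: need a header row and a pattern row")
    header = tuple(lines[0].split("\t"))
    patterns = tuple(lines[1].split("\t"))
    rows = []
    for i, line in enumerate(lines[2:], start=3):
        cells = tuple(line.split("\t"))
        if len(cells) != len(header):
            raise TemplateFormatError(
                f"{len(cells)} cells under {len(header)} columns", row=i
            )
        rows.append(cells)
    return BranchTable(name=name, header=header, patterns=patterns, rows=tuple(rows))


class IDRegistry:
    """Stable label → term-id assignment across compilations.

    Sequential ids within one run; persisting the registry file makes
    recompilation (in any table order) reproduce identical ids.
    """

    def __init__(self, prefix: str = "MRO", start: int = 1):
        self.prefix = prefix
        self._map: dict[str, TermId] = {}
        self._next = start

    def get_or_assign(self, label: str) -> TermId:
        t = self._map.get(label)
        if t is None:
            t = TermId(self.prefix, f"{self._next:07d}")
            self._next += 1
            self._map[label] = t
        return t

    def record(self, label: str, t: TermId) -> None:
        self._map.setdefault(label, t)
        if t.prefix == self.prefix and t.local.isdigit():
            self._next = max(self._next, int(t.local) + 1)

    def save(self, path: Union[str, Path]) -> None:
        lines = [f"{label}\t{t}" for label, t in sorted(self._map.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path], prefix: str = "MRO") -> "IDRegistry":
        reg = cls(prefix=prefix)
        highest = 0
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            if not raw.strip():
                continue
            label, _, curie = raw.partition("\t")
            t = TermId.parse(curie)
            reg._map[label] = t
            if t.prefix == prefix:
                highest = max(highest, int(t.local))
        reg._next = highest + 1
        return reg


#: foreign terms reused from other ontologies; declared with their labels
#: but never re-axiomatized here.  The REO local id is an illustrative
#: stand-in; the others are the real identifiers.
STANDARD_IMPORTS: tuple[OntClass, ...] = (
    OntClass(TermId("BFO", "0000040"), "material entity"),
    OntClass(TermId("GO", "0032991"), "protein complex"),
    OntClass(TermId("PR", "000000001"), "protein"),
    OntClass(TermId("OBI", "0100026"), "organism"),
    OntClass(TermId("IAO", "0000030"), "information content entity"),
    OntClass(TermId("REO", "0000022"), "genetic locus"),
)


def _resolve(cell: str, o: Ontology, where: str) -> TermId:
    label = cell.strip()
    if o.has_label(label):
        return o.get_by_label(label).id
    try:
        parsed = nomenclature.parse_name(label)
        norm = nomenclature.normalize_name(parsed)
        if o.has_label(norm):
            return o.get_by_label(norm).id
    except Exception:
        pass
    raise UnknownTermError(f"unresolvable label {label!r} in {where}")


def declare_rows(t: BranchTable, o: Ontology, registry: IDRegistry) -> list[OntClass]:
    """First pass: register one class per data row (no logical axioms)."""
    id_col = t.column("id")
    label_col = t.column("label")
    parsed = t._parsed
    default_branch: Optional[Branch]
    try:
        default_branch = Branch(t.name)
    except ValueError:
        default_branch = None
    out = []
    for i, row in enumerate(t.rows):
        label = row[label_col].strip()
        if not label:
            raise TemplateFormatError("empty LABEL cell", row=i + 3)
        branch = default_branch
        synonyms: tuple[str, ...] = ()
        fully: Optional[bool] = None
        for j, p in enumerate(parsed):
            cell = row[j].strip()
            if not cell:
                continue
            if p.op == "branch":
                try:
                    branch = Branch(cell)
                except ValueError:
                    raise TemplateFormatError(
                        f"unknown branch {cell!r}", row=i + 3
                    ) from None
            elif p.op == "synonyms":
                synonyms = tuple(s.strip() for s in cell.split("|") if s.strip())
            elif p.op == "fully":
                fully = cell.lower() == "true"
        if branch is None:
            raise TemplateSchemaError(
                f"{t.name}: table name is not a branch and row {i + 3} "
                "has no BRANCH cell"
            )
        if branch is Branch.MOLECULE and fully is None:
            fully = False
        raw_id = row[id_col].strip()
        tid = TermId.parse(raw_id) if raw_id else registry.get_or_assign(label)
        registry.record(label, tid)
        c = OntClass(
            id=tid, label=label, branch=branch, synonyms=synonyms, fully_specified=fully
        )
        o.add_class(c)
        out.append(c)
    return out


def compile_branch(
    t: BranchTable, o: Ontology, registry: Optional[IDRegistry] = None
) -> list[Axiom]:
    """Compile one table: declare its classes, then emit its axioms.

    When used standalone the rows' classes are declared first, so cells may
    reference any row of the same table.  Returns the axioms added.
    """
    if registry is None:
        registry = IDRegistry()
        for c in o.classes():
            registry.record(c.label, c.id)
    declare_rows(t, o, registry)
    return compile_axioms(t, o)


def compile_axioms(t: BranchTable, o: Ontology) -> list[Axiom]:
    """Second pass: emit the axioms of a table whose classes are declared."""
    label_col = t.column("label")
    parsed = t._parsed
    added: list[Axiom] = []

    def emit(ax: Axiom):
        o.add_axiom(ax)
        added.append(ax)

    for i, row in enumerate(t.rows):
        subject = o.get_by_label(row[label_col].strip()).id
        ec_conjuncts: list[ClassExpression] = []
        for j, p in enumerate(parsed):
            cell = row[j].strip()
            if not cell:
                continue
            where = f"{t.name} row {i + 3}, column {t.header[j]!r}"
            if p.op == "sc":
                emit(SubClassOf(subject, Atom(_resolve(cell, o, where))))
            elif p.op == "sc_some":
                emit(
                    SubClassOf(
                        subject,
                        Existential(p.relation, Atom(_resolve(cell, o, where))),
                    )
                )
            elif p.op == "ec":
                ec_conjuncts.append(Atom(_resolve(cell, o, where)))
            elif p.op == "ec_some":
                ec_conjuncts.append(
                    Existential(p.relation, Atom(_resolve(cell, o, where)))
                )
            elif p.op == "ann":
                emit(Annotation(subject, p.key, cell))
        if ec_conjuncts:
            emit(EquivalentTo(subject, conj(*ec_conjuncts)))
    return added


def compile_ontology(
    tables: Sequence[BranchTable],
    registry: Optional[IDRegistry] = None,
    name: str = "mhc-restriction",
    imports: Iterable[OntClass] = STANDARD_IMPORTS,
) -> Ontology:
    """Compile a set of branch tables into one validated ontology.

    Classes of every table are declared first (in table, then row order),
    then axioms are compiled, so cross-table references resolve regardless
    of table order; with a persisted id registry the result is identical
    for any table permutation.  Raises :class:`ValidationError` if the
    result fails validation.
    """
    o = Ontology(name=name)
    if registry is None:
        registry = IDRegistry()
    for c in imports:
        o.add_class(
            OntClass(
                id=c.id, label=c.label, branch=c.branch, synonyms=c.synonyms
            )
        )
        registry.record(c.label, c.id)
    for t in tables:
        declare_rows(t, o, registry)
    for t in tables:
        compile_axioms(t, o)
    diags = o.validate()
    if diags:
        raise ValidationError(diags)
    return o
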