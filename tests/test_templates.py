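"""Branch-template reading and compilation."""

import random

import pytest

from mhcrestrict.errors import (
    TemplateFormatError,
    TemplateSchemaError,
    UnknownTermError,
    DuplicateLabelError,
)
from mhcrestrict.fixtures import example_ontology, example_tables, render_table
from mhcrestrict.model import (
    Annotation,
    Atom,
    Conjunction,
    EquivalentTo,
    Existential,
    OntClass,
    Ontology,
    Relation,
    SubClassOf,
    TermId,
)
from mhcrestrict.templates import (
    BranchTable,
    IDRegistry,
    compile_branch,
    compile_ontology,
    read_branch_table,
)


def _tsv(*rows):
    return "\n".join("\t".join(r) for r in rows) + "\n"


class TestReadBranchTable:
    def test_header_and_patterns_only_gives_zero_rows(self):
        t = read_branch_table(_tsv(("ID", "Label"), ("ID", "LABEL")), name="chain")
        assert t.rows == ()

    def test_ragged_row_reports_row_number(self):
        text = _tsv(
            ("ID", "Label", "Parent", "Extra"),
            ("ID", "LABEL", "SC %", "SC %"),
            ("", "x", "y"),
        )
        with pytest.raises(TemplateFormatError) as err:
            read_branch_table(text, name="chain")
        assert err.value.row == 3

    def test_missing_id_or_label_pattern_is_schema_error(self):
        with pytest.raises(TemplateSchemaError):
            read_branch_table(_tsv(("Label",), ("LABEL",)), name="chain")
        with pytest.raises(TemplateSchemaError):
            read_branch_table(_tsv(("ID", "X"), ("ID", "SC %")), name="chain")

    def test_unknown_pattern_rejected(self):
        with pytest.raises(TemplateSchemaError):
            read_branch_table(
                _tsv(("ID", "Label", "X"), ("ID", "LABEL", "SPLIT=|")), name="chain"
            )

    def test_fixture_chain_table_round_trips_through_tsv(self):
        for t in example_tables():
            again = read_branch_table(render_table(t), name=t.name)
            assert again == t


def _base_ontology():
    o = Ontology()
    o.add_class(OntClass(id=TermId("GO", "0032991"), label="protein complex"))
    return o


class TestCompileBranch:
    def test_molecule_row_yields_three_way_conjunction_definition(self):
        """Two chain cells plus the category cell compile into one
        equivalence whose expression is a 3-way conjunction."""
        o = _base_ontology()
        chain_table = BranchTable(
            name="chain",
            header=("ID", "Label"),
            patterns=("ID", "LABEL"),
            rows=(("", "alpha chain"), ("", "beta chain")),
        )
        reg = IDRegistry()
        compile_branch(chain_table, o, reg)
        mol_table = BranchTable(
            name="molecule",
            header=("ID", "Label", "Category", "Alpha", "Beta"),
            patterns=(
                "ID",
                "LABEL",
                "EC %",
                "EC 'has part' some %",
                "EC 'has part' some %",
            ),
            rows=(("", "the molecule", "protein complex", "alpha chain", "beta chain"),),
        )
        axioms = compile_branch(mol_table, o, reg)
        assert len(axioms) == 1
        (ax,) = axioms
        assert isinstance(ax, EquivalentTo)
        assert isinstance(ax.expr, Conjunction)
        assert len(ax.expr.conjuncts) == 3
        existentials = [
            c for c in ax.expr.conjuncts if isinstance(c, Existential)
        ]
        assert len(existentials) == 2
        assert all(c.relation is Relation.HAS_PART for c in existentials)

    def test_row_with_empty_logical_cells_declares_class_only(self):
        o = _base_ontology()
        t = BranchTable(
            name="chain",
            header=("ID", "Label", "Parent"),
            patterns=("ID", "LABEL", "SC %"),
            rows=(("", "lonely chain", ""),),
        )
        axioms = compile_branch(t, o)
        assert axioms == []
        assert o.get_by_label("lonely chain").label == "lonely chain"

    def test_axiom_count_formula(self):
        """Logical+annotation axiom count = #SC cells + #A cells + #rows
        with at least one EC cell."""
        for table in example_tables():
            o = example_ontology()
            expected = 0
            parsed = table._parsed
            for row in table.rows:
                has_ec = False
                for cell, p in zip(row, parsed):
                    if not cell.strip():
                        continue
                    if p.op in ("sc", "sc_some", "ann"):
                        expected += 1
                    elif p.op in ("ec", "ec_some"):
                        has_ec = True
                expected += 1 if has_ec else 0
            fresh = Ontology()
            # redeclare everything the table needs, then count its axioms
            for c in o.classes():
                fresh.add_class(
                    OntClass(id=c.id, label=c.label, branch=c.branch)
                )
            from mhcrestrict.templates import compile_axioms

            assert len(compile_axioms(table, fresh)) == expected

    def test_unresolvable_label_names_the_cell(self):
        o = _base_ontology()
        t = BranchTable(
            name="chain",
            header=("ID", "Label", "Parent"),
            patterns=("ID", "LABEL", "SC %"),
            rows=(("", "x chain", "no such parent"),),
        )
        with pytest.raises(UnknownTermError) as err:
            compile_branch(t, o)
        assert "no such parent" in str(err.value)
        assert "Parent" in str(err.value)

    def test_duplicate_label_in_branch_rejected(self):
        o = _base_ontology()
        t = BranchTable(
            name="chain",
            header=("ID", "Label"),
            patterns=("ID", "LABEL"),
            rows=(("", "dup"), ("", "dup")),
        )
        with pytest.raises(DuplicateLabelError):
            compile_branch(t, o)

    def test_mhc_name_cells_resolve_after_normalization(self):
        """Tables may write allele names in legacy or lower-case spellings."""
        o = _base_ontology()
        t = BranchTable(
            name="chain",
            header=("ID", "Label"),
            patterns=("ID", "LABEL"),
            rows=(("", "HLA-DPB1*04:02"),),
        )
        compile_branch(t, o)
        t2 = BranchTable(
            name="molecule",
            header=("ID", "Label", "Parent"),
            patterns=("ID", "LABEL", "SC %"),
            rows=(("", "m", "hla-dpb1*0402"),),
        )
        axioms = compile_branch(t2, o)
        assert axioms == [
            SubClassOf(
                o.get_by_label("m").id, Atom(o.get_by_label("HLA-DPB1*04:02").id)
            )
        ]


class TestCompileOntology:
    def test_example_tables_compile_to_valid_ontology(self):
        o = compile_ontology(example_tables())
        assert o.validate() == []

    def test_empty_table_list_gives_import_only_ontology(self):
        o = compile_ontology([])
        assert o.validate() == []
        assert len(o.logical_axioms()) == 0

    def test_shuffled_table_order_identical_after_registry_normalization(
        self, tmp_path
    ):
        reg = IDRegistry()
        first = compile_ontology(example_tables(), registry=reg)
        reg.save(tmp_path / "ids.tsv")
        tables = example_tables()
        random.Random(0).shuffle(tables)
        second = compile_ontology(
            tables, registry=IDRegistry.load(tmp_path / "ids.tsv")
        )
        assert first == second

    def test_recompilation_is_deterministic(self):
        assert compile_ontology(example_tables()) == compile_ontology(
            example_tables()
        )

    def test_annotation_cells_become_annotations(self):
        o = example_ontology()
        b2m = o.get_by_label("beta-2 microglobulin")
        anns = o.annotations_of(b2m.id)
        assert any(
            a.key == "comment" and "outside the MHC locus" in a.value for a in anns
        )
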