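"""Restriction-query expansion and browse-tree construction."""

import pytest

from mhcrestrict.errors import UnknownTermError, WrongBranchError
from mhcrestrict.query import (
    build_tree,
    molecules_in_haplotype,
    molecules_under,
    molecules_with_serotype,
    mutant_molecules,
)


def labels(o, terms):
    return sorted(o.label_of(t) for t in terms)


CLASS_II_MOLECULES = [
    "H2-IAd molecule",
    "H2-IEd molecule",
    "HLA-DPA1*02:01/DPB1*01:01 molecule",
    "HLA-DPA1*02:01/DPB1*04:02 molecule",
    "HLA-DPB1*04:02 molecule",
]


class TestMoleculesUnder:
    def test_leaf_molecule_returns_itself(self, ontology, hierarchy, lid):
        t = lid("H2-IAd molecule")
        assert molecules_under(t, ontology, hierarchy) == {t}

    def test_class_ii_category_enumerates_all_class_ii(self, ontology, hierarchy, lid):
        got = molecules_under(lid("MHC class II protein complex"), ontology, hierarchy)
        assert labels(ontology, got) == CLASS_II_MOLECULES

    def test_chain_query_finds_generic_and_fully_specified(
        self, ontology, hierarchy, lid
    ):
        got = molecules_under(lid("HLA-DPB1*04:02 chain"), ontology, hierarchy)
        assert labels(ontology, got) == [
            "HLA-DPA1*02:01/DPB1*04:02 molecule",
            "HLA-DPB1*04:02 molecule",
        ]

    def test_generic_chain_query_spans_the_locus(self, ontology, hierarchy, lid):
        got = molecules_under(lid("HLA-DPB chain"), ontology, hierarchy)
        assert labels(ontology, got) == [
            "HLA-DPA1*02:01/DPB1*01:01 molecule",
            "HLA-DPA1*02:01/DPB1*04:02 molecule",
            "HLA-DPB1*04:02 molecule",
        ]

    def test_mutants_excluded_unless_flagged(self, ontology, hierarchy, lid):
        root = lid("MHC class I protein complex")
        without = molecules_under(root, ontology, hierarchy)
        with_ = molecules_under(root, ontology, hierarchy, include_mutants=True)
        mutant = lid("HLA-A*02:01 K66A mutant molecule")
        assert mutant not in without
        assert mutant in with_
        assert with_ - without == {mutant}

    def test_monotone_in_subsumption(self, ontology, hierarchy, lid):
        """t1 ⊑ t2 implies molecules_under(t1) ⊆ molecules_under(t2)."""
        pairs = [
            ("MHC class II protein complex", "MHC protein complex"),
            ("HLA-DPB1*04:02 chain", "HLA-DPB chain"),
            ("HLA-DPB1*04:02 molecule", "MHC class II protein complex"),
        ]
        for a, b in pairs:
            assert molecules_under(lid(a), ontology, hierarchy) <= molecules_under(
                lid(b), ontology, hierarchy
            )

    def test_unknown_term(self, ontology, hierarchy):
        from mhcrestrict.model import TermId

        with pytest.raises(UnknownTermError):
            molecules_under(TermId("X", "0000001"), ontology, hierarchy)


class TestSerotype:
    def test_a2_includes_a0201_molecule(self, ontology, hierarchy, lid):
        got = molecules_with_serotype(lid("A2"), ontology, hierarchy)
        assert labels(ontology, got) == ["HLA-A*02:01 molecule"]

    def test_parent_serotype_includes_split_children(self, ontology, hierarchy, lid):
        got = molecules_with_serotype(lid("A9"), ontology, hierarchy)
        assert labels(ontology, got) == ["HLA-A*23:01 molecule"]

    def test_serotype_without_chains_is_empty(self, ontology, hierarchy, lid):
        assert molecules_with_serotype(lid("A24"), ontology, hierarchy) == set()

    def test_results_are_always_molecules(self, ontology, hierarchy, lid):
        root = lid("MHC protein complex")
        all_mols = molecules_under(root, ontology, hierarchy, include_mutants=True)
        for s in ("A2", "A9", "A23", "MHC serotype"):
            assert molecules_with_serotype(lid(s), ontology, hierarchy) <= all_mols

    def test_matches_brute_force_scan_of_definitions(self, ontology, hierarchy, lid):
        """Independent oracle: walk told axioms directly."""
        from mhcrestrict.model import (
            Atom,
            EquivalentTo,
            Existential,
            Relation,
            SubClassOf,
        )

        told_parents = {}
        serotype_of = {}
        parts = {}
        for ax in ontology.logical_axioms():
            if isinstance(ax, SubClassOf) and isinstance(ax.sup, Atom):
                told_parents.setdefault(ax.sub, set()).add(ax.sup.term)
            elif isinstance(ax, SubClassOf) and isinstance(ax.sup, Existential):
                if ax.sup.relation is Relation.HAS_SEROTYPE:
                    serotype_of.setdefault(ax.sub, set()).add(ax.sup.filler.term)
            elif isinstance(ax, EquivalentTo):
                for c in ax.expr.conjuncts:
                    if (
                        isinstance(c, Existential)
                        and c.relation is Relation.HAS_PART
                    ):
                        parts.setdefault(ax.term, set()).add(c.filler.term)

        def ancestors(t):
            seen, stack = {t}, [t]
            while stack:
                for p in told_parents.get(stack.pop(), ()):
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)
            return seen

        target = lid("A9")
        expected = set()
        for m, chains in parts.items():
            for ch in chains:
                for anc in ancestors(ch):
                    for s in serotype_of.get(anc, ()):
                        if target in ancestors(s):
                            expected.add(m)
        assert molecules_with_serotype(target, ontology, hierarchy) == expected

    def test_non_serotype_term_rejected(self, ontology, hierarchy, lid):
        with pytest.raises(WrongBranchError):
            molecules_with_serotype(lid("HLA-A chain"), ontology, hierarchy)


class TestHaplotype:
    def test_h2d_with_class_ii_filter(self, ontology, hierarchy, lid):
        got = molecules_in_haplotype(
            lid("H2d haplotype"),
            ontology,
            hierarchy,
            class_filter=lid("MHC class II protein complex"),
        )
        assert labels(ontology, got) == ["H2-IAd molecule", "H2-IEd molecule"]

    def test_h2d_unfiltered_includes_class_i_member(self, ontology, hierarchy, lid):
        got = molecules_in_haplotype(lid("H2d haplotype"), ontology, hierarchy)
        assert labels(ontology, got) == [
            "H2-IAd molecule",
            "H2-IEd molecule",
            "H2-Kd molecule",
        ]

    def test_empty_haplotype_gives_empty_set(self, ontology, hierarchy, lid):
        assert (
            molecules_in_haplotype(lid("B21 haplotype"), ontology, hierarchy) == set()
        )

    def test_non_haplotype_rejected(self, ontology, hierarchy, lid):
        with pytest.raises(WrongBranchError):
            molecules_in_haplotype(lid("A2"), ontology, hierarchy)


class TestTree:
    def test_locus_view_has_three_roots(self, ontology, hierarchy):
        t = build_tree("locus", ontology, hierarchy)
        assert [r.label for r in t.roots] == [
            "MHC class I protein complex",
            "MHC class II protein complex",
            "non-classical MHC protein complex",
        ]

    def test_dp_subloci_nested_under_dp(self, ontology, hierarchy):
        t = build_tree("locus", ontology, hierarchy)
        class_ii = t.roots[1]
        human = next(c for c in class_ii.children if c.label == "Homo sapiens")
        dp = next(c for c in human.children if c.label == "HLA-DP locus")
        assert {c.label for c in dp.children} >= {
            "HLA-DPA1 locus",
            "HLA-DPB1 locus",
        }

    def test_leaves_agree_with_flat_query(self, ontology, hierarchy, lid):
        t = build_tree("locus", ontology, hierarchy)
        molecule_leaves = set()
        for node in t.iter_nodes():
            if node.id in set(ontology.molecule_ids()):
                molecule_leaves.add(node.id)
        assert molecule_leaves == molecules_under(
            lid("MHC protein complex"), ontology, hierarchy
        )

    def test_children_sorted_and_no_internal_names(self, ontology, hierarchy):
        for view in ("locus", "haplotype", "serotype"):
            t = build_tree(view, ontology, hierarchy)
            for node in t.iter_nodes():
                assert node.id.prefix != "_NORM"
                child_labels = [c.label for c in node.children]
                assert child_labels == sorted(child_labels)

    def test_haplotype_view_groups_by_species(self, ontology, hierarchy):
        t = build_tree("haplotype", ontology, hierarchy)
        by_label = {r.label: r for r in t.roots}
        assert set(by_label) == {"Gallus gallus", "Mus musculus"}
        h2d = next(
            c for c in by_label["Mus musculus"].children if c.label == "H2d haplotype"
        )
        assert {c.label for c in h2d.children} == {
            "H2-IAd molecule",
            "H2-IEd molecule",
            "H2-Kd molecule",
        }
        # the chicken haplotype stub is present but empty
        b21 = next(
            c for c in by_label["Gallus gallus"].children if c.label == "B21 haplotype"
        )
        assert b21.children == ()

    def test_serotype_view_nests_splits(self, ontology, hierarchy):
        t = build_tree("serotype", ontology, hierarchy)
        human = next(r for r in t.roots if r.label == "Homo sapiens")
        nodes = {n.label: n for n in human.iter_nodes()}
        assert "A9" in nodes and "A23" in nodes
        assert any(c.label == "A23" for c in nodes["A9"].children)
        assert {c.label for c in nodes["A23"].children} == {"HLA-A*23:01 molecule"}

    def test_every_molecule_with_attribute_appears_in_view(
        self, ontology, hierarchy, lid
    ):
        hap_tree = build_tree("haplotype", ontology, hierarchy)
        in_view = {n.id for n in hap_tree.iter_nodes()}
        for m in molecules_in_haplotype(lid("H2d haplotype"), ontology, hierarchy):
            assert m in in_view

    def test_mutant_absent_by_default(self, ontology, hierarchy, lid):
        t = build_tree("locus", ontology, hierarchy)
        mutant = lid("HLA-A*02:01 K66A mutant molecule")
        assert mutant not in {n.id for n in t.iter_nodes()}
        t2 = build_tree("locus", ontology, hierarchy, include_mutants=True)
        assert mutant in {n.id for n in t2.iter_nodes()}


def test_mutant_detection(ontology, hierarchy, lid):
    assert {ontology.label_of(m) for m in mutant_molecules(ontology, hierarchy)} == {
        "HLA-A*02:01 K66A mutant molecule"
    }
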