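"""Evidence codes and restriction narrowing."""

import dataclasses

import pytest

from mhcrestrict.evidence import (
    AssayContext,
    Effector,
    EvidenceCode,
    Level,
    applicable_codes,
    infer_restriction,
)
from mhcrestrict.fixtures import random_assay_context


def labels(o, terms):
    return sorted(o.label_of(t) for t in terms)


class TestApplicableCodes:
    def test_effector_only(self):
        c = AssayContext(effector=Effector.CD4)
        assert applicable_codes(c) == [EvidenceCode.TYPE_OF_EFFECTOR_T_CELL]

    def test_single_available_molecule_triggers_code(self, lid):
        c = AssayContext(single_available_molecule=lid("H2-IAd molecule"))
        assert EvidenceCode.SINGLE_MHC_AVAILABLE in applicable_codes(c)

    def test_empty_context_has_no_codes(self):
        assert applicable_codes(AssayContext()) == []

    def test_exact_codes_precede_class_codes(self, lid):
        c = AssayContext(
            effector=Effector.CD4,
            author_stated=lid("H2-IAd molecule"),
            biological_process="cytotoxicity",
        )
        codes = applicable_codes(c)
        assert codes.index(EvidenceCode.AUTHOR_STATEMENT) < codes.index(
            EvidenceCode.TYPE_OF_EFFECTOR_T_CELL
        )
        assert codes.index(EvidenceCode.TYPE_OF_EFFECTOR_T_CELL) < codes.index(
            EvidenceCode.BIOLOGICAL_PROCESS_MEASURED
        )


class TestInferRestriction:
    def test_h2d_cd4_narrows_to_the_two_class_ii_molecules(
        self, ontology, hierarchy, lid
    ):
        """A CD4 response in an H2d (BALB/c) host must implicate exactly
        the two class II molecules of that haplotype."""
        ctx = AssayContext(
            effector=Effector.CD4,
            host_haplotypes=frozenset({lid("H2d haplotype")}),
        )
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert labels(ontology, concl.candidates) == [
            "H2-IAd molecule",
            "H2-IEd molecule",
        ]
        assert concl.codes == (EvidenceCode.TYPE_OF_EFFECTOR_T_CELL,)

    def test_cd8_human_host_gives_all_class_i(self, ontology, hierarchy, lid):
        ctx = AssayContext(
            effector=Effector.CD8, host_taxon=lid("Homo sapiens")
        )
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert labels(ontology, concl.candidates) == [
            "HLA-A*02:01 molecule",
            "HLA-A*23:01 molecule",
        ]
        assert concl.level is Level.CLASS

    def test_empty_context_returns_every_molecule_at_set_level(
        self, ontology, hierarchy
    ):
        concl = infer_restriction(AssayContext(), ontology, hierarchy)
        assert concl.codes == ()
        assert concl.level is Level.SET
        assert len(concl.candidates) == 8  # all non-mutant molecules

    def test_single_molecule_gives_exact_level(self, ontology, hierarchy, lid):
        ctx = AssayContext(single_available_molecule=lid("H2-IAd molecule"))
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert concl.level is Level.EXACT
        assert labels(ontology, concl.candidates) == ["H2-IAd molecule"]
        assert concl.codes == (EvidenceCode.SINGLE_MHC_AVAILABLE,)

    def test_apc_panel_intersects_responders_subtracts_nonresponders(
        self, ontology, hierarchy, lid
    ):
        iad, ied, kd = (
            lid("H2-IAd molecule"),
            lid("H2-IEd molecule"),
            lid("H2-Kd molecule"),
        )
        ctx = AssayContext(
            apc_panel=(
                (frozenset({iad, ied, kd}), True),
                (frozenset({ied}), False),
            )
        )
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert concl.candidates == frozenset({iad, kd})
        assert EvidenceCode.REACTIVITY_DIFFERENT_MHC in concl.codes

    def test_antibody_defined_set_narrows_to_locus_level(
        self, ontology, hierarchy, lid
    ):
        ctx = AssayContext(antibody_defined_set=lid("HLA-A chain"))
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert labels(ontology, concl.candidates) == [
            "HLA-A*02:01 molecule",
            "HLA-A*23:01 molecule",
        ]
        assert concl.codes == (EvidenceCode.SET_OF_MHC_AVAILABLE,)

    def test_defeasible_effector_default_can_be_disabled(
        self, ontology, hierarchy, lid
    ):
        ctx = AssayContext(
            effector=Effector.CD8,
            host_taxon=lid("Mus musculus"),
            assume_effector_class=False,
        )
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert EvidenceCode.TYPE_OF_EFFECTOR_T_CELL not in concl.codes
        assert len(concl.candidates) == 3  # all mouse molecules, class not assumed

    def test_unknown_biological_process_warns_without_filtering(
        self, ontology, hierarchy
    ):
        base = infer_restriction(AssayContext(), ontology, hierarchy)
        concl = infer_restriction(
            AssayContext(biological_process="levitation"), ontology, hierarchy
        )
        assert concl.candidates == base.candidates
        assert any("unknown biological process" in d for d in concl.diagnostics)

    def test_known_biological_process_maps_to_class(self, ontology, hierarchy, lid):
        ctx = AssayContext(
            biological_process="cytotoxicity", host_taxon=lid("Mus musculus")
        )
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert labels(ontology, concl.candidates) == ["H2-Kd molecule"]
        assert concl.codes == (EvidenceCode.BIOLOGICAL_PROCESS_MEASURED,)

    def test_contradictory_evidence_reports_empty_diagnostic(
        self, ontology, hierarchy, lid
    ):
        ctx = AssayContext(
            effector=Effector.CD4,
            author_stated=lid("H2-Kd molecule"),  # class I: contradicts CD4
        )
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert concl.candidates == frozenset()
        assert any("empty candidate set" in d for d in concl.diagnostics)

    def test_conflicting_exact_evidence_keeps_both_codes(
        self, ontology, hierarchy, lid
    ):
        ctx = AssayContext(
            author_stated=lid("H2-IAd molecule"),
            ligand_assay_molecule=lid("H2-IEd molecule"),
        )
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert EvidenceCode.AUTHOR_STATEMENT in concl.codes
        assert EvidenceCode.MHC_LIGAND_ASSAY in concl.codes
        assert any("conflicting exact evidence" in d for d in concl.diagnostics)

    def test_single_and_panel_mutually_exclusive(self, lid):
        with pytest.raises(ValueError):
            AssayContext(
                single_available_molecule=lid("H2-IAd molecule"),
                apc_panel=((frozenset({lid("H2-IEd molecule")}), True),),
            )

    def test_trace_sets_shrink_monotonically(self, ontology, hierarchy, lid):
        ctx = AssayContext(
            effector=Effector.CD4,
            host_haplotypes=frozenset({lid("H2d haplotype")}),
            author_stated=lid("H2-IAd molecule"),
        )
        concl = infer_restriction(ctx, ontology, hierarchy)
        for _, before, after in concl.trace:
            assert after <= before


_EVIDENCE_FIELDS_AND_DEFAULTS = {
    "effector": Effector.UNKNOWN,
    "host_taxon": None,
    "host_haplotypes": frozenset(),
    "single_available_molecule": None,
    "apc_panel": (),
    "antibody_defined_set": None,
    "author_stated": None,
    "ligand_assay_molecule": None,
    "predicted_molecule": None,
    "association_molecule": None,
    "biological_process": None,
}


def reduced_contexts(ctx):
    for f, default in _EVIDENCE_FIELDS_AND_DEFAULTS.items():
        if getattr(ctx, f) != default:
            yield f, dataclasses.replace(ctx, **{f: default})


class TestProperties:
    @pytest.mark.parametrize("seed", range(30))
    def test_removing_evidence_never_shrinks_candidates(
        self, ontology, hierarchy, seed
    ):
        ctx = random_assay_context(seed, ontology)
        full = infer_restriction(ctx, ontology, hierarchy).candidates
        for f, reduced in reduced_contexts(ctx):
            got = infer_restriction(reduced, ontology, hierarchy).candidates
            assert full <= got, f"removing {f} shrank the candidate set"

    @pytest.mark.parametrize("seed", range(20))
    def test_final_set_equals_intersection_of_individual_filters(
        self, ontology, hierarchy, seed
    ):
        """Order-insensitivity: the result equals the intersection of each
        piece of evidence applied on its own (panel subtractions included)."""
        ctx = random_assay_context(seed * 101 + 13, ontology)
        full = infer_restriction(ctx, ontology, hierarchy).candidates
        base = infer_restriction(
            AssayContext(host_taxon=ctx.host_taxon), ontology, hierarchy
        ).candidates
        expected = set(base)
        for f, default in _EVIDENCE_FIELDS_AND_DEFAULTS.items():
            if f == "host_taxon" or getattr(ctx, f) == default:
                continue
            solo = AssayContext(
                host_taxon=ctx.host_taxon, **{f: getattr(ctx, f)}
            )
            expected &= infer_restriction(solo, ontology, hierarchy).candidates
        assert full == frozenset(expected)

    @pytest.mark.parametrize("seed", range(30))
    def test_conclusion_codes_subset_of_applicable(self, ontology, hierarchy, seed):
        ctx = random_assay_context(seed * 7 + 3, ontology)
        concl = infer_restriction(ctx, ontology, hierarchy)
        assert set(concl.codes) <= set(applicable_codes(ctx))
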