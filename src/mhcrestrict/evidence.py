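"""Assign restriction evidence codes and narrow candidate molecule sets.

In T-cell assays the restricting MHC molecule is often not identified
directly: it can be narrowed from the genetic background of the host
(haplotypes of inbred strains), the conditions of the experiment (which
molecules were available on the antigen-presenting cells), or the
biological process measured.  Each route has a controlled evidence code;
:func:`infer_restriction` starts from all molecules of the host species
and applies every piece of evidence in the context as a set filter,
recording the codes used and a shrinking trace.

The CD4 → class II / CD8 → class I inference is a defeasible default
(some T cells recognizing class II-restricted epitopes express CD8); it
can be disabled per context with ``assume_effector_class=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from .errors import WrongBranchError
from .model import (
    Branch,
    CLASS_I_LABEL,
    CLASS_II_LABEL,
    Ontology,
    Relation,
    TermId,
)
from .query import molecules_in_haplotype, molecules_under, mutant_molecules
from .reasoner import InferredHierarchy


class EvidenceCode(Enum):
    """The nine restriction evidence codes; values are the class labels."""

    AUTHOR_STATEMENT = "author statement"
    MHC_LIGAND_ASSAY = "MHC ligand assay"
    MHC_BINDING_PREDICTION = "MHC binding prediction"
    STATISTICAL_ASSOCIATION = "statistical association"
    SINGLE_MHC_AVAILABLE = "single MHC available"
    REACTIVITY_DIFFERENT_MHC = "reactivity of same T cells with different MHC"
    SET_OF_MHC_AVAILABLE = "set of MHC available"
    TYPE_OF_EFFECTOR_T_CELL = "type of effector T cell"
    BIOLOGICAL_PROCESS_MEASURED = "biological process measured"


#: precedence: codes pinning exact molecules first, then set-level, then
#: class-level inference
CODE_PRECEDENCE = tuple(EvidenceCode)


class Effector(Enum):
    CD4 = "CD4"
    CD8 = "CD8"
    UNKNOWN = "unknown"


class Level(Enum):
    EXACT = "exact"
    SET = "set"
    CLASS = "class"


#: default biological-process → effector phenotype map; editable and
#: loadable from a file, since the code is defined but the map is lab lore
DEFAULT_PROCESS_EFFECTOR: dict[str, Effector] = {
    "cytotoxicity": Effector.CD8,
    "cytolysis": Effector.CD8,
    "b cell help": Effector.CD4,
    "antibody production": Effector.CD4,
    "delayed-type hypersensitivity": Effector.CD4,
}


def load_process_map(path: Union[str, Path]) -> dict[str, Effector]:
    """Read ``process<TAB>CD4|CD8`` lines; extends the default map."""
    out = dict(DEFAULT_PROCESS_EFFECTOR)
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        proc, _, eff = line.partition("\t")
        out[proc.strip().lower()] = Effector(eff.strip())
    return out


@dataclass(frozen=True)
class AssayContext:
    """Experimental context from which restriction can be inferred."""

    effector: Effector = Effector.UNKNOWN
    host_taxon: Optional[TermId] = None
    host_haplotypes: frozenset[TermId] = frozenset()
    single_available_molecule: Optional[TermId] = None
    apc_panel: tuple[tuple[frozenset[TermId], bool], ...] = ()
    antibody_defined_set: Optional[TermId] = None
    author_stated: Optional[TermId] = None
    ligand_assay_molecule: Optional[TermId] = None
    predicted_molecule: Optional[TermId] = None
    association_molecule: Optional[TermId] = None
    biological_process: Optional[str] = None
    assume_effector_class: bool = True

    def __post_init__(self):
        if self.single_available_molecule is not None and self.apc_panel:
            raise ValueError(
                "at most one of single_available_molecule / apc_panel may be set"
            )


@dataclass(frozen=True)
class RestrictionConclusion:
    """Candidate molecules, precision level, codes used and filter trace."""

    candidates: frozenset[TermId]
    level: Level
    codes: tuple[EvidenceCode, ...]
    trace: tuple[tuple[str, frozenset[TermId], frozenset[TermId]], ...]
    diagnostics: tuple[str, ...] = ()


def applicable_codes(c: AssayContext) -> list[EvidenceCode]:
    """Every code whose triggering field is populated, in precedence order."""
    populated = {
        EvidenceCode.AUTHOR_STATEMENT: c.author_stated is not None,
        EvidenceCode.MHC_LIGAND_ASSAY: c.ligand_assay_molecule is not None,
        EvidenceCode.MHC_BINDING_PREDICTION: c.predicted_molecule is not None,
        EvidenceCode.STATISTICAL_ASSOCIATION: c.association_molecule is not None,
        EvidenceCode.SINGLE_MHC_AVAILABLE: c.single_available_molecule is not None,
        EvidenceCode.REACTIVITY_DIFFERENT_MHC: bool(c.apc_panel),
        EvidenceCode.SET_OF_MHC_AVAILABLE: c.antibody_defined_set is not None,
        EvidenceCode.TYPE_OF_EFFECTOR_T_CELL: c.effector is not Effector.UNKNOWN,
        EvidenceCode.BIOLOGICAL_PROCESS_MEASURED: c.biological_process is not None,
    }
    return [code for code in CODE_PRECEDENCE if populated[code]]


def _class_filter_term(o: Ontology, effector: Effector) -> TermId:
    label = CLASS_II_LABEL if effector is Effector.CD4 else CLASS_I_LABEL
    return o.get_by_label(label).id


def _host_species(c: AssayContext, o: Ontology, h: InferredHierarchy) -> set[TermId]:
    if c.host_taxon is not None:
        return {c.host_taxon}
    out: set[TermId] = set()
    for hap in c.host_haplotypes:
        if o[hap].branch is not Branch.HAPLOTYPE:
            raise WrongBranchError(f"{hap} is not a haplotype")
        for sp in o.branch_ids(Branch.TAXON):
            if h.related_to(hap, Relation.IN_TAXON, sp):
                out.add(sp)
    return out


def infer_restriction(
    c: AssayContext,
    o: Ontology,
    h: InferredHierarchy,
    process_map: Optional[dict[str, Effector]] = None,
) -> RestrictionConclusion:
    """Narrow the candidate molecule set from the assay context.

    All filters are set intersections (the APC panel additionally
    subtracts non-responding conditions), so the final set is independent
    of application order and removing evidence can only grow it.  An empty
    result is reported as a diagnostic, not raised.
    """
    process_map = DEFAULT_PROCESS_EFFECTOR if process_map is None else process_map
    diagnostics: list[str] = []
    codes: list[EvidenceCode] = []
    trace: list[tuple[str, frozenset[TermId], frozenset[TermId]]] = []

    species = _host_species(c, o, h)
    mutants = mutant_molecules(o, h)
    pool = set(o.molecule_ids()) - mutants
    if species:
        cur = {
            m
            for m in pool
            if any(h.related_to(m, Relation.IN_TAXON, sp) for sp in species)
        }
    else:
        cur = set(pool)

    def apply(step: str, new: set[TermId], code: Optional[EvidenceCode]):
        nonlocal cur
        before = frozenset(cur)
        cur = new
        trace.append((step, before, frozenset(cur)))
        if code is not None:
            codes.append(code)

    # class-level evidence
    if c.effector is not Effector.UNKNOWN and c.assume_effector_class:
        term = _class_filter_term(o, c.effector)
        apply(
            "type of effector T cell",
            cur & molecules_under(term, o, h),
            EvidenceCode.TYPE_OF_EFFECTOR_T_CELL,
        )
    if c.biological_process is not None:
        eff = process_map.get(c.biological_process.strip().lower())
        if eff is None:
            diagnostics.append(
                f"unknown biological process {c.biological_process!r}; no filter applied"
            )
        else:
            term = _class_filter_term(o, eff)
            apply(
                "biological process measured",
                cur & molecules_under(term, o, h),
                EvidenceCode.BIOLOGICAL_PROCESS_MEASURED,
            )

    # host genetic background (no dedicated evidence code)
    if c.host_haplotypes:
        in_haps: set[TermId] = set()
        for hap in sorted(c.host_haplotypes):
            in_haps |= molecules_in_haplotype(hap, o, h)
        apply("host haplotypes", cur & in_haps, None)

    # set-level experimental evidence
    if c.antibody_defined_set is not None:
        apply(
            "set of MHC available",
            cur & molecules_under(c.antibody_defined_set, o, h),
            EvidenceCode.SET_OF_MHC_AVAILABLE,
        )
    if c.apc_panel:
        new = set(cur)
        for available, responded in c.apc_panel:
            if responded:
                new &= set(available)
            else:
                new -= set(available)
        apply(
            "reactivity of same T cells with different MHC",
            new,
            EvidenceCode.REACTIVITY_DIFFERENT_MHC,
        )

    # exact evidence
    exact_sets: list[tuple[EvidenceCode, set[TermId]]] = []
    if c.single_available_molecule is not None:
        exact_sets.append(
            (
                EvidenceCode.SINGLE_MHC_AVAILABLE,
                molecules_under(c.single_available_molecule, o, h, include_mutants=True),
            )
        )
    for code, term in (
        (EvidenceCode.AUTHOR_STATEMENT, c.author_stated),
        (EvidenceCode.MHC_LIGAND_ASSAY, c.ligand_assay_molecule),
        (EvidenceCode.MHC_BINDING_PREDICTION, c.predicted_molecule),
        (EvidenceCode.STATISTICAL_ASSOCIATION, c.association_molecule),
    ):
        if term is not None:
            exact_sets.append((code, molecules_under(term, o, h, include_mutants=True)))
    for code, mset in exact_sets:
        apply(code.value, cur & mset, code)
    if len(exact_sets) > 1:
        sets = [frozenset(s) for _, s in exact_sets]
        if len(set(sets)) > 1 and not frozenset.intersection(*sets):
            diagnostics.append(
                "conflicting exact evidence: "
                + "; ".join(
                    f"{code.value} -> " + ", ".join(sorted(o.label_of(m) for m in s))
                    for code, s in exact_sets
                )
            )

    if not cur:
        diagnostics.append("empty candidate set: evidence is contradictory")

    ordered = tuple(code for code in CODE_PRECEDENCE if code in codes)
    class_level = {
        EvidenceCode.TYPE_OF_EFFECTOR_T_CELL,
        EvidenceCode.BIOLOGICAL_PROCESS_MEASURED,
    }
    if len(cur) == 1:
        level = Level.EXACT
    elif ordered and set(ordered) <= class_level and not c.host_haplotypes:
        level = Level.CLASS
    else:
        level = Level.SET
    return RestrictionConclusion(
        candidates=frozenset(cur),
        level=level,
        codes=ordered,
        trace=tuple(trace),
        diagnostics=tuple(diagnostics),
    )
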