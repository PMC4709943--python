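"""Built-in example ontology and random-ontology generation.

:func:`example_ontology` builds a small but complete ontology exercising
all eight branch design patterns: three molecule categories (class I,
class II, non-classical); a human branch with HLA-A (class I: alpha chain
plus the invariant beta-2 microglobulin) and HLA-DP (class II: alpha plus
beta chain, with DPA1/DPB1 sub-loci under DP, a fully specified
DPA1*02:01/DPB1*01:01 molecule and a generic DPB1*04:02 molecule whose
alpha partner is an unspecified HLA-DPA chain); serotypes A2 and the
A9 → A23/A24 split; a mouse branch whose H2d haplotype carries the class
II molecules H2-IAd and H2-IEd plus the class I H2-Kd; a chicken
haplotype stub; an engineered point mutant linked to its natural
counterpart; and the nine restriction evidence codes.

:func:`random_ontology` draws small seed-controlled ontologies whose axiom
shapes mirror those patterns; they drive the reasoner-versus-brute-force
cross-checks and serialization round-trip tests.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Optional, Union

from .errors import GenerationError
from .model import (
    Atom,
    Branch,
    Conjunction,
    EquivalentTo,
    Existential,
    OntClass,
    Ontology,
    Relation,
    SubClassOf,
    TermId,
)
from .templates import BranchTable, IDRegistry, compile_ontology

# table names in compilation order (also the emitted file names)
BRANCH_ORDER = (
    "taxon",
    "locus",
    "chain",
    "haplotype",
    "serotype",
    "molecule",
    "mutant",
    "evidence",
)

_B2M_COMMENT = (
    "invariant second chain of every class I complex; "
    "encoded outside the MHC locus"
)

_TABLE_SPECS: dict[str, tuple[tuple[str, ...], tuple[str, ...], tuple[tuple[str, ...], ...]]] = {
    "taxon": (
        ("ID", "Label", "Parent"),
        ("ID", "LABEL", "SC %"),
        (
            ("NCBITaxon:9606", "Homo sapiens", "organism"),
            ("NCBITaxon:10090", "Mus musculus", "organism"),
            ("NCBITaxon:9031", "Gallus gallus", "organism"),
        ),
    ),
    "locus": (
        ("ID", "Label", "Parent", "In Taxon"),
        ("ID", "LABEL", "SC %", "SC 'in taxon' some %"),
        (
            ("", "MHC locus", "genetic locus", ""),
            ("", "HLA-A locus", "MHC locus", "Homo sapiens"),
            ("", "HLA-DP locus", "MHC locus", "Homo sapiens"),
            ("", "HLA-DPA1 locus", "HLA-DP locus", "Homo sapiens"),
            ("", "HLA-DPB1 locus", "HLA-DP locus", "Homo sapiens"),
            ("", "H2-IA locus", "MHC locus", "Mus musculus"),
            ("", "H2-IE locus", "MHC locus", "Mus musculus"),
            ("", "H2-K locus", "MHC locus", "Mus musculus"),
        ),
    ),
    "chain": (
        (
            "ID",
            "Label",
            "Branch",
            "Parent",
            "Encoding Locus",
            "In Taxon",
            "Serotype",
            "Haplotype",
            "Synonyms",
            "Comment",
        ),
        (
            "ID",
            "LABEL",
            "BRANCH",
            "SC %",
            "SC 'gene product of' some %",
            "SC 'in taxon' some %",
            "SC 'has serotype' some %",
            "SC 'part of haplotype' some %",
            "SYNONYMS",
            "A comment",
        ),
        (
            ("", "MHC chain", "other", "protein", "", "", "", "", "", ""),
            (
                "",
                "beta-2 microglobulin",
                "",
                "protein",
                "",
                "",
                "",
                "",
                "β2m|β2 microglobulin|B2M",
                _B2M_COMMENT,
            ),
            ("", "HLA-A chain", "", "MHC chain", "HLA-A locus", "Homo sapiens", "", "", "", ""),
            ("", "HLA-A*02:01 chain", "", "HLA-A chain", "", "", "A2", "", "HLA-A*0201 chain", ""),
            ("", "HLA-A*23:01 chain", "", "HLA-A chain", "", "", "A23", "", "HLA-A*2301 chain", ""),
            ("", "HLA-DPA chain", "", "MHC chain", "HLA-DPA1 locus", "Homo sapiens", "", "", "", ""),
            ("", "HLA-DPB chain", "", "MHC chain", "HLA-DPB1 locus", "Homo sapiens", "", "", "", ""),
            ("", "HLA-DPA1*02:01 chain", "", "HLA-DPA chain", "", "", "", "", "HLA-DPA1*0201 chain", ""),
            ("", "HLA-DPB1*01:01 chain", "", "HLA-DPB chain", "", "", "", "", "HLA-DPB1*0101 chain", ""),
            ("", "HLA-DPB1*04:02 chain", "", "HLA-DPB chain", "", "", "", "", "HLA-DPB1*0402 chain", ""),
            ("", "H2-IAd alpha chain", "", "MHC chain", "H2-IA locus", "Mus musculus", "", "H2d haplotype", "", ""),
            ("", "H2-IAd beta chain", "", "MHC chain", "H2-IA locus", "Mus musculus", "", "H2d haplotype", "", ""),
            ("", "H2-IEd alpha chain", "", "MHC chain", "H2-IE locus", "Mus musculus", "", "H2d haplotype", "", ""),
            ("", "H2-IEd beta chain", "", "MHC chain", "H2-IE locus", "Mus musculus", "", "H2d haplotype", "", ""),
            ("", "H2-Kd alpha chain", "", "MHC chain", "H2-K locus", "Mus musculus", "", "H2d haplotype", "", ""),
        ),
    ),
    "haplotype": (
        ("ID", "Label", "Parent", "In Taxon", "Synonyms"),
        ("ID", "LABEL", "SC %", "SC 'in taxon' some %", "SYNONYMS"),
        (
            ("", "MHC haplotype", "", "", ""),
            ("", "H2d haplotype", "MHC haplotype", "Mus musculus", "H-2d"),
            ("", "B21 haplotype", "MHC haplotype", "Gallus gallus", ""),
        ),
    ),
    "serotype": (
        ("ID", "Label", "Parent", "Comment"),
        ("ID", "LABEL", "SC %", "A comment"),
        (
            (
                "",
                "MHC serotype",
                "information content entity",
                "serotype membership depends on the antibody panel used, "
                "so serotypes are modeled as information entities",
            ),
            ("", "A2", "MHC serotype", ""),
            ("", "A9", "MHC serotype", ""),
            ("", "A23", "A9", "split of A9 under a finer antibody panel"),
            ("", "A24", "A9", "split of A9 under a finer antibody panel"),
        ),
    ),
    "molecule": (
        (
            "ID",
            "Label",
            "Branch",
            "Parent",
            "In Taxon",
            "Category",
            "Alpha Chain",
            "Beta Chain",
            "Synonyms",
            "Fully Specified",
        ),
        (
            "ID",
            "LABEL",
            "BRANCH",
            "SC %",
            "SC 'in taxon' some %",
            "EC %",
            "EC 'has part' some %",
            "EC 'has part' some %",
            "SYNONYMS",
            "FULLY SPECIFIED",
        ),
        (
            ("", "MHC protein complex", "other", "protein complex", "", "", "", "", "", ""),
            ("", "MHC class I protein complex", "other", "MHC protein complex", "", "", "", "", "", ""),
            ("", "MHC class II protein complex", "other", "MHC protein complex", "", "", "", "", "", ""),
            ("", "non-classical MHC protein complex", "other", "MHC protein complex", "", "", "", "", "", ""),
            (
                "",
                "HLA-A*02:01 molecule",
                "",
                "",
                "Homo sapiens",
                "MHC class I protein complex",
                "HLA-A*02:01 chain",
                "beta-2 microglobulin",
                "HLA-A*0201",
                "true",
            ),
            (
                "",
                "HLA-A*23:01 molecule",
                "",
                "",
                "Homo sapiens",
                "MHC class I protein complex",
                "HLA-A*23:01 chain",
                "beta-2 microglobulin",
                "HLA-A*2301",
                "true",
            ),
            (
                "",
                "HLA-DPA1*02:01/DPB1*01:01 molecule",
                "",
                "",
                "Homo sapiens",
                "MHC class II protein complex",
                "HLA-DPA1*02:01 chain",
                "HLA-DPB1*01:01 chain",
                "HLA-DPA1*0201/DPB1*0101",
                "true",
            ),
            (
                "",
                "HLA-DPA1*02:01/DPB1*04:02 molecule",
                "",
                "",
                "Homo sapiens",
                "MHC class II protein complex",
                "HLA-DPA1*02:01 chain",
                "HLA-DPB1*04:02 chain",
                "HLA-DPA1*0201/DPB1*0402",
                "true",
            ),
            (
                "",
                "HLA-DPB1*04:02 molecule",
                "",
                "",
                "Homo sapiens",
                "MHC class II protein complex",
                "HLA-DPA chain",
                "HLA-DPB1*04:02 chain",
                "",
                "false",
            ),
            (
                "",
                "H2-IAd molecule",
                "",
                "",
                "Mus musculus",
                "MHC class II protein complex",
                "H2-IAd alpha chain",
                "H2-IAd beta chain",
                "I-Ad|H-2 IAd",
                "true",
            ),
            (
                "",
                "H2-IEd molecule",
                "",
                "",
                "Mus musculus",
                "MHC class II protein complex",
                "H2-IEd alpha chain",
                "H2-IEd beta chain",
                "I-Ed|H-2 IEd",
                "true",
            ),
            (
                "",
                "H2-Kd molecule",
                "",
                "",
                "Mus musculus",
                "MHC class I protein complex",
                "H2-Kd alpha chain",
                "beta-2 microglobulin",
                "Kd|H-2 Kd",
                "true",
            ),
        ),
    ),
    "mutant": (
        ("ID", "Label", "Branch", "Parent", "Natural Variant", "In Taxon", "Fully Specified"),
        (
            "ID",
            "LABEL",
            "BRANCH",
            "SC %",
            "SC 'mutant of' some %",
            "SC 'in taxon' some %",
            "FULLY SPECIFIED",
        ),
        (
            (
                "",
                "HLA-A*02:01 K66A mutant molecule",
                "molecule",
                "MHC class I protein complex",
                "HLA-A*02:01 molecule",
                "Homo sapiens",
                "true",
            ),
        ),
    ),
    "evidence": (
        ("ID", "Label", "Parent", "Definition"),
        ("ID", "LABEL", "SC %", "A definition"),
        (
            (
                "",
                "MHC restriction evidence",
                "information content entity",
                "record of how an epitope's restricting MHC molecule was established",
            ),
            (
                "",
                "author statement",
                "MHC restriction evidence",
                "the authors report a previously determined restriction",
            ),
            (
                "",
                "MHC ligand assay",
                "MHC restriction evidence",
                "the epitope was bound by or eluted from the MHC molecule",
            ),
            (
                "",
                "MHC binding prediction",
                "MHC restriction evidence",
                "a computational algorithm predicted binding of the epitope to the molecule",
            ),
            (
                "",
                "statistical association",
                "MHC restriction evidence",
                "recognition patterns across a typed study population implicate the molecule",
            ),
            (
                "",
                "single MHC available",
                "MHC restriction evidence",
                "T cells responded when only a single MHC molecule was available",
            ),
            (
                "",
                "reactivity of same T cells with different MHC",
                "MHC restriction evidence",
                "differential response with antigen-presenting cells expressing different MHC",
            ),
            (
                "",
                "set of MHC available",
                "MHC restriction evidence",
                "antibody blocking or purification narrowed restriction to a set such as a locus",
            ),
            (
                "",
                "type of effector T cell",
                "MHC restriction evidence",
                "CD8 effectors imply class I restriction, CD4 effectors class II",
            ),
            (
                "",
                "biological process measured",
                "MHC restriction evidence",
                "the measured response implies the effector phenotype and hence the class",
            ),
        ),
    ),
}


def example_tables() -> list[BranchTable]:
    """The example ontology as branch templates, in compilation order."""
    out = []
    for name in BRANCH_ORDER:
        header, patterns, rows = _TABLE_SPECS[name]
        out.append(
            BranchTable(name=name, header=header, patterns=patterns, rows=rows)
        )
    return out


def example_ontology(registry: Optional[IDRegistry] = None) -> Ontology:
    """Compile the built-in example ontology (validates clean)."""
    return compile_ontology(
        example_tables(), registry=registry, name="mhc-restriction-example"
    )


def render_table(t: BranchTable) -> str:
    """Deterministic TSV rendering (UTF-8, LF, no quoting)."""
    lines = ["\t".join(t.header), "\t".join(t.patterns)]
    lines.extend("\t".join(row) for row in t.rows)
    return "\n".join(lines) + "\n"


def write_example_templates(directory: Union[str, Path]) -> list[Path]:
    """Emit the example as one ``<branch>.tsv`` per branch; compiling the
    emitted files reproduces :func:`example_ontology` exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for t in example_tables():
        path = directory / f"{t.name}.tsv"
        path.write_text(render_table(t), encoding="utf-8", newline="\n")
        out.append(path)
    return out


# ---------------------------------------------------------------------------
# random assay contexts (for narrowing-property checks)
# ---------------------------------------------------------------------------


def random_assay_context(seed: int, o: Ontology):
    """Draw one :class:`~mhcrestrict.evidence.AssayContext` over the
    example ontology, populating a random subset of evidence fields.

    Used to exercise the monotone-narrowing property: removing any one
    populated field from the returned context must never shrink the
    inferred candidate set.
    """
    from .evidence import AssayContext, Effector

    rng = random.Random(seed)

    def lid(label):
        return o.get_by_label(label).id

    molecules = [t for t in o.molecule_ids()]
    kwargs: dict = {}
    kwargs["effector"] = rng.choice(
        (Effector.UNKNOWN, Effector.UNKNOWN, Effector.CD4, Effector.CD8)
    )
    if rng.random() < 0.3:
        kwargs["host_taxon"] = rng.choice(o.branch_ids(Branch.TAXON))
    if rng.random() < 0.4:
        kwargs["host_haplotypes"] = frozenset(
            {lid(rng.choice(("H2d haplotype", "B21 haplotype")))}
        )
    if rng.random() < 0.3:
        kwargs["antibody_defined_set"] = lid(
            rng.choice(
                ("MHC class II protein complex", "HLA-A chain", "HLA-DPB chain")
            )
        )
    r = rng.random()
    if r < 0.25:
        kwargs["single_available_molecule"] = rng.choice(molecules)
    elif r < 0.5:
        panel = []
        for _ in range(rng.randint(1, 3)):
            avail = frozenset(rng.sample(molecules, rng.randint(1, 3)))
            panel.append((avail, rng.random() < 0.6))
        kwargs["apc_panel"] = tuple(panel)
    for f in (
        "author_stated",
        "ligand_assay_molecule",
        "predicted_molecule",
        "association_molecule",
    ):
        if rng.random() < 0.2:
            kwargs[f] = rng.choice(molecules)
    if rng.random() < 0.3:
        kwargs["biological_process"] = rng.choice(
            ("cytotoxicity", "b cell help", "antibody production", "levitation")
        )
    return AssayContext(**kwargs)


# ---------------------------------------------------------------------------
# random ontologies
# ---------------------------------------------------------------------------


def random_ontology(seed: int, n_classes: int, n_axioms: int) -> Ontology:
    """Draw a small valid ontology inside the implemented fragment.

    Deterministic for a given seed.  Axiom shapes follow the branch design
    patterns: told atomic subclasses (oriented to keep the told hierarchy
    acyclic), told existentials, and definitional equivalences whose
    expression is a conjunction of atoms and existentials with atomic
    fillers (so every instance is also OBO-expressible).
    """
    if n_classes < 1:
        raise GenerationError("need at least one class")
    if n_axioms > 0 and n_classes < 2:
        raise GenerationError("axioms need at least two classes")
    rng = random.Random(seed)
    o = Ontology(name=f"random-{seed}")
    terms = [TermId("TST", f"{i + 1:07d}") for i in range(n_classes)]
    for i, t in enumerate(terms):
        o.add_class(OntClass(id=t, label=f"test class {i + 1:03d}"))

    seen: set = set()
    defined: set[TermId] = set()
    attempts = 0
    while len(seen) < n_axioms:
        attempts += 1
        if attempts > 200 * n_axioms + 1000:
            raise GenerationError(
                f"cannot draw {n_axioms} distinct axioms over {n_classes} classes"
            )
        shape = rng.random()
        if shape < 0.5:
            i = rng.randrange(1, n_classes)
            k = rng.randrange(0, i)
            ax = SubClassOf(terms[i], Atom(terms[k]))
        elif shape < 0.75:
            i = rng.randrange(0, n_classes)
            k = rng.randrange(0, n_classes)
            rel = rng.choice(list(Relation))
            ax = SubClassOf(terms[i], Existential(rel, Atom(terms[k])))
        else:
            candidates = [t for t in terms if t not in defined]
            if not candidates or n_classes < 3:
                continue
            subject = rng.choice(candidates)
            n_conj = rng.choice((2, 2, 3))
            conjuncts = []
            pool = [t for t in terms if t != subject]
            rng.shuffle(pool)
            for t in pool[:n_conj]:
                if rng.random() < 0.4:
                    conjuncts.append(
                        Existential(rng.choice(list(Relation)), Atom(t))
                    )
                else:
                    conjuncts.append(Atom(t))
            if len(conjuncts) < 2 or len(set(conjuncts)) < 2:
                continue
            ax = EquivalentTo(subject, Conjunction(tuple(conjuncts)))
        if ax in seen:
            continue
        seen.add(ax)
        if isinstance(ax, EquivalentTo):
            defined.add(ax.term)
        o.add_axiom(ax)
    return o
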