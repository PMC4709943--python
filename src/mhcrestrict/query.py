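"""Expand restriction queries to molecule sets and build browse trees.

Query semantics follow how an epitope database needs to search restriction
data: a query on a chain means "molecules containing such a chain" (so a
serotype attached to one chain finds every complex the chain occurs in,
and a query for a generic chain finds the generic molecule as well as
every fully specified molecule containing a matching chain); a query on a
haplotype finds molecules at least one of whose chains belongs to the
haplotype; serotype queries include serotype splits below the queried
term.  Engineered (mutant) molecules are excluded unless asked for.

The tree builder produces the three hierarchical browse views: by locus
(class category → species → locus/sub-locus → molecules), by haplotype
and by serotype (species → grouping term → molecules).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import UnknownTermError, WrongBranchError
from .model import (
    Branch,
    CATEGORY_LABELS,
    Ontology,
    Relation,
    TermId,
)
from .reasoner import InferredHierarchy


def _check_declared(t: TermId, o: Ontology) -> None:
    if t not in o:
        raise UnknownTermError(f"term not declared: {t}")


def mutant_molecules(o: Ontology, h: InferredHierarchy) -> set[TermId]:
    """Molecule-branch classes linked to a natural molecule via 'mutant of'."""
    lhs = {a for (a, _) in h.role_pairs(Relation.MUTANT_OF)}
    return {m for m in o.molecule_ids() if m in lhs}


def _molecule_chains(m: TermId, h: InferredHierarchy) -> set[TermId]:
    """Fillers (possibly internal) f with m ⊑ ∃'has part'.f."""
    return {y for (a, y) in h.role_pairs(Relation.HAS_PART) if a == m}


def molecules_under(
    t: TermId,
    o: Ontology,
    h: InferredHierarchy,
    include_mutants: bool = False,
) -> set[TermId]:
    """Molecules subsumed by ``t``; for a chain class, molecules containing
    a chain subsumed by ``t``."""
    _check_declared(t, o)
    mutants = mutant_molecules(o, h)
    out: set[TermId] = set()
    chain_query = o[t].branch is Branch.CHAIN
    for m in o.molecule_ids():
        if (m, t) in h.subsumptions:
            out.add(m)
        elif chain_query:
            for f in _molecule_chains(m, h):
                if t in h.implied_superclasses(f):
                    out.add(m)
                    break
    if not include_mutants:
        out -= mutants
    return out


def molecules_with_serotype(
    s: TermId, o: Ontology, h: InferredHierarchy
) -> set[TermId]:
    """Molecules having some chain carrying serotype ``s`` or a serotype
    below it (serotype splits are included via their parent links)."""
    _check_declared(s, o)
    if o[s].branch is not Branch.SEROTYPE:
        raise WrongBranchError(f"{s} ({o.label_of(s)!r}) is not a serotype")
    # chains whose has-serotype filler lies at or below s
    chains = {
        c
        for (c, y) in h.role_pairs(Relation.HAS_SEROTYPE)
        if s in h.implied_superclasses(y)
    }
    out: set[TermId] = set()
    for m in o.molecule_ids():
        for f in _molecule_chains(m, h):
            if h.implied_superclasses(f) & chains:
                out.add(m)
                break
    return out


def molecules_in_haplotype(
    hap: TermId,
    o: Ontology,
    h: InferredHierarchy,
    class_filter: Optional[TermId] = None,
) -> set[TermId]:
    """Molecules with at least one chain belonging to haplotype ``hap``,
    optionally intersected with a class-category filter."""
    _check_declared(hap, o)
    if o[hap].branch is not Branch.HAPLOTYPE:
        raise WrongBranchError(f"{hap} ({o.label_of(hap)!r}) is not a haplotype")
    if class_filter is not None:
        _check_declared(class_filter, o)
    members = {
        c
        for (c, y) in h.role_pairs(Relation.PART_OF_HAPLOTYPE)
        if hap in h.implied_superclasses(y)
    }
    out: set[TermId] = set()
    for m in o.molecule_ids():
        for f in _molecule_chains(m, h):
            if h.implied_superclasses(f) & members:
                out.add(m)
                break
    if class_filter is not None:
        out = {m for m in out if (m, class_filter) in h.subsumptions}
    return out


# ---------------------------------------------------------------------------
# browse trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeNode:
    id: TermId
    label: str
    children: tuple["TreeNode", ...] = ()

    def leaf_labels(self) -> set[str]:
        if not self.children:
            return {self.label}
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_labels()
        return out

    def leaf_ids(self) -> set[TermId]:
        if not self.children:
            return {self.id}
        out: set[TermId] = set()
        for c in self.children:
            out |= c.leaf_ids()
        return out

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()


@dataclass(frozen=True)
class Tree:
    view: str  # locus | haplotype | serotype
    roots: tuple[TreeNode, ...]

    def iter_nodes(self):
        for r in self.roots:
            yield from r.iter_nodes()


def _sorted_children(nodes: list[TreeNode]) -> tuple[TreeNode, ...]:
    return tuple(sorted(nodes, key=lambda n: n.label))


def _species_of(o: Ontology, h: InferredHierarchy, t: TermId) -> set[TermId]:
    return {
        sp for sp in o.branch_ids(Branch.TAXON) if h.related_to(t, Relation.IN_TAXON, sp)
    }


def build_tree(
    view: str, o: Ontology, h: InferredHierarchy, include_mutants: bool = False
) -> Tree:
    """Build one browse view over a classified ontology.

    ``locus``: roots are the three molecule categories; species under each
    category; loci (with sub-loci nested) under species; molecules attach
    at the most specific locus covering all their chains.  ``haplotype``
    and ``serotype``: species roots with grouping terms under them and
    molecules as leaves.  Children are sorted by label and internal
    reasoner names never appear.
    """
    if view == "locus":
        return _locus_tree(o, h, include_mutants)
    if view == "haplotype":
        return _haplotype_tree(o, h)
    if view == "serotype":
        return _serotype_tree(o, h)
    raise ValueError(f"unknown view: {view!r}")


def _molecule_pool(o, h, include_mutants):
    mols = set(o.molecule_ids())
    if not include_mutants:
        mols -= mutant_molecules(o, h)
    return mols


def _minimal(ts: set[TermId], h: InferredHierarchy) -> set[TermId]:
    return {
        t
        for t in ts
        if not any(u != t and (u, t) in h.subsumptions for u in ts)
    }


def _chain_loci(f: TermId, o: Ontology, h: InferredHierarchy) -> set[TermId]:
    """Most specific declared loci encoding chain (filler) ``f``."""
    loci = set()
    for y in h.implied_superclasses(f):
        for (a, l) in h.role_pairs(Relation.GENE_PRODUCT_OF):
            if a == y:
                loci |= {
                    d
                    for d in h.implied_superclasses(l)
                    if d in o and o[d].branch is Branch.LOCUS
                }
    return _minimal(loci, h)


def _locus_tree(o: Ontology, h: InferredHierarchy, include_mutants: bool) -> Tree:
    mols = _molecule_pool(o, h, include_mutants)
    categories = [o.get_by_label(lbl) for lbl in CATEGORY_LABELS]
    roots = []
    for cat in categories:
        cat_mols = {m for m in mols if (m, cat.id) in h.subsumptions}
        species_nodes = []
        for sp in o.branch_ids(Branch.TAXON):
            sp_mols = {m for m in cat_mols if h.related_to(m, Relation.IN_TAXON, sp)}
            if not sp_mols:
                continue
            species_nodes.append(_species_locus_node(sp, sp_mols, o, h))
        roots.append(
            TreeNode(id=cat.id, label=cat.label, children=_sorted_children(species_nodes))
        )
    return Tree(view="locus", roots=tuple(roots))


def _species_locus_node(
    sp: TermId, sp_mols: set[TermId], o: Ontology, h: InferredHierarchy
) -> TreeNode:
    # loci to display: each chain's own locus and its ancestors; molecules
    # attach at the most specific locus subsuming all their chains' loci
    shown: set[TermId] = set()
    attach: dict[TermId, set[TermId]] = {}
    orphans: set[TermId] = set()
    all_loci = set(o.branch_ids(Branch.LOCUS))
    species_loci = {
        l for l in all_loci if h.related_to(l, Relation.IN_TAXON, sp)
    }
    for m in sorted(sp_mols):
        per_chain = [
            _chain_loci(f, o, h) & species_loci for f in _molecule_chains(m, h)
        ]
        per_chain = [ls for ls in per_chain if ls]
        if not per_chain:
            orphans.add(m)
            continue
        common: Optional[set[TermId]] = None
        for ls in per_chain:
            shown |= ls
            up = set()
            for l in ls:
                up |= {
                    a
                    for a in h.implied_superclasses(l)
                    if a in species_loci and (l, a) in h.subsumptions
                }
            common = up if common is None else common & up
        site = _minimal(common or set(), h)
        if site:
            target = sorted(site)[0]
            shown |= {
                a for a in common if any((s, a) in h.subsumptions for s in site)
            }
            attach.setdefault(target, set()).add(m)
        else:
            orphans.add(m)
    # ancestors of shown loci within the species
    closed = set(shown)
    for l in shown:
        closed |= {a for a in h.implied_superclasses(l) if a in species_loci}

    def locus_node(l: TermId) -> TreeNode:
        kids = [
            locus_node(c)
            for c in sorted(closed)
            if c != l and l in h.direct_parents.get(c, ())
        ]
        kids += [
            TreeNode(id=m, label=o.label_of(m)) for m in sorted(attach.get(l, ()))
        ]
        return TreeNode(id=l, label=o.label_of(l), children=_sorted_children(kids))

    tops = [
        l
        for l in sorted(closed)
        if not any(p in closed for p in h.direct_parents.get(l, ()))
    ]
    kids = [locus_node(l) for l in tops]
    kids += [TreeNode(id=m, label=o.label_of(m)) for m in sorted(orphans)]
    return TreeNode(id=sp, label=o.label_of(sp), children=_sorted_children(kids))


def _haplotype_tree(o: Ontology, h: InferredHierarchy) -> Tree:
    roots = []
    for sp in o.branch_ids(Branch.TAXON):
        haps = [
            hp
            for hp in o.branch_ids(Branch.HAPLOTYPE)
            if h.related_to(hp, Relation.IN_TAXON, sp)
        ]
        if not haps:
            continue
        hap_nodes = []
        for hp in haps:
            leaves = [
                TreeNode(id=m, label=o.label_of(m))
                for m in sorted(molecules_in_haplotype(hp, o, h))
            ]
            hap_nodes.append(
                TreeNode(id=hp, label=o.label_of(hp), children=_sorted_children(leaves))
            )
        roots.append(
            TreeNode(id=sp, label=o.label_of(sp), children=_sorted_children(hap_nodes))
        )
    return Tree(view="haplotype", roots=_sorted_children(roots))


def _serotype_tree(o: Ontology, h: InferredHierarchy) -> Tree:
    serotypes = o.branch_ids(Branch.SEROTYPE)
    roots = []
    for sp in o.branch_ids(Branch.TAXON):
        sp_mols = {
            m for m in o.molecule_ids() if h.related_to(m, Relation.IN_TAXON, sp)
        }
        shown = {
            s
            for s in serotypes
            if molecules_with_serotype(s, o, h) & sp_mols
        }
        if not shown:
            continue

        def sero_node(s: TermId) -> TreeNode:
            kids = [
                sero_node(c)
                for c in sorted(shown)
                if c != s and s in h.direct_parents.get(c, ())
            ]
            covered: set[TermId] = set()
            for c in shown:
                if c != s and (c, s) in h.subsumptions:
                    covered |= molecules_with_serotype(c, o, h)
            own = (molecules_with_serotype(s, o, h) & sp_mols) - covered
            kids += [TreeNode(id=m, label=o.label_of(m)) for m in sorted(own)]
            return TreeNode(id=s, label=o.label_of(s), children=_sorted_children(kids))

        tops = [
            s
            for s in sorted(shown)
            if not any(p in shown for p in h.direct_parents.get(s, ()))
        ]
        roots.append(
            TreeNode(
                id=sp,
                label=o.label_of(sp),
                children=_sorted_children([sero_node(s) for s in tops]),
            )
        )
    return Tree(view="serotype", roots=_sorted_children(roots))
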