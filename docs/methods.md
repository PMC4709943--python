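# Methods

## The model

MHC molecules are modeled as defined classes in a small description-logic
fragment: atomic classes, conjunction, and existential restriction over six
object relations (`has part`, `gene product of`, `in taxon` — reused from
the Relation Ontology — plus the artifact-defined `has serotype`,
`part of haplotype`, `mutant of`). Eight branch design patterns cover the
domain:

- **taxon** — species, referenced by NCBI Taxonomy identifiers.
- **locus** — genetic loci, nested where sub-loci are useful
  (`HLA-DPA1 locus` ⊑ `HLA-DP locus`); each locus is `in taxon` a species.
- **chain** — MHC protein chains, `gene product of` a locus, optionally
  carrying serotypes and haplotype membership. Generic chains
  (`HLA-DPA chain`) are locus-level placeholders for a chain that an
  experiment did not identify. Beta-2 microglobulin is a chain that is
  deliberately *not* under the MHC chain root and has no encoding locus:
  it is invariant and encoded outside the MHC region.
- **molecule** — protein complexes with definitional equivalences: a
  class I molecule is `class I ⊓ ∃has_part.α ⊓ ∃has_part.β2m`, a class II
  molecule `class II ⊓ ∃has_part.α ⊓ ∃has_part.β`. Molecules using a
  generic chain are marked `fully_specified = false` but are first-class
  query results, because restriction data is stored at exactly that
  precision.
- **haplotype** — allele sets of a chromosome; chains join via
  `part of haplotype`.
- **serotype** — antibody-panel groupings. Because the grouping changes
  with the panel ("serotype splits"), serotypes are information entities:
  they may never occur as `has part` fillers (a validation invariant), and
  splits are told subclass links between serotype terms
  (`A23 ⊑ A9`) with the provenance in an annotation.
- **mutant** — engineered molecules. They are *not* subclasses of their
  natural counterpart (that would pollute restriction queries); the
  `mutant of` existential records the link, and queries exclude mutants
  unless asked.
- **evidence** — the nine restriction evidence codes, modeled as flat
  terms with textual definitions.

Foreign upper-level terms (protein complex, protein, organism, material
entity, information content entity, genetic locus) are declared with their
source-ontology identifiers but not re-axiomatized.

## Template compilation

Each branch is maintained as a TSV table: header row, pattern row, one data
row per class. The pattern mini-language (`SC %`, `SC 'rel' some %`,
`EC %`, `EC 'rel' some %`, `A key`, plus `ID`/`LABEL`/`SYNONYMS`/`BRANCH`/
`FULLY SPECIFIED`) implements only the constructs the eight patterns need.
All `EC` cells of a row form a single definitional equivalence whose
expression is the conjunction of the conjuncts — this is the two-chain
complex pattern, and it means a molecule row with a category cell and two
chain cells yields exactly one logical axiom.

Compilation declares all classes of all tables first, then compiles axioms,
so cross-table references resolve in any table order. Identifiers are
assigned sequentially from a label → id registry that can be persisted,
making recompilation stable and byte-deterministic; cell values resolve by
exact label match, falling back to MHC-name normalization so tables may use
legacy spellings.

## Reasoning

Every pattern lies in an EL-like fragment, so classification is done by a
fragment-specific procedure instead of a general OWL-DL reasoner:
normalization introduces internal names for nested subexpressions (defined
in both directions, preserving equivalence), and four completion rules
(told subsumption, conjunction, existential introduction, existential
elimination) are saturated to fixpoint with a worklist and per-axiom
indexes. The procedure is sound and complete for the fragment and
terminates after polynomially many rule applications (asserted in tests via
the firing counter). Internal names never appear in results or exports.

Declared equivalences between named classes merge into one node whose
canonical representative is the lexicographically smallest id; the
published `direct_parents` map is the transitive reduction (networkx) of
the quotient DAG. A deliberately naive cross-check
(`mhcrestrict.checks.naive_classify`) re-derives subsumption by fixpoint
iteration over the full subexpression lattice with no normalization, no
indexing and no worklist; the two independent code paths are compared
exactly on hundreds of random ontologies.

## Query semantics

A query on a chain class returns molecules *containing* a matching chain
(`∃has_part` filler subsumed by the chain), not chain subclasses — this is
what makes a serotype attached to a chain reach the finer-mapped molecule,
and what makes a generic chain query span both the generic molecule and
every fully specified complex using that chain. Haplotype queries return
molecules with at least one chain in the haplotype (requiring all chains
would wrongly exclude class I molecules, whose β2m belongs to no
haplotype). Serotype queries include split children via the told serotype
hierarchy.

The browse trees mirror the three views a restriction browser needs. In
the locus view, a molecule attaches at the most specific locus subsuming
all its chains' loci (a DP heterodimer with DPA1- and DPB1-encoded chains
attaches at DP, with both sub-loci shown underneath); molecules without
any locus-bearing chain attach directly under their species.

## Evidence inference

`infer_restriction` starts from all (non-mutant) molecules of the host
species — the host is taken from `host_taxon` or derived from the
haplotypes' species — and applies each populated evidence field as a set
filter: effector phenotype and biological process map to a class-category
filter; haplotypes intersect with the haplotype members; antibody-defined
sets and all exact statements intersect with the stated term's molecule
expansion; the APC panel intersects the available sets of responding
conditions and subtracts those of non-responding conditions (the standard
reading of differential APC reactivity, which the source material leaves
implicit). Because every step is an intersection or subtraction against
fixed sets, the final set is order-independent and removing any one field
can only grow it — both are property-tested. Host haplotype narrowing
carries no evidence code of its own (it is genetic background, not one of
the nine codes).

Choices made where the design was open: CD4 → class II / CD8 → class I is
a defeasible default, disabled per context with
`assume_effector_class=False`, since some class II-restricted T cells
express CD8. The biological-process → effector map ships as a small
editable default (cytotoxicity/cytolysis → CD8; B-cell help, antibody
production, delayed-type hypersensitivity → CD4) and can be replaced from
a file, because the code is defined but the mapping itself is lab
convention. Conflicting exact evidence keeps the intersection, reports
*all* codes involved and attaches a conflict diagnostic rather than
discarding either side; an empty final set is a returned diagnostic, never
an exception.

## Serialization

OBO 1.4 is the authoritative round-trip format: told atomic superclasses →
`is_a`, told existentials → `relationship`, definitional equivalences →
`intersection_of` blocks, branch membership and the fully-specified flag →
`subset` values, other annotations → `def`/`comment`/`property_value`.
The writer orders stanzas by id and tags canonically, so write → parse →
write is byte-identical on the supported subset (verified on the example
and random ontologies, and cross-checked structurally with `obonet`).
OWL 2 functional-style syntax is write-only; browse trees export as JSON
with stable key order. Nested fillers and other constructs outside the OBO
subset raise an export error naming the term.

## The example ontology and random generators

The built-in example (9 molecules, 63 classes) is the package's own
reference dataset, built from the same eight TSV templates the compiler
consumes, and exercises every pattern at least once: HLA-A and HLA-DP with
generic chains, the A9 → A23/A24 serotype split (a textbook split chosen
to exercise the machinery), the H2d haplotype with its two class II
molecules and one class I member, a chicken haplotype stub with no members
(haplotype content for birds is not modeled, only the grouping node), one
engineered mutant, and the nine evidence codes. It emulates the *structure*
of real restriction data, not its scale: real nomenclature feeds run to
thousands of alleles per species, carry four-field allele names, null and
expression variants, and far denser serotype tables. Passing tests
therefore demonstrate correctness of the machinery, not coverage of any
species' allele catalogue.

`random_ontology(seed, n_classes, n_axioms)` draws ontologies whose axiom
shapes mirror the branch patterns (atomic subclasses oriented acyclically,
told existentials, definitional conjunctions with atomic fillers — all
OBO-expressible), and `random_assay_context` draws evidence combinations
over the example. Test and acceptance problem sizes — 200 random
ontologies of ≤ 40 classes / ≤ 60 axioms for the reasoner cross-check,
100 random contexts for the narrowing property, 50 for round-trips — keep
the whole suite in seconds while saturating the rule set; the naive oracle
is quadratic-to-cubic in the subexpression count and is the limiting
factor at larger sizes.

## Known limitations

- The logical fragment has no inverse roles, universal restriction,
  negation or cardinality; two-chain composition is expressed by two
  existentials, not an exact-cardinality constraint.
- Serotype assignment attaches to chains, not to chain/peptide complexes;
  panel provenance is an annotation, not a modeled experiment.
- The dialect registry ships with six species prefixes (human, mouse,
  cattle, horse, dog, chicken) and is extensible by configuration; exotic
  nomenclature features (expression suffixes, four-field names) are out of
  scope.
- Evidence strength is not scored; all codes weigh equally and conflicts
  surface as diagnostics.
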