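# mhcrestrict

Toolkit for modeling **MHC restriction** — which major histocompatibility
complex (MHC) molecule presents a given epitope to T cells — as a small,
fully reasoned OBO-style ontology.

Immunologists identify the restricting MHC molecule in very different ways:
exact molecular typing of both protein chains, serotyping with antibody
panels, the known haplotype of an inbred host strain, or indirect clues such
as the effector T-cell phenotype (CD8 → class I, CD4 → class II). An epitope
database has to store all of these precision levels *and* the evidence
behind them, and still answer queries like "everything restricted by
serotype A2" correctly. `mhcrestrict` provides the machinery for that:

- **nomenclature** — parse/normalize MHC designations across species
  dialects (`HLA-DPA1*02:01/DPB1*01:01`, `H2-IAd`, `BoLA-DRB3*010:01`) and
  generate the synonyms immunologists actually use (`HLA-DPB1*0402`,
  `I-Ad`, `H-2d`).
- **templates** — compile per-branch TSV template tables (one table per
  branch of the hierarchy: loci, chains, molecules, haplotypes, serotypes,
  mutants, evidence codes, taxa) into classes and axioms, enforcing one
  design pattern per branch.
- **model / reasoner** — an EL-style class-expression language (atoms,
  conjunction, existential restriction over six relations) with a
  normalization + completion-rule reasoner that materializes the inferred
  subsumption hierarchy. A molecule is a protein complex of two chains:

  ```
  'HLA-DPA1*02:01/DPB1*01:01 molecule' ≡
      'MHC class II protein complex'
      ⊓ ∃has_part.'HLA-DPA1*02:01 chain'
      ⊓ ∃has_part.'HLA-DPB1*01:01 chain'
  ```

  When only one chain is known, a *generic* partner chain stands in
  (`'HLA-DPB1*04:02 molecule'` uses an unspecified `'HLA-DPA chain'`), and
  the reasoner places every fully specified molecule underneath the
  matching generic one automatically.
- **query** — expand restriction queries to molecule sets (by class,
  chain, serotype incl. splits, haplotype) and build the hierarchical
  browse views (class → species → locus/sub-locus → molecule).
- **evidence** — nine controlled evidence codes and an inference engine
  that narrows a candidate molecule set from assay context (host
  haplotypes, APC panels, antibody-defined sets, effector phenotype, ...).

## Worked example

```sh
$ mhcrestrict fixture --out templates            # emit the branch TSVs
$ mhcrestrict compile templates -o example.obo   # compile to OBO 1.4

$ mhcrestrict query example.obo --serotype A2
MRO:0000036	HLA-A*02:01 molecule
```

The serotype query returns the molecule whose restriction was mapped
*finer* than the serotype — A2 is attached to the A*02:01 chain, and the
query walks chain → complex.

```sh
$ mhcrestrict query example.obo --haplotype "H2d haplotype" \
      --class-filter "MHC class II protein complex"
MRO:0000041	H2-IAd molecule
MRO:0000042	H2-IEd molecule
```

These are exactly the two class II molecules a BALB/c (H2d) host can use —
the classic narrowing argument when responding T cells are CD4+. The same
inference, with its evidence code, through the batch interface:

```sh
$ printf 'effector\thost_haplotypes\nCD4\tH2d haplotype\n' > assays.tsv
$ mhcrestrict infer example.obo --assays assays.tsv -o out.tsv
$ cat out.tsv
assay	candidates	level	codes	diagnostics
1	H2-IAd molecule|H2-IEd molecule	set	type of effector T cell
```

The candidate set was narrowed to two molecules, the precision level is
`set` (not `exact`, since two candidates remain), and the evidence code
records *why*: the type of effector T cell.

Other subcommands: `validate`, `classify` (materialized child/parent
pairs), `tree --view locus|haplotype|serotype` (browse-view JSON),
`export --format obo|ofn|json`.

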