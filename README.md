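# phylopipe

Ortholog mining, refinement and supermatrix construction for deep
phylogenomics — analyses that span the whole eukaryotic tree of life
(on the order of 1.8 billion years), where complex paralogy,
endosymbiotic/lateral gene transfer and heterogeneous rates defeat most
off-the-shelf orthology tools.

The pipeline takes per-taxon sequence sets (GenBank downloads,
transcriptome assemblies) plus reference protein sets for orthologous
groups (OGs, OrthoMCL-style), and produces per OG:

1. a refined alignment with paralogs retained (input for gene-tree /
   species-tree reconciliation), and
2. a one-sequence-per-taxon alignment ready for supermatrix
   concatenation, together with a partitioned supermatrix and RAxML-style
   partition file.

It is aimed at groups assembling many-gene, many-taxon matrices from
heterogeneous public and in-house data, who need every removal decision
to be explicit, parameterized and auditable.

## What it does

Sequences are named under a strict `XX_yy_zzzz_<uid>` standard (major
clade, subclade, taxon, unique id — e.g. `Op_me_hsap_12345` for *Homo
sapiens*), which downstream stages exploit directly.

**Taxon stage** (each taxon independent)

- assign candidate sequences to OGs by k-mer-seeded Smith–Waterman
  against the OG reference proteins (or import external tabular hits);
- optionally prescreen taxa with known contamination sources (food
  organisms, endosymbionts) by comparing best scores against target vs
  contaminant references;
- infer proteins from nucleotide data with frameshift recovery: when
  reference hits occur in more than one reading frame, the translation
  switches frames at the inferred breakpoint, skipping nucleotides one
  at a time (at most ~1 residue lost per breakpoint);
- remove alleles/recent paralogs (pairwise identity > 98% over the
  overlap ⇒ drop the shorter) and non-homologs or non-overlapping
  fragments (similarity < 75% ⇒ drop the shorter), both cutoffs
  configurable.

**Gene stage** (each OG independent)

- collapse in-group paralogs: same-taxon sequences that form a
  monophyletic group on a p-distance neighbor-joining guide tree are
  reduced to one representative, iterated to a fixpoint;
- two-pass confidence alignment: score every residue pair of the base
  alignment by its support across perturbed alternative alignments,
  remove sequences scoring below 0.5, realign, delete columns scoring
  below 0.4 (the strict 0.6/0.93 defaults suit closely related taxa);
- screen the gene tree for cross-domain singletons — e.g. a sequence
  labelled `Op_…` nested among `Ba_…` leaves — and remove them
  (contamination or recent LGT; either way no vertical signal);
- select one sequence per taxon: keep the candidate with the most
  same-major-clade neighbors in its surrounding clean clade, ties going
  to the shortest terminal branch.

**Concatenation**: merge the one-per-taxon alignments (plus optional
extra partitions such as SSU rDNA), drop taxa present in fewer than 20
genes, delete columns with more than 50% missing data (strict: exactly
50% survives), and write relaxed PHYLIP/FASTA plus a partition table
(`PROTGAMMALG` for proteins, `GTRGAMMA` for DNA).

## Worked example

One taxon has three paralogs on a gene tree: one inside a clade of 5
Plantae, one inside a clade of 10 Plantae, and one nested within fungi.
The selection rule keeps the copy with the most same-clade neighbors:

```python
>>> from phylopipe.orthoselect import select_orthologs, score_candidate
>>> from phylopipe.seqio import read_newick
>>> tree = read_newick("example_gene_tree.nwk")
>>> records = [(leaf.taxon.label, seqs[leaf.taxon.label])
...            for leaf in tree.leaf_node_iter()]
>>> kept, log = select_orthologs(tree, records)
>>> [n for n, _ in kept if n.startswith("Pl_gr_atha")]
['Pl_gr_atha_10']
>>> score_candidate(tree, "Pl_gr_atha_10").clade_size
10
>>> score_candidate(tree, "Pl_gr_atha_5").clade_size
5
>>> score_candidate(tree, "Pl_gr_atha_99").clade_size   # inside fungi
1
```

The retained copy sits in the 10-Plantae clade (`clade_size` 10); the
copy nested among fungi has no same-clade neighbors at all
(`clade_size` 1) and is discarded.

A full synthetic run, end to end:

```bash
phylopipe simulate --seed 11 --out data/
phylopipe taxon-stage --taxa-dir data/taxa --og-dir data/og_refs --out buckets/
phylopipe gene-stage --buckets-dir buckets/ --out genes/
phylopipe concat --alignments-dir genes/one_per_taxon --out matrix/
# => supermatrix: 30 taxa x 4542 columns, written to matrix/
```

Every record the synthetic generator plants — alleles, in-group
paralogs, non-overlapping fragments, frameshifted transcripts,
cross-domain contaminant copies — is labelled in `data/truth.tsv`, and
every removal appears in a stage audit log with a reason code.

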