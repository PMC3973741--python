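# Methods

## Scope and model of the data

The package curates homologous sequence sets for phylogenomic analyses
spanning very deep divergences (all eukaryotes, with bacterial and
archaeal outgroups).  At that scale the practical obstacles are not
alignment or tree inference per se but data curation: allelic
near-duplicates and assembly redundancy, within-taxon paralogy,
non-overlapping transcript fragments, frameshift errors in
transcriptome data, and misidentified (contaminant) sequences in public
archives.  Each pipeline stage encodes one explicit, parameterized rule
for one of these pathologies; everything removed is logged with a
reason code so that unexpected results can be audited.

Sequence identity is the only notion of distance used for guide
structures (p-distance, 1 − identity fraction over aligned residues);
no substitution-model correction is applied there, because guide trees
only need to order merges and detect same-taxon sister groups, not
estimate divergence times.

## Pairwise refinement

Candidates for one taxon and one orthologous group are compared
all-against-all with global affine-gap alignment: BLOSUM62, gap open
10, extend 0.5 (gap of length k costs `open + (k−1)·ext`), terminal
gaps free, identity and similarity computed over the overlap (columns
with residues in both rows).  Similarity counts columns whose
substitution score is positive.  Nucleotide mode uses +5/−4.

Rules, applied longest-first so the longest sequence always survives
and the procedure is idempotent:

- identity **strictly greater than** 98% over the overlap ⇒ the pair
  are alleles or very recent paralogs; remove the shorter;
- similarity **strictly below** 75% ⇒ motif-sharing non-homolog or
  non-overlapping fragment; remove the shorter.

Both thresholds are exposed (`id_cutoff`, `sim_cutoff`).  Equal-length
ties remove the lexicographically later name, making the output a
deterministic function of the input set.  Note one deliberate
consequence of "over the region of overlap": two fragments whose
optimal alignment shares only a chance micro-overlap can score above
the similarity cutoff and both survive; the guide-tree and confidence
stages handle such cases later.

## Homology search and protein inference

The builtin search is desk-scale BLAST-like machinery: exact amino-acid
4-mers shared between query and reference seed a Smith–Waterman local
alignment (same scoring as above), reported in raw matrix units.
Queries whose best hit scores below `min_score` (default 50) are
dropped.  If no qualifying hit is found at k=4, the search retries at
k=3 — short or highly diverged queries can miss every exact 4-mer seed.
Raw scores are used instead of e-values deliberately: with a fixed
reference set they avoid database-size dependence, and reimplementing
extreme-value statistics would add nothing at this scale.  An
external-table backend accepts 12-column tabular hits for parity with
standard search tools.

Protein inference translates the reading frame(s) with qualifying hits
to the assigned OG's best reference.  All six frames are tried; the
strand with the best hit wins (ties to forward).  With one qualifying
frame, the translation covers the full reference-supported span, mapped
by a free-end-gap global alignment of the frame translation to the
reference and bounded by the open reading frame (mappings beyond a stop
codon are UTR junk and are discarded).  Because free end gaps clip
terminal mismatch runs, the mapped span is extended diagonally by up to
6 codons at each end, stopping at any stop codon.  With hits in two or
more frames, a frameshift is inferred: the switch point is placed at
the reference position maximizing exact matches of the upstream frame
before it plus the downstream frame after it — exact to within a codon
or two for a single indel — and the skipped nucleotides are reported.
Stop codons are never emitted; a single-frame translation that would
contain one is rejected rather than silently truncated.

On 100 simulated transcripts with one planted single-nucleotide indel,
the recovered protein matches the reference at ≥ L−2 positions with the
breakpoint within ±2 codons in 96–99 cases (seed-dependent); the
remainder are rejections or near-misses, never silent errors.

## Guide trees and paralog collapse

Guide trees are neighbor-joining (scikit-bio's implementation) on
p-distance matrices.  In-group paralog collapse finds, on each
iteration, every maximal leaf set that (a) shares one taxon code and
(b) is isolated by a single edge (bipartition-based monophyly — no
rooting is ever assumed), keeps the longest member (name breaks ties),
and repeats until no removal or `max_iter` (default 5; convergence is
usually within 2).  The longest-member rule maximizes downstream
overlap; the original choice of representative is not documented
anywhere we know of, so this is declared, not inherited.

## Confidence alignment

The progressive aligner is profile–profile Needleman–Wunsch over the
guide tree's post-order merges, affine gaps, free terminal ends,
profiles as residue-frequency vectors.  It is deliberately simple: its
job is to be a deterministic, dependency-free substrate for the
confidence machinery, not to compete with production aligners; an
import hook accepts externally computed alignments where those are
preferred.

Confidence scoring follows the Guidance idea: build `n_alternatives`
perturbed alignments; the support of a residue pair co-aligned in a
base column is the fraction of alternatives co-aligning that same pair;
column score = mean over the column's pairs (1.0 for pair-less
columns), sequence score = mean over all pairs involving the sequence.

Perturbation design required care.  Column-bootstrapped guide trees
alone cannot perturb a deterministic profile aligner: near-identical
families realign identically, and an unalignable sequence's placement
against a rigid profile is decided by chance-match offsets whose
competition involves only free end gaps, so gap-penalty variation alone
cannot move it either.  Alternatives therefore combine three seeded
perturbation sources: (1) column-bootstrap guide trees, (2) gap
penalties drawn from ×0.5–1.6 of the base values, and (3) per-cell
score jitter of amplitude 4.5 matrix units — near-optimal co-optimal
sampling in the spirit of GUIDANCE2.  Jitter cannot disturb high-margin
homologous placements (their optima lead by hundreds of units) but
spreads ambiguous ones across their co-optima.  The amplitude was set
by separation of the two score distributions on planted-junk fixtures
across family divergences of 2–8%: junk sequences score ≤ 0.33, family
members ≥ 0.81, identical families exactly 1.0.

The two-pass filter removes sequences with support strictly below
`sp_seq_cutoff` (default 0.5), realigns the survivors, and deletes
columns strictly below `sp_col_cutoff` (default 0.4).  These loose
defaults are intended for extremely diverse datasets, where the
conventional 0.6/0.93 would discard real deep-branching taxa; both are
configurable.  Masked columns are deleted, not gapped, because
downstream concatenation expects dense columns; their indices are
reported for audit.  `n_alternatives` defaults to 10 — enough for
0.1-granular support scores at desk scale; raise it for production
runs.

## Contamination screening on gene trees

A leaf is flagged as a cross-domain singleton iff its nearest
neighborhood — other leaves collected by expanding the edge-distance
radius until at least `min_neighbors` (default 3) are gathered, ties
included — consists of a single domain different from the leaf's own.
Any same-domain leaf in the neighborhood vetoes the flag, so paired
intruders (two related taxa together in an unexpected place, possibly
real signal) are never removed.  Raising `min_neighbors` only grows the
neighborhood, so the flagged set shrinks monotonically as the evidence
requirement rises.  Screening is domain-level (eukaryote vs bacteria vs
archaea) by default, which is the defensible resolution for trees
spanning all of life; a stricter major-clade mode is available for
shallower studies.  Removal deliberately conflates contamination with
recent single-taxon LGT: neither contributes vertical signal to a
supermatrix.

On 100 simulated 40-leaf trees with three planted singletons each (one
per foreign domain block), sensitivity is 100% with zero false flags.

## Ortholog selection

For each taxon with multiple candidates, the kept candidate maximizes
`clade_size`: the leaf count of the largest single-edge-defined leaf
set containing the candidate whose members all share its major clade
(same-taxon co-candidates count; one foreign leaf breaks the clade).
Ties go to the shortest terminal branch, then to name order, making
selection deterministic.  Taxa configured as "orphan" (unknown
phylogenetic position) skip the clade score and use branch length only.

## Supermatrix

Concatenation keys rows by the 10-character taxon prefix, fills absent
taxon×gene cells with `-`, and records partitions in order (OGs sorted
by id, extra partitions such as SSU appended).  `-`, `?` and `X` are
treated as missing on read.  Filters run in the documented order — taxa
with fewer than `min_genes` (20) occupied partitions are dropped, then
columns with strictly more than `max_missing` (50%) missing cells are
deleted and partition ranges recomputed.  Writers (relaxed PHYLIP,
FASTA, partition file, occupancy table) are byte-deterministic.

## Synthetic data

The generator plants, per taxon×OG cell, at most one pathology drawn
from configured rates (defaults: allele 0.15, paralog 0.10, fragment
0.10, frameshift 0.10, contamination 0.05), on top of clean proteins
evolved by uniform substitution down random trees within each domain
(4% per tree level, 15% extra separating domains, protein lengths
80–140).  Alleles are ≥ 99%-identical truncated copies; paralogs 5%
diverged; fragments replace the clean record with two disjoint windows;
frameshifts insert one nucleotide at a random codon; contaminants are
lightly mutated, truncated copies of a foreign-domain taxon's ortholog
filed under the victim's name.  The default roster is 30 taxa (four
eukaryotic clades of five, six bacteria, four archaea) × 40 OGs — small
enough for a complete run in a few minutes on one CPU, large enough
that every pathology occurs dozens of times.  Sequences are emitted as
nucleotide by default (with UTRs and stop codons) so translation is
exercised end to end.

What the generator does *not* emulate: rate heterogeneity across sites
or lineages, a background indel process, codon bias, base composition
artifacts, and assembly errors other than single-nucleotide indels.
Passing tests therefore demonstrate that the rules behave exactly as
specified under controlled pathologies — not that the thresholds are
optimal for any particular real dataset; the thresholds themselves are
all configurable for that reason.

## Numerical and determinism notes

All randomness flows through seeded numpy generators; every stage
processes inputs in sorted order, so shuffled inputs and reruns are
byte-identical, and per-OG work can be distributed across machines and
recombined.  DP tie-breaks: the alignment kernel prefers substitution
over gap-in-first over gap-in-second states; NJ negative branch lengths
are clamped to zero.  Degenerate inputs are handled explicitly: empty
taxa are skipped with a warning, OGs with fewer than 4 sequences skip
confidence filtering, fewer than 3 skip trees, and an OG whose
sequences are all removed is marked failed while the stage continues.

## Known limitations

- The builtin aligner and NJ trees are desk-scale stand-ins; for
  production analyses, import hooks accept external alignments, trees
  and search tables at every stage boundary.
- Identity/similarity of a pair with multiple co-optimal alignments
  depends on which optimum the alignment engine reports; the refinement
  rule is therefore defined over the (shorter, longer) orientation it
  actually computes.
- The contamination screen requires ≥ `min_neighbors`+1 leaves of the
  surrounding domain to act; sparse gene trees can hide singletons.
- E-value statistics are intentionally absent; raw score thresholds
  assume a fixed reference set.
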