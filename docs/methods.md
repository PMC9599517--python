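# Methods notes

This note records the models, parameter choices, and numerical decisions
behind `phagepan`, and what the synthetic-data tests do and do not show
about real data.

## What the generator emulates

`simulate.simulate_pangenome` produces a clade-structured collection of
circular phage genomes whose summary statistics match the target
lineage: genome length N(58,776, 2,523²) bp, G+C 42.1%, ORFs per genome
N(82, 9²), 10 clades, a 13-orthogroup core, clade-specific accessory
orthogroup pools, N(17, 9²) unique genes per genome, and a T8SS (Curli)
module planted in round(9/82 × n) genomes. `emit_linear_contigs`
re-linearizes each genome at a random rotation and appends the first
`overlap_len` bases, reproducing the exact terminal direct repeat an
assembler leaves on a circular template. `simulate_virome_stations`
produces per-station gene tables with a Binomial(total ORFs, prevalence)
number of planted modules per station, a configurable composition
mixture (default 60/30/10 over the canonical five-component module, a
seven-component variant with a second CsgA/B and an adenylate cyclase,
and a two-HK variant), and a truncation fraction placed flush against
contig termini.

### Protein evolution

Each orthogroup has a random ancestor protein (uniform over the 20
residues, leading M). Each clade receives a variant of the ancestor with
i.i.d. substitutions at `between_clade_divergence` (default 0.15
subst/site), and each genome a leaf copy of its clade variant at
`within_clade_divergence` (default 0.02). Substitutions always change
the residue, so the expected substituted fraction equals the divergence
exactly. There are no indels, no rate heterogeneity, no codon model, and
no back-mutation bookkeeping — the goal is separable clades and
recoverable orthogroups, not realistic phylogenetic signal. Consequences
worth keeping in mind:

- Within-orthogroup proteins share a length, so concatenated orthologs
  form a valid alignment without an aligner, and alignment coverage is
  always 1.0 within groups. Real orthologs have indels; the alignment
  identity machinery handles gaps, but the fixtures never exercise
  gapped paths heavily.
- With the default divergences, within-clade AAI is ~96% and
  between-clade AAI ~70%. The real lineage is more diverged (below 50%
  AAI between distant members). The defaults are a calibration choice:
  they keep every within-orthogroup pair inside the regime where the
  k-mer prefilter is reliably sensitive (see below), which is what the
  exact-recovery tests require. Passing those tests therefore shows the
  clustering machinery is correct, not that it would reproduce
  tool-specific orthogroup counts on far more diverged real proteomes.

### Nucleotide assembly

Genes are packed head-to-tail with random intergenic spacers of 12–50 nt.
Every spacer embeds a fixed 12-mer (`TTAATTAGTTAG`) containing a stop
codon in all six reading frames. Without this "stop wall", open reading
stretches run through gene boundaries and a maximal-ORF caller reports
chimeric genes extending into neighbours (~+20 spurious calls per
genome after overlap resolution); with it, stop-bounded regions end at
gene boundaries, as they essentially always do between densely packed
real genes. Coding sequences are back-translated with synonymous codon
weights; the wobble G+C probability is solved numerically (Brent) so the
expected overall G+C matches the configured target, and spacer padding
is biased to offset the A/T-rich wall. Unique-gene lengths absorb the
difference between the genome's length budget and its fixed orthogroup
gene lengths (exact-sum multinomial allocation, 50 aa minimum), so the
configured length distribution is honored without distorting shared
protein lengths.

### Seeding

A single master seed feeds `numpy.random.SeedSequence`; per-genome
streams are spawned children, so any subset of genomes is reproducible
independently of the others. Identical configs produce byte-identical
output.

## Circularization

The exact-repeat detector walks the KMP border chain of the contig and
returns the longest border ≥ `min_overlap` (default 100 bp) that is at
most half the contig and contains no `N` (`N` matches nothing, including
`N`). Relaxed identity (`min_identity < 1`) switches to an ungapped
end-to-end scan from the longest candidate down — the first overlap
clearing the identity threshold is returned. Reverse-complement terminal
repeats are not circularization evidence. The length filter is strictly
greater-than 10 kb, reading "larger than 10 kb" literally. Contigs
shorter than twice the minimum overlap raise a distinct
`ContigTooShortError` rather than returning "no repeat". A repeat
covering more than half the contig is refused at trim time as
degenerate.

## ORF calling

A deliberately simple caller: in every stop-bounded stretch of each of
the six frames it reports the longest variant starting at ATG/GTG/TTG
(genetic code 11), subject to a 90 nt minimum. On circular genomes the
scan runs over the doubled sequence, skips the unbounded leading region,
and deduplicates second-turn copies by start position modulo the genome
length; an ORF can never exceed the genome length (in a stop-bounded
region longer than the genome — astronomically rare in coding-density
data — the first start that fits within one genome length is taken).
No coding-potential or RBS scoring is attempted. `select_genes` adds a
greedy longest-first overlap filter (default: no overlap tolerated)
that discards antisense and embedded spurious ORFs; on synthetic
genomes the selected count matches the planted count to within ~1 gene.
Externally produced gene calls imported from GFF3 take precedence over
the built-in caller in pipeline use.

## Orthology and AAI

Pairwise similarity is global (Needleman–Wunsch) alignment under
BLOSUM62 with affine gaps (open 11, extend 1, the opening position
includes its own extension). Percent identity is identical columns over
all aligned columns — gap columns count in the denominator. This is the
most conservative common convention; it is stated explicitly because
"percent amino-acid similarity" is used loosely in the literature, and
it is surfaced anywhere a threshold is applied (the 45% marker screen,
the 30% orthogroup edge threshold).

The all-vs-all step is restricted by a k-mer Jaccard prefilter (k=5,
threshold 0.02, inverted-index implementation). Shared 5-mer content
decays roughly as identity⁵, so 0.02 keeps every pair above ~55%
identity while unrelated ~220-aa proteins score ~0.002; the 0.02 choice
is deliberate — a 0.05 threshold already loses pairs at ~65% identity,
well inside the regime the orthogroup tests rely on. The marker screen
(`screen_by_reference`) aligns exhaustively rather than through the
prefilter because its 45% decision boundary sits below the prefilter's
reliable range.

Orthogroups are connected components over edges passing identity ≥30%
and coverage ≥0.5; components with a single member are reported
separately as singletons, and groups are numbered by smallest member id
for determinism. This replaces normalized-bitscore MCL clustering with
something deterministic and oracle-testable; counts on real, highly
diverged proteomes would differ from tool-specific values. AAI is the
mean identity over reciprocal best hits (ties broken by alignment
score, then lexicographic gene id); "no reciprocal best hits" raises a
distinct error rather than returning 0. AAI inputs are canonically
ordered internally so AAI(a,b) and AAI(b,a) are bit-identical.

## Clade delineation

The rule: a leaf set is a clade when it appears as a supported
(≥90%) bipartition side with identical membership in both trees and has
≥3 members; only maximal candidates are reported, so clades are
disjoint. Trees are unrooted; the "clade side" of a bipartition is the
side not containing a user-supplied outgroup, defaulting to the minority
side (adequate whenever clades are smaller than half the tree, as
here). When two non-nested candidates overlap — impossible within one
tree, possible across two — neither is reported and a warning is
emitted. Nested supported candidates resolve to the maximal one; this
is a documented choice, as is reporting a coherent supported subgroup
when the two trees disagree about one leaf's placement.

Tree building for synthetic tests uses scikit-bio's neighbor joining on
p-distances and classical Felsenstein column-resampling bootstrap
(support = percent of replicates containing the bipartition, keyed by
the side not containing a fixed reference leaf). Maximum-likelihood
reconstruction is consumed, not computed: any newick with supports as
internal node labels can be fed to `delineate_clades`; supports in
[0, 1] are auto-scaled to percent with a warning. The built-in NJ and
bootstrap exist so the clade rule is testable end-to-end; they make no
claim of matching ML supports on real alignments, where rate
heterogeneity and model choice matter.

## AMG and module analysis

AMG classification is label-driven: genes whose functional category maps
to a cellular function (nucleotide metabolism, DNA hypermodification,
T8SS, other) are AMGs; core viral replication/packaging genes and
unannotated genes are not. Labels are inputs (imported annotation
tables); no database search is performed or emulated.

T8SS module extraction finds maximal runs of component genes with at
most `max_gap_genes` (default 1) intervening non-component genes — the
default tolerates one annotation dropout while staying close to
contiguous operons; 0 restores strict contiguity. Composition strings
are read in the canonical orientation (CsgF before CsgG; majority gene
strand when undecidable), preserving duplicate components. An instance
is terminal when the contig's first or last gene belongs to it; terminal
instances are excluded before composition statistics, because a module
at a contig edge may be truncated. Composition tables rank by count with
lexicographic tie-breaks; percentages are relative to all modules of the
same family.

Family assignment takes the best-identity reference protein's family,
unless the best identity falls below that (component, family) pair's
floor — the minimum pairwise identity among the known-family references
themselves — in which case the protein is unassigned. Floors therefore
encode "no closer than the family's own internal diversity"; on the
synthetic fixtures a small fraction of genuine carriers lands below the
floor, which is the intended conservative behavior.

Station frequencies are per-component hit counts divided by the
station's total viral ORFs. The pairwise count ratio statistic takes
min/max over every unordered pair of gene counts and reports mean ± SD;
pairs of two zeros are skipped, a single zero contributes 0, and an
all-zero input is an error rather than a number. Which pairs and which
ratio the statistic should use is ambiguous in general; min/max over
unordered pairs is this package's documented interpretation.

## Problem sizes used in tests and the reproduction script

Unit tests run on a 20-genome, 4-clade collection with ~30 ORFs per
genome; the clade-rule and module-recovery acceptance checks run at full
scale (82 genomes with explicit clade sizes 3–15; 65 stations × 15,000
ORFs at prevalence 10⁻³, ~1,000 planted modules). The reproduction
script (`scripts/acceptance.py`) runs the complete pipeline at the
default study conditions (82 genomes, 500 bootstrap replicates,
65 stations × 10,000 ORFs) in about a minute on one CPU; AAI clade means
are computed over 30 sampled pairs per stratum rather than all 3,321
genome pairs.

## Known limitations

- No indels in protein evolution; alignment-heavy paths (gapped
  identity, coverage < 1) are exercised only by dedicated unit fixtures,
  not by the generator.
- The generator's clade radiation is star-like (independent clade
  variants of a common ancestor), so deep backbone structure carries no
  signal; this matches the delineation rule's indifference to backbone
  topology but means backbone support values are meaningless in
  synthetic trees.
- Orthogroup counts and pan-genome percentages on real data depend on
  the clustering tool; the connected-components definition here is
  deterministic but not interchangeable with MCL-based clustering at
  high divergence.
- The ORF caller does not model coding potential; on real genomes it
  over-calls relative to trained callers, and imported gene calls should
  be preferred.
- Virome station simulation is gene-table resolution only (no
  nucleotide sequences), so read-level effects (coverage, chimeras) are
  out of scope.
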