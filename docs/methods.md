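# Methods

`trgkit` identifies taxonomically restricted genes (TRGs) in a bacterial
genus, traces them to disrupted noncoding homologs in genomes outside the
genus, clusters them into restricted families, and profiles their sequence
properties. This note records the models, the numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## The classification schema

Input is a focal genus (genome assemblies plus protein-coding gene calls)
and an external collection (genomes, gene calls, proteins, all outside the
genus). Gene products are collapsed into a *nonredundant protein universe*
by exact sequence identity; every record keeps its full (genome, gene)
provenance. Classification proceeds in a fixed stage order and each protein
ends in exactly one terminal status:

1. **External protein screen.** A query with a qualifying hit against the
   external protein collection is `non_trg_external_hit`. The screen
   supports a two-tier database (reference proteomes first, full
   collection second); a hit in any tier disqualifies.
2. **Noncoding-space scan.** For each remaining (putative) candidate and
   each external genome, the locus is first anchored by synteny: the
   nearest annotated gene on each side of the candidate must have a
   reciprocal-best-hit (RBH) ortholog in the target, on one contig, with an
   inter-anchor gap at most 5x the source gap (configurable); joint
   inversion of the anchor pair is accepted, crossing anchors are not.
   Inside a found block — or against the whole genome when no block exists
   — the candidate protein is aligned with the frameshift/stop-aware DP
   (below) and validated by a backward protein search of the hit's implied
   peptide against the candidate genome's entire proteome; the hit counts
   only when that backward best hit is the candidate itself. A validated
   match with query coverage >= 0.90 and zero frameshifts and zero
   premature stops is *coding*: the candidate is a gene missed by the
   target's annotation (`missed_annotation`). Any other validated match is
   a *noncoding* trace, labelled syntenic if it overlaps the synteny block
   by at least one nucleotide. Candidates end the stage as
   `trg_noncoding_trace` or `trg_no_trace`.
3. **Homolog search within the genus.** For each surviving candidate:
   annotated orthologs by reciprocal protein search against every other
   genus genome; noncoding orthologs by the reciprocal DNA search against
   those genomes hard-masked at all annotated regions; annotated paralogs
   by reciprocal protein search within the candidate's own genome
   (identical duplicate gene calls, which collapse into one record, are
   recognized from the record's provenance); noncoding paralogs against
   the masked own genome. Every recorded homolog carries a *restricted*
   flag: an annotated homolog is restricted iff its own record is still in
   the putative set; a nonannotated region is restricted unless its
   implied peptide has a qualifying external protein hit (checked lazily).
4. **Transitive filter and level assignment.** One pass over the recorded
   flags: a candidate with any non-restricted homolog becomes
   `removed_transitive` (attributed to orthologs before paralogs when
   both apply). The pass is a pure function of the flags, so the result
   does not depend on search order. A kept TRG is *species-level* iff its
   source genomes and all its restricted homologs' genomes belong to one
   species, else *genus-level*.

The stage ledger satisfies the arithmetic identity
`n_final = n_putative - n_missed_annotation - n_removed_transitive_orth -
n_removed_transitive_para`, which the code asserts on every run. The
ortholog search runs uniformly against all genus genomes; species-level
confinement is decided afterwards by the level rule, which gives the same
species-level set as restricting the search scope per level would.

## Alignment and the detection model

**Protein-protein** alignment is affine-gap local Smith-Waterman (biotite's
C implementation) under BLOSUM62 with gap open 11, extend 1; a gap of
length g costs `open + (g-1)*extend`. 'X' scores 0 against everything
(it marks ambiguous or frameshift-implied residues), '*' keeps its NCBI
matrix row.

**Protein-vs-DNA** alignment is this package's own local DP over both
strands. Each query residue consumes 3 nt (in frame), 4 nt (one inserted
nucleotide: a +1 frameshift, penalty 30, scored on the last three
nucleotides) or 2 nt (one deleted nucleotide: a -1 frameshift, penalty 30,
scored as 'X'); a consumed stop codon aligns to any residue at -5 and is
recorded as a premature-stop event; codon-sized gaps in the DNA and
residue gaps in the query are affine at the protein gap costs. The
traceback yields the ordered event list and the *implied peptide* — the
DNA-side translation with stops kept as '*' and frameshift-inserted
nucleotides spliced out — which is what the backward validation search
uses. Equal-score ties prefer no-event steps, then fresh starts (shorter
alignments), and equal-scoring strands are resolved by fewer events,
shorter DNA span, smaller start, then the forward strand, so results are
deterministic. The DP is validated against an independent memoized
recursion over the same move grammar, which is itself validated against
exhaustive path enumeration on tiny instances.

**Statistics.** Raw scores map to E-values by the Karlin-Altschul form
`E = K m n exp(-lambda S)` with the tabulated gapped constants for
BLOSUM62 11/1 (lambda 0.267, K 0.041); n is the searched collection's
residue (or nucleotide) count, recorded in the run manifest, and E-values
rescale analytically (E proportional to n) when the database shrinks.

A single E-value threshold (default 10, deliberately permissive: any
detectable similarity disqualifies a candidate) is used across the run.
It cannot be the only filter: by construction a correctly calibrated
E-value assigns E ~ O(1) to the best chance alignment of *any* query
against *any* database, so an exhaustive Smith-Waterman search with a bare
`E <= 10` rule would disqualify essentially every query through chance
alignments — we measured exactly that on this generator's sequence
composition at every scale we tried. The heuristic tools this engine
surrogates do not behave that way because word seeding and composition
adjustments keep such chance alignments out of their reports. `trgkit`
models that reporting behaviour with one knob: a hit must also reach a
minimum bit score (`ScoringScheme.min_bitscore`, default 50 bits — the
classic rule of thumb for an alignment that is nearly always meaningful
regardless of database size). The floor applies wherever a search reports
hits (screen, forward DNA searches, reciprocal legs); the E threshold
keeps its monotone semantics (stricter thresholds never reduce the
putative count, shrinking databases never remove putative calls at the
tested scales). Both knobs are configurable.

For speed, whole-genome DNA searches are gated by a shared-word check
(one exact 18-nt k-mer between query gene and target, either strand): at
the detection floor a qualifying alignment without a single shared word of
that length is not achievable, so a negative gate skips the DP without
changing any call.

## The synthetic clade generator

The generator emulates the data regime the pipeline is built for: a focal
genus of `n_species x strains_per_species` genomes sharing a conserved
gene backbone, plus an external collection carrying (a) annotated homologs
of every conserved gene, (b) intact but unannotated copies of some focal
genes, (c) disrupted noncoding copies of planted TRGs with exact
(stops, frameshifts) counts, inside preserved flank pairs or at unrelated
loci with the flank context broken, and (d) nothing at all for no-trace
TRGs. It also plants species-confined genes, families with prescribed RBH
topology (cliques of nearly identical members; stars whose leaves share
disjoint segments with a hub and nothing with each other), within-genome
paralog pairs, noncoding paralog copies, and "leaky" families whose hub
has an annotated external homolog so that the leaves can only be removed
through transitive homology.

Defaults are the standard study conditions: 5 species x 2 strains,
20 external genomes, 30 conserved genes and 30 planted genes per class,
4 five-member families (two cliques, two stars), 3 paralog pairs,
3 noncoding paralogs, 10 leaky families (hub + 3 leaves); each genome is
~26 kb. Coding sequences are uniform random codons (start ATG, no internal
stops); intergenic background is i.i.d. nucleotides at GC 0.44 — at these
lengths chance similarity stays far below the 50-bit floor, which is what
makes exact truth-table comparisons meaningful. Gene lengths are lognormal
(conserved median ~120 codons; TRG median ~85, floor 70, matching the
short-gene regime where restricted genes live). Divergence is a
per-nucleotide substitution probability (default 0 = noise-free;
substitutions never create or destroy stops inside coding copies).

Disruptions are planted as nonsense codon substitutions and single-
nucleotide insertions (never deletions), spaced so that every event is
recoverable by an *optimal* aligner: frameshifts at least 8 codons from
the fragment ends and 7 codons apart (a frameshift whose flanking match
is worth less than its ~30-point penalty gets trimmed or merged by any
score-maximizing aligner, making the planted count unrecoverable in
principle, not just by this implementation); stops need only 3-codon
margins. The default disruption design cycles through the
stops x frameshifts grid up to (5,4) plus a 12-stop extreme.

What passing the noise-free round trip shows: the schema's bookkeeping,
anchoring, validation and filtering are exact when detection is reliable.
What it does not show: performance under real annotation noise, biased
composition, horizontal transfer, or homology near the detection limit —
real genomes are not i.i.d. and real divergence is not uniform. The
2%-divergence experiments (trace recall, stop-count tolerance) probe the
margin, not field performance.

## Families, disruption summaries, distances, properties

Families are connected components of the RBH graph over kept TRGs (edges:
genus-level reciprocal best protein hits plus within-genome paralog RBH
pairs); single linkage with no extra threshold, so a family id is the
lexicographically smallest member. Density `edges / C(n,2)` separates the
clique (1.0) and star (2/n) signatures. A paralogous pair is an edge whose
endpoints share a source genome.

Disruption profiles take every validated noncoding fragment at coverage
>= 0.90 (configurable) and tabulate (stops, frameshifts) per fragment and
per TRG; per-TRG categories use Venn semantics (a TRG is in the stop
circle if any of its fragments carries a stop, etc.), and the "none" cell
is reported explicitly.

Genome distances are MinHash/Mash: canonical 21-mers (N-containing k-mers
skipped) hashed with a seeded 64-bit splitmix finisher over the 2-bit
packed k-mer; sketch size 100,000 by default; Jaccard estimated on the
bottom-s of the merged sketch; `d = -(1/k) ln(2j/(1+j))`, 0 at j=1 and
capped at 1 for j=0.

Sequence properties: length; Shannon entropy of residue composition
(scipy, base 2); disorder fraction = residues with per-residue score
> 0.5 over length; aggregation frequency = residues covered by a
hexapeptide scoring > 5, over length (residue-coverage semantics — the
published phrasing "over all amino acid residues" denominates by
residues). Disorder/aggregation scores come through a two-column-file
adapter protocol for external predictors; the built-in adapter is a
deterministic window-5 Kyte-Doolittle proxy, clearly not equivalent to
the published predictors — it exists so the thresholding and comparison
machinery is testable end to end. Control sets are sampled per proteome,
matched in count to the TRG set, fully seeded. Group comparisons default
to the unpaired two-sided Mann-Whitney U test: the compared groups are
independent samples subsampled to matched size, for which a paired
signed-rank test is ill-posed; the paired variant is exposed for genuinely
paired inputs. Unannotated ORFs (both strands, first ATG/GTG/TTG of a
stop-to-stop segment through the stop, default minimum 10 codons,
no overlap with annotation) supply the short-peptide control group; the
minimum length and start-codon policy are configurable since published
practice varies.

## Sensitivity protocol

`sensitivity.subsample_experiment` measures putative counts over a grid of
(whole-genome exclusion size x E-value threshold x replicate). All
alignments are computed once at the most permissive setting; each cell is
evaluated by re-thresholding stored scores with E rescaled to the reduced
database's residue count, which is exact under the Karlin-Altschul form
and makes 20+ replicates cheap. Outputs are a long-format table plus a
median/min/max summary (and an optional band plot).

## Degenerate inputs and edge conventions

Empty FASTA files parse to empty lists; sequence before a header is an
error naming the line. A locus at a contig edge has no flank and no
synteny block. A genome shorter than k sketches to the empty sketch.
All-tied group comparisons report p = 1. Masking is idempotent and
length-preserving. Coordinates are 0-based half-open everywhere in memory;
GFF3 converts at the file boundary only. All randomness flows from
explicit integer seeds; reruns are byte-identical.

## Known limitations

* The detection floor trades sensitivity for precision exactly as the
  underlying study design does; homologs whose best alignment is worth
  less than ~50 bits (short or highly diverged) are invisible.
* tFASTy score reproduction is out of scope; the frameshift DP is a
  faithful model of the search *behaviour* (best corresponding peptide
  across frames and disruptions), not of tFASTy's numeric scores.
* The nonredundant universe is exact-identity only; fragment or
  length-trimmed merging is deliberately not performed.
* Heuristic seeding, composition-based statistics, many-to-many
  orthology and rearrangement-aware synteny chains are out of scope.
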