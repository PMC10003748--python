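# trgkit

Identification and characterization of **taxonomically restricted genes**
(TRGs) in bacterial genera — genes with no detectable homolog outside a
focal genus — including the evidence trail for their birth from noncoding
sequence.

Finding a TRG is homology search inverted: a hit *disqualifies* the query.
That makes the result exquisitely sensitive to the reference database and
the significance threshold, and naive screens are dominated by two error
classes: genes that merely *look* restricted because a relative's genome
annotation missed them, and candidates whose homologs are themselves not
restricted. `trgkit` implements a multi-stage procedure that addresses
both, and then characterizes what survives:

* an external protein screen with a single E-value threshold
  (`E = K·m·n·e^(−λS)`, BLOSUM62 gapped constants) plus a bit-score
  reporting floor;
* a frameshift/stop-aware local protein-vs-DNA aligner (six frames, 2/3/4
  nucleotides per residue, penalized frameshifts, stop codons alignable at
  a penalty) that recovers the "best corresponding peptide" from disrupted
  regions and emits an explicit event list — the number of premature stops
  and frameshifts separating a noncoding region from an intact gene;
* synteny anchoring through reciprocal-best-hit (RBH) orthologs of the
  flanking genes, so matches can be split into syntenic and non-syntenic;
* reciprocal validation of every DNA-level hit by a backward protein
  search of the implied peptide;
* ortholog/paralog searches across the genus (annotated proteins and
  masked noncoding space) with transitive filtering: a candidate linked to
  any non-restricted sequence is removed;
* single-linkage TRG families over the RBH graph, disruption-profile
  tables (stops × frameshifts), MinHash/Mash genome distances
  (`d = −(1/k)·ln(2j/(1+j))`, k = 21), and sequence-property comparisons
  (length, Shannon entropy, disorder fraction, aggregation frequency)
  against matched unannotated-ORF and annotated-protein controls with
  rank tests.

A fully seeded synthetic-clade generator plants ground truth for every
branch of this schema (conserved genes, missed annotations, syntenic and
non-syntenic disrupted traces, no-trace TRGs, species-confined genes,
clique/star families, paralogs, transitively-removable "leaky" families),
so the whole pipeline is testable end to end against known answers.
See `docs/methods.md` for the models and design decisions.

## A worked example

Plant two premature stops and one frameshift into a copy of a 100-codon
gene, hide it in random DNA, and recover the disruption profile
(`examples/frameshift_alignment.py`):

```text
score 464, bits 183.3, strand +
query coverage 1.00, identity 0.98
planted stops at codons [6, 85], frameshift at [18]
  stop       at query residue   6 (detail TAA)
  frameshift at query residue  18 (detail 1)
  stop       at query residue  85 (detail TAG)
```

The aligner finds the fragment at full query coverage and reads back
exactly the planted events: this region is three single-nucleotide changes
away from encoding the query protein.

Run the whole classification on a small synthetic clade
(`examples/simulate_and_classify.py`):

```text
input nonredundant proteins: 45
putative restricted genes: 31 (69% of input)
missed annotations: 4
with noncoding trace: 8
with no similarity: 15
removed by transitive homology (orthologs): 4
removed by transitive homology (paralogs): 0
final restricted genes: 23
species-specific: 17
families: 18
high-coverage noncoding fragments: 8
```

Every number matches the generator's planted design: the 4 unannotated
intact copies are caught as missed annotations, the 8 disrupted copies
come back as noncoding traces with their planted stop/frameshift counts,
and the leaky families' 4 leaves are removed purely through their
transitive link to the hub's external homolog. The stage counts obey
`final = putative − missed − removed`.

Other examples (each a short narrative script): `family_topologies.py`
(clique vs star density signatures), `genome_distances.py` (Mash matrix),
`sequence_properties.py` (group medians and rank tests),
`database_size_sensitivity.py` (putative counts vs database size and
threshold).

A thin CLI wraps the same library: `trg simulate --out DIR`,
`trg run --genus-dir ... --external-dir ... --out DIR`,
`trg report --ledger DIR/ledger.json`.

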