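"""Align a protein against a disrupted (noncoding) copy of its gene.

Builds a gene, plants two premature stops and one frameshift into a copy,
embeds the copy in random DNA, and recovers the disruption events with the
frameshift-aware six-frame aligner.
"""

import numpy as np

from trgkit.align_core import align_protein_dna_fs, default_scheme
from trgkit.sequence_io import translate
from trgkit.synthetic_data import disrupt_coding, random_coding_dna, random_dna

rng = np.random.default_rng(0)
gene = random_coding_dna(rng, 100)          # 100-codon gene
protein = translate(gene)[:-1]              # its 99-residue product
fragment, stop_sites, fs_sites = disrupt_coding(gene, n_stops=2, n_frameshifts=1, rng=rng)
target = random_dna(rng, 400, 0.44) + fragment + random_dna(rng, 400, 0.44)

aln = align_protein_dna_fs(protein, target, default_scheme())
print(f"score {aln.score}, bits {aln.bitscore:.1f}, strand {aln.strand}")
print(f"query coverage {aln.query_coverage:.2f}, identity {aln.identity:.2f}")
print(f"planted stops at codons {stop_sites}, frameshift at {fs_sites}")
for e in aln.events:
    print(f"  {e.kind:10s} at query residue {e.query_pos:3d} (detail {e.detail})")
# The event list is the fragment's "disruption profile": the number of
# single-nucleotide changes separating this region from an intact gene.
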