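"""Synteny anchoring: locate the region of a target genome positionally
corresponding to a focal gene locus via RBH orthologs of the nearest
annotated flanking genes, and classify DNA matches as syntenic or not.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align_core import FrameshiftAlignment, ScoringScheme
from .rbh import DEFAULT_E_MAX, RBHPair, best_hit
from .sequence_io import GeneAnnotation, GenomeRecord

DEFAULT_GAP_CAP_FACTOR = 5.0


@dataclass
class SyntenyBlock:
    """The target interval between the orthologs of a locus's flanking genes."""

    trg_gene_id: str
    target_genome_id: str
    target_contig_id: str
    interval: tuple[int, int]
    left_anchor: RBHPair
    right_anchor: RBHPair
    orientation: str  # 'collinear' | 'inverted'

    def __post_init__(self) -> None:
        if self.interval[1] < self.interval[0]:
            raise ValueError("block interval must be non-negative")


def flanking_genes(
    trg: GeneAnnotation, annotations
) -> tuple[GeneAnnotation | None, GeneAnnotation | None]:
    """Nearest annotated gene strictly left and strictly right of the locus."""
    left = right = None
    for a in annotations:
        if (
            a.genome_id != trg.genome_id
            or a.contig_id != trg.contig_id
            or a.gene_id == trg.gene_id
        ):
            continue
        if a.end <= trg.start:
            if left is None or a.end > left.end:
                left = a
        elif a.start >= trg.end:
            if right is None or a.start < right.start:
                right = a
    return left, right


def _ortholog_in_target(
    flank_protein,
    target_proteins,
    source_proteins,
    scheme,
    e_max,
):
    """RBH of a flank protein against the target genome's proteins."""
    fwd = best_hit(flank_protein, target_proteins, scheme, e_max)
    if fwd is None:
        return None
    hit = next(p for p in target_proteins if p.protein_id == fwd.subject_id)
    rev = best_hit(hit, source_proteins, scheme, e_max)
    if rev is None or rev.subject_id != flank_protein.protein_id:
        return None
    return RBHPair(
        a_id=flank_protein.protein_id,
        b_id=hit.protein_id,
        mode="prot-prot",
        forward=fwd,
        reverse=rev,
    )


def find_syntenic_region(
    trg: GeneAnnotation,
    source_genome: GenomeRecord,
    target_genome: GenomeRecord,
    source_annotations,
    target_annotations,
    source_proteins_by_gene: dict,
    target_proteins_by_gene: dict,
    scheme: ScoringScheme,
    e_max: float = DEFAULT_E_MAX,
    gap_cap_factor: float = DEFAULT_GAP_CAP_FACTOR,
) -> SyntenyBlock | None:
    """Anchor the locus of ``trg`` in ``target_genome``.

    One flanking gene per side (the nearest annotated CDS); both flanks
    must have an RBH ortholog in the target, on one contig, with an
    inter-anchor gap at most ``gap_cap_factor`` times the source gap.
    Joint inversion of the two anchors is accepted (orientation
    'inverted'); crossing anchors are rejected.

    ``*_proteins_by_gene`` map gene_id -> ProteinRecord for annotated genes.
    """
    left, right = flanking_genes(trg, source_annotations)
    if left is None or right is None:
        return None  # locus at contig edge: no flank
    target_anns = [
        a for a in target_annotations if a.genome_id == target_genome.genome_id
    ]
    target_proteins = [
        target_proteins_by_gene[a.gene_id]
        for a in target_anns
        if a.gene_id in target_proteins_by_gene
    ]
    source_anns = [
        a for a in source_annotations if a.genome_id == source_genome.genome_id
    ]
    source_proteins = [
        source_proteins_by_gene[a.gene_id]
        for a in source_anns
        if a.gene_id in source_proteins_by_gene
    ]
    anchors = []
    for flank in (left, right):
        protein = source_proteins_by_gene.get(flank.gene_id)
        if protein is None:
            return None
        pair = _ortholog_in_target(
            protein, target_proteins, source_proteins, scheme, e_max
        )
        if pair is None:
            return None
        gene = next(
            a
            for a in target_anns
            if target_proteins_by_gene.get(a.gene_id) is not None
            and target_proteins_by_gene[a.gene_id].protein_id == pair.b_id
        )
        anchors.append((pair, gene))
    (left_pair, left_gene), (right_pair, right_gene) = anchors
    if left_gene.contig_id != right_gene.contig_id:
        return None
    # orientation: collinear keeps the left anchor left of the right anchor;
    # a joint locus inversion flips both the order and the strand relation
    # of both anchors; a flipped order with preserved strands is a crossing
    # and is rejected.
    strands_flipped = (left_gene.strand != left.strand) and (
        right_gene.strand != right.strand
    )
    if left_gene.start <= right_gene.start:
        inner = (left_gene.end, max(right_gene.start, left_gene.end))
        collinear = True
    else:
        if not strands_flipped:
            return None
        inner = (right_gene.end, max(left_gene.start, right_gene.end))
        collinear = False
    source_gap = max(right.start - left.end, 1)
    if (inner[1] - inner[0]) > gap_cap_factor * source_gap:
        return None
    return SyntenyBlock(
        trg_gene_id=trg.gene_id,
        target_genome_id=target_genome.genome_id,
        target_contig_id=left_gene.contig_id,
        interval=inner,
        left_anchor=left_pair,
        right_anchor=right_pair,
        orientation="collinear" if collinear else "inverted",
    )


def classify_match_location(
    aln: FrameshiftAlignment, block: SyntenyBlock | None
) -> str:
    """'syntenic' iff the match overlaps the block interval by >= 1 nt."""
    if block is None:
        return "non_syntenic"
    s, e = aln.dna_span
    bs, be = block.interval
    return "syntenic" if (s < be and bs < e) else "non_syntenic"


def blocks_to_bed(blocks, path) -> None:
    with open(path, "w") as out:
        for b in blocks:
            out.write(
                f"{b.target_contig_id}\t{b.interval[0]}\t{b.interval[1]}\t"
                f"{b.trg_gene_id}|{b.target_genome_id}\t0\t"
                f"{'+' if b.orientation == 'collinear' else '-'}\n"
            )
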