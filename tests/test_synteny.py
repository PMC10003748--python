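"""Synteny anchoring via flank-gene orthologs and match-location calls."""

import numpy as np
import pytest

from trgkit.sequence_io import (
    GeneAnnotation,
    GenomeRecord,
    build_nonredundant_set,
    reverse_complement,
    translate,
)
from trgkit.synteny import classify_match_location, find_syntenic_region
from trgkit.synthetic_data import random_coding_dna, random_dna


def _locus(rng, genome_id, invert=False, split_contigs=False, gap_scale=1):
    """A three-gene locus: flank A, middle gene, flank B (plus spacers)."""
    genes = {}
    rng2 = np.random.default_rng(7)
    for name in ("flankA", "mid", "flankB"):
        genes[name] = random_coding_dna(rng2, 60)
    spacer = lambda: random_dna(rng, 120 * gap_scale, 0.44)
    order = ["flankA", "mid", "flankB"]
    pieces, anns, pos = [], [], 0
    contig = "c1"

    def put(name, dna, strand="+"):
        nonlocal pos
        anns.append(
            GeneAnnotation(f"{name}@{genome_id}", genome_id, contig, pos,
                           pos + len(dna), strand)
        )
        pieces.append(dna)
        pos += len(dna)

    pieces.append(spacer()); pos += 120 * gap_scale
    if invert:
        # joint inversion of the flank pair (strands flip, order flips)
        put("flankB", reverse_complement(genes["flankB"]), "-")
        pieces.append(spacer()); pos += 120 * gap_scale
        put("flankA", reverse_complement(genes["flankA"]), "-")
    elif split_contigs:
        put("flankA", genes["flankA"])
        contigs = [("c1", "".join(pieces) + spacer())]
        contig, pos, pieces = "c2", 0, [spacer()]
        pos = 120 * gap_scale
        put("flankB", genes["flankB"])
        contigs.append(("c2", "".join(pieces) + spacer()))
        genome = GenomeRecord(genome_id, genome_id, "gen", contigs)
        return genome, anns, genes
    else:
        put("flankA", genes["flankA"])
        pieces.append(spacer()); pos += 120 * gap_scale
        if genome_id == "SRC":
            put("mid", genes["mid"])
            pieces.append(spacer()); pos += 120 * gap_scale
        put("flankB", genes["flankB"])
    pieces.append(spacer())
    genome = GenomeRecord(genome_id, genome_id, "gen", [(contig, "".join(pieces))])
    return genome, anns, genes


@pytest.fixture()
def source(rng):
    return _locus(rng, "SRC")


def _proteins(genome, anns):
    nr = build_nonredundant_set(anns, [genome])
    by_gene = {}
    for rec in nr:
        for _g, gene in rec.sources:
            by_gene[gene] = rec
    return by_gene


def _find(source, target, scheme, **kw):
    src_genome, src_anns, _ = source
    tgt_genome, tgt_anns, _ = target
    trg = next(a for a in src_anns if a.gene_id.startswith("mid"))
    return find_syntenic_region(
        trg, src_genome, tgt_genome, src_anns, tgt_anns,
        _proteins(src_genome, src_anns), _proteins(tgt_genome, tgt_anns),
        scheme, **kw,
    )


def test_verbatim_copy_gives_collinear_block_containing_locus(source, scheme, rng):
    src_genome, src_anns, _ = source
    target = _locus(rng, "TGT")
    block = _find(source, target, scheme)
    assert block is not None
    assert block.orientation == "collinear"
    tgt_anns = target[1]
    a = next(x for x in tgt_anns if x.gene_id.startswith("flankA"))
    b = next(x for x in tgt_anns if x.gene_id.startswith("flankB"))
    assert block.interval == (a.end, b.start)
    # on a verbatim self-copy the block brackets the focal gene itself
    self_block = _find(source, source_copy(source), scheme)
    mid = next(x for x in src_anns if x.gene_id.startswith("mid"))
    assert self_block.interval[0] <= mid.start and mid.end <= self_block.interval[1]


def source_copy(source):
    genome, anns, genes = source
    copy = GenomeRecord("COPY", "COPY", "gen", list(genome.contigs))
    anns2 = [
        GeneAnnotation(a.gene_id.replace("@SRC", "@COPY"), "COPY", a.contig_id,
                       a.start, a.end, a.strand)
        for a in anns
    ]
    return copy, anns2, genes


def test_anchors_on_different_contigs_rejected(source, scheme, rng):
    target = _locus(rng, "TGT", split_contigs=True)
    assert _find(source, target, scheme) is None


def test_joint_inversion_accepted(source, scheme, rng):
    target = _locus(rng, "TGT", invert=True)
    block = _find(source, target, scheme)
    assert block is not None and block.orientation == "inverted"


def test_gap_cap_rejects_bloated_target(source, scheme, rng):
    target = _locus(rng, "TGT", gap_scale=40)
    assert _find(source, target, scheme, gap_cap_factor=5.0) is None


def test_contig_edge_locus_has_no_flank(scheme, rng):
    dna = random_coding_dna(np.random.default_rng(7), 60)
    genome = GenomeRecord("SRC", "SRC", "gen", [("c1", dna + random_dna(rng, 500, 0.44))])
    trg = GeneAnnotation("mid@SRC", "SRC", "c1", 0, len(dna), "+")
    assert (
        find_syntenic_region(trg, genome, genome, [trg], [trg], {}, {}, scheme)
        is None
    )


class FakeAln:
    def __init__(self, span):
        self.dna_span = span


class FakeBlock:
    def __init__(self, interval):
        self.interval = interval


def test_match_location_boundary_conventions():
    block = FakeBlock((100, 200))
    assert classify_match_location(FakeAln((150, 160)), block) == "syntenic"
    assert classify_match_location(FakeAln((150, 160)), None) == "non_syntenic"
    # half-open: abutting spans share no nucleotide
    assert classify_match_location(FakeAln((200, 250)), block) == "non_syntenic"
    assert classify_match_location(FakeAln((50, 100)), block) == "non_syntenic"
    assert classify_match_location(FakeAln((199, 201)), block) == "syntenic"
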