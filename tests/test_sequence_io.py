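"""Format I/O, translation, the nonredundant protein universe, ORF
extraction against a brute-force six-frame oracle, and masking."""

import gzip

import pytest

from trgkit.sequence_io import (
    FastaParseError,
    GeneAnnotation,
    GenomeRecord,
    build_nonredundant_set,
    extract_orfs,
    mask_annotated_regions,
    read_fasta,
    read_gff3,
    translate,
    translate_gene,
    write_gff3,
)
from trgkit.synthetic_data import random_dna

from _oracles import six_frame_orfs


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n")
        assert read_fasta(p) == [("a", "ACGT")]

    def test_order_multiline_and_case(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">b desc\nacg\nt\n>a\nTTTT\n")
        assert read_fasta(p) == [("b", "ACGT"), ("a", "TTTT")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("ACGT\n>a\nACGT\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "a.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">z\nGGCC\n")
        assert read_fasta(p) == [("z", "GGCC")]


class TestTranslate:
    @pytest.mark.parametrize(
        "dna,expected",
        [("ATGAAACTG", "MKL"), ("ATGTAA", "M*"), ("ATGNNN", "MX")],
    )
    def test_examples(self, dna, expected):
        assert translate(dna) == expected

    def test_length_contract(self):
        with pytest.raises(ValueError):
            translate("ATGA")


def _genome(contig, genome_id="G1"):
    return GenomeRecord(
        genome_id=genome_id, species_id="sp1", genus_id="gen",
        contigs=[("c1", contig)],
    )


def _ann(gene_id, start, end, strand="+", genome_id="G1"):
    return GeneAnnotation(
        gene_id=gene_id, genome_id=genome_id, contig_id="c1",
        start=start, end=end, strand=strand,
    )


class TestNonredundantSet:
    def test_identical_products_merge(self):
        genome = _genome("ATGAAACTGTAA" + "ATGAAACTGTAA" + "ATGTGGTAA")
        anns = [_ann("g1", 0, 12), _ann("g2", 12, 24), _ann("g3", 24, 33)]
        nr = build_nonredundant_set(anns, [genome])
        assert len(nr) == 2
        assert nr.n_input_genes == 3
        merged = nr.by_id(
            next(r.protein_id for r in nr if r.sequence == "MKL")
        )
        assert {g for _, g in [(s[0], s[1]) for s in merged.sources]} == {"g1", "g2"}

    def test_empty_input(self):
        nr = build_nonredundant_set([], [])
        assert len(nr) == 0 and nr.n_input_genes == 0

    def test_matches_independent_translation_set(self, small_clade):
        """Record count equals the distinct-translation count computed
        with a plain set over independently translated gene calls."""
        genomes = {g.genome_id: g for g in small_clade.genus_genomes}
        expected = {
            translate_gene(genomes[a.genome_id], a)
            for a in small_clade.genus_annotations
        }
        nr = build_nonredundant_set(
            small_clade.genus_annotations, small_clade.genus_genomes
        )
        assert len(nr) == len(expected)
        assert sum(len(r.sources) for r in nr) == len(
            small_clade.genus_annotations
        )

    def test_minus_strand_product_round_trip(self):
        from trgkit.sequence_io import reverse_complement

        cds = "ATGAAACTGTAA"
        genome = _genome("TT" + reverse_complement(cds) + "GG")
        aa = translate_gene(genome, _ann("g1", 2, 14, strand="-"))
        assert aa == "MKL"


class TestExtractOrfs:
    def test_minimal_orf(self):
        genome = _genome("ATGAAATAA")
        (orf,) = extract_orfs(genome, [], min_len_codons=2)
        assert (orf.start, orf.end, orf.strand) == (0, 9, "+")

    def test_annotated_region_excluded(self):
        genome = _genome("ATGAAATAA")
        assert extract_orfs(genome, [_ann("g", 0, 9)], min_len_codons=2) == []

    def test_matches_six_frame_oracle(self, rng):
        seq = random_dna(rng, 10_000, 0.44)
        genome = _genome(seq)
        got = [
            (o.start, o.end, o.strand)
            for o in extract_orfs(genome, [], min_len_codons=10)
        ]
        assert sorted(got) == six_frame_orfs(seq, 10)

    def test_min_len_contract(self):
        with pytest.raises(ValueError):
            extract_orfs(_genome("ATGAAATAA"), [], min_len_codons=1)


class TestMask:
    def test_hard_mask(self):
        masked = mask_annotated_regions(_genome("ACGTACGT"), [_ann("g", 2, 5)])
        assert masked.contigs[0][1] == "ACNNNCGT"

    def test_no_annotations_identity(self):
        g = _genome("ACGTACGT")
        assert mask_annotated_regions(g, []).contigs[0][1] == g.contigs[0][1]

    def test_idempotent_and_union(self):
        g = _genome("ACGTACGTACGT")
        anns = [_ann("a", 0, 6), _ann("b", 4, 8)]
        once = mask_annotated_regions(g, anns)
        twice = mask_annotated_regions(once, anns)
        assert once.contigs[0][1] == "NNNNNNNNACGT"
        assert once.contigs[0][1] == twice.contigs[0][1]


def test_gff3_round_trip(tmp_path):
    anns = [
        _ann("g1", 0, 12),
        _ann("g2", 20, 29, strand="-"),
    ]
    path = tmp_path / "x.gff3"
    write_gff3(path, anns)
    back = read_gff3(path, "G1")
    assert [(a.gene_id, a.start, a.end, a.strand) for a in back] == [
        ("g1", 0, 12, "+"), ("g2", 20, 29, "-"),
    ]


def test_genome_invariants():
    with pytest.raises(ValueError):
        GenomeRecord("g", "s", "x", contigs=[("c", "ACGU")])
    with pytest.raises(ValueError):
        GenomeRecord("g", "s", "x", contigs=[("c", "AC"), ("c", "GT")])
    with pytest.raises(ValueError):
        GeneAnnotation("g", "G", "c", 5, 5, "+")
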