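"""Sequence input/output and the nonredundant protein universe.

Reads genome FASTA and gene annotations (GFF3 CDS rows or tabular gene
calls), translates coding sequences with the bacterial genetic code,
collapses identical protein sequences into a nonredundant set with
per-genome provenance, extracts unannotated open reading frames, and
hard-masks annotated regions.

Coordinates are 0-based half-open throughout; GFF3 readers/writers convert
from/to 1-based inclusive at the file boundary only.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# NCBI translation table 11 (bacterial); alternative initiation codons are
# rendered as 'M' only at ORF starts (see extract_orfs).
GENETIC_CODE_TABLE = 11
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


class FastaParseError(ValueError):
    """Malformed FASTA input (sequence data before any header)."""


class ResolutionError(KeyError):
    """An annotation references a genome/contig that cannot be resolved."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene call on a contig (0-based half-open)."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A genome assembly: contigs plus taxonomic provenance."""

    genome_id: str
    species_id: str
    genus_id: str
    contigs: list[tuple[str, str]]
    assembly_level: str = "complete"

    def __post_init__(self) -> None:
        if self.assembly_level not in ("scaffold", "chromosome", "complete"):
            raise ValueError(f"unknown assembly_level {self.assembly_level!r}")
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"genome {self.genome_id}: duplicate contig ids")
        for cid, seq in self.contigs:
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"genome {self.genome_id} contig {cid}: "
                    f"non-ACGTN characters {sorted(bad)}"
                )

    def contig(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise ResolutionError(
            f"contig {contig_id!r} not found in genome {self.genome_id!r}"
        )

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass(frozen=True)
class ProteinRecord:
    """One distinct amino-acid sequence and every gene call encoding it."""

    protein_id: str
    sequence: str
    sources: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def source_genomes(self) -> set[str]:
        return {g for g, _ in self.sources}


@dataclass
class NonredundantProteinSet:
    """The deduplicated protein universe of a genome collection."""

    records: list[ProteinRecord]
    n_input_genes: int

    def __post_init__(self) -> None:
        if sum(len(r.sources) for r in self.records) != self.n_input_genes:
            raise ValueError("source multiplicities do not sum to input gene count")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_residues(self) -> int:
        return sum(len(r.sequence) for r in self.records)

    def by_id(self, protein_id: str) -> ProteinRecord:
        for r in self.records:
            if r.protein_id == protein_id:
                return r
        raise KeyError(protein_id)


def _open_text(path):
    """Open a possibly gzip-compressed text file."""
    if hasattr(path, "read"):
        return path
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into ``[(id, SEQUENCE), ...]`` in file order.

    The record id is the first whitespace-delimited token of the header;
    sequences are uppercased. Sequence data before the first header raises
    :class:`FastaParseError` naming the offending line number.
    """
    records: list[tuple[str, str]] = []
    current_id = None
    chunks: list[str] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    records.append((current_id, "".join(chunks).upper()))
                current_id = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before first FASTA header"
                    )
                chunks.append(line)
    if current_id is not None:
        records.append((current_id, "".join(chunks).upper()))
    return records


def write_fasta(path, records, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def _gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path, genome_id: str) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file (1-based inclusive -> half-open)."""
    annotations = []
    with _open_text(path) as handle:
        for raw in handle:
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            attrs = _gff3_attributes(fields[8])
            annotations.append(
                GeneAnnotation(
                    gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}-{fields[4]}"),
                    genome_id=genome_id,
                    contig_id=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    product=attrs.get("product", ""),
                )
            )
    return annotations


def write_gff3(path, annotations) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={a.gene_id}"
            if a.product:
                attrs += f";product={a.product}"
            out.write(
                "\t".join(
                    [
                        a.contig_id,
                        "trgkit",
                        "CDS",
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        a.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gene_table(path, genome_id: str | None = None) -> list[GeneAnnotation]:
    """Read a tab-separated gene table.

    Columns: gene_id, genome_id, contig_id, start, end, strand[, product].
    A header line starting with 'gene_id' is skipped.
    """
    annotations = []
    with _open_text(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            f = line.split("\t")
            annotations.append(
                GeneAnnotation(
                    gene_id=f[0],
                    genome_id=genome_id or f[1],
                    contig_id=f[2],
                    start=int(f[3]),
                    end=int(f[4]),
                    strand=f[5],
                    product=f[6] if len(f) > 6 else "",
                )
            )
    return annotations


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def translate(dna: str, table: int = GENETIC_CODE_TABLE) -> str:
    """Translate DNA (length divisible by 3); stops as '*', N-codons as 'X'."""
    if len(dna) % 3 != 0:
        raise ValueError(f"DNA length {len(dna)} not divisible by 3")
    if not dna:
        return ""
    return str(Seq(dna).translate(table=table))


def extract_gene_dna(genome: GenomeRecord, annotation: GeneAnnotation) -> str:
    """Spliced-strand DNA of a gene call (reverse-complemented for '-')."""
    contig = genome.contig(annotation.contig_id)
    if annotation.end > len(contig):
        raise ResolutionError(
            f"gene {annotation.gene_id}: interval exceeds contig length"
        )
    dna = contig[annotation.start : annotation.end]
    if annotation.strand == "-":
        dna = reverse_complement(dna)
    return dna


def translate_gene(genome: GenomeRecord, annotation: GeneAnnotation) -> str:
    """Protein product of a coding call, without the terminal stop."""
    aa = translate(extract_gene_dna(genome, annotation))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(
            f"gene {annotation.gene_id}: internal stop codon in translation"
        )
    return aa


def build_nonredundant_set(
    annotations, genomes
) -> NonredundantProteinSet:
    """Collapse identical translated products into one record per sequence.

    Record order is lexicographic by sequence, and ids are assigned in that
    order, so the result is deterministic for a given input collection.
    """
    genome_index = {g.genome_id: g for g in genomes}
    by_sequence: dict[str, set[tuple[str, str]]] = {}
    n_input = 0
    for ann in annotations:
        if ann.genome_id not in genome_index:
            raise ResolutionError(
                f"gene {ann.gene_id}: unknown genome {ann.genome_id!r}"
            )
        aa = translate_gene(genome_index[ann.genome_id], ann)
        by_sequence.setdefault(aa, set()).add((ann.genome_id, ann.gene_id))
        n_input += 1
    records = [
        ProteinRecord(
            protein_id=f"P{idx:06d}",
            sequence=sequence,
            sources=frozenset(sources),
        )
        for idx, (sequence, sources) in enumerate(sorted(by_sequence.items()))
    ]
    return NonredundantProteinSet(records=records, n_input_genes=n_input)


def _orfs_in_frame(contig_seq: str, offset: int) -> list[tuple[int, int]]:
    """Maximal start->stop ORF intervals (forward coordinates, nt) in a frame.

    Within each stop-to-stop segment the ORF runs from the first start codon
    through the stop codon (intervals include the stop codon).
    """
    orfs = []
    start = None
    i = offset
    n = len(contig_seq)
    while i + 3 <= n:
        codon = contig_seq[i : i + 3]
        if codon in STOP_CODONS:
            if start is not None:
                orfs.append((start, i + 3))
            start = None
        elif start is None and codon in START_CODONS:
            start = i
        i += 3
    return orfs


def extract_orfs(
    genome: GenomeRecord, annotations, min_len_codons: int = 10
) -> list[GeneAnnotation]:
    """Unannotated open reading frames on both strands.

    An ORF runs from the first ATG/GTG/TTG of a stop-to-stop segment through
    the in-frame stop codon; the encoded peptide must be at least
    ``min_len_codons`` residues; ORFs overlapping any annotated feature (on
    either strand) by one or more nucleotides are discarded. Order is
    deterministic: (contig, start, strand).
    """
    if min_len_codons < 2:
        raise ValueError("min_len_codons must be >= 2")
    annotated = {}
    for a in annotations:
        annotated.setdefault(a.contig_id, []).append((a.start, a.end))
    results = []
    counter = 0
    for contig_id, seq in genome.contigs:
        occupied = sorted(annotated.get(contig_id, []))
        candidates = []
        for frame in range(3):
            for s, e in _orfs_in_frame(seq, frame):
                candidates.append((s, e, "+"))
        rc = reverse_complement(seq)
        for frame in range(3):
            for s, e in _orfs_in_frame(rc, frame):
                # map reverse-strand coordinates onto the forward strand
                candidates.append((len(seq) - e, len(seq) - s, "-"))
        for s, e, strand in sorted(candidates):
            if (e - s) // 3 - 1 < min_len_codons:
                continue
            if any(s < oe and os_ < e for os_, oe in occupied):
                continue
            results.append(
                GeneAnnotation(
                    gene_id=f"{genome.genome_id}|orf{counter:05d}",
                    genome_id=genome.genome_id,
                    contig_id=contig_id,
                    start=s,
                    end=e,
                    strand=strand,
                    product="unannotated ORF",
                )
            )
            counter += 1
    return results


def orf_peptide(genome: GenomeRecord, orf: GeneAnnotation) -> str:
    """Peptide encoded by an ORF call; alternative starts rendered as 'M'."""
    aa = translate(extract_gene_dna(genome, orf))
    if aa.endswith("*"):
        aa = aa[:-1]
    return ("M" + aa[1:]) if aa else aa


def mask_annotated_regions(genome: GenomeRecord, annotations) -> GenomeRecord:
    """Hard-mask ('N') every annotated interval; contig lengths unchanged."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for a in annotations:
        if a.genome_id != genome.genome_id:
            continue
        by_contig.setdefault(a.contig_id, []).append((a.start, a.end))
    new_contigs = []
    for cid, seq in genome.contigs:
        intervals = by_contig.get(cid)
        if intervals:
            chars = list(seq)
            for s, e in intervals:
                chars[s:e] = "N" * (min(e, len(seq)) - s)
            seq = "".join(chars)
        new_contigs.append((cid, seq))
    return replace(genome, contigs=new_contigs)
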