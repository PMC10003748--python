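"""The restricted-gene classification state machine.

Stages (in fixed order):

1. external protein screen: a query with a qualifying hit in the external
   protein collection is not restricted;
2. noncoding-space scan of external genomes: synteny-anchored where a
   flank pair can be mapped, whole-genome otherwise; reciprocally
   validated matches are called coding (>= 90% query coverage, no
   frameshifts, no premature stops -> a gene missed by annotation) or
   noncoding (a disrupted or partial trace);
3. ortholog search across the genus (annotated proteins and masked
   noncoding space) and paralog search within the source genome;
4. a single transitive-filter pass removing candidates with any
   non-restricted homolog, then taxonomic-level assignment.

Every sequence comparison goes through the detection model of
:mod:`trgkit.align_core` (single E-value threshold plus bit-score floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import FrameshiftAlignment, ScoringScheme, default_scheme
from .rbh import RBHPair, best_hit, reciprocal_tfs_genome
from .sequence_io import (
    GenomeRecord,
    NonredundantProteinSet,
    ProteinRecord,
    build_nonredundant_set,
    extract_gene_dna,
    mask_annotated_regions,
)
from .synteny import SyntenyBlock, classify_match_location, find_syntenic_region

STATUSES = (
    "non_trg_external_hit",
    "putative",
    "missed_annotation",
    "trg_noncoding_trace",
    "trg_no_trace",
    "removed_transitive",
)

_PRESCREEN_K = 18  # nt k-mer length for the shared-word detectability gate


@dataclass
class PipelineConfig:
    """Thresholds and knobs of a pipeline run."""

    e_max: float = 10.0
    coverage_coding: float = 0.90
    scheme: ScoringScheme = field(default_factory=default_scheme)
    orf_min_codons: int = 10
    synteny_gap_cap: float = 5.0
    high_coverage: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.coverage_coding <= 1):
            raise ValueError("coverage_coding must be in (0, 1]")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")


@dataclass
class Homolog:
    """A recorded homolog of a candidate, with its restricted status."""

    homolog_id: str
    kind: str  # genus_ortholog | species_ortholog | paralog | noncoding_ortholog | noncoding_paralog
    restricted: bool
    genome_id: str | None = None


@dataclass
class TRGCandidate:
    """Per-protein classification state through the pipeline."""

    protein: ProteinRecord
    status: str = "putative"
    level: str = "none"
    noncoding_hits: list = field(default_factory=list)  # (aln, location, genome_id)
    coding_hits: list = field(default_factory=list)
    homologs: list[Homolog] = field(default_factory=list)
    external_hit: object = None
    synteny_blocks: dict = field(default_factory=dict)  # genome_id -> SyntenyBlock
    removal_cause: str | None = None  # 'ortholog' | 'paralog'

    @property
    def protein_id(self) -> str:
        return self.protein.protein_id

    def is_restricted(self) -> bool:
        """Does this sequence currently look taxonomically restricted?"""
        return self.status in ("putative", "trg_noncoding_trace", "trg_no_trace")


@dataclass
class StatusLedger:
    """Stage counts of one pipeline run."""

    n_input: int = 0
    n_putative: int = 0
    n_missed_annotation: int = 0
    n_syntenic_found: int = 0
    n_syntenic_with_hit: int = 0
    n_noncoding_only: int = 0
    n_no_similarity: int = 0
    n_removed_transitive_orth: int = 0
    n_removed_transitive_para: int = 0
    n_final: int = 0
    n_species_specific: int = 0

    def check(self) -> None:
        expected = (
            self.n_putative
            - self.n_missed_annotation
            - self.n_removed_transitive_orth
            - self.n_removed_transitive_para
        )
        if self.n_final != expected:
            raise AssertionError(
                f"ledger inconsistent: n_final={self.n_final}, expected {expected}"
            )

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class PipelineContext:
    """Indexed view of a genus + external collection for one run.

    Builds the nonredundant protein universes, per-genome proteomes,
    per-gene protein lookups, masked genomes and k-mer detectability
    indexes once, so the stage functions stay cheap.
    """

    def __init__(
        self,
        genus_genomes,
        genus_annotations,
        external_genomes,
        external_annotations,
        cfg: PipelineConfig,
    ):
        self.cfg = cfg
        self.genus_genomes = {g.genome_id: g for g in genus_genomes}
        self.external_genomes = {g.genome_id: g for g in external_genomes}
        self.genus_annotations = list(genus_annotations)
        self.external_annotations = list(external_annotations)
        self.genus_nr = build_nonredundant_set(genus_annotations, genus_genomes)
        self.external_nr = build_nonredundant_set(
            external_annotations, external_genomes
        )
        self.species_of = {
            g.genome_id: g.species_id
            for g in list(genus_genomes) + list(external_genomes)
        }
        self._proteins_by_gene = {}
        for nr in (self.genus_nr, self.external_nr):
            for rec in nr:
                for _genome, gene in rec.sources:
                    self._proteins_by_gene[gene] = rec
        self._proteome_cache: dict[str, list[ProteinRecord]] = {}
        self._masked_cache: dict[str, GenomeRecord] = {}
        self._kmer_cache: dict[tuple, set] = {}
        self._anchor_cache: dict[tuple, object] = {}
        self._gene_index = {}
        for a in self.genus_annotations + self.external_annotations:
            self._gene_index[a.gene_id] = a

    # ---- lookups -------------------------------------------------------
    def protein_of_gene(self, gene_id: str) -> ProteinRecord | None:
        return self._proteins_by_gene.get(gene_id)

    def annotation_of_gene(self, gene_id: str):
        return self._gene_index[gene_id]

    def annotations_of_genome(self, genome_id: str):
        if genome_id in self.genus_genomes:
            pool = self.genus_annotations
        else:
            pool = self.external_annotations
        return [a for a in pool if a.genome_id == genome_id]

    def genome(self, genome_id: str) -> GenomeRecord:
        return self.genus_genomes.get(genome_id) or self.external_genomes[genome_id]

    def proteome(self, genome_id: str) -> list[ProteinRecord]:
        """Nonredundant records with at least one source in the genome."""
        if genome_id not in self._proteome_cache:
            nr = (
                self.genus_nr
                if genome_id in self.genus_genomes
                else self.external_nr
            )
            self._proteome_cache[genome_id] = [
                r for r in nr if genome_id in r.source_genomes
            ]
        return self._proteome_cache[genome_id]

    def masked_genome(self, genome_id: str) -> GenomeRecord:
        if genome_id not in self._masked_cache:
            g = self.genome(genome_id)
            self._masked_cache[genome_id] = mask_annotated_regions(
                g, self.annotations_of_genome(genome_id)
            )
        return self._masked_cache[genome_id]

    def source_locus(self, candidate: TRGCandidate):
        """Deterministic representative source (annotation, genome)."""
        genome_id, gene_id = sorted(candidate.protein.sources)[0]
        return self.annotation_of_gene(gene_id), self.genome(genome_id)

    # ---- detectability gate -------------------------------------------
    def _genome_kmers(self, genome: GenomeRecord, tag: str) -> set:
        key = (genome.genome_id, tag)
        if key not in self._kmer_cache:
            k = _PRESCREEN_K
            kmers: set[str] = set()
            for _cid, seq in genome.contigs:
                for i in range(len(seq) - k + 1):
                    word = seq[i : i + k]
                    if "N" not in word:
                        kmers.add(word)
            self._kmer_cache[key] = kmers
        return self._kmer_cache[key]

    def shares_word(self, query_dna: str, genome: GenomeRecord, tag: str) -> bool:
        """Does the genome share an exact k-mer with the query CDS (either
        strand)? A qualifying alignment without a single shared word of
        this length is not achievable at the detection floor, so a negative
        gate safely skips the full DP."""
        from .sequence_io import reverse_complement

        kmers = self._genome_kmers(genome, tag)
        k = _PRESCREEN_K
        for probe in (query_dna, reverse_complement(query_dna)):
            for i in range(len(probe) - k + 1):
                if probe[i : i + k] in kmers:
                    return True
        return False


# ---------------------------------------------------------------------------
# stage 1: external protein screen
# ---------------------------------------------------------------------------

def screen_external_proteins(
    bacteria_nr: NonredundantProteinSet,
    external_protein_sets,
    cfg: PipelineConfig,
) -> list[TRGCandidate]:
    """Mark every query as putative (no qualifying external hit) or not.

    ``external_protein_sets`` is one protein collection or a sequence of
    collections searched in order (two-tier screen: reference proteomes
    first, full collection second); a hit in any tier disqualifies.
    """
    if external_protein_sets and isinstance(
        external_protein_sets[0], ProteinRecord
    ):
        tiers = [list(external_protein_sets)]
    else:
        tiers = [list(t) for t in external_protein_sets]
    candidates = []
    for record in bacteria_nr:
        hit = None
        for tier in tiers:
            if not tier:
                continue
            hit = best_hit(record, tier, cfg.scheme, cfg.e_max)
            if hit is not None:
                break
        candidates.append(
            TRGCandidate(
                protein=record,
                status="putative" if hit is None else "non_trg_external_hit",
                external_hit=hit,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# stage 2: noncoding-space scan
# ---------------------------------------------------------------------------

def classify_genomic_match(
    candidate: TRGCandidate, aln: FrameshiftAlignment, cfg: PipelineConfig
) -> str:
    """'coding' iff high coverage and free of frameshifts and stops."""
    if (
        aln.query_coverage >= cfg.coverage_coding
        and aln.n_frameshifts == 0
        and aln.n_stops == 0
    ):
        return "coding"
    return "noncoding"


def _scan_one_genome(ctx, candidate, target_genome):
    """Synteny-anchored (preferred) or whole-genome reciprocal search."""
    cfg = ctx.cfg
    source_ann, source_genome = ctx.source_locus(candidate)
    block = _find_block(ctx, candidate, source_ann, source_genome, target_genome)
    source_proteome = ctx.proteome(source_genome.genome_id)
    if block is not None:
        candidate.synteny_blocks[target_genome.genome_id] = block
        if block.interval[1] - block.interval[0] < 3:
            return None, block
        result = reciprocal_tfs_genome(
            candidate.protein,
            target_genome,
            source_proteome,
            cfg.scheme,
            cfg.e_max,
            interval=(block.target_contig_id, *block.interval),
        )
    else:
        query_dna = extract_gene_dna(source_genome, source_ann)
        if not ctx.shares_word(query_dna, target_genome, "raw"):
            return None, None
        result = reciprocal_tfs_genome(
            candidate.protein,
            target_genome,
            source_proteome,
            cfg.scheme,
            cfg.e_max,
        )
    if result is None:
        return None, block
    _cid, fwd, _rev = result
    return fwd, block


def _find_block(ctx, candidate, source_ann, source_genome, target_genome):
    key = (source_ann.gene_id, target_genome.genome_id)
    if key not in ctx._anchor_cache:
        ctx._anchor_cache[key] = find_syntenic_region(
            source_ann,
            source_genome,
            target_genome,
            ctx.annotations_of_genome(source_genome.genome_id),
            ctx.annotations_of_genome(target_genome.genome_id),
            {
                a.gene_id: ctx.protein_of_gene(a.gene_id)
                for a in ctx.annotations_of_genome(source_genome.genome_id)
            },
            {
                a.gene_id: ctx.protein_of_gene(a.gene_id)
                for a in ctx.annotations_of_genome(target_genome.genome_id)
            },
            ctx.cfg.scheme,
            ctx.cfg.e_max,
            ctx.cfg.synteny_gap_cap,
        )
    return ctx._anchor_cache[key]


def scan_noncoding_space(candidates, ctx: PipelineContext) -> list[TRGCandidate]:
    """Scan every external genome for each putative candidate.

    Coding-classified reciprocal matches turn the candidate into a missed
    annotation; noncoding matches accumulate with their syntenic /
    non-syntenic location; candidates with neither become no-trace TRGs.
    """
    cfg = ctx.cfg
    for candidate in candidates:
        if candidate.status != "putative":
            continue
        for genome_id in sorted(ctx.external_genomes):
            target = ctx.external_genomes[genome_id]
            fwd, block = _scan_one_genome(ctx, candidate, target)
            if fwd is None:
                continue
            call = classify_genomic_match(candidate, fwd, cfg)
            location = classify_match_location(fwd, block)
            if call == "coding":
                candidate.coding_hits.append((fwd, location, genome_id))
            else:
                candidate.noncoding_hits.append((fwd, location, genome_id))
        if candidate.coding_hits:
            candidate.status = "missed_annotation"
        elif candidate.noncoding_hits:
            candidate.status = "trg_noncoding_trace"
        else:
            candidate.status = "trg_no_trace"
    return candidates


# ---------------------------------------------------------------------------
# stage 3: genus orthologs and paralogs
# ---------------------------------------------------------------------------

def _restricted_status_of_protein(ctx, candidates_by_id, protein_id) -> bool:
    cand = candidates_by_id.get(protein_id)
    if cand is None:
        return False
    return cand.is_restricted()


def _noncoding_region_restricted(ctx, peptide: str) -> bool:
    """A nonannotated homologous region counts as restricted unless its
    implied peptide itself has a qualifying external protein hit."""
    from .rbh import peptide_record

    if not peptide:
        return True
    hit = best_hit(
        peptide_record(peptide), list(ctx.external_nr), ctx.cfg.scheme, ctx.cfg.e_max
    )
    return hit is None


def search_genus_orthologs(candidates, ctx: PipelineContext):
    """Record annotated and noncoding orthologs across the genus.

    Returns (candidates, rbh_pairs): the protein-mode RBH pairs feed the
    family graph downstream.
    """
    cfg = ctx.cfg
    candidates_by_id = {c.protein_id: c for c in candidates}
    rbh_pairs: list[RBHPair] = []
    seen_pairs = set()
    for candidate in candidates:
        if candidate.status not in ("trg_noncoding_trace", "trg_no_trace"):
            continue
        own_genomes = candidate.protein.source_genomes
        own_species = {ctx.species_of[g] for g in own_genomes}
        source_genome_id = sorted(own_genomes)[0]
        source_proteome = ctx.proteome(source_genome_id)
        for genome_id in sorted(ctx.genus_genomes):
            if genome_id in own_genomes:
                continue
            # annotated ortholog: reciprocal best protein hit
            target_proteome = [
                p for p in ctx.proteome(genome_id)
                if p.protein_id != candidate.protein_id
            ]
            fwd = best_hit(candidate.protein, target_proteome, cfg.scheme, cfg.e_max)
            if fwd is not None:
                hit_rec = next(
                    p for p in target_proteome if p.protein_id == fwd.subject_id
                )
                rev = best_hit(hit_rec, source_proteome, cfg.scheme, cfg.e_max)
                if rev is not None and rev.subject_id == candidate.protein_id:
                    same_species = ctx.species_of[genome_id] in own_species
                    candidate.homologs.append(
                        Homolog(
                            homolog_id=hit_rec.protein_id,
                            kind="species_ortholog" if same_species else "genus_ortholog",
                            restricted=_restricted_status_of_protein(
                                ctx, candidates_by_id, hit_rec.protein_id
                            ),
                            genome_id=genome_id,
                        )
                    )
                    pair_key = tuple(
                        sorted((candidate.protein_id, hit_rec.protein_id))
                    )
                    if pair_key not in seen_pairs:
                        seen_pairs.add(pair_key)
                        rbh_pairs.append(
                            RBHPair(
                                a_id=candidate.protein_id,
                                b_id=hit_rec.protein_id,
                                mode="prot-prot",
                                forward=fwd,
                                reverse=rev,
                            )
                        )
            # noncoding ortholog: masked-genome reciprocal DNA search
            source_ann, source_genome = ctx.source_locus(candidate)
            query_dna = extract_gene_dna(source_genome, source_ann)
            masked = ctx.masked_genome(genome_id)
            if ctx.shares_word(query_dna, masked, "masked"):
                result = reciprocal_tfs_genome(
                    candidate.protein, masked, source_proteome, cfg.scheme, cfg.e_max
                )
                if result is not None:
                    _cid, nc_fwd, _rev = result
                    candidate.homologs.append(
                        Homolog(
                            homolog_id=f"{genome_id}:{nc_fwd.dna_span[0]}-{nc_fwd.dna_span[1]}",
                            kind="noncoding_ortholog",
                            restricted=_noncoding_region_restricted(
                                ctx, nc_fwd.implied_peptide
                            ),
                            genome_id=genome_id,
                        )
                    )
    return candidates, rbh_pairs


def search_paralogs(
    candidate: TRGCandidate, ctx: PipelineContext, pair_sink: list | None = None
) -> TRGCandidate:
    """Record annotated and noncoding paralogs within the source genome."""
    cfg = ctx.cfg
    if candidate.status not in ("trg_noncoding_trace", "trg_no_trace"):
        return candidate
    for genome_id in sorted(candidate.protein.source_genomes):
        # identical duplicate gene calls collapse into one record: two or
        # more sources in one genome are a (trivially restricted) paralog
        n_here = sum(1 for g, _ in candidate.protein.sources if g == genome_id)
        if n_here > 1:
            candidate.homologs.append(
                Homolog(
                    homolog_id=candidate.protein_id,
                    kind="paralog",
                    restricted=candidate.is_restricted(),
                    genome_id=genome_id,
                )
            )
        proteome = ctx.proteome(genome_id)
        others = [p for p in proteome if p.protein_id != candidate.protein_id]
        if others:
            fwd = best_hit(candidate.protein, others, cfg.scheme, cfg.e_max)
            if fwd is not None:
                hit_rec = next(
                    p for p in others if p.protein_id == fwd.subject_id
                )
                rev = best_hit(
                    hit_rec,
                    [p for p in proteome if p.protein_id != hit_rec.protein_id],
                    cfg.scheme,
                    cfg.e_max,
                )
                if rev is not None and rev.subject_id == candidate.protein_id:
                    candidate.homologs.append(
                        Homolog(
                            homolog_id=hit_rec.protein_id,
                            kind="paralog",
                            restricted=ctx._paralog_restricted(hit_rec.protein_id)
                            if hasattr(ctx, "_paralog_restricted")
                            else True,
                            genome_id=genome_id,
                        )
                    )
                    if pair_sink is not None:
                        pair_sink.append(
                            RBHPair(
                                a_id=candidate.protein_id,
                                b_id=hit_rec.protein_id,
                                mode="prot-prot",
                                forward=fwd,
                                reverse=rev,
                            )
                        )
        # noncoding paralog in the masked own genome
        source_ann, source_genome = ctx.source_locus(candidate)
        query_dna = extract_gene_dna(source_genome, source_ann)
        masked = ctx.masked_genome(genome_id)
        if ctx.shares_word(query_dna, masked, "masked"):
            result = reciprocal_tfs_genome(
                candidate.protein, masked, ctx.proteome(genome_id),
                cfg.scheme, cfg.e_max,
            )
            if result is not None:
                _cid, nc_fwd, _rev = result
                candidate.homologs.append(
                    Homolog(
                        homolog_id=f"{genome_id}:{nc_fwd.dna_span[0]}-{nc_fwd.dna_span[1]}",
                        kind="noncoding_paralog",
                        restricted=_noncoding_region_restricted(
                            ctx, nc_fwd.implied_peptide
                        ),
                        genome_id=genome_id,
                    )
                )
    return candidate


def search_all_paralogs(candidates, ctx: PipelineContext):
    """Paralog search for every remaining candidate, with correct
    restricted flags for annotated paralog partners; returns the
    within-genome RBH pairs for the family graph."""
    candidates_by_id = {c.protein_id: c for c in candidates}
    ctx._paralog_restricted = lambda pid: _restricted_status_of_protein(
        ctx, candidates_by_id, pid
    )
    pairs: list[RBHPair] = []
    seen = set()
    raw: list[RBHPair] = []
    for candidate in candidates:
        search_paralogs(candidate, ctx, pair_sink=raw)
    for pair in raw:
        key = tuple(sorted(pair.ids()))
        if key not in seen:
            seen.add(key)
            pairs.append(pair)
    del ctx._paralog_restricted
    return candidates, pairs


# ---------------------------------------------------------------------------
# stage 4: transitive filter and level assignment
# ---------------------------------------------------------------------------

def transitive_filter(candidates):
    """Remove candidates with any non-restricted recorded homolog.

    A single pass over the recorded flags (order-independent): removal is
    attributed to orthologs when any non-restricted ortholog exists, else
    to paralogs.
    """
    kept, removed = [], []
    for candidate in candidates:
        if candidate.status not in ("trg_noncoding_trace", "trg_no_trace"):
            continue
        bad = [h for h in candidate.homologs if not h.restricted]
        if bad:
            candidate.status = "removed_transitive"
            candidate.removal_cause = (
                "ortholog"
                if any("ortholog" in h.kind for h in bad)
                else "paralog"
            )
            removed.append(candidate)
        else:
            kept.append(candidate)
    return kept, removed


def assign_taxonomic_level(candidate: TRGCandidate, species_of: dict) -> str:
    """'species' iff the candidate and its restricted homologs are confined
    to a single species; 'genus' otherwise."""
    if candidate.status not in ("trg_noncoding_trace", "trg_no_trace"):
        candidate.level = "none"
        return candidate.level
    species = {species_of[g] for g in candidate.protein.source_genomes}
    for h in candidate.homologs:
        if h.restricted and h.genome_id is not None:
            species.add(species_of[h.genome_id])
    candidate.level = "species" if len(species) == 1 else "genus"
    return candidate.level


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_classification(
    genus_genomes,
    genus_annotations,
    external_genomes,
    external_annotations,
    cfg: PipelineConfig | None = None,
):
    """Run the full schema; returns (candidates, rbh_pairs, ledger, ctx)."""
    cfg = cfg or PipelineConfig()
    ctx = PipelineContext(
        genus_genomes, genus_annotations, external_genomes,
        external_annotations, cfg,
    )
    candidates = screen_external_proteins(
        ctx.genus_nr, list(ctx.external_nr), cfg
    )
    scan_noncoding_space(candidates, ctx)
    candidates, rbh_pairs = search_genus_orthologs(candidates, ctx)
    _, paralog_pairs = search_all_paralogs(candidates, ctx)
    rbh_pairs = rbh_pairs + paralog_pairs
    transitive_filter(candidates)
    for c in candidates:
        assign_taxonomic_level(c, ctx.species_of)
    ledger = build_ledger(candidates)
    return candidates, rbh_pairs, ledger, ctx


def build_ledger(candidates) -> StatusLedger:
    ledger = StatusLedger()
    ledger.n_input = len(candidates)
    for c in candidates:
        if c.status != "non_trg_external_hit":
            ledger.n_putative += 1
        if c.status == "missed_annotation":
            ledger.n_missed_annotation += 1
        if c.synteny_blocks:
            ledger.n_syntenic_found += 1
        if any(loc == "syntenic" for _a, loc, _g in c.noncoding_hits):
            ledger.n_syntenic_with_hit += 1
        if c.status == "trg_noncoding_trace":
            ledger.n_noncoding_only += 1
        if c.status == "trg_no_trace":
            ledger.n_no_similarity += 1
        if c.status == "removed_transitive":
            if c.removal_cause == "paralog":
                ledger.n_removed_transitive_para += 1
            else:
                ledger.n_removed_transitive_orth += 1
        if c.status in ("trg_noncoding_trace", "trg_no_trace"):
            ledger.n_final += 1
            if c.level == "species":
                ledger.n_species_specific += 1
    ledger.check()
    return ledger
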