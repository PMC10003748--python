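"""Synthetic clades with planted ground truth.

Generates a focal genus (species x strains) plus an external genome
collection that together exercise every branch of the restricted-gene
classification schema:

* conserved genes with annotated external homologs (non-TRG);
* genes whose intact coding copy is present but unannotated in an external
  genome (missed annotation);
* TRGs whose disrupted (stop/frameshift-bearing) homolog sits inside a
  preserved flank pair (syntenic trace) or at an unrelated locus with the
  flank context broken (non-syntenic trace);
* TRGs with no trace anywhere;
* species-restricted genes confined to the strains of one species;
* TRG families with prescribed reciprocal-best-hit topology (clique or
  star), within-genome paralog pairs and noncoding paralog copies;
* "leaky" families whose hub has an annotated external homolog, so that
  every leaf is removable only through transitive homology.

Sequence model: coding sequences are uniform random codons (no internal
stops), intergenic background is i.i.d. nucleotides at a configurable GC
so that chance similarity stays far below the detection floor at tested
sizes. Divergence is a per-nucleotide substitution probability applied to
each genome's copy (substitutions that would create or destroy stops are
suppressed inside coding copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sequence_io import (
    GeneAnnotation,
    GenomeRecord,
    STOP_CODONS,
    reverse_complement,
    translate,
)

_NT = "ACGT"
_STOPS = set(STOP_CODONS)


@dataclass
class PlantDesign:
    """Counts of planted genes per truth class."""

    conserved: int = 30
    missed_annotation: int = 30
    syntenic_trace: int = 30
    nonsyntenic_trace: int = 30
    no_trace: int = 30
    species_trg: int = 5
    families: tuple = ((5, "clique"), (5, "clique"), (5, "star"), (5, "star"))
    paralog_pairs: int = 3
    noncoding_paralogs: int = 3
    leaky_families: int = 10
    leaky_family_size: int = 4  # hub + 3 leaves


@dataclass
class SyntheticCladeSpec:
    """Design of a synthetic clade experiment."""

    n_species: int = 5
    strains_per_species: int = 2
    n_external_genomes: int = 20
    design: PlantDesign = field(default_factory=PlantDesign)
    conserved_len_codons: tuple[float, float] = (4.8, 0.25)  # lognormal mu, sigma
    trg_len_codons: tuple[float, float] = (4.45, 0.2)
    min_trg_codons: int = 70
    divergence: float = 0.0
    gc: float = 0.44
    intergenic_len: int = 150
    disruption_design: tuple = (
        (1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1), (1, 2),
        (3, 2), (2, 2), (5, 4), (12, 0), (3, 0), (0, 3), (4, 3),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.3):
            raise ValueError("divergence must be in [0, 0.3]")
        for name in (
            "conserved", "missed_annotation", "syntenic_trace",
            "nonsyntenic_trace", "no_trace", "species_trg",
            "paralog_pairs", "noncoding_paralogs", "leaky_families",
        ):
            if getattr(self.design, name) < 0:
                raise ValueError(f"negative plant count for {name}")


@dataclass
class TruthRow:
    """Ground truth for one planted gene."""

    gene_id: str
    genome_id: str
    species_id: str
    protein: str
    true_class: str
    expected_status: str
    expected_level: str  # 'genus' | 'species' | 'none'
    family_id: str | None = None
    planted_disruptions: tuple[int, int] | None = None  # (n_stops, n_frameshifts)
    trace_genomes: list = field(default_factory=list)  # (genome_id, syntenic)


@dataclass
class GroundTruth:
    rows: list[TruthRow]

    def by_gene(self) -> dict[str, TruthRow]:
        return {r.gene_id: r for r in self.rows}

    def expected_status_of(self, protein_record) -> str:
        """Expected terminal status of a nonredundant protein record."""
        index = self.by_gene()
        statuses = {
            index[g].expected_status
            for _, g in protein_record.sources
            if g in index
        }
        if len(statuses) != 1:
            raise ValueError(
                f"protein {protein_record.protein_id} maps to statuses {statuses}"
            )
        return statuses.pop()

    def expected_level_of(self, protein_record) -> str:
        index = self.by_gene()
        levels = {
            index[g].expected_level
            for _, g in protein_record.sources
            if g in index
        }
        return levels.pop() if len(levels) == 1 else "genus"


@dataclass
class SyntheticClade:
    """A generated clade: genomes, annotations and planted truth."""

    genus_genomes: list[GenomeRecord]
    genus_annotations: list[GeneAnnotation]
    external_genomes: list[GenomeRecord]
    external_annotations: list[GeneAnnotation]
    truth: GroundTruth
    spec: SyntheticCladeSpec

    def genus_annotations_of(self, genome_id: str) -> list[GeneAnnotation]:
        return [a for a in self.genus_annotations if a.genome_id == genome_id]


def random_dna(rng, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_NT), size=length, p=p))


def random_coding_dna(rng, n_codons: int) -> str:
    """ATG + (n_codons - 1) random non-stop codons + TAA."""
    if n_codons < 2:
        raise ValueError("a coding gene needs at least 2 codons")
    codons = []
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list(_NT), size=3))
        if codon not in _STOPS and codon != "ATG":
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


def mutate_coding(dna: str, rate: float, rng) -> str:
    """Substitute nucleotides at ``rate``; never create or destroy a stop."""
    if rate <= 0:
        return dna
    chars = list(dna)
    for codon_start in range(3, len(dna) - 3, 3):
        for off in range(3):
            if rng.random() >= rate:
                continue
            pos = codon_start + off
            old = chars[pos]
            new = rng.choice([c for c in _NT if c != old])
            codon = chars[codon_start : codon_start + 3]
            codon[off] = new
            if "".join(codon) in _STOPS:
                continue
            chars[pos] = new
    return "".join(chars)


def mutate_background(dna: str, rate: float, rng) -> str:
    if rate <= 0:
        return dna
    chars = list(dna)
    for i, c in enumerate(chars):
        if rng.random() < rate:
            chars[i] = rng.choice([x for x in _NT if x != c])
    return "".join(chars)


def disrupt_coding(
    dna: str,
    n_stops: int,
    n_frameshifts: int,
    rng,
    divergence: float = 0.0,
    fs_margin_codons: int = 8,
    fs_spacing_codons: int = 7,
    stop_margin_codons: int = 3,
    stop_spacing_codons: int = 3,
    cross_spacing_codons: int = 4,
) -> tuple[str, list[int], list[int]]:
    """Plant exactly ``n_stops`` nonsense codons and ``n_frameshifts``
    single-nucleotide insertions into a coding sequence.

    Placement keeps every event recoverable by an optimal local aligner:
    an event whose flanking matched segment is worth less than its penalty
    gets trimmed or merged by *any* aligner, so frameshifts (penalty ~30)
    need wide margins and spacing while premature stops (penalty ~5) only
    need small ones. Returns (disrupted_dna, stop_codon_indices,
    frameshift_codon_indices).
    """
    n_codons = len(dna) // 3
    fs_candidates = list(range(fs_margin_codons, n_codons - fs_margin_codons))
    stop_candidates = list(
        range(stop_margin_codons, n_codons - stop_margin_codons)
    )
    if n_frameshifts and len(fs_candidates) < n_frameshifts * fs_spacing_codons:
        raise ValueError(
            f"cannot place {n_frameshifts} frameshifts in {n_codons} codons"
        )
    if n_stops and len(stop_candidates) < n_stops * stop_spacing_codons:
        raise ValueError(f"cannot place {n_stops} stops in {n_codons} codons")
    fs_sites: list[int] = []
    stop_sites: list[int] = []
    attempts = 0
    while len(fs_sites) < n_frameshifts:
        attempts += 1
        if attempts > 20000:
            raise ValueError("disruption placement failed; gene too short")
        c = int(rng.choice(fs_candidates))
        if all(abs(c - s) >= fs_spacing_codons for s in fs_sites):
            fs_sites.append(c)
    while len(stop_sites) < n_stops:
        attempts += 1
        if attempts > 20000:
            raise ValueError("disruption placement failed; gene too short")
        c = int(rng.choice(stop_candidates))
        if all(abs(c - s) >= stop_spacing_codons for s in stop_sites) and all(
            abs(c - s) >= cross_spacing_codons for s in fs_sites
        ):
            stop_sites.append(c)
    stop_sites.sort()
    fs_sites.sort()
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    protected = set(stop_sites) | set(fs_sites)
    if divergence > 0:
        for idx in range(1, len(codons) - 1):
            if idx in protected:
                continue
            codons[idx] = mutate_coding(
                "ATG" + codons[idx] + "TAA", divergence, rng
            )[3:6]
    for s in stop_sites:
        codons[s] = str(rng.choice(list(_STOPS)))
    for f in fs_sites:
        codons[f] = str(rng.choice(list(_NT))) + codons[f]
    return "".join(codons), stop_sites, fs_sites


def _lognormal_codons(rng, mu_sigma, minimum=12) -> int:
    mu, sigma = mu_sigma
    return max(minimum, int(round(float(rng.lognormal(mu, sigma)))))


class _GenomeBuilder:
    """Accumulates (gap -> inserts) over a conserved-gene backbone."""

    def __init__(self, genome_id, species_id, genus_id, rng, gc, intergenic):
        self.genome_id = genome_id
        self.species_id = species_id
        self.genus_id = genus_id
        self.rng = rng
        self.gc = gc
        self.intergenic = intergenic
        self.backbone: list[tuple[str, str, bool]] = []  # (gene_id, dna, annotate)
        self.inserts: dict[int, list[tuple[str, str, bool]]] = {}

    def set_backbone(self, genes) -> None:
        self.backbone = list(genes)

    def insert(self, gap: int, gene_id: str, dna: str, annotate: bool) -> None:
        self.inserts.setdefault(gap, []).append((gene_id, dna, annotate))

    def drop_backbone_gene(self, index: int) -> None:
        gid, dna, _ = self.backbone[index]
        self.backbone[index] = (gid, dna, None)  # None = remove entirely

    def build(self) -> tuple[GenomeRecord, list[GeneAnnotation]]:
        parts = []
        annotations = []
        pos = 0
        contig_id = f"{self.genome_id}_c1"

        def add_intergenic():
            nonlocal pos
            seq = random_dna(self.rng, self.intergenic, self.gc)
            parts.append(seq)
            pos += len(seq)

        def add_gene(gene_id, dna, annotate):
            nonlocal pos
            if annotate:
                annotations.append(
                    GeneAnnotation(
                        gene_id=gene_id,
                        genome_id=self.genome_id,
                        contig_id=contig_id,
                        start=pos,
                        end=pos + len(dna),
                        strand="+",
                    )
                )
            parts.append(dna)
            pos += len(dna)

        add_intergenic()
        for gap_before in range(len(self.backbone) + 1):
            for gene_id, dna, annotate in self.inserts.get(gap_before, []):
                add_gene(gene_id, dna, annotate)
                add_intergenic()
            if gap_before < len(self.backbone):
                gid, dna, annotate = self.backbone[gap_before]
                if annotate is None:
                    continue
                add_gene(gid, dna, annotate)
                add_intergenic()
        genome = GenomeRecord(
            genome_id=self.genome_id,
            species_id=self.species_id,
            genus_id=self.genus_id,
            contigs=[(contig_id, "".join(parts))],
        )
        return genome, annotations


def _segmented_family(rng, topology, size, seg_codons=45, with_external=False):
    """Member coding sequences for a star/leaky family.

    The hub carries one distinct segment per partner; each leaf shares
    exactly its own segment with the hub and is random elsewhere, so
    hub-leaf similarity clears the detection floor while leaf-leaf
    similarity stays at chance level.
    """
    n_partners = size - 1 + (1 if with_external else 0)
    hub_codons = []
    segments = []
    for _ in range(n_partners):
        seg = random_coding_dna(rng, seg_codons + 2)[3:-3]
        segments.append(seg)
        hub_codons.append(seg)
    hub = "ATG" + "".join(hub_codons) + "TAA"
    members = [hub]
    for i in range(size - 1):
        filler = random_coding_dna(rng, seg_codons + 2)[3:-3]
        members.append("ATG" + segments[i] + filler + "TAA")
    external = None
    if with_external:
        filler = random_coding_dna(rng, seg_codons + 2)[3:-3]
        external = "ATG" + filler + segments[-1] + "TAA"
    return members, external


def _clique_family(rng, size, n_codons, divergence=0.02):
    """Nearly identical member sequences (pairwise far above the floor)."""
    base = random_coding_dna(rng, n_codons)
    return [mutate_coding(base, divergence, rng) for _ in range(size)]


def generate_clade(spec: SyntheticCladeSpec) -> SyntheticClade:
    """Generate the clade, external collection, and ground truth."""
    rng = np.random.default_rng(spec.seed)
    d = spec.design
    genus_id = "Focalus"

    focal_ids = []
    species_of = {}
    for s in range(spec.n_species):
        for t in range(spec.strains_per_species):
            gid = f"B{s + 1:02d}s{t + 1}"
            focal_ids.append(gid)
            species_of[gid] = f"sp{s + 1:02d}"
    external_ids = [f"E{e + 1:02d}" for e in range(spec.n_external_genomes)]

    # conserved backbone, shared by every genome (focal and external)
    conserved = [
        (f"cons{j:03d}", random_coding_dna(
            rng, _lognormal_codons(rng, spec.conserved_len_codons, 40)))
        for j in range(d.conserved)
    ]
    n_gaps = len(conserved) - 1
    if n_gaps < 3:
        raise ValueError("design infeasible: need at least 4 conserved genes")

    builders = {}
    for gid in focal_ids:
        b = _GenomeBuilder(
            gid, species_of[gid], genus_id,
            np.random.default_rng(rng.integers(2**31)),
            spec.gc, spec.intergenic_len,
        )
        b.set_backbone(
            (gene_id + "@" + gid, mutate_coding(dna, spec.divergence, b.rng), True)
            for gene_id, dna in conserved
        )
        builders[gid] = b
    ext_builders = {}
    for eid in external_ids:
        b = _GenomeBuilder(
            eid, f"ext_{eid}", "Externus",
            np.random.default_rng(rng.integers(2**31)),
            spec.gc, spec.intergenic_len,
        )
        b.set_backbone(
            (gene_id + "@" + eid, mutate_coding(dna, spec.divergence, b.rng), True)
            for gene_id, dna in conserved
        )
        ext_builders[eid] = b

    truth_rows: list[TruthRow] = []
    for gene_id, dna in conserved:
        for gid in focal_ids:
            truth_rows.append(
                TruthRow(
                    gene_id=gene_id + "@" + gid,
                    genome_id=gid,
                    species_id=species_of[gid],
                    protein=translate(dna)[:-1],
                    true_class="conserved",
                    expected_status="non_trg_external_hit",
                    expected_level="none",
                )
            )

    # gap bookkeeping: each planted focal gene takes a fresh gap in its
    # genome. Plants that break a flank pair in their host (missed
    # annotation, non-syntenic traces) draw from the high gap range and
    # syntenic traces from the low range, so a dropped flank gene can never
    # belong to another TRG's preserved flank pair.
    mid = max(2, n_gaps // 2)
    free_low = {
        gid: list(rng.permutation(np.arange(1, mid))) for gid in focal_ids
    }
    free_high = {
        gid: list(rng.permutation(np.arange(mid, n_gaps))) for gid in focal_ids
    }
    free_ext_gaps = {
        eid: list(rng.permutation(np.arange(1, n_gaps))) for eid in external_ids
    }

    def take_gap(gid, pool="any"):
        pools = {
            "low": (free_low,),
            "high": (free_high,),
            "any": (free_low, free_high),
        }[pool]
        for p in pools:
            if p[gid]:
                return int(p[gid].pop())
        raise ValueError("design infeasible: out of insertion gaps")

    def take_ext_gap(eid):
        if not free_ext_gaps[eid]:
            raise ValueError("design infeasible: out of external gaps")
        return int(free_ext_gaps[eid].pop())

    host_cycle = iter(np.tile(external_ids, 50))
    genome_cycle = iter(np.tile(focal_ids, 100))
    disruption_cycle = iter(
        [spec.disruption_design[i % len(spec.disruption_design)]
         for i in range(10000)]
    )

    def new_trg_dna(min_codons=None):
        n = _lognormal_codons(rng, spec.trg_len_codons, spec.min_trg_codons)
        if min_codons:
            n = max(n, min_codons)
        return random_coding_dna(rng, n)

    def plant_focal(gene_id, gid, dna, gap=None, pool="any"):
        gap = take_gap(gid, pool) if gap is None else gap
        builders[gid].insert(gap, gene_id, dna, True)
        return gap

    # --- missed annotation: intact unannotated copy in one external genome
    for i in range(d.missed_annotation):
        gid = next(genome_cycle)
        host = next(host_cycle)
        dna = new_trg_dna()
        gene_id = f"missed{i:03d}@{gid}"
        gap = plant_focal(gene_id, gid, dna, pool="high")
        copy = mutate_coding(dna, spec.divergence, rng)
        ext_builders[host].insert(take_ext_gap(host), gene_id + "_copy", copy, False)
        ext_builders[host].drop_backbone_gene(gap - 1)  # break the flank pair
        truth_rows.append(
            TruthRow(
                gene_id=gene_id, genome_id=gid, species_id=species_of[gid],
                protein=translate(dna)[:-1],
                true_class="missed_annotation",
                expected_status="missed_annotation",
                expected_level="none",
                trace_genomes=[(host, False)],
            )
        )

    # --- TRGs with a disrupted syntenic trace (flank pair preserved)
    for i in range(d.syntenic_trace):
        gid = next(genome_cycle)
        host = next(host_cycle)
        n_stops, n_fs = next(disruption_cycle)
        dna = new_trg_dna(min_codons=90)
        gene_id = f"tsyn{i:03d}@{gid}"
        gap = plant_focal(gene_id, gid, dna, pool="low")
        fragment, _, _ = disrupt_coding(
            mutate_coding(dna, spec.divergence, rng), n_stops, n_fs, rng
        )
        ext_builders[host].insert(gap, gene_id + "_trace", fragment, False)
        truth_rows.append(
            TruthRow(
                gene_id=gene_id, genome_id=gid, species_id=species_of[gid],
                protein=translate(dna)[:-1],
                true_class="trg_syntenic_trace",
                expected_status="trg_noncoding_trace",
                expected_level="species",
                planted_disruptions=(n_stops, n_fs),
                trace_genomes=[(host, True)],
            )
        )

    # --- TRGs with a non-syntenic trace (flank context broken in the host)
    for i in range(d.nonsyntenic_trace):
        gid = next(genome_cycle)
        host = next(host_cycle)
        n_stops, n_fs = next(disruption_cycle)
        dna = new_trg_dna(min_codons=90)
        gene_id = f"tnon{i:03d}@{gid}"
        gap = plant_focal(gene_id, gid, dna, pool="high")
        fragment, _, _ = disrupt_coding(
            mutate_coding(dna, spec.divergence, rng), n_stops, n_fs, rng
        )
        ext_builders[host].insert(take_ext_gap(host), gene_id + "_trace", fragment, False)
        ext_builders[host].drop_backbone_gene(gap - 1)
        truth_rows.append(
            TruthRow(
                gene_id=gene_id, genome_id=gid, species_id=species_of[gid],
                protein=translate(dna)[:-1],
                true_class="trg_nonsyntenic_trace",
                expected_status="trg_noncoding_trace",
                expected_level="species",
                planted_disruptions=(n_stops, n_fs),
                trace_genomes=[(host, False)],
            )
        )

    # --- TRGs with no trace at all
    for i in range(d.no_trace):
        gid = next(genome_cycle)
        dna = new_trg_dna()
        gene_id = f"tnot{i:03d}@{gid}"
        plant_focal(gene_id, gid, dna)
        truth_rows.append(
            TruthRow(
                gene_id=gene_id, genome_id=gid, species_id=species_of[gid],
                protein=translate(dna)[:-1],
                true_class="trg_no_trace",
                expected_status="trg_no_trace",
                expected_level="species",
            )
        )

    # --- species-restricted genes: identical copy in every strain of one species
    for i in range(d.species_trg):
        sp = f"sp{(i % spec.n_species) + 1:02d}"
        strains = [g for g in focal_ids if species_of[g] == sp]
        dna = new_trg_dna()
        for gid in strains:
            gene_id = f"sptrg{i:03d}@{gid}"
            plant_focal(gene_id, gid, dna)
            truth_rows.append(
                TruthRow(
                    gene_id=gene_id, genome_id=gid, species_id=sp,
                    protein=translate(dna)[:-1],
                    true_class="species_trg",
                    expected_status="trg_no_trace",
                    expected_level="species",
                )
            )

    # --- families with prescribed topology
    species_cycle_start = 0
    for fi, (size, topology) in enumerate(d.families):
        fam_id = f"fam{fi:02d}_{topology}"
        if topology == "clique":
            members = _clique_family(rng, size, _lognormal_codons(
                rng, spec.trg_len_codons, spec.min_trg_codons))
        elif topology == "star":
            members, _ = _segmented_family(rng, "star", size)
        else:
            raise ValueError(f"unknown family topology {topology!r}")
        hosts = [
            focal_ids[(species_cycle_start + k * spec.strains_per_species)
                      % len(focal_ids)]
            for k in range(size)
        ]
        species_cycle_start += 1
        for k, (gid, dna) in enumerate(zip(hosts, members)):
            gene_id = f"{fam_id}_m{k}@{gid}"
            plant_focal(gene_id, gid, dna)
            truth_rows.append(
                TruthRow(
                    gene_id=gene_id, genome_id=gid, species_id=species_of[gid],
                    protein=translate(dna)[:-1],
                    true_class=f"family_{topology}",
                    expected_status="trg_no_trace",
                    expected_level="genus",
                    family_id=fam_id,
                )
            )

    # --- leaky families: hub has an annotated external homolog
    for fi in range(d.leaky_families):
        fam_id = f"leaky{fi:02d}"
        size = d.leaky_family_size
        members, external_copy = _segmented_family(
            rng, "star", size, with_external=True
        )
        host = next(host_cycle)
        ext_gene = f"{fam_id}_ext@{host}"
        ext_builders[host].insert(take_ext_gap(host), ext_gene, external_copy, True)
        hosts = [
            focal_ids[(fi + k * spec.strains_per_species) % len(focal_ids)]
            for k in range(size)
        ]
        for k, (gid, dna) in enumerate(zip(hosts, members)):
            gene_id = f"{fam_id}_m{k}@{gid}"
            plant_focal(gene_id, gid, dna)
            is_hub = k == 0
            truth_rows.append(
                TruthRow(
                    gene_id=gene_id, genome_id=gid, species_id=species_of[gid],
                    protein=translate(dna)[:-1],
                    true_class="leaky_hub" if is_hub else "leaky_leaf",
                    expected_status=(
                        "non_trg_external_hit" if is_hub else "removed_transitive"
                    ),
                    expected_level="none",
                    family_id=fam_id,
                )
            )

    # --- within-genome paralog pairs (annotated, slightly diverged)
    for i in range(d.paralog_pairs):
        gid = next(genome_cycle)
        base = new_trg_dna()
        copy = mutate_coding(base, 0.04, rng)
        for k, dna in enumerate((base, copy)):
            gene_id = f"para{i:03d}_{k}@{gid}"
            plant_focal(gene_id, gid, dna)
            truth_rows.append(
                TruthRow(
                    gene_id=gene_id, genome_id=gid, species_id=species_of[gid],
                    protein=translate(dna)[:-1],
                    true_class="paralog_pair",
                    expected_status="trg_no_trace",
                    expected_level="species",
                    family_id=f"parafam{i:03d}",
                )
            )

    # --- noncoding paralog: disrupted unannotated copy in the same genome
    for i in range(d.noncoding_paralogs):
        gid = next(genome_cycle)
        n_stops, n_fs = next(disruption_cycle)
        n_stops = max(1, n_stops)
        dna = new_trg_dna(min_codons=90)
        gene_id = f"ncpara{i:03d}@{gid}"
        plant_focal(gene_id, gid, dna)
        fragment, _, _ = disrupt_coding(dna, n_stops, n_fs, rng)
        builders[gid].insert(take_gap(gid), gene_id + "_copy", fragment, False)
        truth_rows.append(
            TruthRow(
                gene_id=gene_id, genome_id=gid, species_id=species_of[gid],
                protein=translate(dna)[:-1],
                true_class="noncoding_paralog_owner",
                expected_status="trg_no_trace",
                expected_level="species",
                planted_disruptions=(n_stops, n_fs),
            )
        )

    genus_genomes, genus_annotations = [], []
    for gid in focal_ids:
        genome, anns = builders[gid].build()
        genus_genomes.append(genome)
        genus_annotations.extend(anns)
    external_genomes, external_annotations = [], []
    for eid in external_ids:
        genome, anns = ext_builders[eid].build()
        external_genomes.append(genome)
        external_annotations.extend(anns)

    return SyntheticClade(
        genus_genomes=genus_genomes,
        genus_annotations=genus_annotations,
        external_genomes=external_genomes,
        external_annotations=external_annotations,
        truth=GroundTruth(rows=truth_rows),
        spec=spec,
    )


def plant_noncoding_homolog(
    gene_dna: str,
    target_genome: GenomeRecord,
    n_stops: int,
    n_frameshifts: int,
    divergence: float,
    seed: int,
    contig_index: int = 0,
    position: int | None = None,
) -> tuple[GenomeRecord, tuple[int, int]]:
    """Insert a disrupted copy of ``gene_dna`` into a genome.

    Returns the modified genome and the inserted fragment's half-open
    interval on the target contig.
    """
    rng = np.random.default_rng(seed)
    fragment, _, _ = disrupt_coding(gene_dna, n_stops, n_frameshifts, rng, divergence)
    cid, seq = target_genome.contigs[contig_index]
    pos = len(seq) // 2 if position is None else position
    new_seq = seq[:pos] + fragment + seq[pos:]
    contigs = list(target_genome.contigs)
    contigs[contig_index] = (cid, new_seq)
    return replace(target_genome, contigs=contigs), (pos, pos + len(fragment))
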