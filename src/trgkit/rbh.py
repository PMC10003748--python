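"""Best-hit selection and reciprocal-best-hit (RBH) homology calls.

Two modes: protein-protein (BLASTp surrogate in both directions) and
protein-DNA-protein (forward frameshift-aware DNA search, backward protein
search with the event-spliced implied peptide).

A hit qualifies for best-hit selection only if its E-value is at or below
``e_max`` *and* its bit score reaches the scheme's reporting floor; the
reverse leg of a reciprocal search then accepts the best qualifying hit
(see docs/methods.md on the detection model).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align_core import (
    FrameshiftAlignment,
    ProteinAlignment,
    ScoringScheme,
    align_protein_dna_fs,
    align_protein_protein,
)
from .sequence_io import GenomeRecord, ProteinRecord

DEFAULT_E_MAX = 10.0


def _hit_order_key(aln):
    """Total order for ranking hits: score desc, then deterministic ties."""
    return (
        -aln.score,
        aln.n_frameshifts + aln.n_stops,
        aln.subject_span[1] - aln.subject_span[0],
        aln.subject_span[0],
        aln.subject_id,
    )


def qualifies(aln, scheme: ScoringScheme, e_max: float) -> bool:
    """Is this alignment a reportable hit under the scheme's thresholds?"""
    return (
        aln.score > 0
        and aln.evalue <= e_max
        and aln.bitscore >= scheme.min_bitscore
    )


def best_hit(
    query,
    targets,
    scheme: ScoringScheme,
    e_max: float = DEFAULT_E_MAX,
    db_residues: int | None = None,
    exclude_ids: set[str] | None = None,
) -> ProteinAlignment | None:
    """Highest-scoring qualifying alignment of query against targets.

    E-values use ``db_residues`` as database size n (default: total residue
    count of ``targets``). Returns None when no alignment qualifies.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    targets = list(targets)
    if db_residues is None:
        db_residues = sum(len(t.sequence) for t in targets)
    hits = []
    for t in targets:
        if exclude_ids and t.protein_id in exclude_ids:
            continue
        aln = align_protein_protein(query, t, scheme, db_residues=db_residues)
        if qualifies(aln, scheme, e_max):
            hits.append(aln)
    if not hits:
        return None
    return min(hits, key=_hit_order_key)


@dataclass
class RBHPair:
    """A reciprocal best hit between two sequences."""

    a_id: str
    b_id: str
    mode: str  # 'prot-prot' | 'prot-dna'
    forward: object
    reverse: object

    def ids(self) -> tuple[str, str]:
        return (self.a_id, self.b_id)


def reciprocal_best_hits(
    set_a,
    set_b,
    scheme: ScoringScheme,
    e_max: float = DEFAULT_E_MAX,
) -> list[RBHPair]:
    """All (a, b) with a the best hit of b and b the best hit of a.

    The output is a partial matching on sequence ids (each id appears in at
    most one pair).
    """
    set_a, set_b = list(set_a), list(set_b)
    ids_a = {p.protein_id for p in set_a}
    if ids_a & {p.protein_id for p in set_b}:
        raise ValueError("protein sets must be disjoint by id")
    n_a = sum(len(p.sequence) for p in set_a)
    n_b = sum(len(p.sequence) for p in set_b)
    pairs = []
    for a in set_a:
        fwd = best_hit(a, set_b, scheme, e_max, db_residues=n_b)
        if fwd is None:
            continue
        b = next(p for p in set_b if p.protein_id == fwd.subject_id)
        rev = best_hit(b, set_a, scheme, e_max, db_residues=n_a)
        if rev is not None and rev.subject_id == a.protein_id:
            pairs.append(
                RBHPair(
                    a_id=a.protein_id,
                    b_id=b.protein_id,
                    mode="prot-prot",
                    forward=fwd,
                    reverse=rev,
                )
            )
    return pairs


def reciprocal_tfs(
    query: ProteinRecord,
    target_dna: str,
    source_proteome,
    scheme: ScoringScheme,
    e_max: float = DEFAULT_E_MAX,
    subject_id: str = "dna",
    db_residues: int | None = None,
) -> tuple[FrameshiftAlignment, ProteinAlignment] | None:
    """Forward frameshift-aware DNA search validated by a backward protein search.

    The forward hit's event-spliced implied peptide (stops kept as '*',
    frameshift-inserted nucleotides removed) is searched against the entire
    source proteome; the hit is kept only when the backward best hit is the
    query itself.
    """
    if len(target_dna) < 3:
        return None
    fwd = align_protein_dna_fs(
        query, target_dna, scheme,
        db_residues=db_residues if db_residues is not None else len(target_dna),
        subject_id=subject_id,
    )
    if not qualifies(fwd, scheme, e_max):
        return None
    peptide = fwd.implied_peptide
    if not peptide:
        return None
    rev = best_hit(peptide_record(peptide), list(source_proteome), scheme, e_max)
    if rev is None or rev.subject_id != query.protein_id:
        return None
    return fwd, rev


def peptide_record(peptide: str) -> ProteinRecord:
    """Wrap an implied peptide for use as a reverse-search query."""
    return ProteinRecord(
        protein_id="implied_peptide",
        sequence=peptide,
        sources=frozenset({("-", "-")}),
    )


def reciprocal_tfs_genome(
    query: ProteinRecord,
    target_genome: GenomeRecord,
    source_proteome,
    scheme: ScoringScheme,
    e_max: float = DEFAULT_E_MAX,
    interval: tuple[str, int, int] | None = None,
):
    """reciprocal_tfs against a genome (optionally restricted to an interval).

    Returns (contig_id, FrameshiftAlignment, ProteinAlignment) for the best
    validated hit across contigs, or None. The alignment's dna_span is in
    the coordinates of the searched contig (offset applied for intervals);
    the E-value database size is the whole genome length.
    """
    n = target_genome.total_length
    best_result = None
    contigs = target_genome.contigs
    if interval is not None:
        cid, start, end = interval
        seq = target_genome.contig(cid)[start:end]
        contigs = [(cid, seq)]
    for cid, seq in contigs:
        if len(seq) < 3:
            continue
        result = reciprocal_tfs(
            query, seq, source_proteome, scheme, e_max,
            subject_id=f"{target_genome.genome_id}:{cid}",
            db_residues=n,
        )
        if result is None:
            continue
        fwd, rev = result
        if interval is not None:
            from dataclasses import replace as _dc_replace

            offset = interval[1]
            fwd.dna_span = (fwd.dna_span[0] + offset, fwd.dna_span[1] + offset)
            fwd.subject_span = fwd.dna_span
            fwd.events = [
                _dc_replace(e, dna_pos=e.dna_pos + offset) for e in fwd.events
            ]
        if best_result is None or _hit_order_key(fwd) < _hit_order_key(
            best_result[1]
        ):
            best_result = (cid, fwd, rev)
    return best_result
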