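"""Local alignment: protein-protein (BLASTp surrogate) and frameshift-aware
protein-vs-DNA in six frames (tFASTy surrogate), with Karlin-Altschul
E-values and disruption-event extraction.

The protein-protein path is biotite's affine-gap Smith-Waterman; the
frameshift DP is this package's own kernel (:mod:`trgkit._fsdp`).

Statistics model
----------------
Raw scores are converted with the Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` using fixed gapped constants for
BLOSUM62 with gap open 11 / extend 1. Because a *correctly calibrated*
E-value assigns E ~ O(1) to the best chance alignment of any query against
any database, a bare ``E <= threshold`` test cannot separate homology from
noise for an exhaustive Smith-Waterman search (the heuristic tools it
surrogates simply never report such chance alignments). Searches therefore
also apply a minimum bit-score reporting floor (``ScoringScheme.min_bitscore``,
default 50 bits - the classic rule of thumb for an alignment that is almost
always biologically meaningful regardless of database size). See
docs/methods.md for the full rationale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

import biotite.sequence as bseq
import biotite.sequence.align as balign

from ._blosum import BLOSUM62_TEXT
from ._fsdp import fs_align_kernel
from .sequence_io import ProteinRecord, reverse_complement, translate

ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def read_ncbi_matrix(text: str) -> tuple[str, np.ndarray]:
    """Parse an NCBI-format scoring matrix file into (alphabet, matrix)."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    alphabet = "".join(lines[0].split())
    n = len(alphabet)
    mat = np.zeros((n, n), dtype=np.int32)
    for row, line in enumerate(lines[1 : n + 1]):
        fields = line.split()
        if fields[0] != alphabet[row]:
            raise ValueError(f"matrix row label {fields[0]!r} out of order")
        mat[row, :] = [int(v) for v in fields[1 : n + 1]]
    if not np.array_equal(mat, mat.T):
        raise ValueError("scoring matrix is not symmetric")
    return alphabet, mat


def _codon_tables() -> tuple[np.ndarray, np.ndarray]:
    """aa index and stop flag for each of the 64 codons (table 11)."""
    aa_idx = np.zeros(64, dtype=np.int8)
    stop = np.zeros(64, dtype=np.bool_)
    x_index = ALPHABET.index("X")
    for c0, c1, c2 in itertools.product("ACGT", repeat=3):
        codon = c0 + c1 + c2
        idx = _NT_INDEX[c0] * 16 + _NT_INDEX[c1] * 4 + _NT_INDEX[c2]
        aa = translate(codon)
        if aa == "*":
            stop[idx] = True
            aa_idx[idx] = ALPHABET.index("*")
        else:
            aa_idx[idx] = ALPHABET.index(aa) if aa in ALPHABET else x_index
    return aa_idx, stop


_CODON_AA, _CODON_STOP = _codon_tables()


@dataclass
class ScoringScheme:
    """Substitution scores, gap/frameshift costs and E-value constants.

    A gap of length g costs ``gap_open + (g - 1) * gap_extend``. The
    frameshift penalty and the stop-codon match score follow tFASTy-like
    defaults; lambda/K are the tabulated gapped Karlin-Altschul constants
    for BLOSUM62 11/1.
    """

    alphabet: str
    matrix: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    frameshift_penalty: int = 30
    stop_match_score: int = -5
    lambda_: float = 0.267
    K: float = 0.041
    min_bitscore: float = 50.0

    _index: dict = field(default_factory=dict, repr=False)
    _pp_cache: dict = field(default_factory=dict, repr=False)
    _bio_matrix: object = field(default=None, repr=False)
    _bio_alphabet: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        self._index = {c: i for i, c in enumerate(self.alphabet)}
        self._bio_alphabet = bseq.Alphabet(list(self.alphabet))
        self._bio_matrix = balign.SubstitutionMatrix(
            self._bio_alphabet, self._bio_alphabet, self.matrix
        )

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.fromiter(
                (self._index[c] for c in seq), dtype=np.int8, count=len(seq)
            )
        except KeyError as exc:
            raise ValueError(f"character {exc.args[0]!r} outside alphabet") from exc

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[self._index[a], self._index[b]])


def default_scheme(**overrides) -> ScoringScheme:
    """BLOSUM62 with BLAST-default gap costs; 'X' rescored to 0 vs residues."""
    alphabet, mat = read_ncbi_matrix(BLOSUM62_TEXT)
    mat = mat.copy()
    x = alphabet.index("X")
    star = alphabet.index("*")
    for i in range(len(alphabet)):
        if i != star:
            mat[x, i] = 0
            mat[i, x] = 0
    return ScoringScheme(alphabet=alphabet, matrix=mat, **overrides)


def evalue(score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation for raw score ``score`` over m x n space."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database sizes must be positive")
    return scheme.K * m * n * math.exp(-scheme.lambda_ * score)


def bitscore(score: int, scheme: ScoringScheme) -> float:
    return (scheme.lambda_ * score - math.log(scheme.K)) / math.log(2.0)


@dataclass
class ProteinAlignment:
    """A local protein-protein alignment."""

    query_id: str
    subject_id: str
    score: int
    bitscore: float
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identity: float
    query_coverage: float
    n_columns: int = 0

    @property
    def n_frameshifts(self) -> int:
        return 0

    @property
    def n_stops(self) -> int:
        return 0


@dataclass(frozen=True)
class AlignmentEvent:
    """A coding-capacity disruption observed in an alignment."""

    kind: str  # 'frameshift' | 'stop'
    query_pos: int  # residue index in the query
    dna_pos: int  # forward-strand nt offset of the consumed window
    detail: object  # +1/-1 shift, or the stop codon string

    def __post_init__(self) -> None:
        if self.kind == "frameshift" and self.detail not in (+1, +2, -1, -2):
            raise ValueError("frameshift detail must be a shift in {+-1, +-2}")
        if self.kind == "stop" and not isinstance(self.detail, str):
            raise ValueError("stop detail must be the codon string")


@dataclass
class FrameshiftAlignment:
    """A frameshift/stop-aware local protein-vs-DNA alignment."""

    query_id: str
    subject_id: str
    score: int
    bitscore: float
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]  # alias of dna_span, forward strand
    identity: float
    query_coverage: float
    strand: str
    events: list[AlignmentEvent]
    dna_span: tuple[int, int]
    implied_peptide: str

    @property
    def n_frameshifts(self) -> int:
        return sum(1 for e in self.events if e.kind == "frameshift")

    @property
    def n_stops(self) -> int:
        return sum(1 for e in self.events if e.kind == "stop")


def _seq_of(x) -> str:
    return x.sequence if isinstance(x, ProteinRecord) else str(x)


def _id_of(x, default: str) -> str:
    return x.protein_id if isinstance(x, ProteinRecord) else default


def align_protein_protein(
    query, subject, scheme: ScoringScheme, db_residues: int | None = None
) -> ProteinAlignment:
    """Optimal local alignment of two proteins under the scheme.

    ``db_residues`` sets n in the E-value (defaults to the subject length,
    i.e. a single-sequence database).
    """
    qseq, sseq = _seq_of(query), _seq_of(subject)
    if not qseq or not sseq:
        raise ValueError("sequences must be nonempty")
    key = (qseq, sseq)
    cached = scheme._pp_cache.get(key)
    if cached is None:
        gq = bseq.GeneralSequence(scheme._bio_alphabet)
        gq.code = scheme.encode(qseq)
        gs = bseq.GeneralSequence(scheme._bio_alphabet)
        gs.code = scheme.encode(sseq)
        alns = balign.align_optimal(
            gq,
            gs,
            scheme._bio_matrix,
            gap_penalty=(-scheme.gap_open, -scheme.gap_extend),
            local=True,
            max_number=1,
        )
        aln = alns[0]
        score = int(aln.score)
        trace = aln.trace
        if score <= 0 or len(trace) == 0:
            cached = (0, (0, 0), (0, 0), 0, 0)
        else:
            qcols = trace[:, 0]
            scols = trace[:, 1]
            qpos = qcols[qcols >= 0]
            spos = scols[scols >= 0]
            n_id = sum(
                1
                for qi, si in trace
                if qi >= 0 and si >= 0 and qseq[qi] == sseq[si]
            )
            cached = (
                score,
                (int(qpos.min()), int(qpos.max()) + 1),
                (int(spos.min()), int(spos.max()) + 1),
                n_id,
                len(trace),
            )
        scheme._pp_cache[key] = cached
    score, qspan, sspan, n_id, ncols = cached
    n = db_residues if db_residues is not None else len(sseq)
    return ProteinAlignment(
        query_id=_id_of(query, "query"),
        subject_id=_id_of(subject, "subject"),
        score=score,
        bitscore=bitscore(score, scheme),
        evalue=evalue(score, len(qseq), n, scheme),
        query_span=qspan,
        subject_span=sspan,
        identity=(n_id / ncols) if ncols else 0.0,
        query_coverage=(qspan[1] - qspan[0]) / len(qseq),
        n_columns=ncols,
    )


def _encode_dna(dna: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_NT_INDEX[c] for c in dna), dtype=np.int8, count=len(dna)
        )
    except KeyError as exc:
        raise ValueError(f"character {exc.args[0]!r} is not a nucleotide") from exc


def _traceback(qseq, dna, scheme, best, bi, bj, ptrM, ptrD, ptrI):
    """Reconstruct steps from kernel pointers.

    Returns (qspan, dspan, events_local, n_id, n_cols, peptide) with DNA
    coordinates local to the scanned strand.
    """
    steps = []  # (op, i, j, k) with (i, j) the cell *after* the step
    layer = "M"
    i, j = bi, bj
    while True:
        if layer == "M":
            code = int(ptrM[i, j])
            src, k = code // 16, code % 16
            steps.append(("M", i, j, k))
            i, j = i - 1, j - k
            if src == 0:
                break
            layer = "MDI"[src - 1]
        elif layer == "D":
            src = int(ptrD[i, j])
            steps.append(("D", i, j, 3))
            j -= 3
            layer = "MDI"[src - 1]
        else:
            src = int(ptrI[i, j])
            steps.append(("I", i, j, 1))
            i -= 1
            layer = "MDI"[src - 1]
    steps.reverse()
    q0, j0 = i, j
    events = []
    n_id = 0
    peptide = []
    for op, si, sj, k in steps:
        if op == "I":
            continue
        cj = sj - 3  # codon start within consumed window (k=3 or 4)
        if op == "M" and k == 2:
            peptide.append("X")
            events.append(("frameshift", si - 1, sj - k, k, -1))
            continue
        c0, c1, c2 = dna[cj], dna[cj + 1], dna[cj + 2]
        if c0 < 4 and c1 < 4 and c2 < 4:
            ci = int(c0) * 16 + int(c1) * 4 + int(c2)
            is_stop = bool(_CODON_STOP[ci])
            aa = "*" if is_stop else ALPHABET[_CODON_AA[ci]]
        else:
            is_stop = False
            aa = "X"
        if op == "M" and k == 4:
            events.append(("frameshift", si - 1, sj - k, k, +1))
        if op == "M" and is_stop:
            events.append(
                (
                    "stop",
                    si - 1,
                    sj - k,
                    k,
                    "".join("ACGTN"[int(c)] for c in (c0, c1, c2)),
                )
            )
        peptide.append(aa)
        if op == "M" and not is_stop and aa == qseq[si - 1]:
            n_id += 1
    return (q0, bi), (j0, bj), events, n_id, len(steps), "".join(peptide)


def align_protein_dna_fs(
    query, dna: str, scheme: ScoringScheme, db_residues: int | None = None,
    subject_id: str = "dna",
) -> FrameshiftAlignment:
    """Best local frameshift/stop-aware alignment over both strands.

    Ties between equal-scoring strands are broken by fewer events, shorter
    DNA span, smaller forward-strand start, then '+' strand.
    """
    qseq = _seq_of(query)
    if not qseq:
        raise ValueError("empty query")
    if len(dna) < 3:
        raise ValueError("DNA must be at least one codon long")
    q = scheme.encode(qseq)
    L = len(dna)
    results = []
    for strand in "+-":
        seq = dna if strand == "+" else reverse_complement(dna)
        d = _encode_dna(seq)
        best, bi, bj, ptrM, ptrD, ptrI = fs_align_kernel(
            q,
            d,
            scheme.matrix,
            _CODON_AA,
            _CODON_STOP,
            scheme.gap_open,
            scheme.gap_extend,
            scheme.frameshift_penalty,
            scheme.stop_match_score,
            scheme.alphabet.index("X"),
        )
        if best <= 0 or bi < 0:
            results.append((0, strand, None))
            continue
        qspan, dspan, events, n_id, n_cols, peptide = _traceback(
            qseq, d, scheme, best, bi, bj, ptrM, ptrD, ptrI
        )
        if strand == "-":
            dspan = (L - dspan[1], L - dspan[0])
            events = [
                (kind, qp, L - (start + width), width, det)
                for kind, qp, start, width, det in events
            ]
        results.append(
            (int(best), strand, (qspan, dspan, events, n_id, n_cols, peptide))
        )

    def sort_key(item):
        score, strand, payload = item
        if payload is None:
            return (-score, 0, 0, 0, strand != "+")
        qspan, dspan, events, *_ = payload
        return (
            -score,
            len(events),
            dspan[1] - dspan[0],
            dspan[0],
            strand != "+",
        )

    score, strand, payload = min(results, key=sort_key)
    n = db_residues if db_residues is not None else L
    if payload is None:
        return FrameshiftAlignment(
            query_id=_id_of(query, "query"),
            subject_id=subject_id,
            score=0,
            bitscore=bitscore(0, scheme),
            evalue=evalue(0, len(qseq), n, scheme),
            query_span=(0, 0),
            subject_span=(0, 0),
            identity=0.0,
            query_coverage=0.0,
            strand="+",
            events=[],
            dna_span=(0, 0),
            implied_peptide="",
        )
    qspan, dspan, raw_events, n_id, n_cols, peptide = payload
    events = sorted(
        (
            AlignmentEvent(kind=kind, query_pos=qp, dna_pos=dp, detail=det)
            for kind, qp, dp, _width, det in raw_events
        ),
        key=lambda e: (e.query_pos, e.dna_pos),
    )
    return FrameshiftAlignment(
        query_id=_id_of(query, "query"),
        subject_id=subject_id,
        score=score,
        bitscore=bitscore(score, scheme),
        evalue=evalue(score, len(qseq), n, scheme),
        query_span=qspan,
        subject_span=dspan,
        identity=(n_id / n_cols) if n_cols else 0.0,
        query_coverage=(qspan[1] - qspan[0]) / len(qseq),
        strand=strand,
        events=events,
        dna_span=dspan,
        implied_peptide=peptide,
    )


def extract_events(aln: FrameshiftAlignment) -> tuple[int, int]:
    """(n_frameshifts, n_stops) of an alignment's event list."""
    return aln.n_frameshifts, aln.n_stops


TABULAR_COLUMNS = [
    "query_id", "subject_id", "identity", "length", "q_start", "q_end",
    "s_start", "s_end", "evalue", "bitscore", "n_frameshifts", "n_stops",
]


def alignments_to_tsv(alignments, path) -> None:
    """Export alignments as BLAST outfmt-6-like TSV with event columns."""
    with open(path, "w") as out:
        out.write("\t".join(TABULAR_COLUMNS) + "\n")
        for a in alignments:
            out.write(
                "\t".join(
                    str(v)
                    for v in [
                        a.query_id, a.subject_id, round(a.identity, 4),
                        a.query_span[1] - a.query_span[0],
                        a.query_span[0], a.query_span[1],
                        a.subject_span[0], a.subject_span[1],
                        f"{a.evalue:.3g}", round(a.bitscore, 1),
                        a.n_frameshifts, a.n_stops,
                    ]
                )
                + "\n"
            )
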