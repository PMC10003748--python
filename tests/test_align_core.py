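"""Alignment engine: scores against independent DP/enumeration oracles,
E-value behavior, event extraction and determinism."""

import math

import numpy as np
import pytest

from trgkit.align_core import (
    align_protein_dna_fs,
    align_protein_protein,
    bitscore,
    default_scheme,
    evalue,
    extract_events,
    read_ncbi_matrix,
)
from trgkit._blosum import BLOSUM62_TEXT
from trgkit.sequence_io import reverse_complement, translate
from trgkit.synthetic_data import disrupt_coding, random_coding_dna

from _oracles import fs_align_enumerate, fs_align_oracle, sw_protein_oracle
from conftest import random_protein


def test_matrix_parsing_round_trip():
    alphabet, mat = read_ncbi_matrix(BLOSUM62_TEXT)
    assert alphabet.startswith("ARND") and "*" in alphabet
    assert mat[alphabet.index("W"), alphabet.index("W")] == 11
    assert (mat == mat.T).all()


def test_identical_tripeptide_score(scheme):
    aln = align_protein_protein("MKL", "MKL", scheme)
    assert aln.score == 14  # M:5 + K:5 + L:4
    assert aln.identity == 1.0
    assert aln.query_coverage == 1.0


def test_all_negative_pairs_give_empty_alignment(scheme):
    aln = align_protein_protein("AAAA", "WWWW", scheme)
    assert aln.score == 0
    assert aln.query_coverage == 0.0


def test_protein_alignment_matches_reference_dp(scheme, rng):
    """Optimal local scores equal a plain 3-matrix DP on random 30-mers."""
    for _ in range(20):
        a = random_protein(rng, 30)
        b = random_protein(rng, 30)
        expected = sw_protein_oracle(
            a, b, scheme.score, scheme.gap_open, scheme.gap_extend
        )
        assert align_protein_protein(a, b, scheme).score == expected


def test_evalue_form_and_monotonicity(scheme):
    direct = 0.041 * 100 * 1e6 * math.exp(-0.267 * 40)
    assert evalue(40, 100, 10**6, scheme) == pytest.approx(direct, rel=1e-12)
    assert evalue(50, 100, 10**6, scheme) < evalue(40, 100, 10**6, scheme)
    assert evalue(40, 100, 2 * 10**6, scheme) == pytest.approx(
        2 * evalue(40, 100, 10**6, scheme)
    )
    assert evalue(10**4, 100, 10**6, scheme) == pytest.approx(0.0, abs=1e-200)


def test_fs_reduction_to_protein_alignment(scheme, rng):
    """DNA exactly encoding the query reduces to the protein alignment."""
    for _ in range(5):
        dna = random_coding_dna(rng, 25)
        protein = translate(dna)[:-1]
        fs = align_protein_dna_fs(protein, dna, scheme)
        pp = align_protein_protein(protein, protein, scheme)
        assert fs.score == pp.score
        assert extract_events(fs) == (0, 0)
        assert fs.query_coverage == 1.0
        assert fs.strand == "+"


def test_fs_reverse_strand_recovered(scheme, rng):
    dna = random_coding_dna(rng, 20)
    protein = translate(dna)[:-1]
    fs = align_protein_dna_fs(protein, reverse_complement(dna), scheme)
    assert fs.strand == "-"
    assert extract_events(fs) == (0, 0)
    assert fs.query_coverage == 1.0


def test_single_insertion_yields_one_frameshift(soft_scheme):
    fs = align_protein_dna_fs("MKL", "ATGAAAACTG", soft_scheme)
    assert extract_events(fs) == (1, 0)
    (event,) = fs.events
    assert event.kind == "frameshift"
    assert event.detail == +1


def test_premature_stop_yields_one_stop_event(soft_scheme):
    fs = align_protein_dna_fs("MKLK", "ATGTAACTGAAA", soft_scheme)
    assert extract_events(fs) == (0, 1)
    (event,) = fs.events
    assert event.kind == "stop"
    assert event.query_pos == 1
    assert event.detail == "TAA"


@pytest.mark.parametrize("n_stops,n_frameshifts", [(1, 0), (0, 1), (2, 1), (3, 2)])
def test_planted_disruptions_recovered(scheme, n_stops, n_frameshifts):
    """Event counts planted by the generator come back exactly."""
    gen = np.random.default_rng(5 + n_stops * 10 + n_frameshifts)
    dna = random_coding_dna(gen, 90)
    protein = translate(dna)[:-1]
    fragment, stops, shifts = disrupt_coding(dna, n_stops, n_frameshifts, gen)
    assert (len(stops), len(shifts)) == (n_stops, n_frameshifts)
    fs = align_protein_dna_fs(protein, fragment, scheme)
    assert extract_events(fs) == (n_frameshifts, n_stops)
    assert fs.query_coverage == 1.0


def test_fs_score_matches_recursive_oracle(scheme, rng):
    """Kernel scores equal the memoized-recursion oracle on small inputs."""
    for _ in range(30):
        q = random_protein(rng, int(rng.integers(2, 9)))
        dna = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 31))))
        got = align_protein_dna_fs(q, dna, scheme)
        fwd = fs_align_oracle(
            q, dna, scheme.score, scheme.gap_open, scheme.gap_extend,
            scheme.frameshift_penalty, scheme.stop_match_score,
        )
        rev = fs_align_oracle(
            q, reverse_complement(dna), scheme.score, scheme.gap_open,
            scheme.gap_extend, scheme.frameshift_penalty,
            scheme.stop_match_score,
        )
        assert got.score == max(fwd, rev)


def test_recursive_oracle_agrees_with_exhaustive_enumeration(scheme, rng):
    """The memoized oracle itself is validated by brute-force path
    enumeration on tiny instances."""
    for _ in range(10):
        q = random_protein(rng, int(rng.integers(1, 4)))
        dna = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 10))))
        memo = fs_align_oracle(
            q, dna, scheme.score, scheme.gap_open, scheme.gap_extend,
            scheme.frameshift_penalty, scheme.stop_match_score,
        )
        brute = fs_align_enumerate(
            q, dna, scheme.score, scheme.gap_open, scheme.gap_extend,
            scheme.frameshift_penalty, scheme.stop_match_score,
        )
        assert memo == brute


def test_flanking_sequence_never_decreases_score(scheme, rng):
    """Local alignment: adding unrelated flanks cannot lower the optimum."""
    for _ in range(5):
        dna = random_coding_dna(rng, 30)
        protein = translate(dna)[:-1]
        flank_l = "".join(rng.choice(list("ACGT"), size=60))
        flank_r = "".join(rng.choice(list("ACGT"), size=60))
        bare = align_protein_dna_fs(protein, dna, scheme).score
        flanked = align_protein_dna_fs(protein, flank_l + dna + flank_r, scheme).score
        assert flanked >= bare


def test_alignment_is_deterministic(scheme, rng):
    q = random_protein(rng, 40)
    dna = "".join(rng.choice(list("ACGT"), size=300))
    a = align_protein_dna_fs(q, dna, scheme)
    b = align_protein_dna_fs(q, dna, scheme)
    assert (a.score, a.dna_span, a.strand, len(a.events)) == (
        b.score, b.dna_span, b.strand, len(b.events),
    )


def test_bitscore_increases_with_score(scheme):
    assert bitscore(100, scheme) > bitscore(50, scheme)


def test_invalid_characters_rejected(scheme):
    with pytest.raises(ValueError):
        align_protein_protein("MK9", "MKL", scheme)
    with pytest.raises(ValueError):
        align_protein_dna_fs("MKL", "ATGQQQ", scheme)
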