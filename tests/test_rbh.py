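"""Best-hit selection, reciprocal best hits against a brute-force oracle,
and the reciprocal protein-DNA-protein search."""

import numpy as np
import pytest

from trgkit.align_core import align_protein_protein
from trgkit.rbh import best_hit, reciprocal_best_hits, reciprocal_tfs
from trgkit.sequence_io import ProteinRecord, translate
from trgkit.synthetic_data import (
    disrupt_coding,
    mutate_coding,
    random_coding_dna,
    random_dna,
)

from conftest import random_protein


def _rec(pid, seq, genome="G"):
    return ProteinRecord(pid, seq, frozenset({(genome, pid)}))


@pytest.fixture(scope="module")
def protein_pool():
    rng = np.random.default_rng(3)
    return [_rec(f"p{i}", random_protein(rng, 60)) for i in range(8)]


def test_identical_target_is_best(scheme, protein_pool):
    query = _rec("q", protein_pool[0].sequence)
    hit = best_hit(query, protein_pool, scheme)
    assert hit is not None and hit.subject_id == "p0"


def test_unrelated_targets_give_no_hit(scheme, protein_pool):
    """Chance similarity between random 60-mers stays below the reporting
    floor, so the search correctly returns nothing."""
    rng = np.random.default_rng(99)
    query = _rec("q", random_protein(rng, 60))
    assert best_hit(query, protein_pool, scheme) is None


def test_tie_break_is_deterministic(scheme):
    base = "MKWLEDRAKFHQCYVNSTGIMKWLEDRAKFHQCYVNSTGI"
    targets = [_rec("tb", base), _rec("ta", base)]
    query = _rec("q", base)
    first = best_hit(query, targets, scheme)
    second = best_hit(query, list(reversed(targets)), scheme)
    assert first.subject_id == second.subject_id == "ta"


def test_rbh_matches_brute_force(scheme):
    """RBH pairs equal an exhaustive all-vs-all best-hit cross-check on
    two sets containing planted homolog pairs plus unrelated decoys."""
    rng = np.random.default_rng(12)
    bases = [random_protein(rng, 70) for _ in range(4)]
    set_a = [_rec(f"a{i}", b, "GA") for i, b in enumerate(bases)]
    set_a.append(_rec("a_lone", random_protein(rng, 70), "GA"))
    set_b = [
        _rec(f"b{i}", translate(mutate_coding(
            random_coding_dna(np.random.default_rng(100 + i), 71), 0.0, rng))[:-1])
        for i in range(2)
    ]
    set_b += [_rec(f"b{i+2}", bases[i]) for i in range(4)]

    pairs = reciprocal_best_hits(set_a, set_b, scheme)
    got = {p.ids() for p in pairs}

    # oracle: exhaustive score tables in both directions
    def full_best(query, targets):
        n = sum(len(t.sequence) for t in targets)
        scored = []
        for t in targets:
            aln = align_protein_protein(query, t, scheme, db_residues=n)
            if aln.score > 0 and aln.evalue <= 10 and aln.bitscore >= scheme.min_bitscore:
                scored.append((aln.score, t.protein_id))
        return max(scored)[1] if scored else None

    expected = set()
    for a in set_a:
        b_id = full_best(a, set_b)
        if b_id is None:
            continue
        b = next(t for t in set_b if t.protein_id == b_id)
        if full_best(b, set_a) == a.protein_id:
            expected.add((a.protein_id, b_id))
    assert got == expected
    assert {("a0", "b2"), ("a1", "b3")} <= got
    # partial matching: no id twice
    used = [x for p in got for x in p]
    assert len(used) == len(set(used))


def test_rbh_requires_disjoint_ids(scheme):
    a = [_rec("x", "MKLMKLMKL")]
    with pytest.raises(ValueError):
        reciprocal_best_hits(a, a, scheme)


class TestReciprocalTfs:
    def test_exact_coding_copy_recovered(self, scheme):
        rng = np.random.default_rng(4)
        dna = random_coding_dna(rng, 80)
        query = _rec("q", translate(dna)[:-1])
        proteome = [query, _rec("other", random_protein(rng, 80))]
        target = random_dna(rng, 300, 0.44) + dna + random_dna(rng, 300, 0.44)
        result = reciprocal_tfs(query, target, proteome, scheme)
        assert result is not None
        fwd, rev = result
        assert (fwd.n_frameshifts, fwd.n_stops) == (0, 0)
        assert fwd.query_coverage == 1.0
        assert rev.subject_id == "q"

    def test_unrelated_dna_gives_none(self, scheme):
        rng = np.random.default_rng(5)
        query = _rec("q", random_protein(rng, 80))
        proteome = [query]
        assert reciprocal_tfs(query, random_dna(rng, 2000, 0.44), proteome, scheme) is None

    def test_disrupted_copy_validated(self, scheme):
        rng = np.random.default_rng(6)
        dna = random_coding_dna(rng, 90)
        query = _rec("q", translate(dna)[:-1])
        fragment, _, _ = disrupt_coding(dna, 2, 1, rng)
        target = random_dna(rng, 200, 0.44) + fragment + random_dna(rng, 200, 0.44)
        proteome = [query, _rec("o", random_protein(rng, 90))]
        result = reciprocal_tfs(query, target, proteome, scheme)
        assert result is not None
        fwd, rev = result
        assert (fwd.n_stops, fwd.n_frameshifts) == (2, 1)
        assert rev.subject_id == "q"
        # the implied peptide keeps stops and splices out frameshifts
        assert fwd.implied_peptide.count("*") == 2
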