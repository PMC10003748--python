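"""Sequence-property metrics, matched control sampling, rank tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trgkit.properties import (
    aggregation_frequency,
    build_property_table,
    compare_groups,
    disorder_fraction,
    sample_matched_controls,
    shannon_entropy,
)

from conftest import random_protein


class TestEntropy:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", 0.0),
            ("AABB", 1.0),
            ("ACDEFGHIKLMNPQRSTVWY", math.log2(20)),
        ],
    )
    def test_examples(self, seq, expected):
        assert shannon_entropy(seq) == pytest.approx(expected, abs=1e-12)

    def test_empty_contract(self):
        with pytest.raises(ValueError):
            shannon_entropy("")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_bounds(self, seq):
        h = shannon_entropy(seq)
        assert -1e-9 <= h <= math.log2(min(20, len(seq))) + 1e-9


class TestDisorderAndAggregation:
    def test_disorder_extremes_and_direct_count(self):
        assert disorder_fraction("MKLV", [0.9] * 4) == 1.0
        assert disorder_fraction("MKLV", [0.1] * 4) == 0.0
        assert disorder_fraction("MKLV", [0.6, 0.4, 0.7, 0.2]) == 0.5
        with pytest.raises(ValueError):
            disorder_fraction("MK", [0.5])

    def test_aggregation_coverage_semantics(self):
        seq = "A" * 12
        no_hits = [0.0] * 7
        assert aggregation_frequency(seq, no_hits) == 0.0
        all_hits = [9.0] * 7
        assert aggregation_frequency(seq, all_hits) == 1.0
        one = [0.0] * 7
        one[0] = 9.0  # hexapeptide covering residues 0..5 of 12
        assert aggregation_frequency(seq, one) == 0.5
        with pytest.raises(ValueError):
            aggregation_frequency(seq, [1.0])


class TestMatchedControls:
    def _pools(self, rng, n_trg=10, pool=200):
        trgs = {"P1": [(f"t{i}", random_protein(rng, 50)) for i in range(n_trg)]}
        orfs = {"P1": [(f"o{i}", random_protein(rng, 20)) for i in range(pool)]}
        ann = {"P1": [(f"a{i}", random_protein(rng, 200)) for i in range(pool)]}
        return trgs, orfs, ann

    def test_counts_match(self, rng):
        trgs, orfs, ann = self._pools(rng)
        picked = sample_matched_controls(trgs, orfs, ann, seed=1)
        assert len(picked["ORF"]) == len(picked["annotated"]) == 10

    def test_same_seed_reproducible_different_seed_differs(self, rng):
        trgs, orfs, ann = self._pools(rng)
        one = sample_matched_controls(trgs, orfs, ann, seed=1)
        two = sample_matched_controls(trgs, orfs, ann, seed=1)
        other = sample_matched_controls(trgs, orfs, ann, seed=2)
        assert one == two
        assert one != other  # pools >> n: collision probability is negligible

    def test_shortfall_takes_whole_pool(self, rng):
        trgs, orfs, ann = self._pools(rng, n_trg=10, pool=4)
        picked = sample_matched_controls(trgs, orfs, ann, seed=1)
        assert len(picked["ORF"]) == 4


class TestCompareGroups:
    def test_identical_groups_not_significant(self, rng):
        seqs = [(f"s{i}", random_protein(rng, 50)) for i in range(30)]
        table = build_property_table({"ORF": seqs, "annotated": seqs})
        result = compare_groups(table, "entropy")
        assert result.loc[0, "p_value"] > 0.9

    def test_fully_separated_groups_hit_extreme_statistic(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "group": ["ORF"] * 3 + ["annotated"] * 3,
                "length": [1, 2, 3, 101, 102, 103],
            }
        )
        result = compare_groups(table, "length")
        # Mann-Whitney U of fully separated samples is 0 (or n1*n2)
        assert result.loc[0, "statistic"] in (0.0, 9.0)
        assert result.loc[0, "p_value"] == pytest.approx(0.1, abs=0.01)

    def test_degenerate_all_tied_reports_p_one(self):
        import pandas as pd

        table = pd.DataFrame(
            {"group": ["ORF"] * 3 + ["annotated"] * 3, "length": [5] * 6}
        )
        result = compare_groups(table, "length")
        assert result.loc[0, "p_value"] == 1.0

    def test_planted_median_shift_detected(self, rng):
        a = [(f"a{i}", random_protein(rng, 40)) for i in range(500)]
        b = [(f"b{i}", random_protein(rng, 120)) for i in range(500)]
        table = build_property_table({"ORF": a, "annotated": b})
        result = compare_groups(table, "length")
        assert result.loc[0, "p_value"] < 1e-10


def test_property_table_schema(rng):
    table = build_property_table(
        {"TRG_genus": [("t", random_protein(rng, 60))]}
    )
    row = table.iloc[0]
    assert 0 <= row["disorder_fraction"] <= 1
    assert 0 <= row["aggregation_freq"] <= 1
    assert row["length"] == 60
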