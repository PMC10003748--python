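"""Database-size / threshold sensitivity: monotonicity and the analytic
re-thresholding shortcut."""

import numpy as np
import pytest

from trgkit.sensitivity import SensitivityDesign, subsample_experiment
from trgkit.sequence_io import ProteinRecord
from trgkit.synthetic_data import mutate_coding, random_coding_dna
from trgkit.sequence_io import translate

from conftest import random_protein


@pytest.fixture(scope="module")
def search_setup(scheme):
    """10 queries, 12 single-protein genomes; half the queries have a
    planted homolog somewhere in the database."""
    rng = np.random.default_rng(21)
    queries, database = [], []
    for i in range(5):
        dna = random_coding_dna(rng, 80)
        seq = translate(dna)[:-1]
        queries.append(ProteinRecord(f"q{i}", seq, frozenset({("Q", f"q{i}")})))
        hom = translate(mutate_coding(dna, 0.02, rng))[:-1]
        database.append((f"g{i}", ProteinRecord(f"h{i}", hom, frozenset({(f"g{i}", f"h{i}")}))))
    for i in range(5, 10):
        queries.append(
            ProteinRecord(f"q{i}", random_protein(rng, 80), frozenset({("Q", f"q{i}")}))
        )
    for i in range(5, 12):
        database.append(
            (f"g{i}", ProteinRecord(f"d{i}", random_protein(rng, 90), frozenset({(f"g{i}", f"d{i}")})))
        )
    return queries, database


def test_baseline_no_exclusion_has_single_rep(search_setup, scheme):
    queries, database = search_setup
    design = SensitivityDesign(exclusion_sizes=[0], e_values=[10.0], n_reps=5, seed=0)
    table, summary = subsample_experiment(queries, database, design, scheme)
    assert len(table) == 1
    row = summary.iloc[0]
    assert row["median"] == row["min"] == row["max"] == 5  # unrelated queries


def test_putative_counts_monotone_in_threshold(search_setup, scheme):
    queries, database = search_setup
    design = SensitivityDesign(
        exclusion_sizes=[0, 3], e_values=[10, 1e-3, 1e-20, 1e-100, 1e-180],
        n_reps=10, seed=1,
    )
    table, _ = subsample_experiment(queries, database, design, scheme)
    for (_excl, rep), sub in table.groupby(["exclusion_size", "rep"]):
        # e_values are iterated from permissive to strict within each rep
        counts = sub.sort_values("e_value", ascending=False)["n_putative"].tolist()
        assert counts == sorted(counts)


def test_shrinking_database_never_loses_putatives(search_setup, scheme):
    queries, database = search_setup
    design = SensitivityDesign(
        exclusion_sizes=[0, 2, 5, 8], e_values=[10.0, 1e-20], n_reps=15, seed=3
    )
    table, summary = subsample_experiment(queries, database, design, scheme)
    for e_val, sub in summary.groupby("e_value"):
        sub = sub.sort_values("exclusion_size")
        medians = sub["median"].tolist()
        assert medians == sorted(medians)
        # bands bracket the median
        assert (sub["min"] <= sub["median"]).all()
        assert (sub["median"] <= sub["max"]).all()


def test_nested_database_monotonicity_exact(search_setup, scheme):
    """For explicitly nested databases D' in D, every query putative on D
    is putative on D' (not just in the median)."""
    queries, database = search_setup
    design = SensitivityDesign(exclusion_sizes=[0], e_values=[10.0], n_reps=1)
    full, _ = subsample_experiment(queries, database, design, scheme)
    reduced, _ = subsample_experiment(queries, database[:6], design, scheme)
    assert reduced["n_putative"].iloc[0] >= full["n_putative"].iloc[0]


def test_exclusion_size_contract(search_setup, scheme):
    queries, database = search_setup
    design = SensitivityDesign(exclusion_sizes=[12], e_values=[10.0])
    with pytest.raises(ValueError):
        subsample_experiment(queries, database, design, scheme)
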