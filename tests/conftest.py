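import numpy as np
import pytest

from trgkit.align_core import default_scheme
from trgkit.synthetic_data import (
    PlantDesign,
    SyntheticCladeSpec,
    generate_clade,
)
from trgkit.trg_pipeline import run_classification


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def soft_scheme():
    """Reduced penalties so minimal examples exercise frameshift/stop moves."""
    return default_scheme(frameshift_penalty=2, stop_match_score=-2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_clade():
    """A compact clade exercising every planted class (fast to classify)."""
    spec = SyntheticCladeSpec(
        n_species=3,
        strains_per_species=2,
        n_external_genomes=5,
        design=PlantDesign(
            conserved=12,
            missed_annotation=4,
            syntenic_trace=4,
            nonsyntenic_trace=4,
            no_trace=4,
            species_trg=2,
            families=((3, "clique"), (3, "star")),
            paralog_pairs=1,
            noncoding_paralogs=1,
            leaky_families=2,
            leaky_family_size=3,
        ),
        seed=11,
    )
    return generate_clade(spec)


@pytest.fixture(scope="session")
def small_run(small_clade):
    candidates, rbh_pairs, ledger, ctx = run_classification(
        small_clade.genus_genomes,
        small_clade.genus_annotations,
        small_clade.external_genomes,
        small_clade.external_annotations,
    )
    return {
        "clade": small_clade,
        "candidates": candidates,
        "rbh_pairs": rbh_pairs,
        "ledger": ledger,
        "ctx": ctx,
    }


def random_protein(rng, length):
    """Random amino-acid sequence with codon-uniform composition."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    weights = np.array([4, 2, 2, 2, 2, 4, 2, 3, 1, 6, 2, 2, 4, 2, 6, 4, 1, 4, 2, 1], float)
    weights /= weights.sum()
    return "".join(rng.choice(list(aas), size=length, p=weights))
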