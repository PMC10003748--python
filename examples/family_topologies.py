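"""Cluster restricted genes into families and inspect their topology.

Runs the pipeline on a clade with one planted clique family and one star
family, then prints each family's density: 1.0 means every member pair is
a reciprocal best hit (nearly identical sequences); 2/n is the star
signature of a conserved hub with diverged leaves.
"""

from trgkit.clustering import build_rbh_graph, single_linkage_families
from trgkit.synthetic_data import PlantDesign, SyntheticCladeSpec, generate_clade
from trgkit.trg_pipeline import run_classification

spec = SyntheticCladeSpec(
    n_species=5, strains_per_species=1, n_external_genomes=3,
    design=PlantDesign(
        conserved=10, missed_annotation=0, syntenic_trace=0,
        nonsyntenic_trace=0, no_trace=2, species_trg=0,
        families=((5, "clique"), (5, "star")), paralog_pairs=1,
        noncoding_paralogs=0, leaky_families=0,
    ),
    seed=4,
)
clade = generate_clade(spec)
candidates, rbh_pairs, ledger, ctx = run_classification(
    clade.genus_genomes, clade.genus_annotations,
    clade.external_genomes, clade.external_annotations,
)
kept = [c for c in candidates if c.status.startswith("trg_")]
graph = build_rbh_graph(kept, rbh_pairs)
for fam in single_linkage_families(graph):
    if len(fam) > 1:
        print(f"{fam.family_id}: {len(fam)} members, "
              f"{fam.n_edges} edges, density {fam.density:.2f}")
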