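"""Effect of reference-database size and E-value threshold on the number
of putative restricted genes.

All query-vs-database alignments are computed once; each (exclusion size,
threshold, replicate) cell is then evaluated by re-thresholding the stored
raw scores, with the E-value rescaled analytically to the reduced
database's residue count (E is proportional to n under the Karlin-Altschul
form, so one alignment pass is exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align_core import ScoringScheme, align_protein_protein, bitscore


@dataclass
class SensitivityDesign:
    exclusion_sizes: list[int] = field(default_factory=lambda: [0, 2, 5, 10])
    e_values: list[float] = field(
        default_factory=lambda: [10, 1e-1, 1e-3, 1e-5, 1e-10, 1e-20, 1e-100, 1e-180]
    )
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(e <= 0 for e in self.e_values):
            raise ValueError("e-value thresholds must be positive")


def _score_matrix(queries, database, scheme):
    """Best raw score of each query against each database genome."""
    genome_ids = sorted({g for g, _p in database})
    gi = {g: k for k, g in enumerate(genome_ids)}
    scores = np.zeros((len(queries), len(genome_ids)), dtype=np.int64)
    residues = np.zeros(len(genome_ids), dtype=np.int64)
    for g, p in database:
        residues[gi[g]] += len(p.sequence)
    for qi, q in enumerate(queries):
        for g, p in database:
            aln = align_protein_protein(q, p, scheme)
            k = gi[g]
            if aln.score > scores[qi, k]:
                scores[qi, k] = aln.score
    return genome_ids, scores, residues


def subsample_experiment(
    queries,
    database,
    design: SensitivityDesign,
    scheme: ScoringScheme,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Putative-count table over (exclusion size x threshold x replicate).

    ``database`` is a list of (genome_id, ProteinRecord); exclusions remove
    whole genomes. A query is putative when no remaining hit satisfies
    both the rescaled ``E <= e_value`` and the scheme's bit-score floor.
    Returns (long table, summary with median/min/max per cell).
    """
    rng = np.random.default_rng(design.seed)
    genome_ids, scores, residues = _score_matrix(queries, database, scheme)
    n_genomes = len(genome_ids)
    if any(x >= n_genomes for x in design.exclusion_sizes):
        raise ValueError("exclusion size must be below the database genome count")
    qlen = np.array([len(q.sequence) for q in queries], dtype=np.int64)
    floor_score = math.ceil(
        (scheme.min_bitscore * math.log(2.0) + math.log(scheme.K)) / scheme.lambda_
    )
    rows = []
    for excl in design.exclusion_sizes:
        for rep in range(design.n_reps if excl > 0 else 1):
            keep = np.ones(n_genomes, dtype=bool)
            if excl > 0:
                keep[rng.choice(n_genomes, size=excl, replace=False)] = False
            n_db = int(residues[keep].sum())
            best = scores[:, keep].max(axis=1) if keep.any() else np.zeros(len(queries))
            for e_val in design.e_values:
                # qualifying hit: E <= e_val  <=>  S >= s*(e_val, m, n)
                with np.errstate(divide="ignore"):
                    s_star = (
                        np.log(scheme.K * qlen * max(n_db, 1) / e_val)
                        / scheme.lambda_
                    )
                threshold = np.maximum(np.ceil(s_star), floor_score)
                n_putative = int((best < threshold).sum())
                rows.append(
                    {
                        "exclusion_size": excl,
                        "e_value": e_val,
                        "rep": rep,
                        "n_db_residues": n_db,
                        "n_putative": n_putative,
                    }
                )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["exclusion_size", "e_value"])["n_putative"]
        .agg(["median", "min", "max"])
        .reset_index()
    )
    return table, summary


def plot_bands(summary: pd.DataFrame, path) -> None:
    """Median line with min/max band per threshold (one panel)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for e_val, sub in summary.groupby("e_value"):
        sub = sub.sort_values("exclusion_size")
        ax.plot(sub["exclusion_size"], sub["median"], label=f"E={e_val:g}")
        ax.fill_between(sub["exclusion_size"], sub["min"], sub["max"], alpha=0.2)
    ax.set_xlabel("genomes excluded")
    ax.set_ylabel("putative restricted genes")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
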