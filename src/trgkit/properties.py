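"""Sequence-property profiles of TRGs versus matched controls.

For each group (genus-level TRGs, species-level TRGs, unannotated ORF
peptides, annotated non-TRG proteins) the table carries: length, Shannon
entropy of residue composition, intrinsic-disorder fraction (residues with
a per-residue disorder score above 0.5) and aggregation frequency
(residues inside hexapeptides whose aggregation score exceeds 5, as a
fraction of sequence length). Disorder and aggregation scores come from
pluggable adapters; the built-in adapter is a deterministic
hydropathy-based proxy (window-5 Kyte-Doolittle), which is *not* a
reimplementation of the published disorder/aggregation predictors - it
exists so the thresholding and group-comparison machinery is fully
testable without external binaries.

Group comparisons default to the unpaired two-sided Mann-Whitney U test:
the groups are independent samples subsampled to matched size, for which
a paired signed-rank test would be ill-posed (the paired variant is still
exposed for equal-length paired inputs).
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("TRG_genus", "TRG_species", "ORF", "annotated")

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def shannon_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the observed residue composition."""
    if not seq:
        raise ValueError("empty sequence")
    counts = np.array(list(Counter(seq).values()), dtype=float)
    return float(stats.entropy(counts, base=2))


def disorder_fraction(seq: str, scores) -> float:
    """Fraction of residues with disorder score strictly above 0.5."""
    if len(scores) != len(seq):
        raise ValueError("one disorder score per residue required")
    if not seq:
        raise ValueError("empty sequence")
    return sum(1 for s in scores if s > 0.5) / len(seq)


def aggregation_frequency(seq: str, segment_scores) -> float:
    """Fraction of residues covered by a hexapeptide scoring above 5."""
    expected = max(len(seq) - 5, 0)
    if len(segment_scores) != expected:
        raise ValueError(
            f"expected {expected} hexapeptide scores, got {len(segment_scores)}"
        )
    covered = [False] * len(seq)
    for i, score in enumerate(segment_scores):
        if score > 5:
            for pos in range(i, i + 6):
                covered[pos] = True
    return sum(covered) / len(seq) if seq else 0.0


def _window_mean(values, w=5):
    half = w // 2
    out = []
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out


def proxy_disorder_scores(seq: str) -> list[float]:
    """Hydrophilicity-based disorder proxy in [0, 1] (window-5 mean KD,
    mapped through a logistic; hydrophilic stretches score as disordered)."""
    kd = [_KD.get(c, 0.0) for c in seq]
    return [1.0 / (1.0 + math.exp(m)) for m in _window_mean(kd, 5)]


def proxy_aggregation_scores(seq: str) -> list[float]:
    """Hydrophobicity-based aggregation proxy per hexapeptide (0-100-ish
    scale so the published ">5" rule is exercised)."""
    scores = []
    for i in range(max(len(seq) - 5, 0)):
        hexapeptide = seq[i : i + 6]
        mean_kd = sum(_KD.get(c, 0.0) for c in hexapeptide) / 6.0
        scores.append(50.0 / (1.0 + math.exp(-mean_kd)) - 20.0)
    return scores


def read_score_file(path) -> list[float]:
    """Two-column adapter format: index <tab> score (header lines with '#')."""
    scores = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            scores.append(float(line.split()[-1]))
    return scores


def property_row(
    seq_id: str,
    group: str,
    seq: str,
    disorder_scores=None,
    aggregation_scores=None,
) -> dict:
    if disorder_scores is None:
        disorder_scores = proxy_disorder_scores(seq)
    if aggregation_scores is None:
        aggregation_scores = proxy_aggregation_scores(seq)
    return {
        "seq_id": seq_id,
        "group": group,
        "length": len(seq),
        "entropy": shannon_entropy(seq),
        "disorder_fraction": disorder_fraction(seq, disorder_scores),
        "aggregation_freq": aggregation_frequency(seq, aggregation_scores),
    }


def build_property_table(sequences_by_group: dict[str, list[tuple[str, str]]]) -> pd.DataFrame:
    """PropertyTable for {group: [(seq_id, sequence), ...]} using the
    built-in proxy adapters."""
    rows = []
    for group, entries in sequences_by_group.items():
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        for seq_id, seq in entries:
            rows.append(property_row(seq_id, group, seq))
    return pd.DataFrame(rows)


def sample_matched_controls(
    trgs: dict[str, list],
    orfs: dict[str, list],
    annotated: dict[str, list],
    seed: int,
) -> dict[str, list]:
    """Per-proteome control samples matched in count to the TRG sample.

    Inputs map proteome (genome) id -> [(seq_id, sequence), ...]; for each
    proteome with n TRGs, n ORF and n annotated sequences are drawn without
    replacement (all of them, with a shortfall, if the pool is smaller).
    Fully seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    picked = {"ORF": [], "annotated": []}
    for proteome in sorted(trgs):
        n = len(trgs[proteome])
        for group, pool_map in (("ORF", orfs), ("annotated", annotated)):
            pool = sorted(pool_map.get(proteome, []))
            take = min(n, len(pool))
            if take > 0:
                idx = rng.choice(len(pool), size=take, replace=False)
                picked[group].extend(pool[i] for i in sorted(idx))
    return picked


def compare_groups(
    table: pd.DataFrame, metric: str, paired: bool = False
) -> pd.DataFrame:
    """Two-sided rank test for every group pair present in the table.

    Returns a frame with group medians, the statistic and the p-value.
    Degenerate all-tied comparisons report p = 1.
    """
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    groups = [g for g in GROUPS if g in set(table["group"])]
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            a = table.loc[table["group"] == ga, metric].to_numpy()
            b = table.loc[table["group"] == gb, metric].to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise ValueError("need at least 2 observations per group")
            if np.ptp(np.concatenate([a, b])) == 0:
                stat, p = 0.0, 1.0
            elif paired:
                if len(a) != len(b):
                    raise ValueError("paired test requires equal sizes")
                stat, p = stats.wilcoxon(a, b)
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "metric": metric,
                    "group_a": ga,
                    "group_b": gb,
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)
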