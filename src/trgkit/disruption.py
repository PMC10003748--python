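"""Coding-capacity disruption summaries of TRG-matched noncoding fragments.

Each high-coverage noncoding fragment contributes one profile (its stop and
frameshift counts, taken from the alignment's event list); profiles are
tabulated per fragment and per TRG (Venn semantics: a TRG is in the stop
circle if any of its fragments carries a stop, in the frameshift circle if
any carries a frameshift).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DisruptionProfile:
    trg_id: str
    genome_id: str
    span: tuple[int, int]
    location: str  # 'syntenic' | 'non_syntenic'
    n_stops: int
    n_frameshifts: int
    coverage: float


def profile_disruptions(candidates, high_cov: float = 0.90) -> list[DisruptionProfile]:
    """One profile per (TRG, noncoding fragment) with coverage >= high_cov."""
    profiles = []
    for candidate in sorted(candidates, key=lambda c: c.protein_id):
        for aln, location, genome_id in candidate.noncoding_hits:
            if aln.query_coverage < high_cov:
                continue
            profiles.append(
                DisruptionProfile(
                    trg_id=candidate.protein_id,
                    genome_id=genome_id,
                    span=tuple(aln.dna_span),
                    location=location,
                    n_stops=aln.n_stops,
                    n_frameshifts=aln.n_frameshifts,
                    coverage=aln.query_coverage,
                )
            )
    return profiles


def categorize(profile: DisruptionProfile) -> str:
    if profile.n_stops > 0 and profile.n_frameshifts > 0:
        return "both"
    if profile.n_stops > 0:
        return "stop_only"
    if profile.n_frameshifts > 0:
        return "frameshift_only"
    return "none"


def fragment_categories(profiles) -> dict[str, int]:
    counts = {"both": 0, "stop_only": 0, "frameshift_only": 0, "none": 0}
    for p in profiles:
        counts[categorize(p)] += 1
    return counts


def trg_categories(profiles) -> dict[str, int]:
    """Per-TRG Venn cells over that TRG's fragments."""
    by_trg: dict[str, list[DisruptionProfile]] = {}
    for p in profiles:
        by_trg.setdefault(p.trg_id, []).append(p)
    counts = {"both": 0, "stop_only": 0, "frameshift_only": 0, "none": 0}
    for frags in by_trg.values():
        has_stop = any(f.n_stops > 0 for f in frags)
        has_fs = any(f.n_frameshifts > 0 for f in frags)
        if has_stop and has_fs:
            counts["both"] += 1
        elif has_stop:
            counts["stop_only"] += 1
        elif has_fs:
            counts["frameshift_only"] += 1
        else:
            counts["none"] += 1
    return counts


def summarize_joint_distribution(profiles) -> np.ndarray:
    """Count matrix indexed by (n_stops, n_frameshifts)."""
    if not profiles:
        return np.zeros((1, 1), dtype=int)
    max_s = max(p.n_stops for p in profiles)
    max_f = max(p.n_frameshifts for p in profiles)
    matrix = np.zeros((max_s + 1, max_f + 1), dtype=int)
    for p in profiles:
        matrix[p.n_stops, p.n_frameshifts] += 1
    return matrix


def profiles_to_tsv(profiles, path) -> None:
    with open(path, "w") as out:
        out.write(
            "trg_id\tgenome_id\tstart\tend\tlocation\tn_stops\tn_frameshifts\tcoverage\n"
        )
        for p in profiles:
            out.write(
                f"{p.trg_id}\t{p.genome_id}\t{p.span[0]}\t{p.span[1]}\t"
                f"{p.location}\t{p.n_stops}\t{p.n_frameshifts}\t{p.coverage:.4f}\n"
            )


def summary_json(profiles, path=None) -> dict:
    summary = {
        "n_fragments": len(profiles),
        "fragment_categories": fragment_categories(profiles),
        "trg_categories": trg_categories(profiles),
        "joint_matrix": summarize_joint_distribution(profiles).tolist(),
    }
    if path is not None:
        with open(path, "w") as out:
            json.dump(summary, out, indent=2)
    return summary
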