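"""Run orchestration, the run manifest, and fixed rounding conventions for
reported percentages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from . import clustering, disruption
from .trg_pipeline import PipelineConfig, run_classification


def percent(numerator: int, denominator: int, decimals: int = 0) -> str:
    """``100 * numerator / denominator`` rounded half-up, with a '%' sign."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    value = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    rounded = value.quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{rounded}%"


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's numbers."""

    config_hash: str
    n_genomes: int
    n_external_genomes: int
    n_proteins: int
    n_external_proteins: int
    n_residues: int
    n_external_residues: int
    seed: int
    ledger: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as out:
            json.dump(self.__dict__, out, indent=2)


def _config_hash(cfg: PipelineConfig) -> str:
    payload = (
        f"{cfg.e_max}|{cfg.coverage_coding}|{cfg.orf_min_codons}|"
        f"{cfg.synteny_gap_cap}|{cfg.high_coverage}|{cfg.seed}|"
        f"{cfg.scheme.gap_open}|{cfg.scheme.gap_extend}|"
        f"{cfg.scheme.frameshift_penalty}|{cfg.scheme.stop_match_score}|"
        f"{cfg.scheme.lambda_}|{cfg.scheme.K}|{cfg.scheme.min_bitscore}"
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    genus_genomes,
    genus_annotations,
    external_genomes,
    external_annotations,
    cfg: PipelineConfig | None = None,
    out_dir=None,
):
    """Full classification run plus family and disruption summaries.

    Returns a dict with candidates, rbh_pairs, ledger, families, profiles
    and the manifest; writes TSV/JSON artifacts under ``out_dir`` if given.
    """
    cfg = cfg or PipelineConfig()
    candidates, rbh_pairs, ledger, ctx = run_classification(
        genus_genomes, genus_annotations, external_genomes,
        external_annotations, cfg,
    )
    kept = [c for c in candidates if c.status in ("trg_noncoding_trace", "trg_no_trace")]
    graph = clustering.build_rbh_graph(kept, rbh_pairs)
    species_of_node = {
        c.protein_id: {ctx.species_of[g] for g in c.protein.source_genomes}
        for c in kept
    }
    families = clustering.single_linkage_families(graph, species_of_node)
    profiles = disruption.profile_disruptions(kept, cfg.high_coverage)
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        n_genomes=len(genus_genomes),
        n_external_genomes=len(external_genomes),
        n_proteins=len(ctx.genus_nr),
        n_external_proteins=len(ctx.external_nr),
        n_residues=ctx.genus_nr.total_residues,
        n_external_residues=ctx.external_nr.total_residues,
        seed=cfg.seed,
        ledger=ledger.as_dict(),
    )
    result = {
        "candidates": candidates,
        "rbh_pairs": rbh_pairs,
        "ledger": ledger,
        "graph": graph,
        "families": families,
        "profiles": profiles,
        "manifest": manifest,
        "ctx": ctx,
    }
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def candidates_to_tsv(candidates, path) -> None:
    with open(path, "w") as out:
        out.write(
            "protein_id\tstatus\tlevel\tn_sources\tn_noncoding_hits\t"
            "n_syntenic_hits\tn_coding_hits\tn_homologs\n"
        )
        for c in sorted(candidates, key=lambda c: c.protein_id):
            n_syn = sum(1 for _a, loc, _g in c.noncoding_hits if loc == "syntenic")
            out.write(
                f"{c.protein_id}\t{c.status}\t{c.level}\t{len(c.protein.sources)}\t"
                f"{len(c.noncoding_hits)}\t{n_syn}\t{len(c.coding_hits)}\t"
                f"{len(c.homologs)}\n"
            )


def write_outputs(result, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    candidates_to_tsv(result["candidates"], out / "candidates.tsv")
    with open(out / "ledger.json", "w") as fh:
        json.dump(result["ledger"].as_dict(), fh, indent=2)
    clustering.families_to_tsv(result["families"], out / "families.tsv")
    clustering.graph_to_edge_tsv(result["graph"], out / "rbh_edges.tsv")
    disruption.profiles_to_tsv(result["profiles"], out / "disruption_profiles.tsv")
    disruption.summary_json(result["profiles"], out / "disruption_summary.json")
    result["manifest"].to_json(out / "manifest.json")


def summary_text(result) -> str:
    """Human-readable stage summary; all percentages via :func:`percent`."""
    ledger = result["ledger"]
    lines = [
        f"input nonredundant proteins: {ledger.n_input}",
        f"putative restricted genes: {ledger.n_putative} "
        f"({percent(ledger.n_putative, max(ledger.n_input, 1))} of input)",
        f"missed annotations: {ledger.n_missed_annotation}",
        f"with noncoding trace: {ledger.n_noncoding_only}",
        f"with no similarity: {ledger.n_no_similarity}",
        f"removed by transitive homology (orthologs): {ledger.n_removed_transitive_orth}",
        f"removed by transitive homology (paralogs): {ledger.n_removed_transitive_para}",
        f"final restricted genes: {ledger.n_final}",
        f"species-specific: {ledger.n_species_specific}",
        f"families: {len(result['families'])}",
        f"high-coverage noncoding fragments: {len(result['profiles'])}",
    ]
    return "\n".join(lines)
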