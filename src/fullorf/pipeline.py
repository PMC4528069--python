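"""End-to-end runner: cluster -> join -> split -> cliff -> orf -> pick -> dedup.

Deterministic for fixed inputs (only the simulator is stochastic, and it
is seeded). Emits the standard report bundle plus a stage ledger with
conserved counts (picks after dedup + removals = picks before).
"""
from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from . import clustering, io, orf as orfmod, picking, redundancy
from .cliff import cliff_score
from .model import ESTSet, PipelineConfig

LEDGER_COLUMNS = ["stage", "metric", "count"]


def run_pipeline(
    config: PipelineConfig,
    est_fasta,
    clone_table,
    out_dir,
    sl_fasta=None,
    protein_hits_path=None,
    genome_fasta=None,
    stage: str = "all",
) -> dict:
    """Run the workflow on files; returns the stage ledger dict."""
    ests = io.read_ests(est_fasta, clone_table)
    sl_reads = io.read_fasta(sl_fasta) if sl_fasta else {}
    protein_hits = (
        io.read_protein_hits(protein_hits_path) if protein_hits_path else []
    )
    genome = io.read_fasta(genome_fasta) if genome_fasta else None
    result = run_pipeline_objects(
        config, ests, sl_reads=sl_reads, protein_hits=protein_hits,
        genome=genome, stage=stage,
    )
    write_outputs(result, out_dir, config)
    return result["ledger"]


STAGES = ("cluster", "split", "cliff", "orf", "pick", "all")


def run_pipeline_objects(
    config: PipelineConfig,
    ests: ESTSet,
    sl_reads: Optional[dict] = None,
    protein_hits=None,
    genome: Optional[dict] = None,
    stage: str = "all",
) -> dict:
    """In-memory pipeline; returns all stage products and the ledger.

    ``stage`` stops the workflow early (one of cluster, split, cliff,
    orf, pick, all) for the per-stage CLI subcommands.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    sl_reads = sl_reads or {}
    protein_hits = list(protein_hits or [])
    ledger: dict[str, int] = {}

    def partial(**extra):
        out = {
            "clusters": [],
            "cliff_results": {},
            "orfs": {},
            "picks": [],
            "removed_picks": [],
            "exon_chains": [],
            "unmapped_clones": [],
            "typeb_pairs": [],
            "ests": ests,
            "ledger": ledger,
        }
        out.update(extra)
        return out

    clusters = clustering.cluster_ests(
        ests, config.identity_threshold, config.min_overlap_bp
    )
    ledger["clusters_initial"] = len(clusters)

    clusters = clustering.join_paired_ends(
        clusters, ests,
        identity_threshold=config.identity_threshold,
        min_overlap=config.min_overlap_bp,
    )
    ledger["clusters_after_join"] = len(clusters)
    if stage == "cluster":
        return partial(clusters=clusters)

    split_out = []
    n_split = 0
    for cluster in clusters:
        decision = clustering.detect_backtoback(cluster, protein_hits)
        if decision is None:
            split_out.append(cluster)
            continue
        up, down = clustering.split_cluster(cluster, decision, ests)
        split_out.extend([up, down])
        n_split += 1
    clusters = split_out
    ledger["clusters_split"] = n_split
    ledger["clusters_final"] = len(clusters)
    if stage == "split":
        return partial(clusters=clusters)

    cliff_results = {c.cluster_id: cliff_score(c, config) for c in clusters}
    ledger["clusters_cliff_pass"] = sum(
        1 for r in cliff_results.values() if r.passes
    )
    if stage == "cliff":
        return partial(clusters=clusters, cliff_results=cliff_results)

    supported = orfmod.match_sl_reads(sl_reads, ests, config.sl_min_match)
    sl_clusters = orfmod.sl_flagged_clusters(clusters, supported)
    ledger["sl_flagged_clusters"] = len(sl_clusters)

    nterm = orfmod.conserved_nterm_predictions(protein_hits)
    orfs = {}
    for cluster in clusters:
        annotation = orfmod.find_orf(
            cluster.consensus, protein_hits, cluster_id=cluster.cluster_id
        )
        if annotation is not None:
            annotation = orfmod.classify_five_prime(
                annotation,
                cluster.consensus,
                cliff_result=cliff_results[cluster.cluster_id],
                sl_flag=cluster.cluster_id in sl_clusters,
                nterm_predictions=nterm.get(cluster.cluster_id, ()),
            )
        annotation = orfmod.classify_three_prime(
            annotation, cluster, protein_hits,
            utr3_fraction=config.utr3_est_fraction, ests=ests,
        )
        orfs[cluster.cluster_id] = annotation
    ledger["clusters_with_orf"] = sum(
        1 for a in orfs.values() if a.orf_end > a.orf_start
    )
    ledger["clusters_5p_complete"] = sum(
        1 for a in orfs.values() if a.five_prime_complete
    )
    ledger["clusters_3p_complete"] = sum(
        1 for a in orfs.values() if a.three_prime_complete
    )
    if stage == "orf":
        return partial(clusters=clusters, cliff_results=cliff_results, orfs=orfs)

    suborfs = {}
    for cluster in clusters:
        annotation = orfs[cluster.cluster_id]
        if annotation.orf_end <= annotation.orf_start:
            continue
        if annotation.five_prime_complete and annotation.three_prime_complete:
            picking.flag_fullorf_clones(cluster, annotation, ests)
        subs = picking.detect_alt_transcripts(
            cluster, config.min_block_bp, ests=ests
        )
        for sub in subs:
            sub_orf = orfmod.find_orf(
                sub.consensus, protein_hits, cluster_id=sub.cluster_id
            )
            if sub_orf is not None:
                suborfs[sub.cluster_id] = sub_orf
    complete = [
        c
        for c in clusters
        if orfs[c.cluster_id].five_prime_complete
        and orfs[c.cluster_id].three_prime_complete
    ]
    picks = picking.pick_clones(complete, ests, orfs, config, suborfs=suborfs)
    ledger["alt_transcript_picks"] = sum(
        1 for p in picks if p.pick_reason.value == "alt_transcript"
    )
    ledger["manual_additions"] = sum(
        1 for p in picks if p.pick_reason.value == "manual"
    )
    ledger["picks_before_dedup"] = len(picks)
    if stage == "pick":
        return partial(
            clusters=clusters, cliff_results=cliff_results, orfs=orfs,
            picks=picks,
        )

    chains: list = []
    unmapped: list = []
    removed: list = []
    typeb_pairs: list = []
    if genome:
        clone_reads = {}
        for p in picks:
            clone = ests.clones.get(p.clone_id)
            if clone is None:
                continue
            reads = []
            if clone.est5_id:
                reads.append(ests[clone.est5_id])
            if clone.est3_id:
                reads.append(ests[clone.est3_id])
            clone_reads[p.clone_id] = reads
        chains, unmapped = redundancy.map_exon_chains(clone_reads, genome)
        picks, removed = redundancy.remove_redundant(
            picks, chains, keep=config.picks_per_cluster,
            end_slop=config.fingerprint_end_slop,
        )
        for pick in removed:
            clone = ests.clones.get(pick.clone_id)
            if clone is not None:
                clone.picked = False
        typeb_pairs = redundancy.detect_typeb_clusters(
            clusters, ests, orfs, config
        )
    ledger["dedup_removals"] = len(removed)
    ledger["unmapped_picked_clones"] = len(unmapped)
    ledger["picks_after_dedup"] = len(picks)
    ledger["typeb_pairs"] = len(typeb_pairs)

    return {
        "clusters": clusters,
        "cliff_results": cliff_results,
        "orfs": orfs,
        "picks": picks,
        "removed_picks": removed,
        "exon_chains": chains,
        "unmapped_clones": unmapped,
        "typeb_pairs": typeb_pairs,
        "ests": ests,
        "ledger": ledger,
    }


def write_outputs(result: dict, out_dir, config: PipelineConfig) -> dict:
    os.makedirs(out_dir, exist_ok=True)
    orf_list = [
        a for a in result["orfs"].values() if a.orf_end > a.orf_start
    ]
    paths = io.write_reports(
        result["clusters"],
        result["cliff_results"].values(),
        orf_list,
        result["ests"].clones.values(),
        out_dir,
    )
    ledger_rows = [
        {"stage": "pipeline", "metric": key, "count": value}
        for key, value in result["ledger"].items()
    ]
    paths["ledger"] = os.path.join(out_dir, "ledger.tsv")
    pd.DataFrame(ledger_rows, columns=LEDGER_COLUMNS).to_csv(
        paths["ledger"], sep="\t", index=False
    )
    pick_rows = [
        {
            "clone_id": p.clone_id,
            "cluster_id": p.cluster_id,
            "transcript_id": p.transcript_id,
            "pick_reason": p.pick_reason.value,
            "rank": p.rank,
        }
        for p in result["picks"]
    ]
    paths["picked_clones"] = os.path.join(out_dir, "picked_clones.tsv")
    pd.DataFrame(
        pick_rows,
        columns=["clone_id", "cluster_id", "transcript_id", "pick_reason", "rank"],
    ).to_csv(paths["picked_clones"], sep="\t", index=False)
    if result["typeb_pairs"]:
        rows = [
            {"small_cluster_id": a, "large_cluster_id": b, "identity": round(i, 4)}
            for a, b, i in result["typeb_pairs"]
        ]
    else:
        rows = []
    paths["typeb_pairs"] = os.path.join(out_dir, "typeb_pairs.tsv")
    pd.DataFrame(
        rows, columns=["small_cluster_id", "large_cluster_id", "identity"]
    ).to_csv(paths["typeb_pairs"], sep="\t", index=False)
    if result["exon_chains"]:
        paths["exon_chains"] = os.path.join(out_dir, "exon_chains.bed")
        io.write_exon_chains(paths["exon_chains"], result["exon_chains"])
    paths["config"] = os.path.join(out_dir, "resolved_config.txt")
    io.save_config(config, paths["config"])
    return paths
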