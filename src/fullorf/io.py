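"""Readers and writers for the pipeline's external formats.

Format conventions, enforced here and only here:

* FASTA — sequences via Bio.SeqIO; headers carry ids only.
* Clone table / protein hits / reports — UTF-8 TSV with a header row.
* BED12 — 0-based half-open, blockStarts relative to chromStart.
* GFF3 — 1-based inclusive coordinates.

Everything downstream of this module uses 0-based half-open coordinates.
"""
from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CliffResult,
    CloneRecord,
    Cluster,
    End,
    ESTRecord,
    ESTSet,
    ExonChain,
    OrfAnnotation,
    PipelineConfig,
    Population,
    ProteinHit,
    Strand,
    VALID_ALPHABET,
)

CLONE_TABLE_COLUMNS = ["est_id", "clone_id", "end", "library_id", "population"]

_END_TOKENS = {
    "5": End.FIVE_PRIME,
    "3": End.THREE_PRIME,
    "five_prime": End.FIVE_PRIME,
    "three_prime": End.THREE_PRIME,
}


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_ests(fasta_path, clone_table_path) -> ESTSet:
    """Load end-reads plus their clone metadata into a validated ESTSet.

    The clone table is authoritative for end/library/population. A FASTA id
    without a table row is a hard error naming the id; ESTs whose sequence
    contains characters outside {A,C,G,T,N} are retained with
    ``passed_qc=False`` rather than dropped.
    """
    seqs = read_fasta(fasta_path)
    try:
        table = pd.read_csv(clone_table_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=CLONE_TABLE_COLUMNS)
    missing_cols = set(CLONE_TABLE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(
            f"clone table {clone_table_path}: missing columns {sorted(missing_cols)}"
        )
    rows = {str(r.est_id): r for r in table.itertuples(index=False)}
    ests = []
    for est_id, seq in seqs.items():
        if est_id not in rows:
            raise ValueError(
                f"FASTA id {est_id!r} has no row in clone table {clone_table_path}"
            )
        row = rows[est_id]
        end_token = str(row.end).strip().lower().rstrip("'")
        if end_token not in _END_TOKENS:
            raise ValueError(f"EST {est_id}: unrecognised end {row.end!r}")
        passed_qc = bool(seq) and set(seq) <= VALID_ALPHABET
        ests.append(
            ESTRecord(
                est_id=est_id,
                clone_id=str(row.clone_id),
                end=_END_TOKENS[end_token],
                library_id=str(row.library_id),
                population=Population(str(row.population).strip().lower()),
                sequence=seq if passed_qc else _sanitise(seq),
                passed_qc=passed_qc,
            )
        )
    clones: dict[str, CloneRecord] = {}
    for est in ests:
        rec = clones.get(est.clone_id)
        if rec is None:
            rec = CloneRecord(
                clone_id=est.clone_id,
                est5_id=est.est_id if est.end is End.FIVE_PRIME else None,
                est3_id=est.est_id if est.end is End.THREE_PRIME else None,
                library_id=est.library_id,
            )
            clones[est.clone_id] = rec
        elif est.end is End.FIVE_PRIME:
            rec.est5_id = est.est_id
        else:
            rec.est3_id = est.est_id
    return ESTSet(ests, clones.values())


def _sanitise(seq: str) -> str:
    return "".join(c if c in VALID_ALPHABET else "N" for c in seq.upper()) or "N"


def read_exon_chains(bed12_path) -> list[ExonChain]:
    """Parse BED12 into ExonChains (0-based half-open genomic intervals)."""
    chains = []
    with open(bed12_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{bed12_path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            chrom, start, _end, name, _score, strand = fields[:6]
            block_count = int(fields[9])
            sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
            starts = [int(v) for v in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(
                    f"{bed12_path}:{lineno}: blockCount={block_count} does not "
                    f"match blockSizes/blockStarts lengths"
                )
            chrom_start = int(start)
            exons = tuple(
                (chrom_start + bs, chrom_start + bs + sz)
                for bs, sz in zip(starts, sizes)
            )
            chains.append(
                ExonChain(
                    clone_id=name,
                    target_id=chrom,
                    strand=Strand(strand),
                    exons=exons,
                )
            )
    return chains


def write_exon_chains(path, chains: Iterable[ExonChain]) -> None:
    """Write ExonChains as BED12."""
    with open(path, "w") as fh:
        for chain in chains:
            start = chain.exons[0][0]
            end = chain.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in chain.exons)
            rel = ",".join(str(s - start) for s, _ in chain.exons)
            fh.write(
                "\t".join(
                    [
                        chain.target_id,
                        str(start),
                        str(end),
                        chain.clone_id,
                        "0",
                        chain.strand.value,
                        str(start),
                        str(end),
                        "0",
                        str(len(chain.exons)),
                        sizes,
                        rel,
                    ]
                )
                + "\n"
            )


def read_protein_hits(path) -> list[ProteinHit]:
    """Read a protein-hit TSV (1-based closed alignment coordinates)."""
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    hits = []
    for row in table.itertuples(index=False):
        hits.append(
            ProteinHit(
                cluster_id=str(row.cluster_id),
                strand=Strand(str(row.strand)),
                query_start=int(row.query_start),
                query_end=int(row.query_end),
                subject_start=int(row.subject_start),
                subject_end=int(row.subject_end),
                species=str(row.species),
                evalue=float(row.evalue),
            )
        )
    return hits


def write_protein_hits(path, hits: Iterable[ProteinHit]) -> None:
    rows = [
        {
            "cluster_id": h.cluster_id,
            "strand": h.strand.value,
            "query_start": h.query_start,
            "query_end": h.query_end,
            "subject_start": h.subject_start,
            "subject_end": h.subject_end,
            "species": h.species,
            "evalue": h.evalue,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "strand",
            "query_start",
            "query_end",
            "subject_start",
            "subject_end",
            "species",
            "evalue",
        ],
    ).to_csv(path, sep="\t", index=False)


CLIFF_COLUMNS = [
    "cluster_id",
    "Z",
    "eligible",
    "x",
    "N100",
    "N1000",
    "Nsteep",
    "m_steep",
    "S_peak",
    "S_steep",
    "score",
    "tss_estimate",
    "passes",
]


def write_reports(
    clusters: Iterable[Cluster],
    cliff_results: Iterable[CliffResult],
    orfs: Iterable[OrfAnnotation],
    clones: Iterable[CloneRecord],
    out_dir,
) -> dict[str, str]:
    """Emit the standard report bundle; returns {report_name: path}."""
    clusters = list(clusters)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    cluster_rows = [
        {
            "cluster_id": c.cluster_id,
            "n_ests": len(c.placements),
            "consensus_length": len(c.consensus),
            "n_five_prime_ends": len(c.five_prime_end_positions),
            "n_subclusters": len(c.subclusters),
        }
        for c in clusters
    ]
    paths["clusters"] = os.path.join(out_dir, "clusters.tsv")
    pd.DataFrame(
        cluster_rows,
        columns=[
            "cluster_id",
            "n_ests",
            "consensus_length",
            "n_five_prime_ends",
            "n_subclusters",
        ],
    ).to_csv(paths["clusters"], sep="\t", index=False)

    paths["membership"] = os.path.join(out_dir, "membership.tsv")
    member_rows = [
        {
            "est_id": p.est_id,
            "cluster_id": c.cluster_id,
            "offset": p.offset,
            "strand": p.strand.value,
            "aligned_length": p.aligned_length,
        }
        for c in clusters
        for p in c.placements
    ]
    pd.DataFrame(
        member_rows,
        columns=["est_id", "cluster_id", "offset", "strand", "aligned_length"],
    ).to_csv(paths["membership"], sep="\t", index=False)

    paths["cliff"] = os.path.join(out_dir, "cliff.tsv")
    cliff_rows = [{k: getattr(r, k) for k in CLIFF_COLUMNS} for r in cliff_results]
    pd.DataFrame(cliff_rows, columns=CLIFF_COLUMNS).to_csv(
        paths["cliff"], sep="\t", index=False
    )

    paths["orfs"] = os.path.join(out_dir, "orfs.gff3")
    with open(paths["orfs"], "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            fh.write(
                "\t".join(
                    [
                        orf.cluster_id,
                        "fullorf",
                        "CDS",
                        str(orf.orf_start + 1),  # GFF3 1-based inclusive
                        str(orf.orf_end),
                        ".",
                        orf.strand.value,
                        "0",
                        ";".join(
                            [
                                f"ID=cds_{orf.cluster_id}",
                                f"five_prime_complete={orf.five_prime_complete}",
                                "five_prime_evidence="
                                + ",".join(
                                    sorted(e.value for e in orf.five_prime_evidence)
                                ),
                                f"three_prime_complete={orf.three_prime_complete}",
                                "three_prime_evidence="
                                + ",".join(
                                    sorted(e.value for e in orf.three_prime_evidence)
                                ),
                            ]
                        ),
                    ]
                )
                + "\n"
            )

    paths["picks"] = os.path.join(out_dir, "picks.tsv")
    pick_rows = [
        {
            "clone_id": c.clone_id,
            "library_id": c.library_id,
            "fullorf_status": c.fullorf_status.value,
            "picked": c.picked,
            "pick_reason": c.pick_reason.value,
        }
        for c in clones
    ]
    pd.DataFrame(
        pick_rows,
        columns=["clone_id", "library_id", "fullorf_status", "picked", "pick_reason"],
    ).to_csv(paths["picks"], sep="\t", index=False)

    paths["consensus"] = os.path.join(out_dir, "consensus.fasta")
    write_fasta(
        paths["consensus"], {c.cluster_id: c.consensus for c in clusters if c.consensus}
    )
    return paths


def load_config(path: Optional[str] = None, **overrides) -> PipelineConfig:
    """Load a key=value config file; keyword arguments override file values."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                raw = raw.strip()
                if key == "manual_clone_ids":
                    values[key] = [v for v in raw.split(",") if v]
                else:
                    values[key] = _coerce(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        for f in config.__dataclass_fields__:
            value = getattr(config, f)
            if isinstance(value, list):
                value = ",".join(str(v) for v in value)
            fh.write(f"{f}={value}\n")


def _coerce(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw
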