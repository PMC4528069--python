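"""ORF identification on cluster consensi and 5'/3' completeness calls.

A consensus is 5'-complete when any of four independent lines of evidence
verifies the initiator ATG: an upstream in-frame stop codon, a passing
cliff score with the TSS estimate at or upstream of the ATG, splice-leader
(SL) trans-splicing evidence on a member read, or an ortholog-implied
start position (P) conserved across species that coincides with the ATG.
All applicable flags are recorded; completeness is their disjunction.

3'-completeness rests on the terminal stop codon, or — for 3'-fragment
clusters — on a well-assembled UTR-like stretch with stop codons in all
three frames downstream of any detected coding sequence.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    Cluster,
    End,
    ESTSet,
    FivePrimeEvidence,
    NTermPrediction,
    OrfAnnotation,
    ProteinHit,
    Strand,
    ThreePrimeEvidence,
    revcomp,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
MIN_ORF_BP = 60
SL_SEARCH_WINDOW = 60
EVALUE_DEFAULT = 0.001
EVALUE_UTR3 = 0.1  # relaxed threshold for short coding stretches at contig edges


def enumerate_orfs(consensus: str, min_len: int = MIN_ORF_BP):
    """All maximal ATG->stop ORFs >= min_len in six frames.

    Returns tuples (start, end, frame, strand, has_stop) with start/end on
    forward consensus coordinates, half-open, stop codon included. ORFs
    running off the 3' edge of their frame are reported with
    has_stop=False (end at the last complete codon).
    """
    length = len(consensus)
    out = []
    for strand in (Strand.PLUS, Strand.MINUS):
        seq = consensus if strand is Strand.PLUS else revcomp(consensus)
        for frame in range(3):
            start: Optional[int] = None
            pos = frame
            while pos + 3 <= len(seq):
                codon = seq[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start is not None and pos + 3 - start >= min_len:
                        out.append(
                            _to_forward(start, pos + 3, frame, strand, length)
                            + (True,)
                        )
                    start = None
                elif codon == "ATG" and start is None:
                    start = pos
                pos += 3
            if start is not None and pos - start >= min_len:
                out.append(
                    _to_forward(start, pos, frame, strand, length) + (False,)
                )
    return out


def _to_forward(s: int, e: int, frame: int, strand: Strand, length: int):
    if strand is Strand.PLUS:
        return (s, e, frame, strand)
    return (length - e, length - s, frame, strand)


def find_orf(
    consensus: str,
    protein_hits: Optional[Iterable[ProteinHit]] = None,
    cluster_id: str = "",
    min_len: int = MIN_ORF_BP,
) -> Optional[OrfAnnotation]:
    """Select the ORF for a consensus; None marks a non-coding candidate.

    With protein hits the ORF best overlapping the lowest-e-value hit wins;
    without, the longest ORF wins. Closed (stop-terminated) ORFs beat open
    ones at equal overlap/length.
    """
    if not consensus:
        return None
    orfs = enumerate_orfs(consensus, min_len=min_len)
    if not orfs:
        return None
    hits = [
        h
        for h in (protein_hits or [])
        if (not cluster_id or h.cluster_id == cluster_id)
        and h.evalue <= EVALUE_DEFAULT
    ]
    chosen = None
    if hits:
        best_hit = min(hits, key=lambda h: (h.evalue, h.query_start))
        span = (best_hit.query_start - 1, best_hit.query_end)

        def overlap(o):
            return max(0, min(o[1], span[1]) - max(o[0], span[0]))

        candidates = [o for o in orfs if o[3] is best_hit.strand and overlap(o) > 0]
        if candidates:
            chosen = max(candidates, key=lambda o: (overlap(o), o[4], o[1] - o[0]))
    if chosen is None:
        chosen = max(orfs, key=lambda o: (o[1] - o[0], o[4], -o[0]))
    start, end, frame, strand, _has_stop = chosen
    return OrfAnnotation(
        cluster_id=cluster_id,
        orf_start=start,
        orf_end=end,
        frame=frame,
        strand=strand,
    )


def orf_has_stop(orf: OrfAnnotation, consensus: str) -> bool:
    """True if the annotated ORF terminates in a stop codon on the consensus."""
    if orf.strand is Strand.PLUS:
        codon = consensus[orf.orf_end - 3 : orf.orf_end]
    else:
        codon = revcomp(consensus[orf.orf_start : orf.orf_start + 3])
    return codon in STOP_CODONS


def has_upstream_inframe_stop(orf: OrfAnnotation, consensus: str) -> bool:
    """In-frame stop codon in the UTR upstream of the initiator ATG."""
    if orf.strand is Strand.PLUS:
        pos = orf.orf_start - 3
        while pos >= 0:
            if consensus[pos : pos + 3] in STOP_CODONS:
                return True
            pos -= 3
    else:
        pos = orf.orf_end
        while pos + 3 <= len(consensus):
            if revcomp(consensus[pos : pos + 3]) in STOP_CODONS:
                return True
            pos += 3
    return False


def classify_five_prime(
    orf: OrfAnnotation,
    consensus: str,
    cliff_result=None,
    sl_flag: bool = False,
    nterm_predictions: Sequence[NTermPrediction] = (),
) -> OrfAnnotation:
    """Record all applicable 5'-completeness evidence on the annotation."""
    evidence = orf.five_prime_evidence
    if has_upstream_inframe_stop(orf, consensus):
        evidence.add(FivePrimeEvidence.UPSTREAM_STOP)
    if (
        cliff_result is not None
        and cliff_result.passes
        and cliff_result.tss_estimate is not None
        and orf.strand is Strand.PLUS
        and cliff_result.tss_estimate <= orf.orf_start
    ):
        evidence.add(FivePrimeEvidence.CLIFF)
    if sl_flag:
        evidence.add(FivePrimeEvidence.SL)
    for pred in nterm_predictions:
        if pred.conserved and pred.P == orf.orf_start + 1:
            evidence.add(FivePrimeEvidence.ORTHOLOG_P)
            break
    orf.five_prime_complete = bool(evidence)
    return orf


def match_sl_reads(
    sl_reads: dict[str, str], ests: ESTSet, min_match: int = 20
) -> set[str]:
    """EST ids whose 5' terminus is confirmed by an SL trans-splice read.

    ``sl_reads`` maps read id -> post-SL sequence (the SL tag already
    removed). An EST is supported when the post-SL prefix of length
    ``min_match`` occurs exactly within the EST's first ~60 bases (the
    EST itself may still carry the SL tag ahead of the match).
    """
    supported = set()
    probes = [
        seq[:min_match] for seq in sl_reads.values() if len(seq) >= min_match
    ]
    for est in ests:
        if est.end is not End.FIVE_PRIME:
            continue
        head = est.sequence[: SL_SEARCH_WINDOW + min_match]
        if any(probe in head for probe in probes):
            supported.add(est.est_id)
    return supported


def sl_flagged_clusters(
    clusters: Iterable[Cluster], supported_est_ids: set[str]
) -> set[str]:
    """Cluster ids containing at least one SL-supported EST."""
    return {
        c.cluster_id
        for c in clusters
        if any(p.est_id in supported_est_ids for p in c.placements)
    }


def _coverage_runs(coverage: np.ndarray, start: int, min_cov: int):
    """Contiguous [s, e) runs with coverage >= min_cov, from ``start`` on."""
    runs = []
    s = None
    for i in range(start, len(coverage)):
        if coverage[i] >= min_cov:
            if s is None:
                s = i
        elif s is not None:
            runs.append((s, i))
            s = None
    if s is not None:
        runs.append((s, len(coverage)))
    return runs


def _stops_in_all_frames(segment: str) -> bool:
    frames_hit = set()
    for pos in range(len(segment) - 2):
        if segment[pos : pos + 3] in STOP_CODONS:
            frames_hit.add(pos % 3)
            if len(frames_hit) == 3:
                return True
    return False


def classify_three_prime(
    orf: Optional[OrfAnnotation],
    cluster: Cluster,
    protein_hits: Optional[Iterable[ProteinHit]] = None,
    utr3_fraction: float = 0.66,
    ests: Optional[ESTSet] = None,
    min_window: int = 100,
    min_coverage: int = 2,
) -> OrfAnnotation:
    """3'-end tests on one cluster; returns the (possibly new) annotation.

    STOP_CODON: the ORF ends in a stop on the consensus.
    UTR3_ALLFRAME_STOPS: downstream of the last coding base there is a
    well-assembled (coverage >= min_coverage) window >= min_window bp with
    stop codons in all three frames and no protein hit — a definitive 3'
    limit for any ORF.
    UTR3_EST_FRACTION: no coding detected and more than ``utr3_fraction``
    of placements come from 3' reads — a 3'-UTR fragment cluster.
    """
    hits = [
        h
        for h in (protein_hits or [])
        if h.cluster_id == cluster.cluster_id and h.evalue <= EVALUE_UTR3
    ]
    annotation = orf or OrfAnnotation(
        cluster_id=cluster.cluster_id,
        orf_start=0,
        orf_end=0,
        frame=0,
        strand=Strand.PLUS,
    )
    if orf is not None and orf_has_stop(orf, cluster.consensus):
        annotation.three_prime_evidence.add(ThreePrimeEvidence.STOP_CODON)
        annotation.three_prime_complete = True
        return annotation

    last_coding = 0
    if orf is not None:
        last_coding = orf.orf_end
    for h in hits:
        last_coding = max(last_coding, h.query_end)
    if cluster.consensus and cluster.placements:
        coverage = cluster.coverage()
        for s, e in _coverage_runs(coverage, last_coding, min_coverage):
            if e - s < min_window:
                continue
            if any(h.query_start - 1 < e and h.query_end > s for h in hits):
                continue
            if _stops_in_all_frames(cluster.consensus[s:e]):
                annotation.three_prime_evidence.add(
                    ThreePrimeEvidence.UTR3_ALLFRAME_STOPS
                )
                annotation.three_prime_complete = True
                return annotation

    if orf is None and ests is not None and cluster.placements:
        n3 = sum(
            1
            for p in cluster.placements
            if ests[p.est_id].end is End.THREE_PRIME
        )
        if n3 / len(cluster.placements) > utr3_fraction:
            annotation.three_prime_evidence.add(
                ThreePrimeEvidence.UTR3_EST_FRACTION
            )
    return annotation


def predict_start_from_ortholog(hit: ProteinHit) -> NTermPrediction:
    """Ortholog-implied CDS start on the transcript: P = qs - 3(ss - 1).

    Assumes the unaligned N-terminal part of the subject protein is
    length-conserved; P <= 0 flags a start upstream of the contig.
    """
    P = hit.query_start - 3 * (hit.subject_start - 1)
    return NTermPrediction(
        cluster_id=hit.cluster_id, species=hit.species, P=P
    )


def conserved_nterm_predictions(
    hits: Iterable[ProteinHit], min_species: int = 2
) -> dict[str, list[NTermPrediction]]:
    """Per-cluster N-terminus predictions, flagged conserved when the best
    hit of every compared species implies the same P (>= min_species)."""
    per_cluster: dict[str, dict[str, ProteinHit]] = {}
    for h in hits:
        if h.strand is not Strand.PLUS:
            continue
        best = per_cluster.setdefault(h.cluster_id, {})
        if h.species not in best or h.evalue < best[h.species].evalue:
            best[h.species] = h
    out: dict[str, list[NTermPrediction]] = {}
    for cluster_id, by_species in per_cluster.items():
        preds = [predict_start_from_ortholog(h) for h in by_species.values()]
        values = {p.P for p in preds}
        conserved = len(by_species) >= min_species and len(values) == 1
        for p in preds:
            p.conserved = conserved
        out[cluster_id] = preds
    return out
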