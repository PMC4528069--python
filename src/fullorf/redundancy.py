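"""Redundancy collapse and paralog/allele disambiguation.

Picked clones are mapped to the genome with a naive spliced aligner
(exact 31-mer anchor seeding, colinear chaining, mismatch-tolerant
boundary refinement); clones sharing the same exon fingerprint
(target, strand, exact exon interval tuple) are redundant — divergent
type A/B alleles of one locus collapse onto one fingerprint, while true
paralogs map to distinct loci and survive. Putative type-B clusters are
additionally reported by the identity-band test: a small, single-
population cluster matching a larger mixed cluster at 85-95% identity
over at least part of both ORFs.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional

from .align import infix_identity
from .model import (
    Cluster,
    End,
    ESTRecord,
    ESTSet,
    ExonChain,
    OrfAnnotation,
    PipelineConfig,
    Strand,
    revcomp,
)
from .picking import Pick

ANCHOR_K = 31
MIN_INTRON_BP = 40


def _genome_index(genome: dict[str, str], k: int = ANCHOR_K):
    index: dict[str, list] = defaultdict(list)
    for target_id, seq in genome.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                index[kmer].append((target_id, i))
    return index


def _anchor_segments(read: str, index, k: int = ANCHOR_K):
    """Maximal same-diagonal anchor runs per (target, strand).

    Returns {(target, strand): [(read_start, read_end, g_start, g_end)]}.
    """
    segments: dict[tuple, list] = defaultdict(list)
    for strand, oriented in ((Strand.PLUS, read), (Strand.MINUS, revcomp(read))):
        hits: dict[tuple, list[int]] = defaultdict(list)  # (target, diag) -> read positions
        for i in range(len(oriented) - k + 1):
            for target_id, g in index.get(oriented[i : i + k], ()):
                hits[(target_id, g - i)].append(i)
        for (target_id, diag), read_positions in hits.items():
            read_positions.sort()
            run_start = prev = read_positions[0]
            for i in read_positions[1:]:
                if i > prev + k:  # gap breaks the run
                    segments[(target_id, strand)].append(
                        (run_start, prev + k, diag + run_start, diag + prev + k)
                    )
                    run_start = i
                prev = i
            segments[(target_id, strand)].append(
                (run_start, prev + k, diag + run_start, diag + prev + k)
            )
    return segments


def _matched_extension(limit: int, matches, max_mismatch_run: int = 3):
    """Greedy base-wise extension length under a mismatch-run stop rule.

    Returns (extension, exhausted): extension is rolled back to the last
    matching base when the stop rule fires; exhausted=True means the full
    ``limit`` was consumed (a coverage limit, not an intron crossing).
    """
    mismatch_run = 0
    last_match = 0
    for j in range(1, limit + 1):
        if matches(j):
            mismatch_run = 0
            last_match = j
        else:
            mismatch_run += 1
            if mismatch_run >= max_mismatch_run:
                return last_match, False
    return limit, True


def _snap_motif(genome_seq: str, boundary: int, acceptor: bool,
                radius: int = 3) -> int:
    """Offset snapping a boundary to an adjacent splice motif, or 0.

    For an exon start we look for an AG acceptor immediately upstream;
    for an exon end, a GT donor immediately downstream.
    """
    for delta in sorted(range(-radius, radius + 1), key=abs):
        g = boundary + delta
        if acceptor:
            if 2 <= g <= len(genome_seq) and genome_seq[g - 2 : g] == "AG":
                return delta
        else:
            if 0 <= g <= len(genome_seq) - 2 and genome_seq[g : g + 2] == "GT":
                return delta
    return 0


def _refine_chain(read: str, segments: list, genome_seq: str,
                  min_intron: int = MIN_INTRON_BP):
    """Extend/merge colinear anchor segments into full exon intervals.

    Unanchored read bases between, before and after segments are assigned
    by mismatch-counting (substitution-only extension), so that diverged
    reads with sparse anchors still recover exact exon boundaries.
    """
    segs = sorted(segments)
    # keep a colinear subset (greedy by read order); small read overlaps
    # between runs come from chance matches across a junction and are
    # trimmed rather than dropping the shorter run
    chain = []
    for seg in segs:
        if not chain:
            chain.append(list(seg))
            continue
        prev = chain[-1]
        overlap = prev[1] - seg[0]
        if overlap <= 0 and seg[2] >= prev[3]:
            chain.append(list(seg))
        elif 0 < overlap < seg[1] - seg[0] and seg[2] + overlap >= prev[3]:
            trimmed = [seg[0] + overlap, seg[1], seg[2] + overlap, seg[3]]
            if trimmed[1] > trimmed[0]:
                chain.append(trimmed)
        elif seg[1] - seg[0] > prev[1] - prev[0]:
            chain[-1] = list(seg)
    # merge where the genomic gap is sub-intron-sized
    merged = [chain[0]]
    for seg in chain[1:]:
        prev = merged[-1]
        g_gap = seg[2] - prev[3]
        r_gap = seg[0] - prev[1]
        if g_gap - r_gap < min_intron:
            prev[1], prev[3] = seg[1], seg[3]
        else:
            merged.append(seg)
    # assign every read base between adjacent exons to one side of a
    # single junction cut; the cut may back into the anchored runs by a
    # few bases because chance matches across a junction can extend an
    # anchor past the true boundary. A canonical GT..AG intron at the
    # implied junction earns a bonus so boundaries snap consistently even
    # under mismatches near the junction.
    slack = 5
    for a, b in zip(merged[:-1], merged[1:]):
        lo = max(a[0] + 1, a[1] - slack)
        hi = min(b[1] - 1, b[0] + slack)
        if lo > hi:
            continue
        best_cut, best_score = None, -1.0
        for cut in range(lo, hi + 1):
            score = 0.0
            for j in range(lo, cut):  # left side follows exon a's diagonal
                score += read[j] == genome_seq[a[3] + (j - a[1])]
            for j in range(cut, hi):  # right side follows exon b's diagonal
                score += read[j] == genome_seq[b[2] + (j - b[0])]
            g_donor = a[3] + (cut - a[1])
            g_acceptor = b[2] + (cut - b[0])
            score += 2.0 * (genome_seq[g_donor : g_donor + 2] == "GT")
            score += 2.0 * (genome_seq[g_acceptor - 2 : g_acceptor] == "AG")
            if score > best_score:
                best_score, best_cut = score, cut
        a[3] += best_cut - a[1]
        a[1] = best_cut
        b[2] += best_cut - b[0]
        b[0] = best_cut
    # weakly anchored terminal segments must sit behind a canonical
    # splice junction; otherwise they are chance hits (e.g. on a recent
    # paralog's locus) and are dropped
    min_terminal = 64
    while len(merged) > 1 and merged[0][1] - merged[0][0] < min_terminal:
        if _canonical_junction(genome_seq, merged[0][3], merged[1][2]):
            break
        merged.pop(0)
    while len(merged) > 1 and merged[-1][1] - merged[-1][0] < min_terminal:
        if _canonical_junction(genome_seq, merged[-2][3], merged[-1][2]):
            break
        merged.pop()
    # extend outer ends, match-aware: a coverage limit (read exhausted)
    # extends fully, but sustained mismatch means we ran into an intron —
    # roll back and snap to the nearest splice motif if one is adjacent
    first, last = merged[0], merged[-1]
    ext, exhausted = _matched_extension(
        min(first[0], first[2]),
        lambda j: read[first[0] - j] == genome_seq[first[2] - j],
    )
    first[0] -= ext
    first[2] -= ext
    if not exhausted:
        delta = _snap_motif(genome_seq, first[2], acceptor=True)
        first[0] += delta
        first[2] += delta
    ext, exhausted = _matched_extension(
        min(len(read) - last[1], len(genome_seq) - last[3]),
        lambda j: read[last[1] + j - 1] == genome_seq[last[3] + j - 1],
    )
    last[1] += ext
    last[3] += ext
    if not exhausted:
        delta = _snap_motif(genome_seq, last[3], acceptor=False)
        last[1] += delta
        last[3] += delta
    return [(seg[2], seg[3]) for seg in merged]


def _canonical_junction(genome_seq: str, donor_pos: int, acceptor_pos: int) -> bool:
    return (
        genome_seq[donor_pos : donor_pos + 2] == "GT"
        and genome_seq[acceptor_pos - 2 : acceptor_pos] == "AG"
    )


def map_read(read: str, genome: dict[str, str], index=None,
             k: int = ANCHOR_K) -> Optional[ExonChain]:
    """Spliced mapping of one read; None when no anchor of length k exists."""
    if index is None:
        index = _genome_index(genome, k)
    segments = _anchor_segments(read, index, k)
    if not segments:
        return None
    (target_id, strand), segs = max(
        segments.items(),
        key=lambda kv: sum(s[1] - s[0] for s in kv[1]),
    )
    oriented = read if strand is Strand.PLUS else revcomp(read)
    exons = _refine_chain(oriented, segs, genome[target_id])
    return ExonChain(
        clone_id="", target_id=target_id, strand=strand, exons=tuple(exons)
    )


def map_exon_chains(
    clone_ests: dict[str, list[ESTRecord]],
    genome: dict[str, str],
    k: int = ANCHOR_K,
) -> tuple[list[ExonChain], list[str]]:
    """Map each clone's reads to the genome; returns (chains, unmapped ids).

    A clone's chain is the union of its reads' exon intervals when they
    are colinear on one target/strand; otherwise the better-anchored
    read's chain is used. Clones with no anchored read are reported as
    unmapped and bypass redundancy grouping.
    """
    index = _genome_index(genome, k)
    chains: list[ExonChain] = []
    unmapped: list[str] = []
    for clone_id, reads in clone_ests.items():
        read_chains = []  # (chain, implied gene strand)
        for est in reads:
            chain = map_read(est.sequence, genome, index=index, k=k)
            if chain is None:
                continue
            # a sense 5' read maps on the gene strand; a 3' read is the
            # reverse complement of the insert and maps antisense
            gene_strand = (
                chain.strand
                if est.end is End.FIVE_PRIME
                else chain.strand.flipped()
            )
            read_chains.append((chain, gene_strand))
        if not read_chains:
            unmapped.append(clone_id)
            continue
        groups: dict[tuple, list] = defaultdict(list)
        for ch, gene_strand in read_chains:
            groups[(ch.target_id, gene_strand)].append(ch)
        (target_id, strand), members = max(
            groups.items(),
            key=lambda kv: sum(e - s for ch in kv[1] for s, e in ch.exons),
        )
        intervals = sorted(
            iv for ch in members for iv in ch.exons
        )
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s <= merged[-1][1] + MIN_INTRON_BP - 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        chains.append(
            ExonChain(
                clone_id=clone_id,
                target_id=target_id,
                strand=strand,
                exons=tuple(tuple(iv) for iv in merged),
            )
        )
    return chains, unmapped


def _slop_fingerprint(chain: ExonChain, slop: int):
    """Fingerprint with terminal exon outer edges quantised by slop."""
    exons = [list(iv) for iv in chain.exons]
    if slop > 0:
        exons[0][0] = exons[0][0] // slop
        exons[-1][1] = exons[-1][1] // slop
    return (chain.target_id, chain.strand, tuple(tuple(iv) for iv in exons))


def remove_redundant(
    picks: list[Pick],
    exon_chains: Iterable[ExonChain],
    keep: int = 2,
    end_slop: int = 0,
) -> tuple[list[Pick], list[Pick]]:
    """Collapse picks sharing an exon fingerprint to at most ``keep``.

    Returns (retained, removed). Grouping uses exact interval equality
    (optionally with quantised terminal outer edges); picks without a
    chain bypass grouping and are always retained. Within a group the
    pick order (rank within transcript, then clone id) decides survival,
    so the highest-ranked pick of a group is never removed.
    """
    chain_by_clone = {c.clone_id: c for c in exon_chains}
    groups: dict[tuple, list[Pick]] = defaultdict(list)
    retained: list[Pick] = []
    removed: list[Pick] = []
    for pick in picks:
        chain = chain_by_clone.get(pick.clone_id)
        if chain is None:
            retained.append(pick)
            continue
        groups[_slop_fingerprint(chain, end_slop)].append(pick)
    for fingerprint in sorted(groups, key=repr):
        members = sorted(groups[fingerprint], key=lambda p: (p.rank, p.clone_id))
        retained.extend(members[:keep])
        removed.extend(members[keep:])
    return retained, removed


def detect_typeb_clusters(
    clusters: list[Cluster],
    ests: ESTSet,
    orfs: dict[str, OrfAnnotation],
    config: Optional[PipelineConfig] = None,
) -> list[tuple[str, str, float]]:
    """Report putative type-B (divergent allele) cluster pairs.

    A pair (small, large) qualifies when the smaller cluster has at least
    ``typeb_min_ests`` ESTs of which >= ``typeb_purity`` come from one
    population, the consensus-vs-consensus identity lies in the
    [typeb_identity_low, typeb_identity_high] band, and the alignment
    overlaps both ORFs. Pairs are annotated, never auto-merged.
    """
    config = config or PipelineConfig()
    results = []
    for small in clusters:
        if len(small.placements) < config.typeb_min_ests:
            continue
        pops = [ests[p.est_id].population for p in small.placements]
        top_fraction = max(pops.count(p) for p in set(pops)) / len(pops)
        if top_fraction < config.typeb_purity:
            continue
        orf_small = orfs.get(small.cluster_id)
        if orf_small is None:
            continue
        for large in clusters:
            if large is small or len(large.placements) <= len(small.placements):
                continue
            orf_large = orfs.get(large.cluster_id)
            if orf_large is None or not large.consensus or not small.consensus:
                continue
            identity, (a_start, a_end) = infix_identity(
                small.consensus, large.consensus
            )
            if not (
                config.typeb_identity_low <= identity <= config.typeb_identity_high
            ):
                continue
            if a_end <= orf_large.orf_start or a_start >= orf_large.orf_end:
                continue  # alignment misses the large cluster's ORF
            results.append((small.cluster_id, large.cluster_id, identity))
    return results
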