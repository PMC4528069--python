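"""EST clustering, paired-end joining, consensus building and the
splitting of erroneously co-clustered back-to-back gene pairs.

Assembly is greedy and consensus-anchored: each read joins the first
cluster whose working consensus it matches at or above the identity
threshold over a minimum overlap, otherwise it founds a new cluster.
The stringency default (0.95) is deliberately permissive so that the
high within-type polymorphism of *Ciona*-like data co-assembles, while
recent paralogs and the deeply diverged type-B haplotype do not.
"""
from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import networkx as nx

from .align import Overlap, find_overlap, kmer_index, parse_cigar
from .model import (
    Cluster,
    End,
    ESTSet,
    Placement,
    ProteinHit,
    SplitDecision,
    Strand,
    revcomp,
)

GAP_SENTINEL_BP = 100
_BASE_ORDER = "ACGT"


def _shift_cluster(cluster: Cluster, delta: int) -> None:
    if delta == 0:
        return
    for p in cluster.placements:
        p.offset += delta
    for est_id, blocks in cluster.insertions.items():
        cluster.insertions[est_id] = [(pos + delta, n) for pos, n in blocks]


def _place(
    cluster: Cluster, est_id: str, seq: str, strand: Strand, ov: Overlap
) -> None:
    """Record a placement given an overlap of ``seq`` onto the consensus.

    Read bases outside the aligned core (seed-less flanks and overhangs)
    are projected ungapped; the consensus is extended where the read
    overhangs either end.
    """
    # leading/trailing insertion runs are true overhangs (the consensus
    # simply ends there); fold them into the flanks so they extend it
    ops = parse_cigar(ov.cigar)
    lead = trail = 0
    if len(ops) > 1 and ops[0][1] == "I":
        lead = ops[0][0]
        ops = ops[1:]
    if len(ops) > 1 and ops[-1][1] == "I":
        trail = ops[-1][0]
        ops = ops[:-1]
    middle = _project_ops(ops, seq, ov.q_start + lead)
    left_flank = seq[: ov.q_start + lead]   # sits left of t_start
    right_flank = seq[ov.q_end - trail :]   # sits at [t_end, ...)
    start = ov.t_start - len(left_flank)
    ext_left = max(0, -start)
    if ext_left:
        cluster.consensus = seq[:ext_left] + cluster.consensus
        _shift_cluster(cluster, ext_left)
        start += ext_left
    end = ov.t_end + ext_left + len(right_flank)
    ext_right = end - len(cluster.consensus)
    if ext_right > 0:
        cluster.consensus = cluster.consensus + seq[len(seq) - ext_right :]
    aligned = left_flank + middle + right_flank
    cluster.placements.append(
        Placement(est_id=est_id, offset=start, strand=strand,
                  aligned_length=len(aligned))
    )
    cluster.aligned[est_id] = aligned
    # Record read-only (insertion) blocks: the edit path scatters a long
    # insertion into fragments separated by chance matches, so I runs are
    # coalesced across short non-I stretches before thresholding.
    insertions = []
    tpos = ov.t_start + ext_left
    run_start = None
    run_bases = 0
    gap_cols = 0
    for n, op in ops:
        if op == "I":
            if run_bases == 0:
                run_start = tpos
            run_bases += n
            gap_cols = 0
        else:
            if run_bases:
                gap_cols += n
                if gap_cols > 6:
                    if run_bases >= 10:
                        insertions.append((run_start, run_bases))
                    run_bases = 0
            tpos += n
    if run_bases >= 10:
        insertions.append((run_start, run_bases))
    if insertions:
        cluster.insertions[est_id] = insertions


def _project_ops(ops, query: str, q_from: int) -> str:
    """Project query bases onto target columns for a cigar op list."""
    out = []
    qi = q_from
    for n, op in ops:
        if op in "=X":
            out.append(query[qi : qi + n])
            qi += n
        elif op == "I":
            qi += n
        else:
            out.append("-" * n)
    return "".join(out)


def _found(cluster_id: str, est_id: str, seq: str) -> Cluster:
    cluster = Cluster(cluster_id=cluster_id, consensus=seq)
    cluster.placements.append(
        Placement(est_id=est_id, offset=0, strand=Strand.PLUS,
                  aligned_length=len(seq))
    )
    cluster.aligned[est_id] = seq
    return cluster


def cluster_ests(
    ests: ESTSet,
    identity_threshold: float = 0.95,
    min_overlap: int = 40,
) -> list[Cluster]:
    """Greedy incremental clustering of QC-passing ESTs.

    3' reads are reverse-complemented before comparison so that clusters
    are built in mRNA sense; each read is additionally tried in the
    opposite orientation so that antisense co-assembly (back-to-back gene
    pairs sharing 3' UTR sequence) is represented with MINUS placements
    rather than scattered into separate clusters.
    """
    clusters: list[Cluster] = []
    for est in ests.qc_passing():
        seq = est.sequence if est.end is End.FIVE_PRIME else revcomp(est.sequence)
        placed = False
        for cluster in clusters:
            index = kmer_index(cluster.consensus, 14)
            best: Optional[tuple[Overlap, str, Strand]] = None
            for strand, oriented in (
                (Strand.PLUS, seq),
                (Strand.MINUS, revcomp(seq)),
            ):
                ov = find_overlap(
                    oriented, cluster.consensus, min_overlap=min_overlap,
                    target_index=index,
                )
                if ov is None or ov.identity < identity_threshold:
                    continue
                if best is None or ov.identity > best[0].identity:
                    best = (ov, oriented, strand)
            if best is not None:
                _place(cluster, est.est_id, best[1], best[2], best[0])
                placed = True
                break
        if not placed:
            clusters.append(_found(f"cl{len(clusters):05d}", est.est_id, seq))
    for cluster in clusters:
        cluster.consensus = build_consensus(cluster)
        cluster.refresh_five_prime_ends(ests)
    return clusters


def build_consensus(cluster: Cluster) -> str:
    """Per-column majority vote over placed bases.

    Ties break alphabetically; columns covered only by alignment gaps or
    by nothing at all emit N. N votes never outvote a real base.
    """
    if not cluster.placements:
        raise ValueError(f"cluster {cluster.cluster_id}: no placements")
    length = max(len(cluster.consensus), max(p.end for p in cluster.placements))
    counts = np.zeros((5, length), dtype=np.int32)  # A C G T N
    idx = {b: i for i, b in enumerate(_BASE_ORDER + "N")}
    for p in cluster.placements:
        aligned = cluster.aligned.get(p.est_id)
        if aligned is None:
            continue
        for j, base in enumerate(aligned):
            if base in idx:
                counts[idx[base], p.offset + j] += 1
    out = []
    real = counts[:4]
    for col in range(length):
        col_counts = real[:, col]
        top = col_counts.max()
        if top == 0:
            out.append("N")
        else:
            out.append(_BASE_ORDER[int(np.argmax(col_counts))])
    return "".join(out)


def join_paired_ends(
    clusters: list[Cluster],
    ests: ESTSet,
    min_shared_clones: int = 2,
    identity_threshold: float = 0.95,
    min_overlap: int = 40,
) -> list[Cluster]:
    """Merge clusters linked by >= min_shared_clones clones' opposite ends.

    The merge graph is resolved by connected components. Components are
    merged pairwise: consensi that overlap are co-assembled on a shared
    axis; otherwise the downstream cluster is appended after a run of N
    (a gap sentinel), the 5'-read-bearing cluster first.
    """
    by_est = {
        p.est_id: c.cluster_id for c in clusters for p in c.placements
    }
    by_id = {c.cluster_id: c for c in clusters}
    shared: dict[tuple[str, str], int] = {}
    for clone in ests.clones.values():
        if clone.est5_id is None or clone.est3_id is None:
            continue
        c5 = by_est.get(clone.est5_id)
        c3 = by_est.get(clone.est3_id)
        if c5 is None or c3 is None or c5 == c3:
            continue
        key = tuple(sorted((c5, c3)))
        shared[key] = shared.get(key, 0) + 1
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    graph.add_edges_from(k for k, n in shared.items() if n >= min_shared_clones)
    merged: list[Cluster] = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        if len(members) == 1:
            merged.append(by_id[members[0]])
            continue
        # 5'-heavy clusters first so the joined axis runs 5'->3'
        def five_fraction(cid: str) -> float:
            c = by_id[cid]
            n5 = sum(
                1 for p in c.placements
                if ests[p.est_id].end is End.FIVE_PRIME
            )
            return n5 / max(1, len(c.placements))

        members.sort(key=lambda cid: (-five_fraction(cid), cid))
        base = by_id[members[0]]
        for cid in members[1:]:
            base = _merge_pair(base, by_id[cid], identity_threshold, min_overlap)
        base.consensus = build_consensus(base)
        base.refresh_five_prime_ends(ests)
        merged.append(base)
    return merged


def _merge_pair(
    a: Cluster, b: Cluster, identity_threshold: float, min_overlap: int
) -> Cluster:
    ov = find_overlap(b.consensus, a.consensus, min_overlap=min_overlap)
    out = Cluster(cluster_id=a.cluster_id, consensus=a.consensus)
    out.placements = list(a.placements)
    out.aligned = dict(a.aligned)
    out.insertions = dict(a.insertions)
    if ov is not None and ov.identity >= identity_threshold:
        delta = ov.offset
        if delta < 0:
            out.consensus = b.consensus[:-delta] + out.consensus
            _shift_cluster(out, -delta)
            delta = 0
        tail = delta + len(b.consensus) - len(out.consensus)
        if tail > 0:
            out.consensus = out.consensus + b.consensus[len(b.consensus) - tail :]
    else:
        delta = len(out.consensus) + GAP_SENTINEL_BP
        out.consensus = out.consensus + "N" * GAP_SENTINEL_BP + b.consensus
    for p in b.placements:
        out.placements.append(
            Placement(est_id=p.est_id, offset=p.offset + delta,
                      strand=p.strand, aligned_length=p.aligned_length)
        )
        out.aligned[p.est_id] = b.aligned[p.est_id]
        if p.est_id in b.insertions:
            out.insertions[p.est_id] = [
                (pos + delta, n) for pos, n in b.insertions[p.est_id]
            ]
    return out


def _sixframe_orf_spans(consensus: str, min_orf_bp: int):
    """Spans of ATG->stop ORFs >= min_orf_bp in all six frames.

    Returns (start, end, strand) with start/end on forward consensus
    coordinates, half-open.
    """
    from .orf import enumerate_orfs

    return [
        (o[0], o[1], o[3])
        for o in enumerate_orfs(consensus, min_len=min_orf_bp)
    ]


def _orientation_profile(cluster: Cluster) -> np.ndarray:
    """Coverage-weighted mean placement orientation per consensus column."""
    length = len(cluster.consensus)
    signed = np.zeros(length)
    cov = np.zeros(length)
    for p in cluster.placements:
        sign = 1.0 if p.strand is Strand.PLUS else -1.0
        end = min(p.end, length)
        signed[p.offset : end] += sign
        cov[p.offset : end] += 1.0
    with np.errstate(invalid="ignore"):
        profile = np.where(cov > 0, signed / np.maximum(cov, 1), 0.0)
    return profile


def detect_backtoback(
    cluster: Cluster,
    protein_hits: Optional[Iterable[ProteinHit]] = None,
    min_orf_bp: int = 300,
) -> Optional[SplitDecision]:
    """Detect an opposite-strand back-to-back gene pair within one cluster.

    Requires (a) two non-overlapping ORF spans on opposite strands, the
    plus-strand one upstream, and (b) the mean EST orientation to be
    positive over the upstream span and negative over the downstream one.
    The breakpoint is placed where the running mean orientation crosses
    zero between the spans.
    """
    if not cluster.consensus or not cluster.placements:
        return None
    spans: list[tuple[int, int, Strand]] = []
    hits = [h for h in (protein_hits or []) if h.cluster_id == cluster.cluster_id]
    if hits:
        spans = [(h.query_start - 1, h.query_end, h.strand) for h in hits]
    else:
        spans = _sixframe_orf_spans(cluster.consensus, min_orf_bp)
    plus = [s for s in spans if s[2] is Strand.PLUS]
    minus = [s for s in spans if s[2] is Strand.MINUS]
    if not plus or not minus:
        return None
    profile = _orientation_profile(cluster)
    best: Optional[SplitDecision] = None
    best_len = -1
    for ps, pe, _ in plus:
        for ms, me, _ in minus:
            if pe > ms:  # must be non-overlapping, plus upstream
                continue
            up_mean = float(profile[ps:pe].mean()) if pe > ps else 0.0
            down_mean = float(profile[ms:me].mean()) if me > ms else 0.0
            if up_mean <= 0 or down_mean >= 0:
                continue
            gap = profile[pe : ms + 1]
            negatives = np.nonzero(gap < 0)[0]
            breakpoint = pe + (int(negatives[0]) if negatives.size else len(gap) // 2)
            total = (pe - ps) + (me - ms)
            if total > best_len:
                best_len = total
                best = SplitDecision(
                    cluster_id=cluster.cluster_id,
                    breakpoint=breakpoint,
                    upstream_orf_span=(ps, pe),
                    downstream_orf_span=(ms, me),
                    upstream_mean_orientation=up_mean,
                    downstream_mean_orientation=down_mean,
                )
    return best


def split_cluster(
    cluster: Cluster, decision: SplitDecision, ests: ESTSet
) -> tuple[Cluster, Cluster]:
    """Split a back-to-back cluster at the decision breakpoint.

    Placements with more than half their aligned length downstream of the
    breakpoint move to the new cluster, whose coordinate system is the
    reverse complement of the downstream consensus segment (offsets
    inverted, strands flipped). Ties stay upstream. EST count is conserved.
    """
    bp = decision.breakpoint
    length = len(cluster.consensus)
    if not (0 <= bp <= length):
        raise ValueError(
            f"breakpoint {bp} outside consensus of length {length}"
        )
    up = Cluster(cluster_id=cluster.cluster_id)
    down = Cluster(cluster_id=cluster.cluster_id + "_rc")
    down_len = length - bp
    for p in cluster.placements:
        aligned = cluster.aligned[p.est_id]
        downstream = max(0, min(p.end, length) - max(p.offset, bp))
        if downstream * 2 > p.aligned_length:
            # clip to [bp, length) then mirror into rc coordinates
            clip_s = max(p.offset, bp)
            clip_e = min(p.end, length)
            seg = aligned[clip_s - p.offset : clip_e - p.offset]
            new_offset = length - clip_e
            down.placements.append(
                Placement(
                    est_id=p.est_id,
                    offset=new_offset,
                    strand=p.strand.flipped(),
                    aligned_length=len(seg),
                )
            )
            down.aligned[p.est_id] = revcomp(seg)
        else:
            clip_e = min(p.end, bp) if p.offset < bp else p.end
            clip_e = max(clip_e, p.offset + 1)
            seg = aligned[: clip_e - p.offset]
            up.placements.append(
                Placement(
                    est_id=p.est_id,
                    offset=p.offset,
                    strand=p.strand,
                    aligned_length=len(seg),
                )
            )
            up.aligned[p.est_id] = seg
    if not up.placements or not down.placements:
        raise ValueError("split would create an empty cluster")
    up.consensus = build_consensus(up)
    down.consensus = build_consensus(down)
    # pad rc coordinates so offsets measured from the old 3' end stay valid
    if len(down.consensus) < down_len:
        down.consensus += "N" * (down_len - len(down.consensus))
    up.refresh_five_prime_ends(ests)
    down.refresh_five_prime_ends(ests)
    return up, down
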