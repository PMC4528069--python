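"""Full-ORF clone flagging, alternative-transcript detection and picking.

A clone is full-ORF when the span of its reads on the cluster coordinate
system covers the annotated ORF from initiator ATG through stop. Within a
cluster, up to two full-ORF clones are picked (two per transcript, four
per gene when alternative-transcript sub-clusters exist, most abundant
transcript first); manually listed clones are added unconditionally.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .clustering import build_consensus, cluster_ests
from .model import (
    Cluster,
    End,
    ESTSet,
    FullOrfStatus,
    OrfAnnotation,
    PickReason,
    PipelineConfig,
    Placement,
)


def clone_spans(cluster: Cluster, ests: ESTSet) -> dict[str, tuple]:
    """Per-clone (start, end, has5, has3) spans on cluster coordinates.

    Paired clones span from their 5' read start to their 3' read end;
    single-end clones span that read only.
    """
    spans: dict[str, list] = {}
    for p in cluster.placements:
        est = ests[p.est_id]
        entry = spans.setdefault(est.clone_id, [None, None])
        if est.end is End.FIVE_PRIME:
            entry[0] = p
        else:
            entry[1] = p
    out = {}
    for clone_id, (p5, p3) in spans.items():
        placements = [p for p in (p5, p3) if p is not None]
        start = min(p.offset for p in placements)
        end = max(p.end for p in placements)
        out[clone_id] = (start, end, p5 is not None, p3 is not None)
    return out


def flag_fullorf_clones(
    cluster: Cluster, orf: OrfAnnotation, ests: ESTSet
) -> None:
    """Set fullorf_status on every clone with reads in this cluster.

    FULL iff the clone span covers [orf_start, orf_end]; single-end
    clones qualify only if that one read covers the whole ORF.
    """
    for clone_id, (start, end, _h5, _h3) in clone_spans(cluster, ests).items():
        clone = ests.clones.get(clone_id)
        if clone is None:
            continue
        if start <= orf.orf_start and end >= orf.orf_end:
            clone.fullorf_status = FullOrfStatus.FULL
        else:
            clone.fullorf_status = FullOrfStatus.TRUNCATED


def _deletion_blocks(aligned: str, offset: int, min_block: int,
                     max_interrupt: int = 6):
    """Cluster-coordinate deletion blocks of >= min_block gapped bases.

    Gap runs separated by at most ``max_interrupt`` non-gap characters
    are coalesced: the edit path of a long deletion is typically broken
    up by chance matches inside the missing block.
    """
    blocks = []
    start = None
    gapped = 0
    interrupt = 0
    for i, c in enumerate(aligned):
        if c == "-":
            if gapped == 0:
                start = i
            gapped += 1
            interrupt = 0
            end = i + 1
        elif gapped:
            interrupt += 1
            if interrupt > max_interrupt:
                if gapped >= min_block:
                    blocks.append((offset + start, offset + end))
                gapped = 0
    if gapped >= min_block:
        blocks.append((offset + start, offset + end))
    return blocks


def detect_alt_transcripts(
    cluster: Cluster,
    min_block: int = 25,
    min_support: int = 2,
    ests: Optional[ESTSet] = None,
) -> list[Cluster]:
    """Partition a cluster into transcript sub-clusters by indel pattern.

    Insertion/deletion blocks >= min_block bp relative to the consensus
    (the footprint of alternative exon usage) define a presence/absence
    vector per EST; two or more patterns each supported by >= min_support
    ESTs yield sub-clusters with their own consensi. ESTs not spanning
    every block region are left unassigned. With ``ests`` supplied, each
    sub-cluster is re-assembled from its member reads so its consensus
    carries the isoform's own exon structure (insertion bases relative
    to the parent consensus are otherwise unrepresentable).
    """
    edge_margin = 20  # indel blocks hugging a read's ends are artefacts
    per_est: dict[str, list] = {}
    all_blocks: list[tuple] = []
    for p in cluster.placements:
        aligned = cluster.aligned.get(p.est_id, "")
        blocks = [
            b
            for b in _deletion_blocks(aligned, p.offset, min_block)
            if b[0] >= p.offset + edge_margin and b[1] <= p.end - edge_margin
        ]
        blocks += [
            ("ins", pos, n)
            for pos, n in cluster.insertions.get(p.est_id, [])
            if p.offset + edge_margin <= pos <= p.end - edge_margin
        ]
        per_est[p.est_id] = blocks
        all_blocks.extend(blocks)
    if not all_blocks:
        cluster.subclusters = []
        return []
    # canonicalise deletions by interval overlap, insertions by position
    # proximity (alignment jitter of a few bp around the same junction)
    deletions = sorted(b for b in all_blocks if b[0] != "ins")
    canonical: list = []
    for s, e in deletions:
        if canonical and s <= canonical[-1][1]:
            canonical[-1][1] = max(canonical[-1][1], e)
        else:
            canonical.append([s, e])
    canonical = [("del", tuple(b)) for b in canonical]
    # an insertion site groups all recorded read-only blocks within a
    # block-length neighbourhood (the edit path fragments long insertions)
    site_link = 2 * min_block
    ins_sites: list[int] = []
    for _, pos, _n in sorted(b for b in all_blocks if b[0] == "ins"):
        if ins_sites and pos - ins_sites[-1] <= site_link:
            continue
        ins_sites.append(pos)
    canonical += [("ins", site) for site in ins_sites]

    def has_feature(blocks, kind, feat):
        if kind == "del":
            s, e = feat
            return any(
                b[0] != "ins" and b[0] <= s and b[1] >= e for b in blocks
            )
        site = feat
        total = sum(
            b[2] for b in blocks
            if b[0] == "ins" and abs(b[1] - site) <= site_link
        )
        return total >= min_block

    # a read must reach well past a junction on both sides before its
    # presence/absence call is trusted: placements starting near the
    # junction have distorted local alignments
    junction_margin = 120

    def spans(p, kind, feat):
        if kind == "del":
            s, e = feat[0] - 25, feat[1] + 25
        else:
            s, e = feat - junction_margin, feat + junction_margin
        return p.offset <= s and p.end >= e

    # keep only features seen independently in >= min_support reads;
    # a phantom block in a single noisy read must not drive a partition
    canonical = [
        (kind, feat)
        for kind, feat in canonical
        if sum(
            1
            for p in cluster.placements
            if spans(p, kind, feat)
            and has_feature(per_est[p.est_id], kind, feat)
        )
        >= min_support
    ]
    if not canonical:
        cluster.subclusters = []
        return []

    patterns: dict[tuple, list[Placement]] = {}
    for p in cluster.placements:
        if not all(spans(p, kind, feat) for kind, feat in canonical):
            continue
        mask = tuple(
            has_feature(per_est[p.est_id], kind, feat)
            for kind, feat in canonical
        )
        patterns.setdefault(mask, []).append(p)
    supported = {
        mask: ps for mask, ps in patterns.items() if len(ps) >= min_support
    }
    if len(supported) < 2:
        cluster.subclusters = []
        return []
    subclusters = []
    for j, mask in enumerate(sorted(supported, key=lambda m: (-len(supported[m]), m))):
        sub_id = f"{cluster.cluster_id}.t{j}"
        sub = None
        if ests is not None:
            member_ids = {p.est_id for p in supported[mask]}
            subset = ESTSet(
                [ests[i] for i in sorted(member_ids)],
                [
                    c for c in ests.clones.values()
                    if (c.est5_id in member_ids) or (c.est3_id in member_ids)
                ],
            )
            reassembled = cluster_ests(subset)
            if reassembled:
                sub = max(reassembled, key=lambda c: len(c.placements))
                sub.cluster_id = sub_id
        if sub is None:
            sub = Cluster(cluster_id=sub_id)
            sub.placements = list(supported[mask])
            sub.aligned = {
                p.est_id: cluster.aligned[p.est_id] for p in sub.placements
            }
            sub.consensus = build_consensus(sub)
        subclusters.append(sub)
    cluster.subclusters = subclusters
    return subclusters


@dataclass
class Pick:
    clone_id: str
    cluster_id: str
    transcript_id: str
    pick_reason: PickReason
    rank: int


def _rank_key(clone_id: str, span, orf: OrfAnnotation):
    start, end, _h5, _h3 = span
    if start <= orf.orf_start:
        overhang = (0, orf.orf_start - start)
    else:
        overhang = (1, start - orf.orf_start)
    return (*overhang, -(end - start), clone_id)


def pick_clones(
    clusters: list[Cluster],
    ests: ESTSet,
    orfs: dict[str, OrfAnnotation],
    config: Optional[PipelineConfig] = None,
    suborfs: Optional[dict[str, OrfAnnotation]] = None,
) -> list[Pick]:
    """Pick a provisional non-redundant clone list.

    Clusters without sub-clusters contribute up to ``picks_per_cluster``
    FULL clones; clusters with transcript sub-clusters contribute up to
    ``picks_per_gene_max`` in total, at most two per transcript, more
    abundant transcripts first. Candidates are ranked by 5' read start
    closest to (but not inside) the ORF, then longer span, then clone id.
    Manually configured clone ids are appended unconditionally.
    """
    config = config or PipelineConfig()
    suborfs = suborfs or {}
    picks: list[Pick] = []
    picked_ids = set()

    def pick_from(unit: Cluster, orf: OrfAnnotation, limit: int,
                  transcript_id: str, reason: PickReason, parent_id: str) -> int:
        spans = clone_spans(unit, ests)
        candidates = []
        for clone_id, span in spans.items():
            clone = ests.clones.get(clone_id)
            if clone is None or clone.fullorf_status is not FullOrfStatus.FULL:
                continue
            if clone_id in picked_ids:
                continue
            candidates.append((clone_id, span))
        candidates.sort(key=lambda cs: _rank_key(cs[0], cs[1], orf))
        n = 0
        for rank, (clone_id, _span) in enumerate(candidates[:limit], 1):
            clone = ests.clones[clone_id]
            clone.picked = True
            clone.pick_reason = reason
            picks.append(
                Pick(clone_id=clone_id, cluster_id=parent_id,
                     transcript_id=transcript_id, pick_reason=reason,
                     rank=rank)
            )
            picked_ids.add(clone_id)
            n += 1
        return n

    for cluster in clusters:
        if cluster.subclusters:
            remaining = config.picks_per_gene_max
            subs = sorted(
                cluster.subclusters, key=lambda s: (-len(s.placements), s.cluster_id)
            )
            for sub in subs:
                if remaining <= 0:
                    break
                orf = suborfs.get(sub.cluster_id) or orfs.get(cluster.cluster_id)
                if orf is None:
                    continue
                flag_fullorf_clones(sub, orf, ests)
                limit = min(2, remaining)
                remaining -= pick_from(
                    sub, orf, limit, sub.cluster_id,
                    PickReason.ALT_TRANSCRIPT, cluster.cluster_id,
                )
        else:
            orf = orfs.get(cluster.cluster_id)
            if orf is None:
                continue
            pick_from(
                cluster, orf, config.picks_per_cluster, cluster.cluster_id,
                PickReason.AUTOMATIC, cluster.cluster_id,
            )

    for clone_id in config.manual_clone_ids:
        if clone_id in picked_ids:
            continue
        clone = ests.clones.get(clone_id)
        if clone is None:
            continue
        clone.picked = True
        clone.pick_reason = PickReason.MANUAL
        picks.append(
            Pick(clone_id=clone_id, cluster_id="", transcript_id="",
                 pick_reason=PickReason.MANUAL, rank=0)
        )
        picked_ids.add(clone_id)
    return picks
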