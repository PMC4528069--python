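"""Seeded pairwise alignment helpers built on edlib.

The clusterer needs overlap alignments (free end gaps on both sequences),
which edlib does not provide directly. We recover them by k-mer diagonal
seeding to localise the shared region, then an infix (HW) edit-distance
alignment of the overlapping substrings, with generous padding so that
moderate indels (e.g. skipped exons) are absorbed.

'N' is treated as matching any base, so uncovered consensus columns do not
depress identity.
"""
from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional

import edlib

_N_EQUALITIES = [("N", b) for b in "ACGT"]
_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def parse_cigar(cigar: str):
    """Yield (length, op) pairs from an extended cigar string."""
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_identity(cigar: str):
    """(matches, columns) of an extended cigar."""
    matches = cols = 0
    for n, op in parse_cigar(cigar):
        cols += n
        if op == "=":
            matches += n
    return matches, cols


def cigar_identity_gapless(cigar: str):
    """(matches, substitution columns) of an extended cigar.

    Gap columns are excluded: in Sanger EST data indels against a
    consensus are structural events (alternative exon usage, unsequenced
    gaps) rather than base-level disagreement, so the identity that
    drives clustering decisions is measured over aligned base pairs only.
    """
    matches = cols = 0
    for n, op in parse_cigar(cigar):
        if op in "=X":
            cols += n
        if op == "=":
            matches += n
    return matches, cols


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


@dataclass
class Overlap:
    """An overlap alignment of a query onto a target.

    ``offset`` is the target coordinate of query base ``q_start`` minus
    ``q_start`` itself, i.e. where query base 0 would sit on (an extended)
    target axis; it may be negative (query overhangs the target's left end).
    """

    offset: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    identity: float
    columns: int
    cigar: str


def _ungapped_identity(a: str, b: str) -> float:
    if not a or len(a) != len(b):
        return 0.0
    return sum(x == y or x == "N" or y == "N" for x, y in zip(a, b)) / len(a)


def find_overlap(
    query: str,
    target: str,
    k: int = 14,
    min_overlap: int = 40,
    pad: int = 150,
    band: int = 60,
    target_index: Optional[dict] = None,
) -> Optional[Overlap]:
    """Best overlap placement of ``query`` on ``target``, or None.

    Seeds on exact k-mers, votes for the dominant diagonal (summing support
    over a +/-``band`` neighbourhood so indel-split diagonals reinforce each
    other), then aligns the implied overlapping substrings.
    """
    if len(query) < k or len(target) < k:
        return None
    index = target_index if target_index is not None else kmer_index(target, k)
    votes: Counter = Counter()
    for i in range(len(query) - k + 1):
        for p in index.get(query[i : i + k], ()):
            votes[p - i] += 1
    if not votes:
        return None
    diag = max(votes, key=lambda d: (sum(votes[d2] for d2 in votes
                                         if abs(d2 - d) <= band), -abs(d)))
    q_start = max(0, -diag)
    q_end = min(len(query), len(target) - diag)
    if q_end - q_start < min_overlap:
        return None
    # Query bases clipped at the target ends are usually true overhangs
    # (the consensus simply ends there) — but a tail displaced by an
    # interior insertion also looks like one. Displacement duplicates the
    # target terminus, so content decides: if the clipped piece matches
    # the adjacent target end, fold it back into the alignment where the
    # insertion can be represented explicitly.
    m = len(query) - q_end
    if m >= 10 and _ungapped_identity(query[q_end:], target[-m:]) >= 0.8:
        q_end = len(query)
    if q_start >= 10 and _ungapped_identity(
        query[:q_start], target[:q_start]
    ) >= 0.8:
        q_start = 0
    w_start = max(0, diag + q_start - pad)
    w_end = min(len(target), diag + q_end + pad)
    sub = query[q_start:q_end]
    res = edlib.align(
        sub,
        target[w_start:w_end],
        mode="HW",
        task="path",
        additionalEqualities=_N_EQUALITIES,
    )
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc_s, loc_e = res["locations"][0]
    matches, cols = cigar_identity_gapless(res["cigar"])
    if cols < min_overlap:
        return None
    t_start = w_start + loc_s
    t_end = w_start + loc_e + 1
    return Overlap(
        offset=t_start - q_start,
        q_start=q_start,
        q_end=q_end,
        t_start=t_start,
        t_end=t_end,
        identity=matches / cols,
        columns=cols,
        cigar=res["cigar"],
    )


def project_query(overlap: Overlap, query: str) -> str:
    """Project the aligned query segment onto target coordinates.

    Returns a string covering target [t_start, t_end): query bases at
    match/mismatch columns, '-' where the target has an extra base, with
    query insertions dropped (cluster coordinates follow the consensus).
    """
    out = []
    qi = overlap.q_start
    for n, op in parse_cigar(overlap.cigar):
        if op in "=X":
            out.append(query[qi : qi + n])
            qi += n
        elif op == "I":  # extra query bases: no target column
            qi += n
        else:  # 'D': extra target bases
            out.append("-" * n)
    return "".join(out)


def global_identity(a: str, b: str) -> float:
    """Identity of the global (NW) alignment of two sequences."""
    res = edlib.align(a, b, mode="NW", task="path",
                      additionalEqualities=_N_EQUALITIES)
    matches, cols = cigar_identity(res["cigar"])
    return matches / cols if cols else 0.0


def infix_identity(a: str, b: str):
    """Identity and aligned span of the best infix alignment of a within b.

    Returns (identity, (b_start, b_end)); used for consensus-vs-consensus
    comparisons where the shorter sequence is expected to be contained.
    """
    if len(a) > len(b):
        a, b = b, a
    res = edlib.align(a, b, mode="HW", task="path",
                      additionalEqualities=_N_EQUALITIES)
    matches, cols = cigar_identity(res["cigar"])
    loc_s, loc_e = res["locations"][0]
    return (matches / cols if cols else 0.0), (loc_s, loc_e + 1)
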