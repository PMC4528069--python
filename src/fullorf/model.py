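"""Core domain types for the full-ORF cDNA identification pipeline.

All internal coordinates are 0-based half-open. Format boundaries
(BED12, GFF3, protein-hit tables) convert at I/O time only.
"""
from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional

VALID_ALPHABET = frozenset("ACGTN")


class End(enum.Enum):
    """Which end of a cDNA insert a read was sequenced from."""

    FIVE_PRIME = "5"
    THREE_PRIME = "3"


class Strand(enum.Enum):
    """Orientation of a read or feature relative to a reference sense."""

    PLUS = "+"
    MINUS = "-"

    def flipped(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS


class Population(enum.Enum):
    ATLANTIC = "atlantic"
    PACIFIC = "pacific"
    OTHER = "other"


class FullOrfStatus(enum.Enum):
    UNKNOWN = "unknown"
    FULL = "full"
    TRUNCATED = "truncated"


class PickReason(enum.Enum):
    AUTOMATIC = "automatic"
    ALT_TRANSCRIPT = "alt_transcript"
    MANUAL = "manual"
    NONE = "none"


class FivePrimeEvidence(enum.Enum):
    UPSTREAM_STOP = "upstream_stop"
    CLIFF = "cliff"
    SL = "sl"
    ORTHOLOG_P = "ortholog_p"


class ThreePrimeEvidence(enum.Enum):
    STOP_CODON = "stop_codon"
    UTR3_ALLFRAME_STOPS = "utr3_allframe_stops"
    UTR3_EST_FRACTION = "utr3_est_fraction"


@dataclass
class ESTRecord:
    """One single-pass Sanger end-read of a cloned cDNA insert.

    ``sequence`` is stored exactly as sequenced (read orientation);
    3' reads are reverse-complemented only transiently during assembly.
    """

    est_id: str
    clone_id: str
    end: End
    library_id: str
    population: Population
    sequence: str
    passed_qc: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"EST {self.est_id}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"EST {self.est_id}: invalid characters {sorted(bad)!r}"
            )
        self.sequence = self.sequence.upper()


@dataclass
class CloneRecord:
    """A physical cDNA clone, linked to its 5'/3' end reads."""

    clone_id: str
    est5_id: Optional[str] = None
    est3_id: Optional[str] = None
    library_id: str = ""
    fullorf_status: FullOrfStatus = FullOrfStatus.UNKNOWN
    picked: bool = False
    pick_reason: PickReason = PickReason.NONE

    def __post_init__(self) -> None:
        if self.est5_id is None and self.est3_id is None:
            raise ValueError(f"clone {self.clone_id}: no EST on either end")


class ESTSet:
    """Validated collection of ESTRecords with their clone table.

    Enforces uniqueness of (clone_id, end) and provides id lookup.
    """

    def __init__(self, ests=(), clones=()):
        self.ests: dict[str, ESTRecord] = {}
        self.clones: dict[str, CloneRecord] = {}
        seen_clone_end = set()
        for est in ests:
            if est.est_id in self.ests:
                raise ValueError(f"duplicate EST id {est.est_id}")
            key = (est.clone_id, est.end)
            if key in seen_clone_end:
                raise ValueError(
                    f"duplicate (clone_id, end) = ({est.clone_id}, "
                    f"{est.end.value}')"
                )
            seen_clone_end.add(key)
            self.ests[est.est_id] = est
        for clone in clones:
            self.clones[clone.clone_id] = clone

    def __len__(self) -> int:
        return len(self.ests)

    def __iter__(self):
        return iter(self.ests.values())

    def __getitem__(self, est_id: str) -> ESTRecord:
        return self.ests[est_id]

    def qc_passing(self) -> list[ESTRecord]:
        return [e for e in self.ests.values() if e.passed_qc]


@dataclass
class Placement:
    """Position of one EST on a cluster's coordinate system."""

    est_id: str
    offset: int
    strand: Strand
    aligned_length: int

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"placement {self.est_id}: negative offset")
        if self.aligned_length < 1:
            raise ValueError(f"placement {self.est_id}: aligned_length < 1")

    @property
    def end(self) -> int:
        return self.offset + self.aligned_length


@dataclass
class Cluster:
    """A gene-wise group of co-assembled ESTs with a consensus sequence.

    ``aligned`` holds, per placed EST, its sequence projected onto cluster
    coordinates (gaps as '-', insertions relative to the consensus dropped)
    so that column-wise voting and coverage are direct array operations.
    """

    cluster_id: str
    placements: list[Placement] = field(default_factory=list)
    consensus: str = ""
    subclusters: list["Cluster"] = field(default_factory=list)
    five_prime_end_positions: list[int] = field(default_factory=list)
    aligned: dict[str, str] = field(default_factory=dict)
    # per-EST insertion blocks relative to the consensus, as
    # (cluster position, length) — the footprint of an exon the
    # consensus lacks; deletions appear as '-' runs in ``aligned``
    insertions: dict[str, list] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.placements)

    def est_ids(self) -> list[str]:
        return [p.est_id for p in self.placements]

    def refresh_five_prime_ends(self, ests: "ESTSet") -> None:
        """Recompute sense-orientation 5' read start positions (Z list)."""
        self.five_prime_end_positions = sorted(
            p.offset
            for p in self.placements
            if p.strand is Strand.PLUS
            and ests[p.est_id].end is End.FIVE_PRIME
        )

    def coverage(self):
        import numpy as np

        cov = np.zeros(len(self.consensus), dtype=int)
        for p in self.placements:
            cov[p.offset : min(p.end, len(self.consensus))] += 1
        return cov


@dataclass
class CliffResult:
    """All quantities of the cliff 5'-end test for one cluster."""

    cluster_id: str
    Z: int
    eligible: bool
    x: Optional[int] = None
    N100: Optional[int] = None
    N1000: Optional[int] = None
    Nsteep: Optional[int] = None
    m_steep: Optional[float] = None
    S_peak: Optional[float] = None
    S_steep: Optional[float] = None
    score: Optional[float] = None
    tss_estimate: Optional[int] = None
    passes: bool = False


@dataclass
class OrfAnnotation:
    """ORF location on a cluster consensus plus completeness evidence."""

    cluster_id: str
    orf_start: int
    orf_end: int
    frame: int
    strand: Strand
    five_prime_complete: bool = False
    five_prime_evidence: set = field(default_factory=set)
    three_prime_complete: bool = False
    three_prime_evidence: set = field(default_factory=set)


@dataclass
class ProteinHit:
    """A protein alignment onto a cluster consensus (BLASTx surrogate).

    Coordinates are 1-based closed intervals, per standard alignment
    notation; they are not converted because the N-terminus prediction
    formula is defined in that notation.
    """

    cluster_id: str
    strand: Strand
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    species: str
    evalue: float

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("query_start > query_end")
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start > subject_end")


@dataclass
class NTermPrediction:
    """Ortholog-implied CDS start (P) on a transcript, 1-based.

    P <= 0 means the implied start lies upstream of the contig; it is
    flagged, never clamped.
    """

    cluster_id: str
    species: str
    P: int
    conserved: bool = False

    @property
    def upstream_of_contig(self) -> bool:
        return self.P <= 0


@dataclass
class ExonChain:
    """Ordered genomic exon intervals of one clone's spliced alignment."""

    clone_id: str
    target_id: str
    strand: Strand
    exons: tuple

    def __post_init__(self) -> None:
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"chain {self.clone_id}: no exons")
        prev_end = -1
        for s, e in exons:
            if s >= e:
                raise ValueError(f"chain {self.clone_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(
                    f"chain {self.clone_id}: exons overlap or out of order"
                )
            prev_end = e
        self.exons = exons

    @property
    def fingerprint(self):
        return (self.target_id, self.strand, self.exons)


@dataclass
class SplitDecision:
    """Breakpoint for separating a back-to-back co-clustered gene pair."""

    cluster_id: str
    breakpoint: int
    upstream_orf_span: tuple
    downstream_orf_span: tuple
    upstream_mean_orientation: float
    downstream_mean_orientation: float

    def __post_init__(self) -> None:
        if not (
            self.upstream_orf_span[1] <= self.breakpoint
            <= self.downstream_orf_span[0]
        ):
            raise ValueError("breakpoint not between the two ORF spans")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with field-standard defaults."""

    identity_threshold: float = 0.95
    min_overlap_bp: int = 40
    cliff_min_score: float = 10.0
    cliff_log_base: float = 0.0  # 0 => natural log
    min_5p_ends: int = 5
    window_bp: int = 100
    step_bp: int = 50
    region_bp: int = 1000
    utr3_est_fraction: float = 0.66
    typeb_identity_low: float = 0.85
    typeb_identity_high: float = 0.95
    typeb_purity: float = 0.90
    typeb_min_ests: int = 5
    picks_per_cluster: int = 2
    picks_per_gene_max: int = 4
    min_insert_bp: int = 700
    min_block_bp: int = 25
    sl_min_match: int = 20
    fingerprint_end_slop: int = 0
    manual_clone_ids: list = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "identity_threshold",
            "utr3_est_fraction",
            "typeb_identity_low",
            "typeb_identity_high",
            "typeb_purity",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.window_bp > self.region_bp:
            raise ValueError("window_bp > region_bp")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]
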