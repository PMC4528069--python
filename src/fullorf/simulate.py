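"""Synthetic genomes, transcript sets and Sanger-style EST clone libraries.

The generator emulates the statistical structure the pipeline assumes in a
highly polymorphic ascidian-like transcriptome:

* multi-exon genes with short 5' UTRs (length distribution peaked near
  40 bp) and ORFs of a few hundred codons;
* recent paralog pairs at a target transcript identity (distinct loci);
* deeply diverged subspecies haplotypes (type A/B) at a single locus,
  generated by uniform substitution — type-B clones all derive from the
  Atlantic population, as in mixed sympatric sampling;
* back-to-back opposite-strand gene pairs with overlapping 3' UTRs;
* SL trans-spliced transcripts whose mature mRNA begins with a fixed
  16-nt splice-leader tag;
* reverse-transcriptase 5' drop-off modelled as a geometric per-base
  termination from the mRNA 3' end toward the 5' end, followed by a
  >= 0.7 kb insert size selection;
* paired 5'/3' reads with substitution errors.

All randomness flows from a single numpy Generator seeded explicitly, so
fixed seeds give byte-identical FASTA output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    CloneRecord,
    End,
    ESTRecord,
    ESTSet,
    ExonChain,
    Population,
    Strand,
    revcomp,
)

SL_TAG = "ATTCTATTTGAATAAG"  # fixed 16-nt splice-leader tag
BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}

LIBRARY_BY_POPULATION = {
    Population.ATLANTIC: "libA",
    Population.PACIFIC: "libP",
    Population.OTHER: "libO",
}


@dataclass
class GeneSpec:
    """Ground truth for one simulated gene (or allele haplotype)."""

    gene_id: str
    target_id: str
    strand: Strand
    exons: tuple  # genomic intervals, 0-based half-open, ascending
    transcript: str  # mature mRNA (includes SL tag when sl_spliced)
    orf_start: int  # on mature mRNA
    orf_end: int
    sl_spliced: bool = False
    paralog_of: Optional[str] = None
    paralog_identity: Optional[float] = None
    allele_of: Optional[str] = None
    allele_b_divergence: float = 0.0
    backtoback_partner: Optional[str] = None
    alt_deletion: Optional[tuple] = None  # (start, length) on mRNA: 2nd isoform

    @property
    def tss(self) -> int:
        return 0

    @property
    def utr5_len(self) -> int:
        return self.orf_start

    def isoform(self, which: int) -> str:
        if which == 0 or self.alt_deletion is None:
            return self.transcript
        s, n = self.alt_deletion
        return self.transcript[:s] + self.transcript[s + n :]

    def truth_chain(self) -> ExonChain:
        return ExonChain(
            clone_id=self.gene_id,
            target_id=self.target_id,
            strand=self.strand,
            exons=self.exons,
        )


@dataclass
class LibraryParams:
    """Clone-library construction parameters."""

    n_clones_per_gene: int = 20
    rt_dropoff_p: float = 0.001
    read_len_mean: int = 600
    read_len_sd: int = 50
    error_rate: float = 0.01
    min_insert_bp: int = 700
    # type-B haplotypes occur only in the (mixed) Atlantic sample, so type-B
    # clusters run markedly smaller than their type-A counterparts
    allele_b_clone_fraction: float = 0.4
    population_mix: dict = field(
        default_factory=lambda: {
            Population.ATLANTIC: 0.5,
            Population.PACIFIC: 0.5,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rt_dropoff_p", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, n)])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons - 2:
        codon = _random_seq(rng, 3)
        if codon not in _STOPS:
            codons.append(codon)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(codons) + stop


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Uniform substitutions at the given per-base rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _split_exons(rng: np.random.Generator, length: int, n_exons: int,
                 min_exon: int = 80) -> list[int]:
    """Exon lengths summing to ``length``; falls back to fewer exons."""
    while n_exons > 1 and length < n_exons * min_exon:
        n_exons -= 1
    if n_exons == 1:
        return [length]
    cuts = sorted(
        rng.choice(
            np.arange(min_exon, length - min_exon),
            size=n_exons - 1,
            replace=False,
        )
    )
    # enforce the minimum on every piece
    ok = all(
        b - a >= min_exon
        for a, b in zip([0] + list(cuts), list(cuts) + [length])
    )
    if not ok:
        return _split_exons(rng, length, n_exons, min_exon)
    bounds = [0] + list(int(c) for c in cuts) + [length]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


def simulate_gene_set(
    n_genes: int,
    seed: int = 0,
    paralog_pairs: int = 0,
    ab_pairs: int = 0,
    backtoback_pairs: int = 0,
    sl_genes: int = 0,
    alt_splice_genes: int = 0,
    paralog_identity: float = 0.90,
    allele_b_divergence: float = 0.08,
    backtoback_overlap: int = 60,
    max_exons: int = 3,
    utr5_mode: int = 40,
) -> tuple[dict[str, str], list[GeneSpec], pd.DataFrame]:
    """Generate a genome, gene specs and a gene-level truth table.

    ``n_genes`` counts base genes; paralogs and type-B alleles are derived
    extras. Back-to-back pairs consume two base genes each (single-exon,
    opposite strands, 3' UTRs overlapping by ``backtoback_overlap`` bp on
    the genome). The feature counts must fit: backtoback uses the first
    2*backtoback_pairs genes; SL, alt-splice, paralog and A/B features are
    assigned to subsequent distinct genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    needed = 2 * backtoback_pairs + paralog_pairs + ab_pairs + sl_genes + alt_splice_genes
    if needed > n_genes:
        raise ValueError(
            f"feature assignments need {needed} genes but n_genes={n_genes}"
        )
    rng = np.random.default_rng(seed)
    specs: list[GeneSpec] = []
    genome_parts: list[str] = []
    cursor = 0
    target_id = "scaf1"

    def spacer():
        nonlocal cursor
        n = int(rng.integers(200, 500))
        genome_parts.append(_random_seq(rng, n))
        cursor += n

    def draw_core(sl: bool):
        # 5' UTR length peaked near utr5_mode (gamma with that mode)
        utr5 = max(5, int(rng.gamma(5.0, utr5_mode / 4.0)))
        orf = _random_orf(rng, int(rng.integers(170, 300)))
        utr3 = int(rng.integers(200, 350))
        core = _random_seq(rng, utr5) + orf + _random_seq(rng, utr3)
        prefix = SL_TAG if sl else ""
        orf_start = len(prefix) + utr5
        return prefix + core, orf_start, orf_start + len(orf), utr3

    gene_index = 0

    def next_id():
        nonlocal gene_index
        gene_index += 1
        return f"g{gene_index:03d}"

    # --- back-to-back pairs (single exon, overlapping 3' UTRs) ---
    for _ in range(backtoback_pairs):
        id_a, id_b = next_id(), next_id()
        t_a, orf_s_a, orf_e_a, utr3_a = draw_core(sl=False)
        t_b, orf_s_b, orf_e_b, utr3_b = draw_core(sl=False)
        ov = min(backtoback_overlap, utr3_a - 10, utr3_b - 10)
        spacer()
        start_a = cursor
        genome_parts.append(t_a)
        cursor += len(t_a)
        # the genomic overlap: last ov bases of A's transcript are the
        # reverse complement of the last ov bases of B's transcript
        t_b = t_b[: len(t_b) - ov] + revcomp(t_a[len(t_a) - ov :])
        start_b = cursor - ov
        genome_parts.append(revcomp(t_b)[ov:])
        cursor += len(t_b) - ov
        specs.append(
            GeneSpec(
                gene_id=id_a, target_id=target_id, strand=Strand.PLUS,
                exons=((start_a, start_a + len(t_a)),),
                transcript=t_a, orf_start=orf_s_a, orf_end=orf_e_a,
                backtoback_partner=id_b,
            )
        )
        specs.append(
            GeneSpec(
                gene_id=id_b, target_id=target_id, strand=Strand.MINUS,
                exons=((start_b, start_b + len(t_b)),),
                transcript=t_b, orf_start=orf_s_b, orf_end=orf_e_b,
                backtoback_partner=id_a,
            )
        )

    # --- remaining base genes with optional features ---
    n_plain = n_genes - 2 * backtoback_pairs
    features = (
        ["sl"] * sl_genes
        + ["alt"] * alt_splice_genes
        + ["paralog"] * paralog_pairs
        + ["ab"] * ab_pairs
    )
    features += ["plain"] * (n_plain - len(features))
    for feature in features:
        gid = next_id()
        sl = feature == "sl"
        transcript, orf_s, orf_e, _ = draw_core(sl=sl)
        genomic = transcript[len(SL_TAG) :] if sl else transcript
        n_exons = int(rng.integers(1, max_exons + 1))
        exon_lens = _split_exons(rng, len(genomic), n_exons)
        spacer()
        exons = []
        pos = 0
        for i, el in enumerate(exon_lens):
            exons.append((cursor, cursor + el))
            genome_parts.append(genomic[pos : pos + el])
            cursor += el
            pos += el
            if i < len(exon_lens) - 1:
                intron = int(rng.integers(100, 400))
                # canonical GT..AG splice dinucleotides
                genome_parts.append("GT" + _random_seq(rng, intron - 4) + "AG")
                cursor += intron
        spec = GeneSpec(
            gene_id=gid, target_id=target_id, strand=Strand.PLUS,
            exons=tuple(exons), transcript=transcript,
            orf_start=orf_s, orf_end=orf_e, sl_spliced=sl,
        )
        if feature == "alt":
            # a skipped internal block in half the clones
            del_len = 80
            lo = orf_s + 30
            hi = orf_e - 30 - del_len
            del_start = int(rng.integers(lo, hi))
            del_start = orf_s + ((del_start - orf_s) // 3) * 3
            spec.alt_deletion = (del_start, del_len)
        specs.append(spec)
        if feature == "paralog":
            pid = next_id()
            p_transcript = _mutate(rng, transcript, 1.0 - paralog_identity)
            spacer()
            p_start = cursor
            genome_parts.append(p_transcript)
            cursor += len(p_transcript)
            specs.append(
                GeneSpec(
                    gene_id=pid, target_id=target_id, strand=Strand.PLUS,
                    exons=((p_start, p_start + len(p_transcript)),),
                    transcript=p_transcript,
                    orf_start=orf_s, orf_end=orf_e,
                    paralog_of=gid, paralog_identity=paralog_identity,
                )
            )
        elif feature == "ab":
            bid = gid + "B"
            b_transcript = _mutate(rng, transcript, allele_b_divergence)
            specs.append(
                GeneSpec(
                    gene_id=bid, target_id=target_id, strand=spec.strand,
                    exons=spec.exons,  # same locus: the genome carries type A
                    transcript=b_transcript,
                    orf_start=orf_s, orf_end=orf_e,
                    allele_of=gid, allele_b_divergence=allele_b_divergence,
                )
            )
    spacer()
    genome = {target_id: "".join(genome_parts)}
    truth = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "target_id": s.target_id,
                "strand": s.strand.value,
                "transcript_length": len(s.transcript),
                "orf_start": s.orf_start,
                "orf_end": s.orf_end,
                "tss": s.tss,
                "utr5_len": s.utr5_len,
                "n_exons": len(s.exons),
                "exons": ";".join(f"{a}-{b}" for a, b in s.exons),
                "sl_spliced": s.sl_spliced,
                "paralog_of": s.paralog_of or "",
                "allele_of": s.allele_of or "",
                "backtoback_partner": s.backtoback_partner or "",
                "alt_deletion": (
                    f"{s.alt_deletion[0]}+{s.alt_deletion[1]}"
                    if s.alt_deletion
                    else ""
                ),
            }
            for s in specs
        ]
    )
    return genome, specs, truth


def simulate_clone_library(
    gene_specs: list[GeneSpec], params: LibraryParams
) -> tuple[ESTSet, pd.DataFrame]:
    """Simulate an end-sequenced clone library from a gene set.

    First-strand synthesis starts at the mRNA 3' end; the number of bases
    reverse-transcribed is geometric with per-base termination probability
    ``rt_dropoff_p`` (truncated at the transcript length, i.e. the enzyme
    cannot run past the 5' end). Inserts shorter than ``min_insert_bp``
    are discarded by size selection. Each surviving clone yields a sense
    5' read and a reverse-complemented 3' read with substitution errors.
    """
    rng = np.random.default_rng(params.seed)
    populations = sorted(params.population_mix, key=lambda p: p.value)
    weights = np.array([params.population_mix[p] for p in populations], float)
    weights = weights / weights.sum()
    ests: list[ESTRecord] = []
    clones: list[CloneRecord] = []
    truth_rows = []
    for spec in gene_specs:
        n_clones = params.n_clones_per_gene
        if spec.allele_of:
            n_clones = max(1, round(n_clones * params.allele_b_clone_fraction))
        for i in range(n_clones):
            isoform = 0
            if spec.alt_deletion is not None and rng.random() < 0.5:
                isoform = 1
            mrna = spec.isoform(isoform)
            L = len(mrna)
            if params.rt_dropoff_p > 0:
                insert_len = min(L, int(rng.geometric(params.rt_dropoff_p)))
            else:
                insert_len = L
            if insert_len < params.min_insert_bp:
                continue  # size selection
            t5 = L - insert_len
            insert = mrna[t5:]
            if spec.allele_of:
                population = Population.ATLANTIC
            else:
                population = populations[
                    int(rng.choice(len(populations), p=weights))
                ]
            library_id = LIBRARY_BY_POPULATION[population]
            clone_id = f"{spec.gene_id}_c{i:03d}"
            rl5 = int(
                np.clip(rng.normal(params.read_len_mean, params.read_len_sd),
                        100, insert_len)
            )
            rl3 = int(
                np.clip(rng.normal(params.read_len_mean, params.read_len_sd),
                        100, insert_len)
            )
            read5 = _mutate(rng, insert[:rl5], params.error_rate)
            read3 = _mutate(rng, revcomp(insert[insert_len - rl3 :]),
                            params.error_rate)
            ests.append(
                ESTRecord(
                    est_id=clone_id + ".5", clone_id=clone_id,
                    end=End.FIVE_PRIME, library_id=library_id,
                    population=population, sequence=read5,
                )
            )
            ests.append(
                ESTRecord(
                    est_id=clone_id + ".3", clone_id=clone_id,
                    end=End.THREE_PRIME, library_id=library_id,
                    population=population, sequence=read3,
                )
            )
            clones.append(
                CloneRecord(
                    clone_id=clone_id, est5_id=clone_id + ".5",
                    est3_id=clone_id + ".3", library_id=library_id,
                )
            )
            truth_rows.append(
                {
                    "clone_id": clone_id,
                    "gene_id": spec.gene_id,
                    "isoform": isoform,
                    "t5": t5,
                    "insert_len": insert_len,
                    "full_orf": t5 <= spec.orf_start,
                    "population": population.value,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "clone_id", "gene_id", "isoform", "t5", "insert_len",
            "full_orf", "population",
        ],
    )
    return ESTSet(ests, clones), truth


def simulate_sl_reads(
    gene_specs: list[GeneSpec], reads_per_gene: int = 3,
    read_len: int = 150, seed: int = 0,
) -> dict[str, str]:
    """Post-SL portions of SL-evidence reads for the SL-spliced genes."""
    out = {}
    for spec in gene_specs:
        if not spec.sl_spliced:
            continue
        body = spec.transcript[len(SL_TAG) :]
        for j in range(reads_per_gene):
            out[f"sl_{spec.gene_id}_{j}"] = body[:read_len]
    return out


def simulate_tss_end_positions(
    rng: np.random.Generator,
    transcript_len: int,
    n_ends: int,
    rt_dropoff_p: float = 0.001,
    min_insert_bp: int = 700,
) -> list[int]:
    """5' read start positions for a cluster containing the true TSS.

    Positions are measured on cluster coordinates with the TSS at 0;
    each is transcript_len − insert_len under the geometric RT model,
    conditioned on surviving size selection.
    """
    positions = []
    while len(positions) < n_ends:
        k = min(transcript_len, int(rng.geometric(rt_dropoff_p)))
        if k >= min_insert_bp:
            positions.append(transcript_len - k)
    return sorted(positions)


def simulate_truncated_end_positions(
    rng: np.random.Generator,
    span: int,
    n_ends: int,
) -> list[int]:
    """5' end positions for a cluster whose 5' pile-up is absent.

    Uniform premature-termination positions only, as in a cluster missing
    the transcript 5' end.
    """
    return sorted(int(v) for v in rng.integers(0, span, n_ends))
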