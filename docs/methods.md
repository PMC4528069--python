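# Methods

This note documents the models and procedures implemented in `fullorf`,
the parameters that matter, the synthetic-data generator's scope, and the
numerical/design choices made where the design was genuinely open.

## Clustering and consensus

ESTs are assembled greedily against growing cluster consensi: 3′ reads
are reverse-complemented first so clusters are built in mRNA sense, and
each read is additionally tried in the opposite orientation so that
antisense co-assembly (back-to-back gene pairs sharing 3′-UTR genomic
sequence) is represented as MINUS-strand placements rather than lost.
A read joins the first cluster whose consensus it matches at
`identity_threshold` (default **0.95**, chosen to absorb high intra-type
polymorphism while separating recent paralogs and the ~8–12%-divergent
type-B haplotype) over at least `min_overlap_bp` (**40 bp**, preventing
spurious short-overlap merges); otherwise it founds a new cluster.
Unmerged reads remain singletons.

Pairwise alignment is seeded on exact 14-mers; the dominant diagonal
(votes summed over a ±60 bp band) localises the overlap, which is then
aligned by edit distance (edlib) within a ±150 bp padded window.
**Identity is computed over aligned base pairs only** (match/mismatch
columns): in Sanger EST data an indel against the consensus is a
structural event — alternative exon usage or an unsequenced gap — not
base-level disagreement, and counting a skipped exon as 80 mismatches
would eject real isoform reads from their gene cluster. `N` matches any
base, so uncovered consensus columns do not depress identity. A clipped
read tail that duplicates the consensus terminus is recognised as
insertion displacement (not an overhang) and folded back into the
alignment, where the insertion becomes an explicit block.

Consensus is per-column majority vote over placed bases; ties break
alphabetically; columns with no real-base coverage emit `N`. Clusters
sharing the opposite ends of ≥ 2 clones are joined (connected
components); non-overlapping consensi are concatenated with a 100 bp `N`
sentinel, the 5′-read-rich cluster first.

## Back-to-back splitting

A cluster is split when (a) it carries two non-overlapping ORF spans on
opposite strands (protein hits when available, otherwise six-frame ORFs
≥ 300 bp) with the plus-strand span upstream, and (b) the
coverage-weighted mean placement orientation is positive over the
upstream span and negative over the downstream one. The breakpoint is
the first position between the spans where the per-position mean
orientation turns negative. Placements with > 50% of aligned length
downstream move to a new cluster whose coordinates are the reverse
complement of the downstream segment (ties stay upstream); both consensi
are rebuilt and EST count is conserved.

## The cliff test

Reverse transcription proceeds 3′→5′ and can terminate prematurely
anywhere but never runs past the mRNA 5′ end; a cluster containing the
transcription start therefore shows a sharp spatial concentration of 5′
read start positions, while a 5′-truncated cluster shows only a
scattered tail. Parameters (defaults): window **100 bp**, step
**50 bp**, region **1000 bp**, minimum 5′ ends **Z ≥ 5**, pass score
**≥ 10**.

Choices that the formulas do not pin down:

* **Log base.** The decay term e^(−log(Z−4)) is read with natural log,
  giving 1/(Z−4); both e and 10 readings satisfy the printed endpoints
  (1.0 at Z = 5; → 1/3), and the base is configurable
  (`cliff_log_base`).
* **S_steep.** Implemented as e^(−ln2/m_steep) = 2^(−1/m_steep): this is
  the only reading under which a perfect cluster (all N_steep ends
  coincident, Δx = 0, m_steep = ∞) scores 1.0, which is the stated
  behaviour of the score. m_i = N_steep/Δx_i in ends/bp.
* **N_steep rounding**: ceiling with a 10⁻⁶ tolerance (so the vanishing
  decay remainder at the asymptote cannot round 20.0000001 up to 21),
  floored at 2 (a gradient needs two points), capped at N₁₀₀.
* **Ties**: equal-count windows take the smallest x; equal-gradient runs
  take the most 5′ run. Both biases point toward the 5′-most TSS, which
  is what the test is for.
* **Region**: [x, x+1000) includes the peak window (so S_peak ≤ 1) and
  truncates at the consensus end without rescaling.
* **Scan range**: the peak window scan is restricted to window starts in
  the first `region_bp` of the cluster. The start of transcription can
  only be at the cluster 5′ end; scanning the whole consensus lets the
  densest window of a truncated cluster sit at the 3′ edge of its end
  distribution, where the downstream region is empty and N₁₀₀/N₁₀₀₀
  trivially approaches 1 — a systematic false-positive channel (10–26%
  of truncated clusters under the geometric RT model) that the
  restriction removes entirely. `find_peak_window` itself keeps an
  optional `scan_limit` argument and scans everything by default.

## ORF annotation and completeness evidence

Six-frame ATG→stop enumeration (minimum **60 bp**, which excludes noise
ORFs in UTR-only clusters while far below real gene length); the ORF
overlapping the best protein hit wins when hits exist, otherwise the
longest. 5′ evidence — upstream in-frame stop; passing cliff with TSS
estimate at/upstream of the ATG; SL trans-splice support; conserved
ortholog-implied start P = query_start − 3(subject_start − 1) equal to
the ATG position (confirmatory only; it ranks last and requires ≥ 2
agreeing species). All applicable flags are recorded; completeness is
their disjunction. 3′ evidence — terminal stop codon; else a
well-assembled (coverage ≥ 2 — the chosen operationalisation of
"well-assembled") window of ≥ 100 bp downstream of the last coding base
with stop codons in all three frames and no protein hit; clusters with
no detected coding and > 66% 3′-EST placements are labelled 3′-UTR
fragments. An ORF running off the consensus edge is never 3′-complete.
Protein-hit e-value thresholds: 0.001 generally, relaxed to 0.1 on the
3′-test path where short coding stretches at contig edges matter.

SL matching is exact-substring: an EST is SL-supported when the post-SL
prefix (≥ `sl_min_match` = **20 nt**) of any SL-evidence read occurs
within the EST's first ~60 bases (the EST itself may still carry the SL
tag). Unique SL sequence plus Sanger-quality 5′ termini make alignment
statistics unnecessary at this scale.

## Clone picking

Clone span = 5′-read start to 3′-read end on cluster coordinates
(single-end clones qualify only if the one read covers the whole ORF);
FULL ⇔ span ⊇ ORF. Per cluster: up to **2** FULL clones, ranked by
(5′ start closest to but not inside the ORF, longer span, clone id) — a
deterministic total order favouring clones with minimal 5′-UTR overhang.
Alternative transcripts: indel blocks ≥ `min_block_bp` (**25 bp**)
against the consensus define per-read presence/absence patterns;
deletion blocks are coalesced across ≤ 6 interrupting columns and
insertion blocks grouped within two block lengths (the edit path
fragments long indels with chance matches); features must be seen in
≥ 2 reads, and a read must reach 120 bp past a junction before its call
is trusted (placements starting near a junction have distorted local
alignments). Two or more patterns with ≥ 2 reads each yield transcript
sub-clusters, re-assembled from their member reads so each consensus
carries its own exon structure; then up to **4** picks per gene, ≤ 2 per
transcript, abundant transcripts first. Manually listed clone ids are
added unconditionally.

## Redundancy and paralogy

Picked clones are mapped to the genome by exact **31-mer** anchor
seeding, colinear chaining per target/strand (small read overlaps
between runs — chance matches across a junction — are trimmed), merging
of sub-intron (< 40 bp) genomic gaps, and boundary refinement: every
unanchored read base between adjacent exons is assigned to one side of a
single junction cut chosen to maximise matches, with a bonus for a
canonical GT..AG intron at the implied junction; the cut may back a few
bases into an anchored run, because chance matches can extend an anchor
past the true boundary. Weakly anchored (< 64 bp) terminal segments
without canonical junction motifs are dropped (they are typically chance
hits on a recent paralog's locus). Outer ends extend match-aware: read
exhaustion extends fully (a coverage limit), sustained mismatch (an
intron crossing) rolls back and snaps to an adjacent splice motif.
A clone's chain is the union of its reads' chains on the best
target/strand, with gene strand inferred from each read's end (3′ reads
map antisense). Unmapped clones are reported and bypass dedup.

Exon fingerprints use exact interval equality (configurable terminal-end
slop, default 0); fingerprint groups are trimmed to `keep` = 2 by pick
rank, so the top-ranked pick of a group is never removed. Same-locus
type A/B allele picks share a fingerprint and collapse; paralogs map to
distinct loci and survive. Independently, putative type-B clusters are
*annotated* (never auto-merged): a cluster of ≥ 5 ESTs, ≥ 90% from one
population, matching a larger cluster at 85–95% consensus identity with
the alignment overlapping both ORFs.

## The simulator

The generator emulates: multi-exon genes (1–3 exons, ≥ 80 bp, GT..AG
introns of 100–400 bp) with 5′ UTRs gamma-distributed with mode ≈ 40 bp,
ORFs of 170–300 codons, 3′ UTRs of 200–350 bp; paralog pairs at a target
transcript identity (default 0.90) at distinct loci; type-B alleles by
uniform substitution at a single locus (default divergence **0.08** —
inside the 85–95% detection band yet safely below the 0.95 clustering
threshold under ~1% sequencing error; the biological range runs up to
~12%), with type-B clones drawn only from the Atlantic population and at
0.4× depth (the haplotype occurs only in the mixed sympatric sample);
back-to-back single-exon pairs whose 3′ UTRs overlap on the genome
(default 60 bp); SL genes whose mature mRNA starts with a fixed 16-nt
splice-leader tag; optionally a second isoform lacking an internal 80 bp
block. Clone libraries: first-strand synthesis length geometric with
per-base termination `rt_dropoff_p` (default **0.001**), truncated at
the transcript length, so P(full-length | kept) = (1−p)^(L−m) under the
`min_insert_bp` = **700** size selection; paired reads of
Normal(600, 50) bp (clipped) with uniform substitution errors (default
**0.01**); no indel sequencing errors.

What the simulator does *not* model — and hence what passing tests do
not establish about real data: chromatogram-level quality variation and
vector contamination; indel sequencing error; RT blockage by mRNA
secondary structure (internal false cliffs); poly-A site heterogeneity;
expression-level skew across genes; non-canonical splice sites; genomic
repeats and low-complexity sequence, which would stress the exact-anchor
mapper far more than clean simulated loci do.

For cliff characterisation, end-position profiles are generated
directly: TSS-bearing clusters draw insert lengths from the geometric
model on 0.9–1.6 kb transcripts (the pile-up at the mRNA 5′ end is the
signal); truncated clusters draw uniform termination positions on
2.5–4 kb transcripts, since clusters missing their 5′ end arise from
long, under-covered mRNAs.

## Known limitations

* The greedy first-fit clusterer is order-dependent; it stands in for a
  full overlap-graph assembler and occasionally leaves marginal-overlap
  reads as singletons.
* The spliced mapper requires one exact 31-mer per exon: small exons
  (≲ 100 bp) of highly diverged (≥ 8%) reads are sometimes missed, and
  such clones then carry partial fingerprints.
* Exon fingerprinting at zero end-slop is strict: clones truncated at
  different 5′ points have different terminal intervals and will not
  group, so redundancy removal is most effective among full-length
  clones (the relevant case, since only FULL clones are picked).
* Alternative-transcript partitioning trusts only reads spanning all
  indel features deeply; shallow clusters may fail to split or may leave
  many reads unassigned to a sub-cluster.
* The cliff test's TSS estimate is the start of the steepest run, which
  sits at or 5′ of the densest termination point; it is an upper bound
  on the UTR, not a base-precise TSS call.
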