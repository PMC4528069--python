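"""Clustering, consensus, paired-end joining and back-to-back splitting."""
import collections

import numpy as np
import pytest

from fullorf import (
    End,
    LibraryParams,
    build_consensus,
    cluster_ests,
    detect_backtoback,
    join_paired_ends,
    simulate_clone_library,
    simulate_gene_set,
    split_cluster,
)
from fullorf.align import global_identity
from fullorf.model import Cluster, Placement, Strand, revcomp

from conftest import estset_from_reads, make_est, random_seq


def mutate_at_rate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestClusterEsts:
    def test_identical_copies_form_one_cluster(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 800)
        ests = estset_from_reads(
            [make_est(f"c{i}.5", seq) for i in range(10)]
        )
        clusters = cluster_ests(ests)
        assert len(clusters) == 1
        assert len(clusters[0]) == 10

    def test_threshold_separates_90pc_identical_pair(self):
        """Pair built at measured ~90% identity: split at 0.95, merged
        at 0.85 (identity verified with an independent global aligner)."""
        rng = np.random.default_rng(1)
        a = random_seq(rng, 1000)
        b = mutate_at_rate(rng, a, 0.10)
        identity = global_identity(a, b)
        assert 0.87 <= identity <= 0.93
        reads = [make_est(f"a{i}.5", a) for i in range(5)] + [
            make_est(f"b{i}.5", b) for i in range(5)
        ]
        ests = estset_from_reads(reads)
        assert len(cluster_ests(ests, identity_threshold=0.95)) == 2
        assert len(cluster_ests(ests, identity_threshold=0.85)) == 1

    def test_unrelated_genes_stay_apart(self):
        _g, specs, _t = simulate_gene_set(3, seed=2)
        ests, truth = simulate_clone_library(
            specs,
            LibraryParams(n_clones_per_gene=5, rt_dropoff_p=0,
                          error_rate=0, read_len_mean=800, read_len_sd=40,
                          seed=3),
        )
        clusters = cluster_ests(ests)
        gene_of = dict(zip(truth.clone_id, truth.gene_id))
        assert len(clusters) == 3
        for cluster in clusters:
            genes = {gene_of[e.rsplit(".", 1)[0]] for e in cluster.est_ids()}
            assert len(genes) == 1

    def test_three_prime_reads_enter_in_sense(self):
        rng = np.random.default_rng(4)
        transcript = random_seq(rng, 900)
        reads = [make_est("c0.5", transcript[:600])] + [
            make_est(f"c{i}.3", revcomp(transcript[300:]),
                     end=End.THREE_PRIME)
            for i in range(3)
        ]
        clusters = cluster_ests(estset_from_reads(reads))
        assert len(clusters) == 1
        assert all(p.strand is Strand.PLUS for p in clusters[0].placements)

    def test_every_qc_est_in_exactly_one_cluster(self, noisy_library):
        ests = noisy_library["ests"]
        clusters = cluster_ests(ests)
        placed = [e for c in clusters for e in c.est_ids()]
        assert sorted(placed) == sorted(
            e.est_id for e in ests.qc_passing()
        )

    def test_lowering_threshold_never_increases_cluster_count(self):
        _g, specs, _t = simulate_gene_set(3, seed=5, paralog_pairs=1)
        ests, _ = simulate_clone_library(
            specs,
            LibraryParams(n_clones_per_gene=4, rt_dropoff_p=0,
                          error_rate=0.01, seed=6),
        )
        counts = [
            len(cluster_ests(ests, identity_threshold=t))
            for t in (0.99, 0.95, 0.90, 0.85)
        ]
        assert counts == sorted(counts, reverse=True)


class TestConsensus:
    def test_single_est_consensus_is_that_est(self):
        seq = "ACGTACGTAA"
        clusters = cluster_ests(estset_from_reads([make_est("c1.5", seq)]))
        assert clusters[0].consensus == seq

    def test_majority_base_wins(self):
        cluster = Cluster(cluster_id="c")
        for i, seq in enumerate(["ACGTACGT", "ACGTACGT", "ACCTACGT"]):
            cluster.placements.append(
                Placement(est_id=f"e{i}", offset=0, strand=Strand.PLUS,
                          aligned_length=8)
            )
            cluster.aligned[f"e{i}"] = seq
        assert build_consensus(cluster) == "ACGTACGT"

    def test_two_two_tie_breaks_alphabetically(self):
        cluster = Cluster(cluster_id="c")
        for i, seq in enumerate(["CA", "CA", "CC", "CC"]):
            cluster.placements.append(
                Placement(est_id=f"e{i}", offset=0, strand=Strand.PLUS,
                          aligned_length=2)
            )
            cluster.aligned[f"e{i}"] = seq
        assert build_consensus(cluster)[1] == "A"

    def test_uncovered_column_emits_n(self):
        cluster = Cluster(cluster_id="c", consensus="ACGTACGT")
        cluster.placements.append(
            Placement(est_id="e0", offset=4, strand=Strand.PLUS,
                      aligned_length=4)
        )
        cluster.aligned["e0"] = "ACGT"
        assert build_consensus(cluster) == "NNNNACGT"


class TestJoinPairedEnds:
    def _two_fragment_library(self, n_shared):
        """5' reads and 3' reads of one long gene with no sequence overlap."""
        rng = np.random.default_rng(10)
        transcript = random_seq(rng, 2400)
        reads = []
        for i in range(n_shared):
            reads.append(make_est(f"c{i}.5", transcript[:700]))
            reads.append(
                make_est(f"c{i}.3", revcomp(transcript[-700:]),
                         end=End.THREE_PRIME)
            )
        return estset_from_reads(reads)

    def test_two_shared_clones_merge(self):
        ests = self._two_fragment_library(3)
        clusters = cluster_ests(ests)
        assert len(clusters) == 2
        joined = join_paired_ends(clusters, ests)
        assert len(joined) == 1
        assert len(joined[0]) == 6

    def test_one_shared_clone_does_not_merge(self):
        ests = self._two_fragment_library(1)
        clusters = cluster_ests(ests)
        assert len(join_paired_ends(clusters, ests)) == len(clusters)

    def test_chain_merges_into_single_component(self):
        """A-B and B-C links with >=2 shared clones give one component."""
        rng = np.random.default_rng(11)
        t1 = random_seq(rng, 1600)
        t2 = random_seq(rng, 1600)
        bridge = t1[-500:] + t2[:500]
        reads = []
        for i in range(2):
            reads.append(make_est(f"x{i}.5", t1[:600]))
            reads.append(
                make_est(f"x{i}.3", revcomp(bridge[:900]), end=End.THREE_PRIME)
            )
        for i in range(2):
            reads.append(make_est(f"y{i}.5", bridge[-900:]))
            reads.append(
                make_est(f"y{i}.3", revcomp(t2[-600:]), end=End.THREE_PRIME)
            )
        ests = estset_from_reads(reads)
        clusters = cluster_ests(ests)
        if len(clusters) == 1:
            pytest.skip("fragments co-assembled; no join needed")
        joined = join_paired_ends(clusters, ests)
        sizes = sorted(len(c) for c in joined)
        assert sizes[-1] == 8


@pytest.fixture(scope="module")
def cocluster():
    genome, specs, _ = simulate_gene_set(2, seed=5, backtoback_pairs=1)
    ests, truth = simulate_clone_library(
        specs,
        LibraryParams(n_clones_per_gene=12, rt_dropoff_p=0,
                      error_rate=0.003, seed=6),
    )
    clusters = join_paired_ends(cluster_ests(ests), ests)
    cluster = max(clusters, key=len)
    gene_of = dict(zip(truth.clone_id, truth.gene_id))
    return specs, ests, cluster, gene_of


class TestBacktobackSplit:
    def test_decision_breakpoint_in_overlap_region(self, cocluster):
        specs, ests, cluster, gene_of = cocluster
        genes = {gene_of[e.rsplit(".", 1)[0]] for e in cluster.est_ids()}
        assert genes == {"g001", "g002"}  # the pair really co-clustered
        decision = detect_backtoback(cluster)
        assert decision is not None
        assert (
            decision.upstream_orf_span[1]
            <= decision.breakpoint
            <= decision.downstream_orf_span[0]
        )

    def test_split_memberships_match_truth(self, cocluster):
        specs, ests, cluster, gene_of = cocluster
        decision = detect_backtoback(cluster)
        up, down = split_cluster(cluster, decision, ests)
        up_genes = {gene_of[e.rsplit(".", 1)[0]] for e in up.est_ids()}
        down_genes = {gene_of[e.rsplit(".", 1)[0]] for e in down.est_ids()}
        assert up_genes == {"g001"} and down_genes == {"g002"}
        assert len(up) + len(down) == len(cluster)

    def test_single_gene_cluster_yields_no_decision(self, clean_library):
        clusters = cluster_ests(clean_library["ests"])
        for cluster in clusters:
            assert detect_backtoback(cluster) is None

    def test_same_strand_orfs_do_not_split(self):
        """Operon-like same-strand ORFs: orientation never switches."""
        rng = np.random.default_rng(8)
        from fullorf.simulate import _random_orf

        consensus = (
            random_seq(rng, 30) + _random_orf(rng, 120)
            + random_seq(rng, 60) + _random_orf(rng, 120)
            + random_seq(rng, 30)
        )
        cluster = Cluster(cluster_id="c", consensus=consensus)
        for i in range(6):
            cluster.placements.append(
                Placement(est_id=f"e{i}.5", offset=0, strand=Strand.PLUS,
                          aligned_length=len(consensus))
            )
            cluster.aligned[f"e{i}.5"] = consensus
        assert detect_backtoback(cluster) is None

    def test_tie_placement_stays_upstream(self):
        consensus = "A" * 200
        cluster = Cluster(cluster_id="c", consensus=consensus)
        specs = [
            ("up", 0, 100, Strand.PLUS),
            ("tie", 50, 100, Strand.PLUS),  # exactly 50% downstream of 100
            ("down", 100, 100, Strand.MINUS),
        ]
        for name, offset, length, strand in specs:
            cluster.placements.append(
                Placement(est_id=name, offset=offset, strand=strand,
                          aligned_length=length)
            )
            cluster.aligned[name] = "A" * length
        from fullorf.model import SplitDecision

        decision = SplitDecision(
            cluster_id="c", breakpoint=100, upstream_orf_span=(0, 100),
            downstream_orf_span=(100, 200),
            upstream_mean_orientation=1.0,
            downstream_mean_orientation=-1.0,
        )
        ests = estset_from_reads(
            [make_est(n, "A" * 100) for n, *_ in specs]
        )
        up, down = split_cluster(cluster, decision, ests)
        assert {p.est_id for p in up.placements} == {"up", "tie"}
        assert {p.est_id for p in down.placements} == {"down"}

    def test_breakpoint_outside_consensus_is_error(self):
        from fullorf.model import SplitDecision

        cluster = Cluster(cluster_id="c", consensus="A" * 50)
        cluster.placements.append(
            Placement(est_id="e", offset=0, strand=Strand.PLUS,
                      aligned_length=50)
        )
        cluster.aligned["e"] = "A" * 50
        decision = SplitDecision(
            cluster_id="c", breakpoint=80, upstream_orf_span=(0, 10),
            downstream_orf_span=(90, 100),
            upstream_mean_orientation=1.0,
            downstream_mean_orientation=-1.0,
        )
        ests = estset_from_reads([make_est("e", "A" * 50)])
        with pytest.raises(ValueError):
            split_cluster(cluster, decision, ests)
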