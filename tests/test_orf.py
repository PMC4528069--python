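"""ORF finding, 5'/3' completeness evidence, SL matching, P formula."""
import numpy as np
import pytest

from fullorf import (
    LibraryParams,
    cluster_ests,
    find_orf,
    join_paired_ends,
    match_sl_reads,
    simulate_clone_library,
    simulate_gene_set,
)
from fullorf.model import (
    CliffResult,
    Cluster,
    End,
    FivePrimeEvidence,
    NTermPrediction,
    Placement,
    ProteinHit,
    Strand,
)
from fullorf.orf import (
    classify_five_prime,
    classify_three_prime,
    conserved_nterm_predictions,
    predict_start_from_ortholog,
    sl_flagged_clusters,
    ThreePrimeEvidence,
)

from conftest import estset_from_reads, make_est, random_seq


class TestFindOrf:
    def test_hand_translated_example(self):
        # ATG at 2, in-frame TAG ends at 14
        orf = find_orf("AAATGAAACCCTAG", min_len=6)
        assert (orf.orf_start, orf.orf_end) == (2, 14)
        assert orf.strand is Strand.PLUS

    def test_simulated_consensus_recovers_truth_orf(self, clean_library):
        ests = clean_library["ests"]
        specs = {s.gene_id: s for s in clean_library["specs"]}
        truth = clean_library["clone_truth"]
        gene_of = dict(zip(truth.clone_id, truth.gene_id))
        clusters = join_paired_ends(cluster_ests(ests), ests)
        assert len(clusters) == len(specs)
        for cluster in clusters:
            gene = gene_of[cluster.est_ids()[0].rsplit(".", 1)[0]]
            spec = specs[gene]
            orf = find_orf(cluster.consensus, cluster_id=cluster.cluster_id)
            assert (orf.orf_start, orf.orf_end) == (
                spec.orf_start, spec.orf_end
            )

    def test_all_n_consensus_is_noncoding(self):
        assert find_orf("N" * 300) is None

    def test_protein_hit_steers_selection(self):
        rng = np.random.default_rng(0)
        from fullorf.simulate import _random_orf

        short = _random_orf(rng, 30)   # 90 bp
        long = _random_orf(rng, 60)    # 180 bp
        consensus = "CC" + short + "TTT" + long + "AA"
        hit = ProteinHit(
            cluster_id="c", strand=Strand.PLUS,
            query_start=3, query_end=2 + len(short),
            subject_start=1, subject_end=30, species="fish", evalue=1e-30,
        )
        without = find_orf(consensus, cluster_id="c")
        with_hit = find_orf(consensus, [hit], cluster_id="c")
        assert without.orf_end - without.orf_start == len(long)
        assert (with_hit.orf_start, with_hit.orf_end) == (2, 2 + len(short))


class TestFivePrime:
    def _orf(self, start=30, end=330):
        from fullorf.model import OrfAnnotation

        return OrfAnnotation(cluster_id="c", orf_start=start, orf_end=end,
                             frame=0, strand=Strand.PLUS)

    def test_upstream_inframe_stop(self):
        rng = np.random.default_rng(1)
        consensus = (
            random_seq(rng, 21) + "TAA" + "CCCCCC" + "ATG" + "A" * 300
        )
        orf = classify_five_prime(self._orf(start=30), consensus)
        assert FivePrimeEvidence.UPSTREAM_STOP in orf.five_prime_evidence
        assert orf.five_prime_complete

    def test_cliff_evidence_requires_tss_at_or_upstream(self):
        consensus = "C" * 400
        passing = CliffResult(cluster_id="c", Z=20, eligible=True,
                              tss_estimate=10, score=50.0, passes=True)
        orf = classify_five_prime(self._orf(), consensus, cliff_result=passing)
        assert orf.five_prime_evidence == {FivePrimeEvidence.CLIFF}
        downstream = CliffResult(cluster_id="c", Z=20, eligible=True,
                                 tss_estimate=200, score=50.0, passes=True)
        orf2 = classify_five_prime(self._orf(), consensus,
                                   cliff_result=downstream)
        assert not orf2.five_prime_complete

    def test_sl_flag_alone_completes(self):
        orf = classify_five_prime(self._orf(), "C" * 400, sl_flag=True)
        assert orf.five_prime_evidence == {FivePrimeEvidence.SL}

    def test_conserved_ortholog_start_matches_atg(self):
        pred = NTermPrediction(cluster_id="c", species="fish", P=31,
                               conserved=True)
        orf = classify_five_prime(self._orf(start=30), "C" * 400,
                                  nterm_predictions=[pred])
        assert orf.five_prime_evidence == {FivePrimeEvidence.ORTHOLOG_P}

    def test_all_applicable_evidence_recorded(self):
        rng = np.random.default_rng(2)
        consensus = random_seq(rng, 21) + "TAA" + "CCCCCC" + "C" * 370
        cliff = CliffResult(cluster_id="c", Z=20, eligible=True,
                            tss_estimate=0, score=60.0, passes=True)
        orf = classify_five_prime(self._orf(start=30), consensus,
                                  cliff_result=cliff, sl_flag=True)
        assert orf.five_prime_evidence >= {
            FivePrimeEvidence.UPSTREAM_STOP,
            FivePrimeEvidence.CLIFF,
            FivePrimeEvidence.SL,
        }


class TestSlMatching:
    def test_thirty_base_prefix_match(self):
        rng = np.random.default_rng(3)
        body = random_seq(rng, 200)
        ests = estset_from_reads([make_est("c1.5", body)])
        assert match_sl_reads({"r1": body[:30]}, ests) == {"c1.5"}

    def test_nineteen_base_agreement_is_rejected(self):
        rng = np.random.default_rng(4)
        body = random_seq(rng, 200)
        probe = body[:19] + ("A" if body[19] != "A" else "C") + body[20:60]
        ests = estset_from_reads([make_est("c1.5", body)])
        assert match_sl_reads({"r1": probe}, ests) == set()

    def test_simulator_sl_genes_flag_exactly_their_clusters(self):
        from fullorf.simulate import simulate_sl_reads

        _g, specs, _t = simulate_gene_set(4, seed=6, sl_genes=2)
        ests, truth = simulate_clone_library(
            specs,
            LibraryParams(n_clones_per_gene=6, rt_dropoff_p=0,
                          error_rate=0, seed=7),
        )
        clusters = join_paired_ends(cluster_ests(ests), ests)
        supported = match_sl_reads(simulate_sl_reads(specs), ests)
        flagged = sl_flagged_clusters(clusters, supported)
        gene_of = dict(zip(truth.clone_id, truth.gene_id))
        sl_genes = {s.gene_id for s in specs if s.sl_spliced}
        expected = {
            c.cluster_id
            for c in clusters
            if gene_of[c.est_ids()[0].rsplit(".", 1)[0]] in sl_genes
        }
        assert flagged == expected


class TestThreePrime:
    def test_stop_codon_on_consensus(self, clean_library):
        ests = clean_library["ests"]
        clusters = join_paired_ends(cluster_ests(ests), ests)
        cluster = clusters[0]
        orf = find_orf(cluster.consensus, cluster_id=cluster.cluster_id)
        out = classify_three_prime(orf, cluster, ests=ests)
        assert out.three_prime_evidence == {ThreePrimeEvidence.STOP_CODON}
        assert out.three_prime_complete

    def test_allframe_stop_window_downstream_of_coding(self):
        rng = np.random.default_rng(5)
        # 150 bp UTR-like segment with stops in all three frames
        utr = list(random_seq(rng, 150))
        for frame, pos in ((0, 30), (1, 61), (2, 92)):
            utr[pos : pos + 3] = "TAA"
            assert pos % 3 == frame
        consensus = "ATG" + "GCA" * 40 + "".join(utr)  # ORF runs to edge of CDS
        cluster = Cluster(cluster_id="c", consensus=consensus)
        for i in range(2):
            cluster.placements.append(
                Placement(est_id=f"e{i}", offset=0, strand=Strand.PLUS,
                          aligned_length=len(consensus))
            )
            cluster.aligned[f"e{i}"] = consensus
        from fullorf.model import OrfAnnotation

        orf = OrfAnnotation(cluster_id="c", orf_start=0, orf_end=123,
                            frame=0, strand=Strand.PLUS)
        out = classify_three_prime(orf, cluster)
        assert ThreePrimeEvidence.UTR3_ALLFRAME_STOPS in out.three_prime_evidence
        assert out.three_prime_complete

    def test_orf_to_consensus_edge_is_never_complete(self):
        consensus = "ATG" + "GCA" * 50  # no stop, runs to the edge
        cluster = Cluster(cluster_id="c", consensus=consensus)
        cluster.placements.append(
            Placement(est_id="e", offset=0, strand=Strand.PLUS,
                      aligned_length=len(consensus))
        )
        cluster.aligned["e"] = consensus
        from fullorf.model import OrfAnnotation

        orf = OrfAnnotation(cluster_id="c", orf_start=0,
                            orf_end=len(consensus), frame=0,
                            strand=Strand.PLUS)
        out = classify_three_prime(orf, cluster)
        assert not out.three_prime_complete

    def test_three_prime_fragment_cluster_labelled(self):
        reads = [
            make_est(f"c{i}.3", "GCAA" * 50, end=End.THREE_PRIME)
            for i in range(8)
        ] + [make_est(f"d{i}.5", "GCAA" * 50) for i in range(2)]
        ests = estset_from_reads(reads)
        cluster = Cluster(cluster_id="c", consensus="GCAA" * 50)
        for est in reads:
            cluster.placements.append(
                Placement(est_id=est.est_id, offset=0, strand=Strand.PLUS,
                          aligned_length=200)
            )
            cluster.aligned[est.est_id] = est.sequence
        out = classify_three_prime(None, cluster, ests=ests)
        assert out.three_prime_evidence == {
            ThreePrimeEvidence.UTR3_EST_FRACTION
        }


class TestNTermPrediction:
    @pytest.mark.parametrize(
        "query_start,subject_start,expected",
        [(100, 1, 100), (100, 11, 70), (10, 11, -20)],
    )
    def test_p_formula(self, query_start, subject_start, expected):
        hit = ProteinHit(
            cluster_id="c", strand=Strand.PLUS,
            query_start=query_start, query_end=query_start + 300,
            subject_start=subject_start, subject_end=subject_start + 100,
            species="fish", evalue=1e-20,
        )
        pred = predict_start_from_ortholog(hit)
        assert pred.P == expected
        assert pred.upstream_of_contig == (expected <= 0)

    def test_conserved_flag_requires_cross_species_agreement(self):
        def hit(species, qs, ss):
            return ProteinHit(
                cluster_id="c", strand=Strand.PLUS, query_start=qs,
                query_end=qs + 300, subject_start=ss,
                subject_end=ss + 100, species=species, evalue=1e-20,
            )

        agreeing = conserved_nterm_predictions(
            [hit("fish", 100, 1), hit("mouse", 106, 3)]
        )
        assert all(p.conserved for p in agreeing["c"])
        disagreeing = conserved_nterm_predictions(
            [hit("fish", 100, 1), hit("mouse", 100, 3)]
        )
        assert not any(p.conserved for p in disagreeing["c"])
        single = conserved_nterm_predictions([hit("fish", 100, 1)])
        assert not any(p.conserved for p in single["c"])
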