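import numpy as np
import pytest

import cistopo as ct
from cistopo import ocr
from cistopo.model import CoverageTrack, Gene, Genome, GenomicInterval, Peak
from cistopo.permutation import ShiftConstraint
from cistopo.tf import TFPeakSet

import _oracles


def peak(start, end, chrom="chr1", name="", q=5.0):
    return Peak(GenomicInterval(chrom, start, end), (start + end) // 2, 1.0, q, name)


class TestReplicatePolicy:
    def test_intersection_of_replicates(self):
        rep1 = [peak(0, 100), peak(1_000, 1_100), peak(5_000, 5_100)]
        rep2 = [peak(50, 150), peak(5_050, 5_120)]
        tf = TFPeakSet.from_replicates("KN1", rep1, rep2)
        assert [p.start for p in tf.peaks] == [0, 5_000]
        assert tf.replicate_policy_applied

    def test_single_replicate_kept_with_caveat(self, caplog):
        tf = TFPeakSet.from_replicates("TB1", [peak(0, 100)], None)
        assert len(tf.peaks) == 1 and not tf.replicate_policy_applied


class TestOCROverlap:
    def test_fraction_counts(self, toy_genome):
        loocrs = [peak(1_000 * i, 1_000 * i + 200) for i in range(9)]
        tf = TFPeakSet(
            "KN1",
            tuple(peak(1_000 * i + 50, 1_000 * i + 150) for i in range(9))
            + (peak(100_000, 100_100),),
        )
        res = ct.tfbs_ocr_overlap(
            tf, loocrs, [], ShiftConstraint(toy_genome), n_perm=5, seed=0
        )
        assert res["LoOCR"].observed == pytest.approx(0.9)
        assert res["either"].observed == pytest.approx(0.9)
        assert res["dOCR"].observed == 0.0

    def test_empty_tf_set_errors(self, toy_genome):
        with pytest.raises(ValueError):
            ct.tfbs_ocr_overlap(
                TFPeakSet("X", ()), [], [], ShiftConstraint(toy_genome)
            )

    def test_planted_overlap_enriched(self, rng):
        genome = Genome({"chr1": 2_000_000})
        ocrs = [
            peak(int(s), int(s) + 500)
            for s in rng.choice(np.arange(0, 1_990_000, 5_000), 200, replace=False)
        ]
        sites = []
        for i in range(100):
            if i < 90:
                host = ocrs[int(rng.integers(0, len(ocrs)))]
                s = int(rng.integers(host.start, host.end - 100))
            else:
                s = int(rng.integers(0, 1_999_000))
            sites.append(peak(s, s + 100))
        tf = TFPeakSet("KN1", tuple(sites))
        res = ct.tfbs_ocr_overlap(tf, ocrs, [], ShiftConstraint(genome), n_perm=100, seed=4)
        assert res["LoOCR"].observed >= 0.85
        assert res["LoOCR"].p_empirical <= 0.01


class TestSignalRankConcordance:
    def _ocrs(self, n, rng):
        out = []
        for i in range(n):
            s = 5_000 * i
            out.append(peak(s, s + 400, q=float(n - i)))  # rank = index
        return out

    def test_monotone_signal_gives_rho_near_one(self, rng):
        ocrs = self._ocrs(200, rng)
        tf_sites = [
            Peak(GenomicInterval("chr1", p.summit - 50, p.summit + 50), p.summit, float(p.qvalue))
            for p in ocrs
        ]
        res = ct.signal_rank_concordance(ocrs, tf_sites)
        assert res.spearman_rho >= 0.99

    def test_reversed_signal_gives_rho_near_minus_one(self, rng):
        ocrs = self._ocrs(200, rng)
        tf_sites = [
            Peak(GenomicInterval("chr1", p.summit - 50, p.summit + 50), p.summit, 1000.0 - float(p.qvalue))
            for p in ocrs
        ]
        res = ct.signal_rank_concordance(ocrs, tf_sites)
        assert res.spearman_rho <= -0.99

    def test_independent_signal_rho_centred_on_zero(self):
        rhos = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            ocrs = [peak(5_000 * i, 5_000 * i + 400, q=float(r.uniform(1, 20))) for i in range(100)]
            tf_sites = [
                Peak(
                    GenomicInterval("chr1", p.summit - 50, p.summit + 50),
                    p.summit,
                    float(r.uniform(0, 10)),
                )
                for p in ocrs
            ]
            rhos.append(ct.signal_rank_concordance(ocrs, tf_sites).spearman_rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_constant_signal_undefined(self):
        ocrs = [peak(0, 400, q=3.0), peak(5_000, 5_400, q=9.0)]
        res = ct.signal_rank_concordance(ocrs, [])
        assert np.isnan(res.spearman_rho)

    def test_coverage_track_aggregation(self):
        ocrs = [peak(10_000, 10_400, q=2.0)]
        track = CoverageTrack([("chr1", 10_100, 10_200, 3.0)])
        res = ct.signal_rank_concordance(ocrs, track)
        assert res.rank_bin_matrix[0] == pytest.approx(300.0)


class TestCobinding:
    def test_single_overlap_locus(self):
        a = TFPeakSet("A", (peak(0, 10),))
        b = TFPeakSet("B", (peak(5, 15),))
        n, _ = ct.cobinding(a, b, [])
        assert n == 1

    def test_disjoint_sets_have_zero_loci_but_shared_targets(self):
        gene = Gene("gX", GenomicInterval("chr1", 10_000, 12_000, "+"))
        a = TFPeakSet("A", (peak(9_000, 9_100),))
        b = TFPeakSet("B", (peak(11_000, 11_100),))
        n, common = ct.cobinding(a, b, [gene])
        assert n == 0 and common == {"gX"}

    def test_symmetry_and_brute_force(self, toy_genome, rng):
        a = TFPeakSet(
            "A", tuple(Peak(iv, iv.midpoint) for iv in _oracles.random_intervals(rng, toy_genome, 80, 50, 400))
        )
        b = TFPeakSet(
            "B", tuple(Peak(iv, iv.midpoint) for iv in _oracles.random_intervals(rng, toy_genome, 80, 50, 400))
        )
        n_ab, t_ab = ct.cobinding(a, b, [])
        n_ba, t_ba = ct.cobinding(b, a, [])
        assert n_ab == n_ba and t_ab == t_ba
        # oracle: connected components over >=1 bp overlaps with both TFs
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(("a", i) for i in range(len(a.peaks)))
        g.add_nodes_from(("b", j) for j in range(len(b.peaks)))
        for tag1, set1 in (("a", a.peaks), ("b", b.peaks)):
            for tag2, set2 in (("a", a.peaks), ("b", b.peaks)):
                for i, p in enumerate(set1):
                    for j, q in enumerate(set2):
                        if (tag1, i) != (tag2, j) and _oracles.overlaps(p.interval, q.interval):
                            g.add_edge((tag1, i), (tag2, j))
        n_expected = sum(
            1
            for comp in nx.connected_components(g)
            if {t for t, _ in comp} == {"a", "b"}
        )
        assert n_ab == n_expected


class TestNetwork:
    def _classified_loocrs(self, genes, rng):
        peaks = []
        for g in genes:
            s = g.interval.start - 500
            peaks.append(peak(s, s + 300, name=f"loocr_{g.id}"))
        return ct.classify_ocrs(peaks, genes)

    def test_self_edge_detected(self):
        gene = Gene("gTF", GenomicInterval("chr1", 10_000, 12_000, "+"))
        loocrs = self._classified_loocrs([gene], None)
        tf = TFPeakSet("ZIM16", (peak(9_550, 9_650),), gene_id="gTF")
        edges, coverage = ct.build_network([tf], {"gTF"}, loocrs)
        assert edges[0].self_edge and coverage == 1.0

    def test_planted_half_coverage(self, rng):
        genes = [
            Gene(f"g{i}", GenomicInterval("chr1", 10_000 + 10_000 * i, 12_000 + 10_000 * i, "+"))
            for i in range(200)
        ]
        loocrs = self._classified_loocrs(genes, rng)
        covered = [g for g in genes[:100]]
        tfs = []
        for t in range(4):
            sites = tuple(
                peak(g.interval.start - 450, g.interval.start - 350)
                for g in covered[t::4]
            )
            tfs.append(TFPeakSet(f"TF{t}", sites))
        edges, coverage = ct.build_network(tfs, {g.id for g in genes}, loocrs)
        assert coverage == pytest.approx(0.5, abs=0.01)

    def test_no_peaks_no_edges(self):
        edges, coverage = ct.build_network([TFPeakSet("A", ())], {"g1"}, [])
        assert edges == [] and coverage == 0.0

    def test_edge_count_monotone_in_peak_count(self):
        genes = [
            Gene(f"g{i}", GenomicInterval("chr1", 10_000 + 10_000 * i, 12_000 + 10_000 * i, "+"))
            for i in range(10)
        ]
        loocrs = self._classified_loocrs(genes, None)
        sites = [peak(g.interval.start - 450, g.interval.start - 350) for g in genes]
        prev = 0
        for k in (2, 5, 10):
            edges, _ = ct.build_network(
                [TFPeakSet("A", tuple(sites[:k]))], {g.id for g in genes}, loocrs
            )
            assert len(edges) >= prev
            prev = len(edges)


class TestAnchorClasses:
    def _links(self, genes, docr_start):
        docr = peak(docr_start, docr_start + 400, name="d1")
        loops = [
            ct.Loop(
                GenomicInterval("chr1", docr_start - 100, docr_start + 500),
                GenomicInterval("chr1", genes[0].interval.start - 2_000, genes[0].interval.start + 2_000),
            )
        ]
        classified = ct.classify_loops(loops, genes)
        links, _, _ = ct.docr_gene_links(classified, [docr])
        return links

    def test_classes_and_normalisation(self):
        genes = [Gene("gX", GenomicInterval("chr1", 100_000, 102_000, "+"))]
        links = self._links(genes, 20_000)
        loocr = peak(99_500, 99_800)
        joint_tf = TFPeakSet("J", (peak(20_100, 20_200), peak(99_600, 99_700)))
        docr_tf = TFPeakSet("D", (peak(20_100, 20_200),))
        local_tf = TFPeakSet("L", (peak(99_600, 99_700),))
        for tf, expect in ((joint_tf, "Joint"), (docr_tf, "dOCR_only"), (local_tf, "Local_only")):
            pct = ct.tf_anchor_classes(tf, links, [loocr])
            assert pct[expect] == pytest.approx(100.0)
            assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)
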