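import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cistopo as ct
from cistopo import loops as lp
from cistopo.differential import DEGCall
from cistopo.model import ExpressionTable, Gene, GenomicInterval, Loop, Peak, SNPRecord

import _oracles


def gene(gid, start, chrom="chr1", strand="+", length=2_000):
    return Gene(gid, GenomicInterval(chrom, start, start + length, strand))


def anchor(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def docr(start, width=400, chrom="chr1"):
    iv = GenomicInterval(chrom, start, start + width)
    return Peak(iv, iv.midpoint, name=f"d{start}")


class TestClassifyLoops:
    def test_anchor_states(self):
        genes = [gene("gA", 50_000), gene("gB", 150_000)]
        loops = [
            Loop(anchor(48_000, 52_000), anchor(148_000, 152_000)),
            Loop(anchor(48_000, 52_000), anchor(100_000, 101_000)),
            Loop(anchor(10_000, 11_000), anchor(100_000, 101_000)),
        ]
        out = ct.classify_loops(loops, genes)
        assert [c.klass for c in out] == [
            "gene_gene",
            "intergenic_gene",
            "intergenic_intergenic",
        ]
        assert out[1].genic_anchor_genes == ("gA",)
        assert out[1].intergenic_anchor.start == 100_000

    def test_partition_and_brute_force(self, toy_genome, rng):
        genes = [
            Gene(f"g{i}", iv)
            for i, iv in enumerate(
                _oracles.random_intervals(rng, toy_genome, 30, 500, 4000, stranded=True)
            )
        ]
        loops = []
        for _ in range(100):
            a, b = _oracles.random_intervals(rng, ct.Genome({"chr1": 200_000}), 2, 500, 3000)
            loops.append(Loop(a, b))
        out = ct.classify_loops(loops, genes)
        assert len(out) == 100
        from cistopo.ocr import local_window

        windows = [local_window(x).interval for x in genes]
        for c in out:
            a_hit = {genes[j].id for j in _oracles.assign_all_pairs([c.loop.anchor_a], windows)[0]}
            b_hit = {genes[j].id for j in _oracles.assign_all_pairs([c.loop.anchor_b], windows)[0]}
            assert set(c.genes_a) == a_hit and set(c.genes_b) == b_hit
            expect = (
                "gene_gene"
                if a_hit and b_hit
                else ("intergenic_intergenic" if not a_hit and not b_hit else "intergenic_gene")
            )
            assert c.klass == expect

    def test_body_definition_is_stricter(self):
        genes = [gene("gA", 50_000)]
        loops = [Loop(anchor(47_500, 48_500), anchor(100_000, 101_000))]
        by_window = ct.classify_loops(loops, genes, genic_definition="window")
        by_body = ct.classify_loops(loops, genes, genic_definition="body")
        assert by_window[0].klass == "intergenic_gene"
        assert by_body[0].klass == "intergenic_intergenic"


class TestDOCRGeneLinks:
    def test_links_fraction_and_hubs(self):
        genes = [gene("gA", 50_000), gene("gB", 150_000), gene("gC", 90_000)]
        d1 = docr(10_000)
        loops = [
            Loop(anchor(9_900, 10_500), anchor(48_000, 52_000)),  # d1 -> gA
            Loop(anchor(9_900, 10_500), anchor(148_000, 152_000)),  # d1 -> gB
            Loop(anchor(9_900, 10_500), anchor(88_000, 92_000)),  # d1 -> gC
            Loop(anchor(30_000, 31_000), anchor(48_000, 52_000)),  # no dOCR
        ]
        classified = ct.classify_loops(loops, genes)
        links, fraction, hubs = ct.docr_gene_links(classified, [d1])
        assert len(links) == 3 and fraction == pytest.approx(0.75)
        assert len(hubs) == 1 and hubs.iloc[0]["n_targets"] == 3

    def test_no_docrs_gives_zero(self):
        genes = [gene("gA", 50_000)]
        loops = [Loop(anchor(10_000, 11_000), anchor(48_000, 52_000))]
        classified = ct.classify_loops(loops, genes)
        _, fraction, _ = ct.docr_gene_links(classified, [])
        assert fraction == 0.0


def expr_table(fpkm: dict[str, float]) -> ExpressionTable:
    return ExpressionTable(
        pd.DataFrame({"s1": pd.Series(fpkm), "s2": pd.Series(fpkm)})
    )


class TestLoopsPerGene:
    def test_distinct_loop_count(self):
        genes = [gene("gA", 50_000)]
        loops = [
            Loop(anchor(48_000, 52_000), anchor(100_000, 101_000)),
            Loop(anchor(48_000, 52_000), anchor(120_000, 121_000)),
            Loop(anchor(10_000, 11_000), anchor(47_500, 49_000)),
        ]
        classified = ct.classify_loops(loops, genes)
        counts, summary = ct.loops_per_gene(classified, genes, expr_table({"gA": 1.0}))
        assert counts["gA"] == 3

    def test_planted_expression_scaling(self, rng):
        genes = []
        loops = []
        fpkm = {}
        for i in range(150):
            start = 50_000 + 50_000 * i
            gid = f"g{i}"
            genes.append(gene(gid, start))
            n_loops = int(rng.integers(0, 5))
            for k in range(n_loops):
                loops.append(
                    Loop(
                        anchor(start - 2_000, start + 2_000),
                        anchor(start + 10_000 + 3_000 * k, start + 11_000 + 3_000 * k),
                    )
                )
            fpkm[gid] = float((1 + n_loops) * 10 * rng.lognormal(0, 0.2))
        classified = ct.classify_loops(loops, genes)
        counts, summary = ct.loops_per_gene(classified, genes, expr_table(fpkm))
        assert summary.attrs["spearman_rho"] > 0.5
        assert summary.attrs["spearman_p"] < 1e-4


class TestExpressionByLoopClass:
    def _setup(self, rng, boost=3.0):
        genes, loops, docrs, fpkm = [], [], [], {}
        for i in range(600):
            start = 50_000 + 50_000 * i
            gid = f"g{i}"
            genes.append(gene(gid, start))
            mode = i % 3
            base = float(rng.lognormal(np.log(10), 0.4))
            if mode == 0:  # dOCR-looped
                docrs.append(docr(start - 10_000))
                loops.append(
                    Loop(anchor(start - 10_100, start - 9_500), anchor(start - 2_000, start + 2_000))
                )
                fpkm[gid] = base * boost
            elif mode == 1:  # gene-gene looped
                loops.append(
                    Loop(anchor(start - 2_000, start + 2_000), anchor(start + 500, start + 1_500))
                )
                fpkm[gid] = base
            else:
                fpkm[gid] = base
        classified = ct.classify_loops(loops, genes)
        links, _, _ = ct.docr_gene_links(classified, docrs)
        return genes, classified, links, expr_table(fpkm)

    def test_priority_and_planted_difference(self, rng):
        genes, classified, links, expr = self._setup(rng)
        groups, summary = ct.expression_by_loop_class(genes, links, classified, expr)
        from collections import Counter

        c = Counter(groups.values())
        assert c["docr_looped"] == 200 and c["other_looped"] == 200 and c["no_loop"] == 200
        assert summary.attrs["p_docr_vs_noloop"] < 1e-4

    def test_all_loopless_degenerate(self):
        genes = [gene("gA", 50_000)]
        groups, summary = ct.expression_by_loop_class(genes, [], [], expr_table({"gA": 1.0}))
        assert groups == {"gA": "no_loop"}
        assert np.isnan(summary.attrs["p_docr_vs_noloop"])


class TestActiveDOCRTargetEnrichment:
    def test_fisher_matches_hypergeometric_oracle(self):
        # a=30,b=70 active vs a=50,b=950 background
        degs = [DEGCall(f"e{i}", "ear", 3.0, 1e-4) for i in range(80)]
        degs += [DEGCall(f"n{i}", "none", 1.0, 0.5) for i in range(1020)]
        links = []
        active_idx = {"ear": list(range(100))}
        genes_active = [f"e{i}" for i in range(30)] + [f"n{i}" for i in range(70)]
        genes_bg_only = [f"e{i}" for i in range(30, 50)] + [f"n{i}" for i in range(70, 950)]
        classified = None
        for j, gid in enumerate(genes_active + genes_bg_only):
            iv_a = GenomicInterval("chr1", 1_000 * j, 1_000 * j + 500)
            cl = lp.ClassifiedLoop(
                Loop(iv_a, GenomicInterval("chr1", 1_000 * j + 600, 1_000 * j + 900)),
                lp.INTERGENIC_GENE,
                (),
                (gid,),
            )
            links.append(lp.DOCRGeneLink(cl, (j,), (gid,)))
        out = ct.active_docr_target_enrichment(active_idx, links, degs)
        row = out[out.tissue == "ear"].iloc[0]
        assert (row.a, row.b, row.bg_a, row.bg_b) == (30, 70, 50, 950)
        expected = stats.fisher_exact([[30, 70], [50, 950]], alternative="greater")[1]
        assert row.fisher_p == pytest.approx(expected)
        assert expected < 1e-10

    def test_empty_active_set_warns_no_test(self):
        out = ct.active_docr_target_enrichment({"ear": []}, [], [])
        assert out.iloc[0].fisher_p == 1.0


class TestClassifySNPs:
    def test_margin_rule(self):
        genes = [gene("gA", 50_000)]
        snps = [
            SNPRecord("chr1", 55_500, "s1", "EL"),  # 3.5 kb beyond gene end
            SNPRecord("chr1", 51_000, "s2", "EL"),  # inside gene body
            SNPRecord("chr1", 48_000, "s3", "EL"),  # within 3 kb upstream margin
        ]
        out = ct.classify_snps(snps, genes)
        assert [s.locality for s in out] == [
            "intergenic",
            "genic_or_proximal",
            "genic_or_proximal",
        ]

    def test_matches_brute_force(self, toy_genome, rng):
        genes = [
            Gene(f"g{i}", iv)
            for i, iv in enumerate(
                _oracles.random_intervals(rng, toy_genome, 25, 500, 4000, stranded=True)
            )
        ]
        snps = [
            SNPRecord(iv.chrom, iv.start, f"s{i}", "EL")
            for i, iv in enumerate(_oracles.random_intervals(rng, toy_genome, 300, 1, 1))
        ]
        out = ct.classify_snps(snps, genes)
        padded = [
            GenomicInterval(g.chrom, max(0, g.interval.start - 3_000), g.interval.end + 3_000)
            for g in genes
        ]
        for s in out:
            inside = any(p.chrom == s.chrom and p.start <= s.pos < p.end for p in padded)
            assert s.locality == ("genic_or_proximal" if inside else "intergenic")


class TestSNPLoopLink:
    def _classified(self):
        genes = [gene("gA", 150_000)]
        loops = [Loop(anchor(50_000, 51_000), anchor(148_000, 152_000))]
        return genes, ct.classify_loops(loops, genes)

    def test_window_reach(self):
        genes, classified = self._classified()
        near = SNPRecord("chr1", 49_000 - 1_000, "s1", "EL", locality="intergenic")
        far = SNPRecord("chr1", 50_000 - 3_000, "s2", "EL", locality="intergenic")
        links, _ = ct.snp_loop_link([near, far], classified, [], window=5_000)
        assert [l.snp.id for l in links] == ["s1"]
        assert links[0].candidate_genes == ("gA",)

    def test_monotone_in_window(self):
        genes, classified = self._classified()
        snp = SNPRecord("chr1", 44_000, "s1", "EL", locality="intergenic")
        linked = []
        for window in (2_000, 8_000, 16_000, 30_000):
            links, _ = ct.snp_loop_link([snp], classified, [], window=window)
            linked.append(len(links))
        assert linked == sorted(linked)

    def test_in_docr_flags(self):
        genes, classified = self._classified()
        inside = SNPRecord("chr1", 70_100, "s1", "EL", locality="intergenic")
        outside = SNPRecord("chr1", 80_000, "s2", "EL", locality="intergenic")
        _, flags = ct.snp_loop_link([inside, outside], classified, [docr(70_000)])
        assert flags.tolist() == [True, False]

    def test_unclassified_snp_rejected(self):
        genes, classified = self._classified()
        with pytest.raises(ValueError):
            ct.snp_loop_link([SNPRecord("chr1", 1, "s", "EL")], classified, [])
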