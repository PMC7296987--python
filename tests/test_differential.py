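import numpy as np
import pandas as pd
import pytest

import cistopo as ct
from cistopo import differential
from cistopo.model import ExpressionTable, Gene, GenomicInterval, Peak

import _oracles


def table(rows, samples, qvalue=None):
    df = pd.DataFrame(rows, columns=samples)
    q = pd.Series(qvalue) if qvalue is not None else None
    return ExpressionTable(df, qvalue=q)


GROUPS2 = {"ear_1": "ear", "tassel_1": "tassel"}


class TestCallDEGs:
    def test_pseudocounted_fold_change(self):
        expr = table(
            pd.DataFrame({"ear_1": [30.0], "tassel_1": [10.0]}, index=["g1"]),
            ["ear_1", "tassel_1"],
            qvalue={"g1": 0.001},
        )
        (call,) = ct.call_degs(expr, GROUPS2)
        assert call.direction == "ear"
        assert call.fc == pytest.approx(31 / 11)

    @pytest.mark.parametrize(
        "ear,tassel,q,expected",
        [
            (12.0, 10.0, 0.001, "none"),  # fc 1.18 below threshold
            (30.0, 10.0, 0.02, "none"),  # q above threshold
            (2.0, 30.0, 0.001, "tassel"),
        ],
    )
    def test_thresholds(self, ear, tassel, q, expected):
        expr = table(
            pd.DataFrame({"ear_1": [ear], "tassel_1": [tassel]}, index=["g1"]),
            ["ear_1", "tassel_1"],
            qvalue={"g1": q},
        )
        (call,) = ct.call_degs(expr, GROUPS2)
        assert call.direction == expected

    def test_swapping_tissues_swaps_directions(self, rng):
        n = 50
        vals = rng.lognormal(2, 1, size=(n, 6))
        vals[:10, :3] *= 5
        df = pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(n)],
            columns=[f"{t}_{r}" for t in ("ear", "tassel") for r in (1, 2, 3)],
        )
        groups = {s: s.rsplit("_", 1)[0] for s in df.columns}
        fwd = ct.call_degs(ExpressionTable(df), groups)
        rev = ct.call_degs(ExpressionTable(df), groups, group_a="tassel", group_b="ear")
        swap = {"ear": "tassel", "tassel": "ear", "none": "none"}
        assert [c.direction for c in fwd] == [swap[c.direction] for c in rev]

    def test_missing_q_with_too_few_replicates_errors(self):
        expr = table(
            pd.DataFrame({"ear_1": [1.0], "tassel_1": [2.0]}, index=["g1"]),
            ["ear_1", "tassel_1"],
        )
        with pytest.raises(ValueError, match="replicates"):
            ct.call_degs(expr, GROUPS2)


def g(gid, start, end=None, strand="+"):
    end = end or start + 2_000
    return Gene(gid, GenomicInterval("chr1", start, end, strand))


def diff_peak(start, end, feature, tissue, change):
    iv = GenomicInterval("chr1", start, end)
    return (Peak(iv, iv.midpoint), feature, tissue, change)


class TestAssociateFeatureChanges:
    def test_token_accumulation_and_distal_tally(self):
        genes = [g("gX", 10_000)]
        peaks = [
            diff_peak(10_100, 10_500, "K4me3", "ear", "enriched"),
            diff_peak(50_000, 50_400, "OCR", "tassel", "enriched"),
        ]
        changes, n_distal = ct.associate_feature_changes(peaks, genes)
        assert changes == [
            differential.FeatureChange("gX", frozenset({"K4me3_up:ear"}))
        ]
        assert n_distal == 1

    def test_unknown_feature_errors(self):
        with pytest.raises(ValueError, match="feature"):
            ct.associate_feature_changes(
                [diff_peak(0, 10, "H3K36me3", "ear", "enriched")], [g("gX", 10_000)]
            )

    def test_matches_brute_force(self, toy_genome, rng):
        genes = [
            Gene(f"g{i}", iv)
            for i, iv in enumerate(
                _oracles.random_intervals(rng, toy_genome, 20, 500, 4000, stranded=True)
            )
        ]
        peaks = [
            (Peak(iv, iv.midpoint), "OCR", "ear", "enriched")
            for iv in _oracles.random_intervals(rng, toy_genome, 150, 100, 900)
        ]
        changes, _ = ct.associate_feature_changes(peaks, genes)
        from cistopo.ocr import local_window

        windows = [local_window(x).interval for x in genes]
        expected = _oracles.assign_all_pairs([p.interval for p, *_ in peaks], windows)
        hit_genes = {genes[j].id for exp in expected for j in exp}
        assert {c.gene_id for c in changes} == hit_genes


class TestCombinedFeatureEffect:
    def test_combined_changes_have_stronger_fold_change(self, rng):
        n = 200
        gene_ids = [f"g{i}" for i in range(n)]
        fc_planted = {}
        changes = []
        for i, gid in enumerate(gene_ids):
            if i < 100:
                changes.append(
                    differential.FeatureChange(gid, frozenset({"K4me3_up:tassel"}))
                )
                fc_planted[gid] = 2.0
            else:
                changes.append(
                    differential.FeatureChange(
                        gid, frozenset({"K4me3_up:tassel", "OCR_up:tassel"})
                    )
                )
                fc_planted[gid] = 4.0
        tassel = np.array([10.0 * fc_planted[gid] * float(rng.lognormal(0, 0.1)) for gid in gene_ids])
        ear = np.full(n, 10.0)
        df = pd.DataFrame(
            {"ear_1": ear, "tassel_1": tassel}, index=gene_ids
        )
        expr = ExpressionTable(df)
        degs = [differential.DEGCall(gid, "tassel", 1 / fc_planted[gid], 0.001) for gid in gene_ids]
        out = ct.combined_feature_effect(
            degs, changes, expr, GROUPS2, tissue="tassel"
        )
        by_feat = out.set_index("features")
        single = by_feat.loc["K4me3_up:tassel"]
        combined = by_feat.loc["K4me3_up:tassel+OCR_up:tassel"]
        assert combined["median_fc"] > single["median_fc"]
        assert combined["p_vs_K4me3_up:tassel"] < 0.01
        # disjoint combination sets cover every enriched gene with >= 1 change
        assert out["n"].sum() == out.attrs["n_enriched_with_change"]

    def test_headline_fraction(self):
        degs = [differential.DEGCall(f"g{i}", "ear", 3.0, 1e-4) for i in range(100)]
        changes = [
            differential.FeatureChange(f"g{i}", frozenset({"OCR_up:ear"}))
            for i in range(40)
        ]
        expr = ExpressionTable(
            pd.DataFrame(
                {"ear_1": np.ones(100), "tassel_1": np.ones(100)},
                index=[f"g{i}" for i in range(100)],
            )
        )
        out = ct.combined_feature_effect(degs, changes, expr, GROUPS2, tissue="ear")
        assert out.attrs["fraction_with_change"] == pytest.approx(0.40)


class TestActiveDOCRs:
    def _docr(self, start):
        iv = GenomicInterval("chr1", start, start + 400)
        return Peak(iv, iv.midpoint, name=f"d{start}")

    def test_evidence_rules(self):
        docrs = [self._docr(1_000), self._docr(10_000), self._docr(20_000)]
        diff_ocr = [diff_peak(1_100, 1_300, "OCR", "ear", "enriched")]
        diff_k27 = [diff_peak(10_050, 10_350, "K27me3", "ear", "depleted")]
        active, conflicted = ct.call_active_docrs(docrs, diff_ocr, diff_k27)
        by_name = {a.docr.name: a for a in active}
        assert by_name["d1000"].tissue == "ear"
        assert by_name["d1000"].evidence == frozenset({"more_open"})
        assert by_name["d10000"].evidence == frozenset({"weaker_K27"})
        assert "d20000" not in by_name and not conflicted

    def test_conflicting_evidence_excluded(self):
        docrs = [self._docr(1_000)]
        diff_ocr = [diff_peak(1_000, 1_400, "OCR", "ear", "enriched")]
        diff_k27 = [diff_peak(1_000, 1_400, "K27me3", "tassel", "depleted")]
        active, conflicted = ct.call_active_docrs(docrs, diff_ocr, diff_k27)
        assert active == [] and len(conflicted) == 1

    def test_symmetric_under_tissue_relabel(self):
        docrs = [self._docr(1_000), self._docr(5_000)]
        diff_ocr = [
            diff_peak(1_000, 1_400, "OCR", "ear", "enriched"),
            diff_peak(5_000, 5_400, "OCR", "tassel", "enriched"),
        ]
        active, _ = ct.call_active_docrs(docrs, diff_ocr, [])
        relabel = {"ear": "tassel", "tassel": "ear"}
        diff_swapped = [
            (p, f, relabel[t], c) for p, f, t, c in diff_ocr
        ]
        active_swapped, _ = ct.call_active_docrs(docrs, diff_swapped, [])
        assert {a.docr.name: relabel[a.tissue] for a in active} == {
            a.docr.name: a.tissue for a in active_swapped
        }

    def test_k27_flank_extends_reach(self):
        docrs = [self._docr(1_000)]
        diff_k27 = [diff_peak(1_500, 1_900, "K27me3", "ear", "depleted")]
        active0, _ = ct.call_active_docrs(docrs, [], diff_k27, k27_flank=0)
        active200, _ = ct.call_active_docrs(docrs, [], diff_k27, k27_flank=200)
        assert active0 == [] and len(active200) == 1
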