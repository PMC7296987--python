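"""Tissue-enriched genes, differential chromatin features and active dOCRs.

Two-tissue (ear vs tassel) logic: genes are called enriched by FPKM fold
change and q-value; differential ATAC/H3K4me3/H3K27me3 peaks are assigned
to genes through their local windows; dOCRs are called tissue-active when
they are more open and/or carry weaker H3K27me3 in one tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _intervals, ocr
from .model import ExpressionTable, Gene, Genome, Peak

log = logging.getLogger(__name__)

FEATURES = ("OCR", "K4me3", "K27me3")
CHANGES = ("enriched", "depleted")

# (peak, feature, tissue, change) as produced by io.read_differential_peaks
DiffPeak = tuple[Peak, str, str, str]


@dataclass(frozen=True)
class DEGCall:
    gene_id: str
    direction: str  # tissue label or "none"
    fc: float  # group_a/group_b mean-FPKM ratio (pseudocounted)
    q: float


@dataclass(frozen=True)
class FeatureChange:
    """Feature-change tokens accumulated by a gene, e.g. ``OCR_up:ear``."""

    gene_id: str
    features: frozenset


@dataclass(frozen=True)
class ActiveDOCR:
    docr: Peak
    tissue: str
    evidence: frozenset  # subset of {"more_open", "weaker_K27"}


def call_degs(
    expr: ExpressionTable,
    groups: Mapping[str, str],
    group_a: str = "ear",
    group_b: str = "tassel",
    fc_threshold: float = 1.5,
    q_threshold: float = 0.01,
    pseudocount: float = 1.0,
) -> list[DEGCall]:
    """Call tissue-enriched genes at FC > 1.5, q < 0.01 (defaults).

    ``groups`` maps sample label -> tissue.  Fold change is
    ``(mean_a + pseudocount) / (mean_b + pseudocount)``.  When the table
    carries no per-gene q-values, a fallback Welch t-test on
    log2(FPKM + 1) with Benjamini-Hochberg adjustment is used; it
    requires >= 3 replicates per group.
    """
    a_samples = [s for s in expr.samples if groups.get(s) == group_a]
    b_samples = [s for s in expr.samples if groups.get(s) == group_b]
    if not a_samples or not b_samples:
        raise ValueError(f"need samples for both {group_a!r} and {group_b!r}")
    mean_a = expr.mean_fpkm(a_samples)
    mean_b = expr.mean_fpkm(b_samples)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)

    if expr.qvalue is not None and not expr.qvalue.isna().all():
        q = expr.qvalue.astype(float)
    else:
        if len(a_samples) < 3 or len(b_samples) < 3:
            raise ValueError(
                "no q-values supplied and fewer than 3 replicates per group "
                "for the fallback t-test"
            )
        la = np.log2(expr.values[a_samples].to_numpy() + 1.0)
        lb = np.log2(expr.values[b_samples].to_numpy() + 1.0)
        t = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        pvals = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
        q = pd.Series(multipletests(pvals, method="fdr_bh")[1], index=expr.genes)

    calls = []
    for gid in expr.genes:
        f, qv = float(fc[gid]), float(q[gid])
        if qv < q_threshold and f > fc_threshold:
            direction = group_a
        elif qv < q_threshold and 1.0 / f > fc_threshold:
            direction = group_b
        else:
            direction = "none"
        calls.append(DEGCall(gid, direction, f, qv))
    return calls


def _token(feature: str, tissue: str, change: str) -> str:
    updown = "up" if change == "enriched" else "down"
    return f"{feature}_{updown}:{tissue}"


def associate_feature_changes(
    diff_peaks: Sequence[DiffPeak],
    genes: Sequence[Gene],
    upstream: int = ocr.DEFAULT_UPSTREAM,
    genome: Genome | None = None,
) -> tuple[list[FeatureChange], int]:
    """Accumulate on each gene every differential peak overlapping its
    local window; peaks hitting no window count toward the distal tally.

    Returns ``(feature_changes, n_distal_differential_peaks)``.
    """
    for _, feature, _, change in diff_peaks:
        if feature not in FEATURES:
            raise ValueError(f"unknown feature label {feature!r}")
        if change not in CHANGES:
            raise ValueError(f"unknown change label {change!r}")
    assignment = ocr.assign_genes(
        [p for p, *_ in diff_peaks], genes, upstream, genome
    )
    acc: dict[str, set] = {g.id: set() for g in genes}
    n_distal = 0
    for i, (_, feature, tissue, change) in enumerate(diff_peaks):
        gids = assignment[i]
        if not gids:
            n_distal += 1
            continue
        for gid in gids:
            acc[gid].add(_token(feature, tissue, change))
    changes = [
        FeatureChange(gid, frozenset(toks)) for gid, toks in acc.items() if toks
    ]
    return changes, n_distal


def combined_feature_effect(
    degs: Sequence[DEGCall],
    feature_changes: Sequence[FeatureChange],
    expr: ExpressionTable,
    groups: Mapping[str, str],
    tissue: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Expression fold change of tissue-enriched gene sets carrying single
    vs combined chromatin-feature changes.

    One row per observed feature combination among ``tissue``-enriched
    genes: n, median FC toward the tissue, and a rank-sum p against each
    single-feature set.  Frame attrs carry the headline count of enriched
    genes with >= 1 feature change.
    """
    other = sorted({t for t in groups.values() if t != tissue})
    if len(other) != 1:
        raise ValueError("expected exactly two tissues in groups")
    t_samples = [s for s in expr.samples if groups[s] == tissue]
    o_samples = [s for s in expr.samples if groups[s] == other[0]]
    fc = (expr.mean_fpkm(t_samples) + pseudocount) / (
        expr.mean_fpkm(o_samples) + pseudocount
    )

    enriched = {d.gene_id for d in degs if d.direction == tissue}
    by_gene = {c.gene_id: c.features for c in feature_changes}
    sets: dict[frozenset, list[float]] = {}
    n_changed = 0
    for gid in enriched:
        feats = by_gene.get(gid, frozenset())
        if not feats:
            continue
        n_changed += 1
        sets.setdefault(feats, []).append(float(fc[gid]))

    single = {fs: v for fs, v in sets.items() if len(fs) == 1}
    rows = []
    for fs, vals in sorted(sets.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        row = {
            "features": "+".join(sorted(fs)),
            "n_features": len(fs),
            "n": len(vals),
            "median_fc": float(np.median(vals)),
        }
        for sfs, svals in single.items():
            key = f"p_vs_{next(iter(sfs))}"
            if fs == sfs or len(vals) < 2 or len(svals) < 2:
                row[key] = float("nan")
            else:
                row[key] = float(
                    stats.mannwhitneyu(vals, svals, alternative="two-sided").pvalue
                )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_enriched"] = len(enriched)
    out.attrs["n_enriched_with_change"] = n_changed
    out.attrs["fraction_with_change"] = (
        n_changed / len(enriched) if enriched else float("nan")
    )
    return out


def call_active_docrs(
    docrs: Sequence[Peak],
    diff_ocr_peaks: Sequence[DiffPeak],
    diff_k27_peaks: Sequence[DiffPeak],
    tissues: tuple[str, str] = ("ear", "tassel"),
    k27_flank: int = 0,
) -> tuple[list[ActiveDOCR], list[Peak]]:
    """Call tissue-active dOCRs: more open and/or weaker H3K27me3 in one tissue.

    A dOCR is active in tissue T when it overlaps a T-enriched differential
    OCR peak, or when its interval extended by ``k27_flank`` overlaps a
    T-depleted H3K27me3 differential peak.  dOCRs with evidence for both
    tissues are excluded and returned separately.
    """
    evidence: dict[int, dict[str, set]] = {}

    def _collect(peaks: Sequence[DiffPeak], want_change: str, tag: str, flank: int):
        for tissue in tissues:
            sel = [
                p.interval
                for p, feature, t, change in peaks
                if t == tissue and change == want_change
            ]
            if not sel:
                continue
            ref = _intervals.merged(sel)
            if flank:
                queries = [
                    ocr.GenomicInterval(
                        d.chrom, max(0, d.start - flank), d.end + flank
                    )
                    for d in docrs
                ]
            else:
                queries = [d.interval for d in docrs]
            hit = _intervals.overlaps_any(queries, ref)
            for i, h in enumerate(hit):
                if h:
                    evidence.setdefault(i, {}).setdefault(tissue, set()).add(tag)

    _collect(diff_ocr_peaks, "enriched", "more_open", 0)
    _collect(diff_k27_peaks, "depleted", "weaker_K27", k27_flank)

    active: list[ActiveDOCR] = []
    conflicted: list[Peak] = []
    for i, per_tissue in sorted(evidence.items()):
        if len(per_tissue) > 1:
            conflicted.append(docrs[i])
            continue
        tissue, tags = next(iter(per_tissue.items()))
        active.append(ActiveDOCR(docrs[i], tissue, frozenset(tags)))
    if conflicted:
        log.info(
            "excluded %d dOCRs with conflicting tissue evidence", len(conflicted)
        )
    return active, conflicted
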