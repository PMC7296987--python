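"""Chromatin-loop classification, dOCR-gene links, expression and SNP linkage.

Loops are classified by anchor content (gene-gene, intergenic-gene,
intergenic-intergenic); intergenic-gene loops whose intergenic anchor
contains a dOCR become candidate enhancer-promoter contacts; intergenic
trait SNPs are linked to target genes through those loops via a 5-kb
window centred on the SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals, ocr
from .model import (
    ExpressionTable,
    Gene,
    Genome,
    GenomicInterval,
    Loop,
    Peak,
    SNPRecord,
)

log = logging.getLogger(__name__)

GENE_GENE = "gene_gene"
INTERGENIC_GENE = "intergenic_gene"
INTERGENIC_INTERGENIC = "intergenic_intergenic"

INTERGENIC = "intergenic"
GENIC_OR_PROXIMAL = "genic_or_proximal"


@dataclass(frozen=True)
class ClassifiedLoop:
    loop: Loop
    klass: str
    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]

    @property
    def gene_anchor_genes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.genes_a) | set(self.genes_b)))

    @property
    def intergenic_anchor(self) -> GenomicInterval | None:
        """The non-genic anchor of an intergenic-gene loop."""
        if self.klass != INTERGENIC_GENE:
            return None
        return self.loop.anchor_b if self.genes_a else self.loop.anchor_a

    @property
    def genic_anchor_genes(self) -> tuple[str, ...]:
        return self.genes_a if self.genes_a else self.genes_b


@dataclass(frozen=True)
class DOCRGeneLink:
    """One intergenic-gene loop whose intergenic anchor holds >= 1 dOCR."""

    loop: ClassifiedLoop
    docr_indices: tuple[int, ...]  # indices into the dOCR list
    target_genes: tuple[str, ...]


@dataclass(frozen=True)
class SNPLoopLink:
    snp: SNPRecord
    window: GenomicInterval
    loop_indices: tuple[int, ...]  # intergenic-gene loops reached
    candidate_genes: tuple[str, ...]


def classify_loops(
    loops: Sequence[Loop],
    genes: Sequence[Gene],
    upstream: int = ocr.DEFAULT_UPSTREAM,
    genome: Genome | None = None,
    genic_definition: str = "window",
) -> list[ClassifiedLoop]:
    """Partition loops by whether each anchor overlaps a gene.

    An anchor is genic when it overlaps >= 1 bp of a gene's local window
    (``genic_definition="window"``, mirroring the LoOCR rule) or of the
    gene body alone (``"body"``).
    """
    if genic_definition == "window":
        windows = ocr.local_windows(genes, upstream, genome)
        ivs = [w.interval for w in windows]
        ids = [w.gene_id for w in windows]
    elif genic_definition == "body":
        ivs = [g.interval for g in genes]
        ids = [g.id for g in genes]
    else:
        raise ValueError("genic_definition must be 'window' or 'body'")

    anchors: list[GenomicInterval] = []
    for lp in loops:
        anchors.extend((lp.anchor_a, lp.anchor_b))
    pairs = _intervals.overlapping_pairs(anchors, ivs)
    per_anchor: dict[int, set] = {}
    for i, j in pairs:
        per_anchor.setdefault(i, set()).add(ids[j])

    out = []
    for k, lp in enumerate(loops):
        ga = tuple(sorted(per_anchor.get(2 * k, ())))
        gb = tuple(sorted(per_anchor.get(2 * k + 1, ())))
        if ga and gb:
            klass = GENE_GENE
        elif ga or gb:
            klass = INTERGENIC_GENE
        else:
            klass = INTERGENIC_INTERGENIC
        out.append(ClassifiedLoop(lp, klass, ga, gb))
    return out


def docr_gene_links(
    classified: Sequence[ClassifiedLoop], docrs: Sequence[Peak]
) -> tuple[list[DOCRGeneLink], float, pd.DataFrame]:
    """dOCR-gene loops and the fraction of intergenic anchors containing one.

    Returns ``(links, fraction, hub_table)`` where ``fraction`` is
    (intergenic-gene anchors holding >= 1 dOCR) / (all intergenic-gene
    anchors) and ``hub_table`` lists dOCRs linked to more than one gene.
    """
    ig = [cl for cl in classified if cl.klass == INTERGENIC_GENE]
    links: list[DOCRGeneLink] = []
    if ig and docrs:
        docr_ivs = [d.interval for d in docrs]
        anchor_ivs = [cl.intergenic_anchor for cl in ig]
        pairs = _intervals.overlapping_pairs(anchor_ivs, docr_ivs)
        per_anchor: dict[int, list[int]] = {}
        for i, j in pairs:
            per_anchor.setdefault(i, []).append(j)
        for i, cl in enumerate(ig):
            hits = per_anchor.get(i)
            if hits and cl.genic_anchor_genes:
                links.append(
                    DOCRGeneLink(cl, tuple(sorted(hits)), cl.genic_anchor_genes)
                )
    fraction = len(links) / len(ig) if ig else 0.0

    targets_per_docr: dict[int, set] = {}
    for link in links:
        for j in link.docr_indices:
            targets_per_docr.setdefault(j, set()).update(link.target_genes)
    hub_rows = [
        {"docr_index": j, "n_targets": len(t), "targets": ",".join(sorted(t))}
        for j, t in sorted(targets_per_docr.items())
        if len(t) > 1
    ]
    return links, fraction, pd.DataFrame(hub_rows)


def loops_per_gene(
    classified: Sequence[ClassifiedLoop],
    genes: Sequence[Gene],
    expression: ExpressionTable,
    upstream: int = ocr.DEFAULT_UPSTREAM,
    genome: Genome | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Distinct-loop count per gene and median FPKM per count bin.

    A loop counts for a gene when >= 1 of its anchors overlaps the gene's
    local window.  The summary frame has bins {0,1,2,3,4+} and carries a
    Spearman rho between loop count and mean FPKM in its attrs.
    """
    windows = ocr.local_windows(genes, upstream, genome)
    win_ivs = [w.interval for w in windows]
    counts: dict[str, set] = {g.id: set() for g in genes}
    anchors = []
    anchor_loop = []
    for k, cl in enumerate(classified):
        anchors.extend((cl.loop.anchor_a, cl.loop.anchor_b))
        anchor_loop.extend((k, k))
    for i, j in _intervals.overlapping_pairs(anchors, win_ivs):
        counts[windows[j].gene_id].add(anchor_loop[i])
    n_loops = {gid: len(s) for gid, s in counts.items()}

    mean_fpkm = expression.mean_fpkm()
    gids = [g.id for g in genes if g.id in mean_fpkm.index]
    x = np.array([n_loops[g] for g in gids], dtype=float)
    y = np.array([mean_fpkm[g] for g in gids], dtype=float)
    rows = []
    for label, lo, hi in [("0", 0, 0), ("1", 1, 1), ("2", 2, 2), ("3", 3, 3), ("4+", 4, np.inf)]:
        sel = (x >= lo) & (x <= hi)
        rows.append(
            {
                "loop_bin": label,
                "n_genes": int(sel.sum()),
                "median_fpkm": float(np.median(y[sel])) if sel.any() else float("nan"),
            }
        )
    summary = pd.DataFrame(rows)
    if len(set(x)) > 1 and len(set(y)) > 1:
        rho, p = stats.spearmanr(x, y)
        summary.attrs["spearman_rho"] = float(rho)
        summary.attrs["spearman_p"] = float(p)
    else:
        summary.attrs["spearman_rho"] = float("nan")
        summary.attrs["spearman_p"] = float("nan")
    return n_loops, summary


DOCR_LOOPED = "docr_looped"
OTHER_LOOPED = "other_looped"
NO_LOOP = "no_loop"


def expression_by_loop_class(
    genes: Sequence[Gene],
    links: Sequence[DOCRGeneLink],
    classified: Sequence[ClassifiedLoop],
    expression: ExpressionTable,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Three-group expression comparison with precedence
    dOCR-looped > other-looped > no-loop (each gene in exactly one group)."""
    docr_genes = {g for link in links for g in link.target_genes}
    looped_genes = {
        g for cl in classified for g in cl.gene_anchor_genes
    }
    group: dict[str, str] = {}
    for g in genes:
        if g.id in docr_genes:
            group[g.id] = DOCR_LOOPED
        elif g.id in looped_genes:
            group[g.id] = OTHER_LOOPED
        else:
            group[g.id] = NO_LOOP
    mean_fpkm = expression.mean_fpkm()
    dist = {
        k: np.array(
            [mean_fpkm[g.id] for g in genes if group[g.id] == k and g.id in mean_fpkm.index]
        )
        for k in (DOCR_LOOPED, OTHER_LOOPED, NO_LOOP)
    }
    rows = [
        {
            "group": k,
            "n": len(v),
            "median_fpkm": float(np.median(v)) if len(v) else float("nan"),
        }
        for k, v in dist.items()
    ]
    summary = pd.DataFrame(rows)

    def _p(a: str, b: str) -> float:
        va, vb = dist[a], dist[b]
        if len(va) < 2 or len(vb) < 2:
            return float("nan")
        return float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)

    summary.attrs["p_docr_vs_other"] = _p(DOCR_LOOPED, OTHER_LOOPED)
    summary.attrs["p_docr_vs_noloop"] = _p(DOCR_LOOPED, NO_LOOP)
    summary.attrs["p_other_vs_noloop"] = _p(OTHER_LOOPED, NO_LOOP)
    return group, summary


def active_docr_target_enrichment(
    active_docr_indices: Mapping[str, Sequence[int]],
    links: Sequence[DOCRGeneLink],
    degs,
) -> pd.DataFrame:
    """Are tissue-enriched genes over-represented among the targets of
    tissue-active dOCR links, against all dOCR links as background?

    ``active_docr_indices`` maps tissue -> indices (into the dOCR list) of
    dOCRs active in that tissue.  One row per tissue: the 2x2 counts, both
    proportions and a one-sided Fisher p.  Frame attrs carry the
    tissue-by-tissue cross table of active-link targets.
    """
    direction = {d.gene_id: d.direction for d in degs}
    all_targets = sorted({g for link in links for g in link.target_genes})
    docr_targets: dict[int, set] = {}
    for link in links:
        for j in link.docr_indices:
            docr_targets.setdefault(j, set()).update(link.target_genes)

    rows = []
    cross: dict[tuple[str, str], int] = {}
    tissues = sorted(active_docr_indices)
    for tissue in tissues:
        idx = set(active_docr_indices[tissue])
        active_targets = sorted(
            {g for j in idx for g in docr_targets.get(j, ())}
        )
        if not active_targets:
            log.warning("no %s-active dOCR link targets: test skipped", tissue)
            rows.append(
                {
                    "tissue": tissue,
                    "a": 0,
                    "b": 0,
                    "bg_a": sum(1 for g in all_targets if direction.get(g) == tissue),
                    "bg_b": sum(1 for g in all_targets if direction.get(g) != tissue),
                    "prop_active": float("nan"),
                    "prop_background": float("nan"),
                    "fisher_p": 1.0,
                }
            )
            continue
        a = sum(1 for g in active_targets if direction.get(g) == tissue)
        b = len(active_targets) - a
        bg_a = sum(1 for g in all_targets if direction.get(g) == tissue)
        bg_b = len(all_targets) - bg_a
        if min(a + b, bg_a + bg_b) == 0 or (a + bg_a) == 0:
            p = 1.0
            log.warning("zero-margin table for %s: p reported as 1", tissue)
        else:
            _, p = stats.fisher_exact([[a, b], [bg_a, bg_b]], alternative="greater")
        rows.append(
            {
                "tissue": tissue,
                "a": a,
                "b": b,
                "bg_a": bg_a,
                "bg_b": bg_b,
                "prop_active": a / (a + b),
                "prop_background": bg_a / (bg_a + bg_b) if (bg_a + bg_b) else float("nan"),
                "fisher_p": float(p),
            }
        )
        for other in tissues:
            cross[(tissue, other)] = sum(
                1 for g in active_targets if direction.get(g) == other
            )
    out = pd.DataFrame(rows)
    out.attrs["cross_table"] = cross
    return out


def classify_snps(
    snps: Sequence[SNPRecord],
    genes: Sequence[Gene],
    margin: int = 3000,
) -> list[SNPRecord]:
    """Label SNPs intergenic when > ``margin`` bp from every gene span
    (symmetric, strand-independent), else genic-or-proximal."""
    padded = [
        GenomicInterval(g.chrom, max(0, g.interval.start - margin), g.interval.end + margin)
        for g in genes
    ]
    ref = _intervals.merged(padded) if padded else {}
    pos_by_chrom: dict[str, list[int]] = {}
    order: dict[str, list[int]] = {}
    for i, s in enumerate(snps):
        pos_by_chrom.setdefault(s.chrom, []).append(s.pos)
        order.setdefault(s.chrom, []).append(i)
    flags = np.zeros(len(snps), dtype=bool)
    hit = _intervals.points_in(
        {c: np.array(p, dtype=np.int64) for c, p in pos_by_chrom.items()}, ref
    )
    for chrom, idxs in order.items():
        flags[np.array(idxs)] = hit[chrom]
    return [
        s.with_locality(GENIC_OR_PROXIMAL if f else INTERGENIC)
        for s, f in zip(snps, flags)
    ]


def snp_loop_link(
    intergenic_snps: Sequence[SNPRecord],
    classified: Sequence[ClassifiedLoop],
    docrs: Sequence[Peak],
    window: int = 5000,
) -> tuple[list[SNPLoopLink], np.ndarray]:
    """Link intergenic SNPs to genes through intergenic-gene loops.

    A SNP links to every intergenic-gene loop whose intergenic anchor
    overlaps the ``window``-bp window centred on the SNP; candidate genes
    are the loops' gene-anchor genes.  Also returns per-SNP flags for the
    SNP position falling inside a dOCR.
    """
    for s in intergenic_snps:
        if s.locality != INTERGENIC:
            raise ValueError(f"SNP {s.id} is not classified intergenic")
    ig = [(k, cl) for k, cl in enumerate(classified) if cl.klass == INTERGENIC_GENE]
    half = window // 2
    windows = [
        GenomicInterval(s.chrom, max(0, s.pos - half), s.pos + half)
        for s in intergenic_snps
    ]
    anchor_ivs = [cl.intergenic_anchor for _, cl in ig]
    links: list[SNPLoopLink] = []
    per_snp: dict[int, list[int]] = {}
    if anchor_ivs:
        for i, j in _intervals.overlapping_pairs(windows, anchor_ivs):
            per_snp.setdefault(i, []).append(j)
    for i, snp in enumerate(intergenic_snps):
        hits = per_snp.get(i, [])
        if not hits:
            continue
        loop_idx = tuple(sorted(ig[j][0] for j in hits))
        genes = tuple(
            sorted({g for j in hits for g in ig[j][1].genic_anchor_genes})
        )
        links.append(SNPLoopLink(snp, windows[i], loop_idx, genes))

    if docrs:
        docr_ref = _intervals.merged([d.interval for d in docrs])
        pos_by_chrom: dict[str, list[int]] = {}
        order: dict[str, list[int]] = {}
        for i, s in enumerate(intergenic_snps):
            pos_by_chrom.setdefault(s.chrom, []).append(s.pos)
            order.setdefault(s.chrom, []).append(i)
        in_docr = np.zeros(len(intergenic_snps), dtype=bool)
        hit = _intervals.points_in(
            {c: np.array(p, dtype=np.int64) for c, p in pos_by_chrom.items()},
            docr_ref,
        )
        for chrom, idxs in order.items():
            in_docr[np.array(idxs)] = hit[chrom]
    else:
        in_docr = np.zeros(len(intergenic_snps), dtype=bool)
    return links, in_docr
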