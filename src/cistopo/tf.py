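"""TF binding sites vs open chromatin: overlap, co-binding, networks, anchors.

Binding-site sets come from ChIP-seq or DAP-seq peak files; high-confidence
sets keep only peaks supported by both replicates.  Sites are relate to
LoOCRs/dOCRs by >= 1 bp overlap with shift-randomised controls, to target
genes through gene local windows, and to loop anchors for the joint
distal/local binding classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals, ocr
from .loops import DOCRGeneLink
from .model import CoverageTrack, Gene, Genome, GenomicInterval, Peak
from .permutation import EnrichmentResult, ShiftConstraint, overlap_enrichment

log = logging.getLogger(__name__)

PROVENANCES = ("in_vivo_chip", "dap", "protoplast_chip")

DOCR_ONLY = "dOCR_only"
LOCAL_ONLY = "Local_only"
JOINT = "Joint"


@dataclass(frozen=True)
class TFPeakSet:
    """Binding sites of one TF, optionally reduced to replicate-supported peaks."""

    name: str
    peaks: tuple[Peak, ...]
    provenance: str = "in_vivo_chip"
    replicate_policy_applied: bool = False
    gene_id: str = ""  # the TF's own gene, for self-edge detection

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @staticmethod
    def from_replicates(
        name: str,
        rep1: Sequence[Peak],
        rep2: Sequence[Peak] | None,
        provenance: str = "in_vivo_chip",
        gene_id: str = "",
    ) -> "TFPeakSet":
        """High-confidence set: rep1 peaks overlapping >= 1 rep2 peak.

        With a single replicate the full set is kept and a caveat logged.
        """
        if rep2 is None:
            log.info("TF %s: single replicate, no intersection applied", name)
            return TFPeakSet(name, tuple(rep1), provenance, False, gene_id)
        ref = _intervals.merged([p.interval for p in rep2])
        hit = _intervals.overlaps_any([p.interval for p in rep1], ref)
        kept = tuple(p for p, h in zip(rep1, hit) if h)
        return TFPeakSet(name, kept, provenance, True, gene_id)


def tfbs_ocr_overlap(
    tf: TFPeakSet,
    loocrs: Sequence[Peak],
    docrs: Sequence[Peak],
    constraint: ShiftConstraint,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, EnrichmentResult]:
    """Fractions of TF sites overlapping LoOCRs, dOCRs and either,
    each with a shifted-TF-site control enrichment."""
    if not tf.peaks:
        raise ValueError(f"TF set {tf.name} is empty")
    sites = [p.interval for p in tf.peaks]
    refs = {
        "LoOCR": [p.interval for p in loocrs],
        "dOCR": [p.interval for p in docrs],
        "either": [p.interval for p in loocrs] + [p.interval for p in docrs],
    }
    rng = np.random.default_rng(seed)
    return {
        key: overlap_enrichment(
            sites, ref, constraint, n_perm=n_perm, seed=rng, shift_query=True
        )
        for key, ref in refs.items()
    }


@dataclass(frozen=True)
class RankConcordance:
    spearman_rho: float
    spearman_p: float
    rank_bin_matrix: np.ndarray  # mean TF signal per OCR-significance bin
    n_ocrs: int


def signal_rank_concordance(
    ocr_peaks: Sequence[Peak],
    tf_signal: Sequence[Peak] | CoverageTrack,
    halfwidth: int = 500,
    n_rank_bins: int = 20,
) -> RankConcordance:
    """Concordance between OCR significance and TF signal near OCR summits.

    OCRs are ranked by q-value significance; TF signal is aggregated in
    +/- ``halfwidth`` bp of each summit (summed peak scores, or integrated
    coverage).  Returns the Spearman correlation between rank and signal
    and the per-rank-bin mean signal backing a heat-map.
    """
    if not ocr_peaks:
        raise ValueError("need OCR peaks")
    # significance: larger is more significant for -log10(q), smaller for raw q
    sig = np.array(
        [p.qvalue if p.q_neglog10 else -p.qvalue for p in ocr_peaks], dtype=float
    )
    agg = np.zeros(len(ocr_peaks), dtype=float)
    if isinstance(tf_signal, CoverageTrack):
        for i, p in enumerate(ocr_peaks):
            lo = max(0, p.summit - halfwidth)
            agg[i] = float(tf_signal.per_base(p.chrom, lo, p.summit + halfwidth).sum())
    else:
        windows = [
            GenomicInterval(p.chrom, max(0, p.summit - halfwidth), p.summit + halfwidth)
            for p in ocr_peaks
        ]
        tf_ivs = [p.interval for p in tf_signal]
        for i, j in _intervals.overlapping_pairs(windows, tf_ivs):
            agg[i] += tf_signal[j].score
    if len(set(agg)) <= 1 or len(set(sig)) <= 1:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(sig, agg)
    order = np.argsort(-sig, kind="stable")  # most significant first
    bins = np.array_split(agg[order], min(n_rank_bins, len(ocr_peaks)))
    matrix = np.array([b.mean() for b in bins])
    return RankConcordance(float(rho), float(p), matrix, len(ocr_peaks))


def _target_genes(
    tf: TFPeakSet,
    genes: Sequence[Gene],
    upstream: int = ocr.DEFAULT_UPSTREAM,
    genome: Genome | None = None,
) -> set[str]:
    assignment = ocr.assign_genes(list(tf.peaks), genes, upstream, genome)
    return {g for gids in assignment.values() for g in gids}


def cobinding(
    tf_a: TFPeakSet,
    tf_b: TFPeakSet,
    genes: Sequence[Gene],
    upstream: int = ocr.DEFAULT_UPSTREAM,
    genome: Genome | None = None,
) -> tuple[int, set[str]]:
    """Count distinct co-bound loci and the common target gene set.

    Loci: overlapping A-B site pairs merged by union-find (>= 1 bp
    overlap); the locus count is the number of connected components that
    contain sites of both TFs.  Common targets: intersection of each TF's
    independently assigned target genes.
    """
    a_ivs = [p.interval for p in tf_a.peaks]
    b_ivs = [p.interval for p in tf_b.peaks]
    n_a = len(a_ivs)
    parent = list(range(n_a + len(b_ivs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    cross = _intervals.overlapping_pairs(a_ivs, b_ivs)
    for i, j in cross:
        union(i, n_a + j)
    # merge overlapping sites within each TF so a shared locus counts once
    for i, j in _intervals.overlapping_pairs(a_ivs, a_ivs):
        if i != j:
            union(i, j)
    for i, j in _intervals.overlapping_pairs(b_ivs, b_ivs):
        if i != j:
            union(n_a + i, n_a + j)
    comp_has: dict[int, set] = {}
    for i in range(n_a):
        comp_has.setdefault(find(i), set()).add("a")
    for j in range(len(b_ivs)):
        comp_has.setdefault(find(n_a + j), set()).add("b")
    n_loci = sum(1 for members in comp_has.values() if members == {"a", "b"})

    common = _target_genes(tf_a, genes, upstream, genome) & _target_genes(
        tf_b, genes, upstream, genome
    )
    return n_loci, common


@dataclass(frozen=True)
class RegulatoryEdge:
    tf: str
    target: str
    site: GenomicInterval
    site_class: str = "LoOCR"
    self_edge: bool = False


def build_network(
    tfs: Sequence[TFPeakSet],
    candidate_targets: set[str],
    classified_loocrs: Sequence["ocr.ClassifiedOCR"],
) -> tuple[list[RegulatoryEdge], float]:
    """TF -> gene edges where a TF site overlaps a LoOCR assigned to the gene.

    ``classified_loocrs`` carry their gene assignments (from
    ``ocr.classify_ocrs``); only LoOCRs are considered.  Returns the edge
    list and the fraction of candidate targets covered by >= 1 edge.
    """
    loocrs = [c for c in classified_loocrs if c.klass == ocr.LOCAL]
    loocr_ivs = [c.peak.interval for c in loocrs]
    edges: list[RegulatoryEdge] = []
    for tf in tfs:
        site_ivs = [p.interval for p in tf.peaks]
        hit_genes: dict[int, set] = {}
        for i, j in _intervals.overlapping_pairs(site_ivs, loocr_ivs):
            hit_genes.setdefault(i, set()).update(loocrs[j].assigned_genes)
        for i, gids in sorted(hit_genes.items()):
            for gid in sorted(gids):
                edges.append(
                    RegulatoryEdge(
                        tf.name,
                        gid,
                        site_ivs[i],
                        self_edge=bool(tf.gene_id) and tf.gene_id == gid,
                    )
                )
    covered = {e.target for e in edges} & candidate_targets
    coverage = len(covered) / len(candidate_targets) if candidate_targets else 0.0
    return edges, coverage


def tf_anchor_classes(
    tf: TFPeakSet,
    links: Sequence[DOCRGeneLink],
    loocrs: Sequence[Peak],
) -> dict[str, float]:
    """Per dOCR-gene loop, classify the TF's binding pattern.

    Joint: >= 1 site in the loop's intergenic (dOCR) anchor AND >= 1 site
    in a LoOCR overlapping the gene anchor; otherwise dOCR-only or
    Local-only.  Returns percentages over classified loop-TF pairs
    (loops where the TF binds neither anchor are not counted).
    """
    site_merged = _intervals.merged([p.interval for p in tf.peaks]) if tf.peaks else {}
    loocr_ivs = [p.interval for p in loocrs]
    counts = {DOCR_ONLY: 0, LOCAL_ONLY: 0, JOINT: 0}
    for link in links:
        cl = link.loop
        docr_anchor = cl.intergenic_anchor
        gene_anchor = (
            cl.loop.anchor_a if cl.intergenic_anchor is cl.loop.anchor_b else cl.loop.anchor_b
        )
        in_docr = bool(
            _intervals.overlaps_any([docr_anchor], site_merged)[0]
        ) if docr_anchor is not None else False
        # LoOCRs of the gene anchor
        anchor_loocrs = [
            iv
            for iv in loocr_ivs
            if iv.chrom == gene_anchor.chrom
            and iv.start < gene_anchor.end
            and gene_anchor.start < iv.end
        ]
        in_local = bool(
            anchor_loocrs
            and _intervals.overlaps_any(anchor_loocrs, site_merged).any()
        )
        if in_docr and in_local:
            counts[JOINT] += 1
        elif in_docr:
            counts[DOCR_ONLY] += 1
        elif in_local:
            counts[LOCAL_ONLY] += 1
    total = sum(counts.values())
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}
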