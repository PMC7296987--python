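"""Local/distal OCR classification, peak-to-gene assignment and metaprofiles.

A gene's *local window* runs from 3 kb upstream of its TSS through its TTS
(strand-aware, clamped to the chromosome).  An OCR overlapping >= 1 bp of
any local window is a local OCR (LoOCR) and is assigned to every such gene;
the remainder are distal OCRs (dOCRs), the candidate distal regulatory
elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import _intervals
from .model import CoverageTrack, ExpressionTable, Gene, Genome, GenomicInterval, Peak

log = logging.getLogger(__name__)

LOCAL = "LoOCR"
DISTAL = "dOCR"
DEFAULT_UPSTREAM = 3000


@dataclass(frozen=True)
class LocalWindow:
    """3-kb-upstream-of-TSS-through-TTS window of one gene."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class ClassifiedOCR:
    peak: Peak
    klass: str  # LOCAL or DISTAL
    assigned_genes: tuple[str, ...]


@dataclass(frozen=True)
class Metaprofile:
    """Mean signal per bin at offsets relative to a set of anchors."""

    bin_centers: np.ndarray  # bp offsets, -flank .. +flank
    mean: np.ndarray
    n_anchors: int


@dataclass(frozen=True)
class ExpressionComparison:
    """Two FPKM distributions and a two-sided rank-sum (Mann-Whitney) p."""

    group_a: np.ndarray
    group_b: np.ndarray
    pvalue: float


def local_window(
    gene: Gene, upstream: int = DEFAULT_UPSTREAM, genome: Genome | None = None
) -> LocalWindow:
    """The gene body extended ``upstream`` bp 5' of the TSS, clamped to bounds."""
    if upstream < 0:
        raise ValueError("upstream must be >= 0")
    iv = gene.interval
    if gene.strand == "+":
        start, end = max(0, iv.start - upstream), iv.end
    else:
        length = genome.length_of(iv.chrom) if genome is not None else None
        end = iv.end + upstream if length is None else min(length, iv.end + upstream)
        start = iv.start
    return LocalWindow(gene.id, GenomicInterval(iv.chrom, start, end, gene.strand))


def local_windows(
    genes: Sequence[Gene], upstream: int = DEFAULT_UPSTREAM, genome: Genome | None = None
) -> list[LocalWindow]:
    return [local_window(g, upstream, genome) for g in genes]


def assign_genes(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    upstream: int = DEFAULT_UPSTREAM,
    genome: Genome | None = None,
    by_summit: bool = False,
) -> dict[int, tuple[str, ...]]:
    """Map peak index -> ids of every gene whose local window it overlaps.

    With ``by_summit`` the peak is represented by its summit base only.
    """
    windows = local_windows(genes, upstream, genome)
    if by_summit:
        reps = [GenomicInterval(p.chrom, p.summit, p.summit + 1) for p in peaks]
    else:
        reps = [p.interval for p in peaks]
    win_ivs = [w.interval for w in windows]
    pairs = _intervals.overlapping_pairs(reps, win_ivs)
    out: dict[int, list[str]] = {i: [] for i in range(len(peaks))}
    for i, j in pairs:
        out[i].append(windows[j].gene_id)
    return {i: tuple(sorted(set(g))) for i, g in out.items()}


def classify_ocrs(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    upstream: int = DEFAULT_UPSTREAM,
    genome: Genome | None = None,
    by_summit: bool = False,
) -> list[ClassifiedOCR]:
    """Partition peaks into LoOCRs (>= 1 bp overlap with a local window,
    assigned to every such gene) and dOCRs (no overlap)."""
    if not genes:
        log.warning("empty gene list: all %d peaks classified distal", len(peaks))
        return [ClassifiedOCR(p, DISTAL, ()) for p in peaks]
    assignment = assign_genes(peaks, genes, upstream, genome, by_summit)
    return [
        ClassifiedOCR(p, LOCAL if assignment[i] else DISTAL, assignment[i])
        for i, p in enumerate(peaks)
    ]


def split_classes(
    classified: Sequence[ClassifiedOCR],
) -> tuple[list[Peak], list[Peak]]:
    loocrs = [c.peak for c in classified if c.klass == LOCAL]
    docrs = [c.peak for c in classified if c.klass == DISTAL]
    return loocrs, docrs


def transcribed_docrs(
    docrs: Sequence[Peak],
    transcripts: Sequence[tuple[GenomicInterval, float]],
    coding_fpkm: Sequence[float] | None = None,
) -> tuple[np.ndarray, ExpressionComparison | None]:
    """Flag dOCRs overlapping >= 1 intergenic transcript.

    Returns per-dOCR boolean flags and, when ``coding_fpkm`` is given and
    both groups are non-empty, a comparison of coding-gene FPKMs against
    the FPKMs of transcripts that overlap a dOCR (two-sided rank-sum).
    """
    tx_ivs = [iv for iv, _ in transcripts]
    if not transcripts:
        return np.zeros(len(docrs), dtype=bool), None
    flags = _intervals.overlaps_any([p.interval for p in docrs], _intervals.merged(tx_ivs))
    comparison = None
    if coding_fpkm is not None:
        docr_merged = _intervals.merged([p.interval for p in docrs])
        tx_hit = _intervals.overlaps_any(tx_ivs, docr_merged)
        docr_tx_fpkm = np.array([v for (iv, v), hit in zip(transcripts, tx_hit) if hit])
        coding = np.asarray(coding_fpkm, dtype=float)
        if len(docr_tx_fpkm) and len(coding):
            stat = stats.mannwhitneyu(coding, docr_tx_fpkm, alternative="two-sided")
            comparison = ExpressionComparison(coding, docr_tx_fpkm, float(stat.pvalue))
    return flags, comparison


# ----------------------------------------------------------- metaprofile


def metaprofile(
    track: CoverageTrack,
    anchors: Sequence[tuple],
    flank: int = 3000,
    binsize: int = 50,
    genome: Genome | None = None,
) -> Metaprofile:
    """Per-bin mean signal in ``[-flank, +flank)`` around anchor positions.

    Anchors are ``(chrom, pos)`` or ``(chrom, pos, strand)`` tuples; minus
    strand flips the profile so that bins read 5'->3'.  Every base weighs
    equally within its bin; bases without coverage contribute 0; bases
    outside the chromosome are treated as missing (excluded from the bin
    denominator), and bins with no in-bounds base anywhere are NaN.
    """
    if not anchors:
        raise ValueError("metaprofile needs at least one anchor")
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of binsize")
    n_bins = 2 * flank // binsize
    width = 2 * flank
    total = np.zeros(n_bins, dtype=float)
    count = np.zeros(n_bins, dtype=np.int64)
    for anchor in anchors:
        chrom, pos = anchor[0], int(anchor[1])
        strand = anchor[2] if len(anchor) > 2 else "."
        win_start = pos - flank
        lo = win_start
        hi = pos + flank
        if genome is not None:
            length = genome.length_of(chrom)
            lo, hi = max(0, lo), min(length, hi)
        if lo >= hi:
            continue
        vals = track.per_base(chrom, lo, hi)
        offsets = np.arange(lo, hi) - win_start  # 0 .. width-1
        if strand == "-":
            offsets = width - 1 - offsets
        bins = offsets // binsize
        total += np.bincount(bins, weights=vals, minlength=n_bins)
        count += np.bincount(bins, minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    nz = count > 0
    mean[nz] = total[nz] / count[nz]
    centers = np.arange(n_bins) * binsize - flank + binsize // 2
    return Metaprofile(centers, mean, len(anchors))


# ----------------------------------------------------- chromatin classes

ACTIVE_CLASS = frozenset({"open", "K4", "K9ac"})
REPRESSED_CLASS = frozenset({"K27"})
NONE_CLASS: frozenset = frozenset()


def gene_state_classes(
    genes: Sequence[Gene],
    loocr_peaks: Sequence[Peak],
    k4_peaks: Sequence[Peak],
    k9ac_peaks: Sequence[Peak],
    k27_peaks: Sequence[Peak],
    expression: ExpressionTable,
    upstream: int = DEFAULT_UPSTREAM,
    genome: Genome | None = None,
) -> tuple[dict[str, frozenset], "pd.DataFrame"]:
    """Label each gene by the combinatorial presence of chromatin features.

    A gene carries a feature when >= 1 peak of that assay overlaps its local
    window, giving 16 possible {open, K4, K9ac, K27} classes.  The summary
    frame holds per-class n and median FPKM plus pairwise rank-sum p-values
    between the fully active class, the K27-only class and the empty class.
    """
    import pandas as pd

    windows = local_windows(genes, upstream, genome)
    win_ivs = [w.interval for w in windows]
    feature_sets = {
        "open": loocr_peaks,
        "K4": k4_peaks,
        "K9ac": k9ac_peaks,
        "K27": k27_peaks,
    }
    labels: dict[str, set] = {g.id: set() for g in genes}
    for feature, peaks in feature_sets.items():
        if not peaks:
            continue
        hit = _intervals.overlaps_any(
            win_ivs, _intervals.merged([p.interval for p in peaks])
        )
        for w, h in zip(windows, hit):
            if h:
                labels[w.gene_id].add(feature)
    classes = {gid: frozenset(s) for gid, s in labels.items()}

    mean_fpkm = expression.mean_fpkm()
    rows = []
    by_class: dict[frozenset, list[float]] = {}
    for gid, cls in classes.items():
        if gid in mean_fpkm.index:
            by_class.setdefault(cls, []).append(float(mean_fpkm[gid]))
    for cls, vals in sorted(by_class.items(), key=lambda kv: sorted(kv[0])):
        rows.append(
            {
                "class": "+".join(sorted(cls)) or "none",
                "n": len(vals),
                "median_fpkm": float(np.median(vals)),
            }
        )
    summary = pd.DataFrame(rows)

    def _p(a: frozenset, b: frozenset) -> float:
        va, vb = by_class.get(a, []), by_class.get(b, [])
        if len(va) < 2 or len(vb) < 2:
            return float("nan")
        return float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)

    summary.attrs["p_active_vs_none"] = _p(ACTIVE_CLASS, NONE_CLASS)
    summary.attrs["p_active_vs_k27"] = _p(ACTIVE_CLASS, REPRESSED_CLASS)
    summary.attrs["p_k27_vs_none"] = _p(REPRESSED_CLASS, NONE_CLASS)
    return classes, summary
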