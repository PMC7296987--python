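"""TAD-boundary conservation between tissues and Hi-C PET quality statistics.

Boundaries are genomic points (bin edges at the calling resolution); two
tissues' boundary sets are matched within a tolerance (10 kb by default)
to quantify conservation.  Hi-C quality is summarised by the intra- vs
inter-chromosomal PET ratio and the fraction of fixed-size bins reaching
a PET-end count threshold (the map-resolution criterion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _intervals, ocr
from .model import Gene, Genome, GenomicInterval, PETRecord, Peak

log = logging.getLogger(__name__)

Boundary = tuple[str, int]  # (chrom, pos)


@dataclass(frozen=True)
class BoundarySet:
    tissue: str
    positions: tuple[Boundary, ...]

    @staticmethod
    def from_points(tissue: str, points: Sequence[Boundary]) -> "BoundarySet":
        return BoundarySet(tissue, tuple(sorted(set(points))))

    @staticmethod
    def from_intervals(
        tissue: str, intervals: Sequence[GenomicInterval]
    ) -> "BoundarySet":
        """Collapse boundary bins (intervals) to their midpoints."""
        return BoundarySet.from_points(
            tissue, [(iv.chrom, iv.midpoint) for iv in intervals]
        )


@dataclass(frozen=True)
class ConservationResult:
    matched: tuple[tuple[Boundary, Boundary], ...]
    a_specific: tuple[Boundary, ...]
    b_specific: tuple[Boundary, ...]

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def a_specific_fraction(self) -> float:
        n = self.n_matched + len(self.a_specific)
        return len(self.a_specific) / n if n else float("nan")

    @property
    def b_specific_fraction(self) -> float:
        n = self.n_matched + len(self.b_specific)
        return len(self.b_specific) / n if n else float("nan")


def conserved_boundaries(
    set_a: BoundarySet,
    set_b: BoundarySet,
    tol: int = 10_000,
    matching: str = "greedy",
) -> ConservationResult:
    """Match boundaries of two tissues within ``tol`` bp.

    ``greedy``: process A in genomic order, pairing each boundary with the
    leftmost unmatched B boundary within tolerance.  For equal-width
    tolerance windows this one-pass rule yields a maximum one-to-one
    matching, so the conserved count is symmetric in the two tissues.
    ``any``: a boundary is matched when any boundary of the other set lies
    within tolerance (not one-to-one).
    """
    if matching not in ("greedy", "any"):
        raise ValueError("matching must be 'greedy' or 'any'")
    a_by: dict[str, list[int]] = {}
    b_by: dict[str, list[int]] = {}
    for chrom, pos in set_a.positions:
        a_by.setdefault(chrom, []).append(pos)
    for chrom, pos in set_b.positions:
        b_by.setdefault(chrom, []).append(pos)

    matched: list[tuple[Boundary, Boundary]] = []
    a_spec: list[Boundary] = []
    b_spec: list[Boundary] = []
    for chrom in sorted(set(a_by) | set(b_by)):
        a_pos = sorted(a_by.get(chrom, []))
        b_pos = sorted(b_by.get(chrom, []))
        if matching == "any":
            b_arr = np.array(b_pos, dtype=np.int64)
            a_arr = np.array(a_pos, dtype=np.int64)
            for p in a_pos:
                if len(b_arr) and np.abs(b_arr - p).min() <= tol:
                    near = int(b_arr[np.abs(b_arr - p).argmin()])
                    matched.append(((chrom, p), (chrom, near)))
                else:
                    a_spec.append((chrom, p))
            for p in b_pos:
                if not (len(a_arr) and np.abs(a_arr - p).min() <= tol):
                    b_spec.append((chrom, p))
            continue
        taken = np.zeros(len(b_pos), dtype=bool)
        b_arr = np.array(b_pos, dtype=np.int64)
        for p in a_pos:
            lo = int(np.searchsorted(b_arr, p - tol, side="left"))
            hi = int(np.searchsorted(b_arr, p + tol, side="right"))
            free = [k for k in range(lo, hi) if not taken[k]]
            if free:
                k = free[0]  # leftmost unmatched within tolerance
                taken[k] = True
                matched.append(((chrom, p), (chrom, int(b_arr[k]))))
            else:
                a_spec.append((chrom, p))
        for k, p in enumerate(b_pos):
            if not taken[k]:
                b_spec.append((chrom, p))
    return ConservationResult(tuple(matched), tuple(a_spec), tuple(b_spec))


def boundary_ocr_split(
    boundaries: Sequence[Boundary],
    ocrs: Sequence[Peak],
    genes: Sequence[Gene],
    boundary_halfwidth: int = 2500,
    prom_up: int = 1000,
    prom_down: int = 200,
    summit_halfwidth: int = 100,
) -> tuple[list[Peak], list[Peak]]:
    """Split boundary-resident OCRs into promoter and non-promoter classes.

    OCRs are first resized to 200 bp centred on their summit; those whose
    resized span overlaps a boundary window ``[pos - halfwidth,
    pos + halfwidth)`` are kept and split by overlap with strand-aware
    promoter windows (1 kb upstream to 200 bp downstream of each TSS).
    Returns the original Peak records, ``(promoter, non_promoter)``.
    """
    resized = [
        GenomicInterval(p.chrom, max(0, p.summit - summit_halfwidth), p.summit + summit_halfwidth)
        for p in ocrs
    ]
    windows = [
        GenomicInterval(chrom, max(0, pos - boundary_halfwidth), pos + boundary_halfwidth)
        for chrom, pos in boundaries
    ]
    in_boundary = (
        _intervals.overlaps_any(resized, _intervals.merged(windows))
        if windows
        else np.zeros(len(ocrs), dtype=bool)
    )
    prom_windows = []
    for g in genes:
        if g.strand == "+":
            prom_windows.append(
                GenomicInterval(g.chrom, max(0, g.tss - prom_up), g.tss + prom_down)
            )
        else:
            prom_windows.append(
                GenomicInterval(g.chrom, max(0, g.tss + 1 - prom_down), g.tss + 1 + prom_up)
            )
    is_prom = (
        _intervals.overlaps_any(resized, _intervals.merged(prom_windows))
        if prom_windows
        else np.zeros(len(ocrs), dtype=bool)
    )
    promoter = [p for p, b, pr in zip(ocrs, in_boundary, is_prom) if b and pr]
    non_promoter = [p for p, b, pr in zip(ocrs, in_boundary, is_prom) if b and not pr]
    return promoter, non_promoter


@dataclass(frozen=True)
class HiCQC:
    n_intra: int
    n_inter: int
    ratio: float  # inf marker when no interchromosomal PETs
    bin_fraction: float
    n_bins: int
    threshold: int
    binsize: int


def hic_qc(
    pets: Sequence[PETRecord],
    genome: Genome,
    binsize: int = 5000,
    threshold: int = 1000,
    all_bins: bool = False,
) -> HiCQC:
    """Intra/inter PET ratio and the fraction of bins with enough PET ends.

    Each PET contributes both ends to the per-bin histogram.  The
    denominator is bins with >= 1 observed end (sequencing-reachable bins)
    unless ``all_bins`` asks for every genomic bin.
    """
    n_intra = sum(1 for p in pets if p.intrachromosomal)
    n_inter = len(pets) - n_intra
    ratio = float("inf") if n_inter == 0 else n_intra / n_inter

    counts: dict[str, np.ndarray] = {
        chrom: np.zeros((length + binsize - 1) // binsize, dtype=np.int64)
        for chrom, length in genome.items()
    }
    for p in pets:
        for chrom, pos in ((p.chrom1, p.pos1), (p.chrom2, p.pos2)):
            counts[chrom][pos // binsize] += 1
    all_counts = np.concatenate([c for c in counts.values()]) if counts else np.array([])
    if all_bins:
        denom = len(all_counts)
        num = int((all_counts >= threshold).sum())
    else:
        observed = all_counts[all_counts >= 1]
        denom = len(observed)
        num = int((observed >= threshold).sum())
    fraction = num / denom if denom else float("nan")
    return HiCQC(n_intra, n_inter, ratio, fraction, denom, threshold, binsize)
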