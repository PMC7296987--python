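"""Co-expression of looped gene pairs vs a distance-matched random-pair null.

Pearson correlation of each looped gene pair across a multi-tissue
expression panel, compared with random same-chromosome gene pairs whose
TSS distance falls in the same log10-distance bin.  Both pair sets are
split into batches; the batch-mean PCCs are compared by a two-tailed
Welch t-test (the reference design: 1000 batches over a 65-tissue panel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .model import ExpressionTable, Gene

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePair:
    gene_a: str
    gene_b: str
    distance: int  # TSS-to-TSS, bp
    pcc: float = float("nan")

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("gene pair must join two distinct genes")


@dataclass(frozen=True)
class BatchComparison:
    n_batches: int
    real_batch_means: np.ndarray
    null_batch_means: np.ndarray
    t: float
    p: float


def pairs_from_loops(classified_loops, genes: Sequence[Gene]) -> list[GenePair]:
    """Distinct same-chromosome gene pairs joined by gene-gene loops,
    one pair per (gene on anchor A, gene on anchor B) combination."""
    tss = {g.id: g.tss for g in genes}
    chrom = {g.id: g.chrom for g in genes}
    seen: set[tuple[str, str]] = set()
    out: list[GenePair] = []
    for cl in classified_loops:
        if not (cl.genes_a and cl.genes_b):
            continue
        for ga in cl.genes_a:
            for gb in cl.genes_b:
                if ga == gb or chrom.get(ga) != chrom.get(gb):
                    continue
                key = (min(ga, gb), max(ga, gb))
                if key in seen:
                    continue
                seen.add(key)
                out.append(GenePair(key[0], key[1], abs(tss[ga] - tss[gb])))
    return out


def pair_pcc(
    pairs: Sequence[GenePair], panel: ExpressionTable
) -> tuple[list[GenePair], int]:
    """Attach the Pearson correlation across panel samples to each pair.

    Pairs with a gene missing from the panel or with a zero-variance
    profile are dropped; the drop count is returned alongside.
    """
    if len(panel.samples) < 3:
        raise ValueError("panel must have >= 3 samples")
    genes = set(panel.genes)
    out = []
    dropped = 0
    for pair in pairs:
        if pair.gene_a not in genes or pair.gene_b not in genes:
            dropped += 1
            continue
        xa = panel.profile(pair.gene_a)
        xb = panel.profile(pair.gene_b)
        if np.std(xa) == 0 or np.std(xb) == 0:
            dropped += 1
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        out.append(replace(pair, pcc=r))
    if dropped:
        log.info("pair_pcc: dropped %d pairs (missing gene or zero variance)", dropped)
    return out, dropped


def distance_matched_null(
    real_pairs: Sequence[GenePair],
    genes: Sequence[Gene],
    seed: int | np.random.Generator,
    n_sets: int = 1,
    bin_width_log10: float = 0.1,
) -> list[GenePair]:
    """Random same-chromosome gene pairs matching the real pairs' TSS
    distances within log10 bins of width ``bin_width_log10``.

    For each real pair one null pair is drawn per set, without replacement
    within a set, excluding the real looped pairs themselves.  When a bin
    has no unused candidate the nearest non-empty bin is used (logged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        if len(gs) < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 genes")
    real_keys = {(min(p.gene_a, p.gene_b), max(p.gene_a, p.gene_b)) for p in real_pairs}

    def dist_bin(d: int) -> int:
        return int(np.floor(np.log10(max(d, 1)) / bin_width_log10))

    # all candidate same-chromosome pairs, grouped by distance bin
    candidates: dict[int, list[GenePair]] = {}
    for chrom, gs in sorted(by_chrom.items()):
        gs = sorted(gs, key=lambda g: g.tss)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                ga, gb = gs[i], gs[j]
                key = (min(ga.id, gb.id), max(ga.id, gb.id))
                if key in real_keys:
                    continue
                d = abs(ga.tss - gb.tss)
                if d == 0:
                    continue
                candidates.setdefault(dist_bin(d), []).append(
                    GenePair(key[0], key[1], d)
                )
    for b in candidates:
        candidates[b].sort(key=lambda p: (p.gene_a, p.gene_b))

    out: list[GenePair] = []
    n_fallback = 0
    for _ in range(n_sets):
        used: set[tuple[str, str]] = set()
        for pair in real_pairs:
            b = dist_bin(pair.distance)
            chosen = None
            # walk outward from the target bin until an unused candidate exists
            bins = sorted(candidates, key=lambda x: (abs(x - b), x))
            for bb in bins:
                avail = [
                    c for c in candidates[bb] if (c.gene_a, c.gene_b) not in used
                ]
                if avail:
                    if bb != b:
                        n_fallback += 1
                    chosen = avail[int(rng.integers(0, len(avail)))]
                    break
            if chosen is None:
                raise ValueError("no candidate gene pairs left to sample")
            used.add((chosen.gene_a, chosen.gene_b))
            out.append(chosen)
    if n_fallback:
        log.info(
            "distance_matched_null: %d draws fell back to a neighbouring bin",
            n_fallback,
        )
    return out


def batch_ttest(
    real_pairs: Sequence[GenePair],
    null_pairs: Sequence[GenePair],
    seed: int | np.random.Generator,
    n_batches: int = 1000,
) -> BatchComparison:
    """Batch-mean comparison of real vs null PCCs (two-tailed Welch t).

    Each pair set is randomly partitioned into ``n_batches`` batches of
    near-equal size (difference <= 1); the test runs on the per-batch mean
    PCCs.  When a set has fewer pairs than batches the batch count is
    reduced to the smaller pair count (logged).
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = min(len(real_pairs), len(null_pairs), n_batches)
    if n < n_batches:
        log.info("batch_ttest: reducing batches from %d to %d", n_batches, n)
    if n < 2:
        raise ValueError("need at least 2 pairs per set")

    shared_perm = (
        rng.permutation(len(real_pairs)) if len(real_pairs) == len(null_pairs) else None
    )

    def batch_means(pairs: Sequence[GenePair]) -> np.ndarray:
        pcc = np.array([p.pcc for p in pairs], dtype=float)
        if np.isnan(pcc).any():
            raise ValueError("pairs must carry PCCs (run pair_pcc first)")
        perm = shared_perm if shared_perm is not None else rng.permutation(len(pcc))
        return np.array([chunk.mean() for chunk in np.array_split(pcc[perm], n)])

    real_means = batch_means(real_pairs)
    null_means = batch_means(null_pairs)
    if np.std(real_means) == 0 and np.std(null_means) == 0:
        t = 0.0 if np.mean(real_means) == np.mean(null_means) else float("inf")
        p = 1.0 if t == 0.0 else 0.0
        log.warning("batch_ttest: zero variance in both batch-mean sets")
    else:
        res = stats.ttest_ind(real_means, null_means, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return BatchComparison(n, real_means, null_means, t, p)
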