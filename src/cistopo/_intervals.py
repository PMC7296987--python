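"""Internal sorted-array interval machinery.

All heavy overlap logic runs on per-chromosome numpy arrays of merged,
sorted intervals; the public modules convert to and from the record
dataclasses at their boundaries.  Semantics throughout: an overlap is
>= 1 shared bp between half-open spans.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import GenomicInterval

ChromArrays = dict[str, tuple[np.ndarray, np.ndarray]]


def by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def to_arrays(intervals: Iterable[GenomicInterval]) -> ChromArrays:
    """Per-chromosome (starts, ends) arrays sorted by start (not merged)."""
    out: ChromArrays = {}
    for chrom, ivs in by_chrom(intervals).items():
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        order = np.lexsort((ends, starts))
        out[chrom] = (starts[order], ends[order])
    return out


def merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals into disjoint runs (book-ended spans stay split-free)."""
    if len(starts) == 0:
        return starts, ends
    cummax = np.maximum.accumulate(ends)
    # a new run starts where the interval begins beyond everything seen so far
    new_run = np.empty(len(starts), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > cummax[:-1]
    run_first = np.nonzero(new_run)[0]
    run_last = np.append(run_first[1:] - 1, len(starts) - 1)
    return starts[run_first], cummax[run_last]


def merged(intervals: Iterable[GenomicInterval]) -> ChromArrays:
    return {c: merge_arrays(s, e) for c, (s, e) in to_arrays(intervals).items()}


def any_overlap_arrays(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    m_starts: np.ndarray,
    m_ends: np.ndarray,
) -> np.ndarray:
    """Boolean per query: overlaps >=1 bp of the merged reference runs."""
    if len(m_starts) == 0 or len(q_starts) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    # first reference run ending beyond the query start
    idx = np.searchsorted(m_ends, q_starts, side="right")
    hit = idx < len(m_starts)
    hit[hit] &= m_starts[idx[hit]] < q_ends[hit]
    return hit


def overlaps_any(
    queries: Sequence[GenomicInterval], reference: ChromArrays
) -> np.ndarray:
    """Vector of booleans, one per query interval in input order."""
    flags = np.zeros(len(queries), dtype=bool)
    grouped: dict[str, list[int]] = {}
    for i, iv in enumerate(queries):
        grouped.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in grouped.items():
        if chrom not in reference:
            continue
        m_starts, m_ends = reference[chrom]
        qs = np.array([queries[i].start for i in idxs], dtype=np.int64)
        qe = np.array([queries[i].end for i in idxs], dtype=np.int64)
        flags[np.array(idxs)] = any_overlap_arrays(qs, qe, m_starts, m_ends)
    return flags


def points_in(positions: Mapping[str, np.ndarray], reference: ChromArrays) -> dict[str, np.ndarray]:
    """Per-chromosome boolean masks: position falls inside a merged run."""
    out: dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in reference or len(pos) == 0:
            out[chrom] = np.zeros(len(pos), dtype=bool)
            continue
        m_starts, m_ends = reference[chrom]
        idx = np.searchsorted(m_ends, pos, side="right")
        hit = idx < len(m_starts)
        hit[hit] &= m_starts[idx[hit]] <= pos[hit]
        out[chrom] = hit
    return out


def overlapping_pairs(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (i, j) index pairs with a[i] overlapping b[j] (sweep per chromosome)."""
    pairs: list[tuple[int, int]] = []
    a_by: dict[str, list[int]] = {}
    b_by: dict[str, list[int]] = {}
    for i, iv in enumerate(a):
        a_by.setdefault(iv.chrom, []).append(i)
    for j, iv in enumerate(b):
        b_by.setdefault(iv.chrom, []).append(j)
    for chrom, ai in a_by.items():
        bj = b_by.get(chrom)
        if not bj:
            continue
        bj_sorted = sorted(bj, key=lambda j: b[j].start)
        b_starts = np.array([b[j].start for j in bj_sorted], dtype=np.int64)
        b_ends = np.array([b[j].end for j in bj_sorted], dtype=np.int64)
        max_len = int((b_ends - b_starts).max())
        for i in ai:
            iv = a[i]
            # candidates: b.start in [iv.start - max_len, iv.end)
            lo = int(np.searchsorted(b_starts, iv.start - max_len, side="left"))
            hi = int(np.searchsorted(b_starts, iv.end, side="left"))
            for k in range(lo, hi):
                if b_ends[k] > iv.start and b_starts[k] < iv.end:
                    pairs.append((i, bj_sorted[k]))
    return pairs


def complement(
    reference: ChromArrays, genome_lengths: Mapping[str, int]
) -> ChromArrays:
    """Per-chromosome gaps not covered by the merged reference runs."""
    out: ChromArrays = {}
    for chrom, length in genome_lengths.items():
        if chrom in reference:
            m_starts, m_ends = reference[chrom]
            m_starts = np.clip(m_starts, 0, length)
            m_ends = np.clip(m_ends, 0, length)
            gap_starts = np.concatenate(([0], m_ends))
            gap_ends = np.concatenate((m_starts, [length]))
            keep = gap_starts < gap_ends
            out[chrom] = (gap_starts[keep], gap_ends[keep])
        else:
            out[chrom] = (
                np.array([0], dtype=np.int64),
                np.array([length], dtype=np.int64),
            )
    return out
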