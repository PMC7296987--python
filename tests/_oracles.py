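"""Independent brute-force oracles used to verify the interval machinery.

Everything here is deliberately naive (all-pairs scans, per-base loops)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np

from cistopo.model import GenomicInterval


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def assign_all_pairs(queries, windows) -> list[set]:
    """Per query: indices of every window it overlaps (O(n*m) scan)."""
    return [{j for j, w in enumerate(windows) if overlaps(q, w)} for q in queries]


def overlap_fraction(queries, reference) -> float:
    hit = sum(1 for q in queries if any(overlaps(q, r) for r in reference))
    return hit / len(queries)


def metaprofile_per_base(track, anchors, flank, binsize, genome=None):
    """Naive per-base averaging with out-of-bounds bases excluded."""
    n_bins = 2 * flank // binsize
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for anchor in anchors:
        chrom, pos = anchor[0], int(anchor[1])
        strand = anchor[2] if len(anchor) > 2 else "."
        for off in range(2 * flank):
            base = pos - flank + off
            if genome is not None and not (0 <= base < genome.length_of(chrom)):
                continue
            val = float(track.per_base(chrom, base, base + 1)[0])
            b = off if strand != "-" else (2 * flank - 1 - off)
            sums[b // binsize] += val
            counts[b // binsize] += 1
    out = np.full(n_bins, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def max_boundary_matching(a_pos, b_pos, tol) -> int:
    """Maximum bipartite matching size between two position lists."""
    import networkx as nx

    g = nx.Graph()
    a_nodes = [("a", i) for i in range(len(a_pos))]
    b_nodes = [("b", j) for j in range(len(b_pos))]
    g.add_nodes_from(a_nodes, bipartite=0)
    g.add_nodes_from(b_nodes, bipartite=1)
    for i, p in enumerate(a_pos):
        for j, q in enumerate(b_pos):
            if abs(p - q) <= tol:
                g.add_edge(("a", i), ("b", j))
    match = nx.bipartite.maximum_matching(g, top_nodes=a_nodes)
    return sum(1 for k in match if k[0] == "a")


def pet_end_histogram(pets, genome, binsize):
    counts = {
        chrom: np.zeros((length + binsize - 1) // binsize, dtype=int)
        for chrom, length in genome.items()
    }
    for p in pets:
        counts[p.chrom1][p.pos1 // binsize] += 1
        counts[p.chrom2][p.pos2 // binsize] += 1
    return counts


def random_intervals(rng, genome, n, min_len=100, max_len=2000, stranded=False):
    chroms = list(genome)
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, genome.length_of(chrom) - length))
        strand = ("+", "-")[int(rng.integers(0, 2))] if stranded else "."
        out.append(GenomicInterval(chrom, start, start + length, strand))
    return out
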