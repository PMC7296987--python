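"""Core genomic data model.

Every coordinate in the package is 0-based, half-open ``[start, end)`` on a
named chromosome, the BED convention.  GFF3 input (1-based, closed) is
converted at the parsing boundary and never leaks inward.  Sorting is total
and stable: ``(chrom lexicographic, start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Malformed input file (carries the offending line number when known)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def shifted(self, delta: int) -> "GenomicInterval":
        return replace(self, start=self.start + delta, end=self.end + delta)


class Genome:
    """Ordered map chromosome name -> length in bp."""

    def __init__(self, lengths: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        seen: dict[str, int] = {}
        for name, length in items:
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if name in seen:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            seen[name] = int(length)
        self._lengths = seen

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._lengths == other._lengths

    def items(self):
        return self._lengths.items()

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def check(self, iv: GenomicInterval) -> None:
        if iv.end > self.length_of(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.length_of(iv.chrom)}"
            )

    def check_names(self, chroms: Iterable[str], context: str = "input") -> None:
        """Error listing every chromosome name absent from the genome table."""
        missing = sorted({c for c in chroms if c not in self._lengths})
        if missing:
            raise ValueError(
                f"{context} references chromosomes not in the genome table: "
                + ", ".join(missing)
            )


@dataclass(frozen=True)
class Gene:
    """A stranded gene model; TSS/TTS are derived from strand.

    On the + strand the TSS is ``interval.start`` and the TTS is
    ``interval.end - 1``; on the - strand the two are swapped.
    """

    id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r} must be stranded (+ or -)")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class Peak:
    """An interval call (OCR, histone mark or TF binding site).

    ``qvalue`` is stored in the dialect of its source: narrowPeak carries
    -log10(q) (``q_neglog10=True``), plain tables carry raw q.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    qvalue: float = float("nan")
    name: str = ""
    q_neglog10: bool = True

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError("peak score must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class Loop:
    """An intrachromosomal chromatin loop: an ordered pair of anchors.

    Anchors are canonicalised so that ``anchor_a`` precedes ``anchor_b`` by
    start coordinate; ``span`` is the distance between anchor midpoints.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor_b.start < self.anchor_a.start:
            a, b = self.anchor_b, self.anchor_a
            object.__setattr__(self, "anchor_a", a)
            object.__setattr__(self, "anchor_b", b)

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom

    @property
    def span(self) -> int:
        return abs(self.anchor_b.midpoint - self.anchor_a.midpoint)


class ExpressionTable:
    """Gene x sample FPKM matrix with optional per-gene differential stats."""

    def __init__(
        self,
        values: pd.DataFrame,
        qvalue: pd.Series | None = None,
        fold_change: pd.Series | None = None,
    ):
        if (values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression table")
        self.values = values.astype(float)
        self.qvalue = qvalue.reindex(values.index) if qvalue is not None else None
        self.fold_change = (
            fold_change.reindex(values.index) if fold_change is not None else None
        )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy()

    def mean_fpkm(self, samples: Sequence[str] | None = None) -> pd.Series:
        sub = self.values if samples is None else self.values[list(samples)]
        return sub.mean(axis=1)


class CoverageTrack:
    """Sparse per-base signal (bedGraph semantics: absent bases are 0).

    Per chromosome the records are sorted, non-overlapping ``[start, end)``
    steps with finite values.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if not np.isfinite(value):
                raise ValueError(f"non-finite coverage value on {chrom}:{start}")
            if start >= end:
                raise ValueError(f"empty coverage record {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            vals = np.array([r[2] for r in recs], dtype=float)
            if len(recs) > 1 and (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping coverage records on {chrom}")
            self._data[chrom] = (starts, ends, vals)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def records(self):
        for chrom in self.chroms:
            starts, ends, vals = self._data[chrom]
            for s, e, v in zip(starts, ends, vals):
                yield chrom, int(s), int(e), float(v)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over ``[start, end)``; uncovered bases are 0."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._data:
            return out
        starts, ends, vals = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start) - start
            b = min(int(ends[i]), end) - start
            if a < b:
                out[a:b] = vals[i]
        return out


@dataclass(frozen=True)
class PETRecord:
    """One Hi-C paired-end tag: the two mapped ends."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2


@dataclass(frozen=True)
class SNPRecord:
    """A trait-associated point variant (0-based position)."""

    chrom: str
    pos: int
    id: str
    trait: str
    locality: str | None = None  # set by classify_snps

    def with_locality(self, locality: str) -> "SNPRecord":
        return replace(self, locality=locality)


def sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def sorted_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(ivs, key=sort_key)


def sorted_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    return sorted(peaks, key=lambda p: sort_key(p.interval))
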