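"""Readers and writers for the plain-text formats the pipeline touches.

Supported: genome table (``chrom<TAB>length``), BED3/6, narrowPeak,
broadPeak, GFF3 genes, a tabular gene table, BEDPE loops, bedGraph
coverage, and TSVs for expression panels, SNPs and Hi-C PETs.  All
readers validate against the model invariants and report malformed lines
by number; all writers emit tab-separated text that round-trips.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    CoverageTrack,
    ExpressionTable,
    FormatError,
    Gene,
    Genome,
    GenomicInterval,
    Loop,
    PETRecord,
    Peak,
    SNPRecord,
    sorted_peaks,
)

PEAK_DIALECTS = ("bed", "narrowpeak", "broadpeak")
GENE_DIALECTS = ("gff3", "gene_tsv")


def _lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _bad(path, lineno: int, msg: str) -> FormatError:
    return FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- genome


def read_genome(path) -> Genome:
    items = []
    for lineno, f in _lines(path):
        if len(f) < 2:
            raise _bad(path, lineno, "genome table needs 2 columns")
        items.append((f[0], int(f[1])))
    return Genome(items)


def write_genome(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


# ----------------------------------------------------------------- peaks


def read_intervals(path, dialect: str = "bed") -> list[Peak]:
    """Read a BED / narrowPeak / broadPeak file as Peak records.

    narrowPeak summits come from column 10 (offset from start); plain BED
    and broadPeak use the interval midpoint.  Output is sorted by
    ``(chrom, start, end)``.
    """
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    for lineno, f in _lines(path):
        if len(f) < 3:
            raise _bad(path, lineno, "need at least 3 columns")
        if dialect == "narrowpeak" and len(f) < 10:
            raise _bad(path, lineno, "narrowPeak needs 10 columns")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
        except ValueError:
            raise _bad(path, lineno, "non-integer coordinates") from None
        if start >= end:
            raise _bad(path, lineno, f"start {start} >= end {end}")
        name = f[3] if len(f) > 3 and f[3] != "." else ""
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        score = 0.0
        qvalue = math.nan
        q_neglog10 = True
        if dialect in ("narrowpeak", "broadpeak") and len(f) >= 9:
            try:
                score = float(f[6])
                qvalue = float(f[8])
            except ValueError:
                raise _bad(path, lineno, "non-numeric signal/q columns") from None
        elif len(f) > 4 and f[4] not in (".", ""):
            score = float(f[4])
        if dialect == "narrowpeak":
            try:
                offset = int(f[9])
            except ValueError:
                raise _bad(path, lineno, "non-integer summit offset") from None
            summit = start + offset if offset >= 0 else (start + end) // 2
        else:
            summit = (start + end) // 2
        try:
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    summit=summit,
                    score=max(score, 0.0),
                    qvalue=qvalue,
                    name=name,
                    q_neglog10=q_neglog10,
                )
            )
        except ValueError as exc:
            raise _bad(path, lineno, str(exc)) from None
    return sorted_peaks(peaks)


def write_peaks(peaks: Sequence[Peak], path, dialect: str = "narrowpeak") -> None:
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in sorted_peaks(peaks):
            name = p.name or "."
            if dialect == "narrowpeak":
                q = -1.0 if math.isnan(p.qvalue) else p.qvalue
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t{p.interval.strand}"
                    f"\t{p.score:g}\t-1\t{q:g}\t{p.summit - p.start}\n"
                )
            else:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:g}"
                    f"\t{p.interval.strand}\n"
                )


def write_intervals_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    return [p.interval for p in read_intervals(path, dialect="bed")]


# ----------------------------------------------------------------- genes


def read_genes(path, dialect: str = "gff3") -> list[Gene]:
    """Read gene models; GFF3 rows of type ``gene`` (1-based, closed) are
    converted to 0-based half-open.  Unstranded or duplicated genes are errors.
    """
    if dialect not in GENE_DIALECTS:
        raise ValueError(f"unknown gene dialect {dialect!r}")
    genes: list[Gene] = []
    seen: set[str] = set()
    for lineno, f in _lines(path):
        if dialect == "gff3":
            if len(f) < 9:
                raise _bad(path, lineno, "GFF3 needs 9 columns")
            if f[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = f[0], f[3], f[4], f[6], f[8]
            start, end = int(start1) - 1, int(end1)
            gene_id = ""
            for token in attrs.split(";"):
                key, _, value = token.strip().partition("=")
                if key == "ID":
                    gene_id = value.removeprefix("gene:")
                    break
            if not gene_id:
                raise _bad(path, lineno, "gene row without ID attribute")
        else:
            if len(f) < 5:
                raise _bad(path, lineno, "gene_tsv needs id, chrom, start, end, strand")
            gene_id, chrom, start, end, strand = (
                f[0],
                f[1],
                int(f[2]),
                int(f[3]),
                f[4],
            )
        if strand not in ("+", "-"):
            raise _bad(path, lineno, f"gene {gene_id!r} missing strand")
        if gene_id in seen:
            raise _bad(path, lineno, f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        try:
            genes.append(Gene(gene_id, GenomicInterval(chrom, start, end, strand)))
        except ValueError as exc:
            raise _bad(path, lineno, str(exc)) from None
    return sorted(genes, key=lambda g: (g.chrom, g.interval.start, g.interval.end))


def write_genes(genes: Sequence[Gene], path, dialect: str = "gff3") -> None:
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tcistopo\tgene\t{g.interval.start + 1}"
                    f"\t{g.interval.end}\t.\t{g.strand}\t.\tID={g.id}\n"
                )
        else:
            for g in genes:
                fh.write(
                    f"{g.id}\t{g.chrom}\t{g.interval.start}\t{g.interval.end}"
                    f"\t{g.strand}\n"
                )


# ----------------------------------------------------------------- loops


def read_loops(path) -> tuple[list[Loop], int]:
    """Read BEDPE loops; interchromosomal rows are skipped and counted.

    Returns ``(loops, n_skipped_interchromosomal)``.
    """
    loops: list[Loop] = []
    skipped = 0
    for lineno, f in _lines(path):
        if len(f) < 6:
            raise _bad(path, lineno, "BEDPE needs at least 6 columns")
        c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
        if c1 != c2:
            skipped += 1
            continue
        try:
            loops.append(
                Loop(GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2))
            )
        except ValueError as exc:
            raise _bad(path, lineno, str(exc)) from None
    return loops, skipped


def write_loops(loops: Sequence[Loop], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )


# -------------------------------------------------------------- coverage


def read_coverage(path) -> CoverageTrack:
    records = []
    for lineno, f in _lines(path):
        if len(f) < 4:
            raise _bad(path, lineno, "bedGraph needs 4 columns")
        try:
            records.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        except ValueError:
            raise _bad(path, lineno, "malformed bedGraph row") from None
    try:
        return CoverageTrack(records)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_coverage(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ------------------------------------------------------------------ PETs


def read_pets(path, genome: Genome | None = None) -> list[PETRecord]:
    pets: list[PETRecord] = []
    for lineno, f in _lines(path):
        if f[0] == "chrom1":  # header
            continue
        if len(f) < 4:
            raise _bad(path, lineno, "PET rows need 4 columns")
        rec = PETRecord(f[0], int(f[1]), f[2], int(f[3]))
        if genome is not None:
            for chrom, pos in ((rec.chrom1, rec.pos1), (rec.chrom2, rec.pos2)):
                if chrom not in genome or not (0 <= pos < genome.length_of(chrom)):
                    raise _bad(path, lineno, f"position {chrom}:{pos} out of bounds")
        pets.append(rec)
    return pets


def write_pets(pets: Sequence[PETRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom1\tpos1\tchrom2\tpos2\n")
        for p in pets:
            fh.write(f"{p.chrom1}\t{p.pos1}\t{p.chrom2}\t{p.pos2}\n")


# ------------------------------------------------------------------ SNPs


def read_snps(path) -> list[SNPRecord]:
    snps: list[SNPRecord] = []
    first = True
    for lineno, f in _lines(path):
        if first and f[0] in ("chrom", "CHROM"):
            first = False
            continue
        first = False
        if len(f) < 4:
            raise _bad(path, lineno, "SNP rows need chrom, pos, id, trait")
        snps.append(SNPRecord(f[0], int(f[1]), f[2], f[3]))
    return snps


def write_snps(snps: Sequence[SNPRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tid\ttrait\tlocality\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.id}\t{s.trait}\t{s.locality or '.'}\n")


# ------------------------------------------------------------ expression


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    qvalue = None
    fold_change = None
    if "qvalue" in df.columns:
        qvalue = df.pop("qvalue")
    if "fold_change" in df.columns:
        fold_change = df.pop("fold_change")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric FPKM value ({exc})") from None
    if values.isna().any().any():
        raise FormatError(f"{path}: missing FPKM values")
    return ExpressionTable(values, qvalue=qvalue, fold_change=fold_change)


def write_expression(table: ExpressionTable, path) -> None:
    df = table.values.copy()
    if table.qvalue is not None:
        df["qvalue"] = table.qvalue
    if table.fold_change is not None:
        df["fold_change"] = table.fold_change
    df.to_csv(path, sep="\t", index_label="gene")


# ------------------------------------------------- differential peak BEDs


def read_differential_peaks(path) -> list[tuple[Peak, str, str, str]]:
    """Read a differential-peak BED: chrom, start, end, feature, tissue, change.

    ``feature`` names the assay (OCR, K4me3, K27me3), ``tissue`` the tissue the
    peak is polarised toward, ``change`` is ``enriched`` or ``depleted``.
    Returns ``(peak, feature, tissue, change)`` tuples.
    """
    out = []
    for lineno, f in _lines(path):
        if f[0] == "chrom":
            continue
        if len(f) < 6:
            raise _bad(path, lineno, "differential peaks need 6 columns")
        chrom, start, end, feature, tissue, change = (
            f[0],
            int(f[1]),
            int(f[2]),
            f[3],
            f[4],
            f[5],
        )
        if change not in ("enriched", "depleted"):
            raise _bad(path, lineno, f"unknown change {change!r}")
        iv = GenomicInterval(chrom, start, end)
        out.append((Peak(iv, iv.midpoint), feature, tissue, change))
    return out


def write_differential_peaks(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tfeature\ttissue\tchange\n")
        for peak, feature, tissue, change in rows:
            fh.write(
                f"{peak.chrom}\t{peak.start}\t{peak.end}"
                f"\t{feature}\t{tissue}\t{change}\n"
            )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
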