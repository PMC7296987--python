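"""Seeded generator of a complete toy two-tissue regulatory-genomics dataset.

The bundle emulates every input the pipeline reads — a multi-chromosome
genome, stranded genes, local/distal OCRs at a planted proportion,
histone-mark peaks, differential-peak sets, coverage tracks, chromatin
loops with planted co-expressed pairs and dOCR-gene links, a multi-tissue
expression panel, trait SNPs and Hi-C PETs — with a manifest of every
planted label so each pipeline stage can be checked against ground truth.

The generator is a pure function of its :class:`SimConfig`: the same
config yields a byte-identical file bundle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .model import Gene, Genome, GenomicInterval, Loop, PETRecord, Peak, SNPRecord

TISSUES = ("ear", "tassel")

_PAD = 3000  # bp kept gene-free on both sides of each gene body
_MIN_GENE_LEN, _MAX_GENE_LEN = 1500, 3000
_MIN_OCR_LEN, _MAX_OCR_LEN = 300, 600
_GAP_EDGE_MARGIN = 2000  # distal features keep this distance from gap edges


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults plant the magnitudes the pipeline is meant to recover: 63%
    local OCRs, a (0.70, 0.25, 0.05) loop-class mix, 65% of intergenic-gene
    loop anchors holding a dOCR, looped-pair expression correlation 0.4,
    and 3x enrichments for active-dOCR targeting and SNP-in-dOCR placement.
    """

    seed: int = 1
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 400
    n_ocrs: int = 1200
    local_fraction: float = 0.63
    n_tissues_panel: int = 65
    n_replicates: int = 3
    deg_fraction: float = 0.15
    deg_fc: float = 3.0
    tf_in_ocr_rate: float = 0.9
    n_tfs: int = 3
    tf_sites_per_tf: int = 200
    n_loops: int = 600
    loop_class_mix: tuple[float, float, float] = (0.70, 0.25, 0.05)
    looped_pair_pcc: float = 0.4
    docr_in_anchor_rate: float = 0.65
    active_docr_target_enrichment: float = 3.0
    # base per-tissue rate at which a dOCR-gene loop targets that tissue's
    # enriched genes; active links use enrichment x this rate (capped at 1)
    docr_link_deg_rate: float = 0.25
    active_link_fraction: float = 0.30
    n_snps: int = 1000
    snp_intergenic_fraction: float = 0.33
    snp_in_docr_enrichment: float = 3.0
    transcribed_docr_fraction: float = 0.12
    replicate_noise_sigma: float = 0.05
    n_pets: int = 20_000
    intra_inter_ratio: float = 5.36
    n_boundaries: int = 40
    boundary_conserved_fraction: float = 0.70

    def genes_per_chrom(self) -> list[int]:
        base = self.n_genes // self.n_chroms
        extra = self.n_genes % self.n_chroms
        return [base + (1 if i < extra else 0) for i in range(self.n_chroms)]

    def validate(self) -> None:
        fractions = (
            self.local_fraction,
            self.deg_fraction,
            self.tf_in_ocr_rate,
            self.docr_in_anchor_rate,
            self.docr_link_deg_rate,
            self.active_link_fraction,
            self.snp_intergenic_fraction,
            self.transcribed_docr_fraction,
            self.boundary_conserved_fraction,
            *self.loop_class_mix,
        )
        if any(not (0.0 <= f <= 1.0) for f in fractions):
            raise ValueError("all fractions must lie in [0, 1]")
        if abs(sum(self.loop_class_mix) - 1.0) > 1e-9:
            raise ValueError("loop_class_mix must sum to 1")
        if (
            min(
                self.snp_in_docr_enrichment,
                self.active_docr_target_enrichment,
                self.deg_fc,
            )
            <= 0
        ):
            raise ValueError("enrichments and fold changes must be positive")
        slot = (self.chrom_length - 20_000) / max(self.genes_per_chrom())
        if slot < _MAX_GENE_LEN + 2 * _PAD + 2_000:
            raise ValueError(
                "infeasible config: chromosomes too short for the gene count"
            )


@dataclass
class SimBundle:
    """Paths of the written files plus the planted-label manifest."""

    outdir: Path
    config: SimConfig
    paths: dict[str, Path]
    manifest: pd.DataFrame

    def path(self, key: str) -> Path:
        return self.paths[key]


class _GapAllocator:
    """Places non-overlapping intervals inside intergenic gaps."""

    def __init__(self, gaps: list[GenomicInterval], rng: np.random.Generator):
        self.gaps = [g for g in gaps if g.length > 2 * _GAP_EDGE_MARGIN + _MAX_OCR_LEN]
        self.rng = rng
        self.used: dict[int, list[tuple[int, int]]] = {
            i: [] for i in range(len(self.gaps))
        }

    def _weights(self, chrom: str | None) -> np.ndarray:
        w = np.array(
            [
                (g.length - 2 * _GAP_EDGE_MARGIN)
                if (chrom is None or g.chrom == chrom)
                else 0.0
                for g in self.gaps
            ]
        )
        total = w.sum()
        if total <= 0:
            raise ValueError(f"no intergenic space available on {chrom}")
        return w / total

    def place(
        self, width: int, margin: int = 300, chrom: str | None = None
    ) -> GenomicInterval:
        weights = self._weights(chrom)
        for _ in range(300):
            gi = int(self.rng.choice(len(self.gaps), p=weights))
            gap = self.gaps[gi]
            lo = gap.start + _GAP_EDGE_MARGIN
            hi = gap.end - _GAP_EDGE_MARGIN - width
            if hi <= lo:
                continue
            start = int(self.rng.integers(lo, hi + 1))
            end = start + width
            if not any(
                start - margin < ue and us < end + margin for us, ue in self.used[gi]
            ):
                self.used[gi].append((start, end))
                return GenomicInterval(gap.chrom, start, end)
        raise ValueError("could not place interval: intergenic space saturated")


def _rasterised_track(
    bumps: list[tuple[str, int, float, float]],
    chrom_length: int,
    step: int = 25,
) -> list[tuple[str, int, int, float]]:
    """Sum Gaussian bumps (chrom, center, amplitude, sigma) onto a step grid."""
    acc: dict[str, dict[int, float]] = {}
    for chrom, center, amp, sigma in bumps:
        half = int(3 * sigma)
        b_lo = max(0, (center - half) // step)
        b_hi = min((chrom_length - 1) // step, (center + half) // step)
        grid = acc.setdefault(chrom, {})
        for b in range(b_lo, b_hi + 1):
            mid = b * step + step / 2
            val = amp * float(np.exp(-0.5 * ((mid - center) / sigma) ** 2))
            if val > 0.01:
                grid[b] = grid.get(b, 0.0) + val
    records = []
    for chrom in sorted(acc):
        for b in sorted(acc[chrom]):
            records.append(
                (
                    chrom,
                    b * step,
                    min((b + 1) * step, chrom_length),
                    round(acc[chrom][b], 4),
                )
            )
    return records


def simulate(config: SimConfig, outdir) -> SimBundle:
    """Write the full synthetic bundle into ``outdir`` and return it."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = cio.ensure_dir(outdir)
    paths: dict[str, Path] = {}
    rows: list[dict] = []

    def note(record_type: str, record_id: str, label: str, extra: str = "") -> None:
        rows.append(
            {
                "record_type": record_type,
                "record_id": record_id,
                "label": label,
                "extra": extra,
            }
        )

    # ------------------------------------------------------------ genome
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = Genome({c: config.chrom_length for c in chroms})
    paths["genome"] = out / "genome.txt"
    cio.write_genome(genome, paths["genome"])

    # ------------------------------------------------------------- genes
    genes: list[Gene] = []
    gid = 0
    for chrom, n_c in zip(chroms, config.genes_per_chrom()):
        usable_lo, usable_hi = 10_000, config.chrom_length - 10_000
        slot = (usable_hi - usable_lo) / n_c
        for k in range(n_c):
            gid += 1
            length = int(rng.integers(_MIN_GENE_LEN, _MAX_GENE_LEN + 1))
            slot_lo = int(usable_lo + k * slot) + _PAD
            slot_hi = int(usable_lo + (k + 1) * slot) - _PAD - length
            start = int(rng.integers(slot_lo, slot_hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(
                    f"gene_{gid:04d}",
                    GenomicInterval(chrom, start, start + length, strand),
                )
            )
    paths["genes"] = out / "genes.gff3"
    cio.write_genes(genes, paths["genes"], dialect="gff3")
    gene_by_id = {g.id: g for g in genes}

    # intergenic gaps: complement of gene spans padded by 3 kb on both sides
    gaps: list[GenomicInterval] = []
    for chrom in chroms:
        spans = sorted(
            (g.interval.start - _PAD, g.interval.end + _PAD)
            for g in genes
            if g.chrom == chrom
        )
        prev = 0
        for s, e in spans:
            if s > prev:
                gaps.append(GenomicInterval(chrom, prev, s))
            prev = max(prev, e)
        if prev < config.chrom_length:
            gaps.append(GenomicInterval(chrom, prev, config.chrom_length))
    alloc = _GapAllocator(gaps, rng)

    # --------------------------------------- chromatin state per gene
    state_choices = [
        (frozenset({"open", "K4", "K9ac"}), 0.40),
        (frozenset({"K27"}), 0.15),
        (frozenset(), 0.20),
        (frozenset({"open", "K4"}), 0.10),
        (frozenset({"open"}), 0.08),
        (frozenset({"K4"}), 0.04),
        (frozenset({"K9ac"}), 0.03),
    ]
    probs = np.array([p for _, p in state_choices])
    picks = rng.choice(len(state_choices), size=len(genes), p=probs / probs.sum())
    gene_state = {g.id: state_choices[int(k)][0] for g, k in zip(genes, picks)}
    for g in genes:
        note("gene_state", g.id, "+".join(sorted(gene_state[g.id])) or "none")

    def window_of(g: Gene) -> GenomicInterval:
        iv = g.interval
        if g.strand == "+":
            return GenomicInterval(iv.chrom, iv.start - _PAD, iv.end)
        return GenomicInterval(iv.chrom, iv.start, iv.end + _PAD)

    # -------------------------------------------------------------- OCRs
    n_local = round(config.local_fraction * config.n_ocrs)
    n_distal = config.n_ocrs - n_local
    open_genes = [g for g in genes if "open" in gene_state[g.id]]
    if not open_genes:
        raise ValueError("infeasible config: no open genes to host local OCRs")
    ocr_peaks: list[Peak] = []

    def _peak(iv: GenomicInterval, name: str) -> Peak:
        summit = int(rng.integers(iv.start + iv.length // 4, iv.end - iv.length // 4))
        score = float(np.round(rng.lognormal(1.5, 0.6), 3))
        qv = float(np.round(rng.uniform(2.0, 20.0), 3))
        return Peak(iv, summit, score, qv, name, q_neglog10=True)

    counts = np.zeros(len(open_genes), dtype=int)
    for i in range(n_local):
        counts[i % len(open_genes)] += 1
    k = 0
    for g, n_here in zip(open_genes, counts):
        if n_here == 0:
            continue
        win = window_of(g)
        slot = win.length / n_here
        for j in range(int(n_here)):
            k += 1
            width = int(
                rng.integers(
                    _MIN_OCR_LEN,
                    max(_MIN_OCR_LEN, min(_MAX_OCR_LEN, int(slot) - 60)) + 1,
                )
            )
            lo = int(win.start + j * slot) + 20
            hi = int(win.start + (j + 1) * slot) - 20 - width
            start = int(rng.integers(lo, max(lo, hi) + 1))
            name = f"ocr_{k:05d}"
            ocr_peaks.append(_peak(GenomicInterval(win.chrom, start, start + width), name))
            note("ocr", name, "local", g.id)
    distal_names: list[str] = []
    for i in range(n_distal):
        k += 1
        width = int(rng.integers(_MIN_OCR_LEN, _MAX_OCR_LEN + 1))
        name = f"ocr_{k:05d}"
        ocr_peaks.append(_peak(alloc.place(width), name))
        distal_names.append(name)
        note("ocr", name, "distal")
    paths["ocrs"] = out / "ocrs.narrowPeak"
    cio.write_peaks(ocr_peaks, paths["ocrs"], dialect="narrowpeak")
    peak_by_name = {p.name: p for p in ocr_peaks}

    # ------------------------------------------------------- mark peaks
    mark_files = {"K4": "k4me3.bed", "K9ac": "k9ac.bed", "K27": "k27me3.bed"}
    for mark, fname in mark_files.items():
        peaks = []
        for g in genes:
            if mark not in gene_state[g.id]:
                continue
            win = window_of(g)
            width = int(rng.integers(800, min(1500, win.length - 40) + 1))
            start = int(rng.integers(win.start, win.end - width + 1))
            iv = GenomicInterval(win.chrom, start, start + width)
            peaks.append(Peak(iv, iv.midpoint, 1.0, name=f"{mark}_{g.id}"))
        paths[f"mark_{mark}"] = out / fname
        cio.write_peaks(peaks, paths[f"mark_{mark}"], dialect="bed")

    # ------------------------------------------------- expression (2 tissues)
    base_log = rng.normal(1.0, 0.7, size=len(genes))
    base_mu = {}
    for g, bl in zip(genes, base_log):
        state = gene_state[g.id]
        shift = 0.0
        if {"open", "K4", "K9ac"} <= state:
            shift = np.log(10.0)
        elif "K27" in state:
            shift = -1.0
        base_mu[g.id] = float(np.exp(bl + shift))

    # DEGs are planted among expressed genes (base mean >= 1 FPKM), where a
    # pseudocounted fold change of deg_fc is detectable
    n_deg = round(config.deg_fraction * len(genes))
    expressed = np.array(
        [g.id for g in genes if base_mu[g.id] >= 1.0], dtype=object
    )
    deg_ids = [str(x) for x in rng.permutation(expressed)[:n_deg]]
    deg_direction = {
        gid: TISSUES[i % 2] for i, gid in enumerate(sorted(deg_ids))
    }

    # combined vs single chromatin-feature changes among the DEGs: genes
    # with both an OCR and a K4me3 change get a doubled fold change
    feature_plan: dict[str, tuple[str, ...]] = {}
    for tissue in TISSUES:
        ids = sorted(g for g, d in deg_direction.items() if d == tissue)
        third = len(ids) // 4
        for gid_ in ids[:third]:
            feature_plan[gid_] = ("OCR",)
        for gid_ in ids[third : 2 * third]:
            feature_plan[gid_] = ("K4me3",)
        for gid_ in ids[2 * third : 3 * third]:
            feature_plan[gid_] = ("OCR", "K4me3")

    sample_names = [
        f"{tissue}_{r + 1}" for tissue in TISSUES for r in range(config.n_replicates)
    ]
    expr = np.zeros((len(genes), len(sample_names)))
    for i, g in enumerate(genes):
        mu = {t: base_mu[g.id] for t in TISSUES}
        d = deg_direction.get(g.id)
        if d is not None:
            fc = config.deg_fc * (2.0 if len(feature_plan.get(g.id, ())) > 1 else 1.0)
            mu[d] *= fc
            note("deg", g.id, d, f"fc={fc:g}")
        for j, s in enumerate(sample_names):
            tissue = s.rsplit("_", 1)[0]
            expr[i, j] = mu[tissue] * float(
                np.exp(rng.normal(0.0, config.replicate_noise_sigma))
            )
    expr_df = pd.DataFrame(
        np.round(expr, 4), index=[g.id for g in genes], columns=sample_names
    )
    paths["expression"] = out / "expression.tsv"
    expr_df.to_csv(paths["expression"], sep="\t", index_label="gene")

    # ----------------------------------------------- differential peaks
    diff_rows: list[tuple[Peak, str, str, str]] = []
    for gid_, feats in sorted(feature_plan.items()):
        g = gene_by_id[gid_]
        win = window_of(g)
        tissue = deg_direction[gid_]
        for feat in feats:
            width = int(rng.integers(400, 900))
            start = int(rng.integers(win.start, win.end - width + 1))
            iv = GenomicInterval(win.chrom, start, start + width)
            diff_rows.append((Peak(iv, iv.midpoint), feat, tissue, "enriched"))
            note("feature_change", gid_, f"{feat}_up:{tissue}")

    # ------------------------------------------------------------- loops
    n_gg = round(config.loop_class_mix[0] * config.n_loops)
    n_ig = round(config.loop_class_mix[1] * config.n_loops)
    n_ii = config.n_loops - n_gg - n_ig

    # planted co-expressed pairs: disjoint same-chromosome gene pairs
    pair_list: list[tuple[str, str]] = []
    for chrom in chroms:
        ids = [g.id for g in genes if g.chrom == chrom]
        ids = list(rng.permutation(np.array(ids, dtype=object)))
        for a, b in zip(ids[0::2], ids[1::2]):
            pair_list.append((str(a), str(b)))
    n_planted_pairs = min(len(pair_list), n_gg)
    pair_list = pair_list[:n_planted_pairs]
    for a, b in pair_list:
        note("coexpr_pair", f"{a}|{b}", "planted")

    def gene_anchor(gid_: str) -> GenomicInterval:
        g = gene_by_id[gid_]
        tss = g.tss
        return GenomicInterval(g.chrom, max(0, tss - 2000), tss + 2000)

    loops: list[Loop] = []
    loop_labels: list[tuple[str, str]] = []  # (class, extra)
    for a, b in pair_list:
        loops.append(Loop(gene_anchor(a), gene_anchor(b)))
        loop_labels.append(("gene_gene", f"{a}|{b}"))
    pair_keys = {tuple(sorted(p)) for p in pair_list}
    gene_ids_by_chrom = {
        chrom: [g.id for g in genes if g.chrom == chrom] for chrom in chroms
    }
    while len(loops) < n_gg:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        ids = gene_ids_by_chrom[chrom]
        a, b = (str(x) for x in rng.choice(np.array(ids, dtype=object), 2, replace=False))
        if tuple(sorted((a, b))) in pair_keys:
            continue
        loops.append(Loop(gene_anchor(a), gene_anchor(b)))
        loop_labels.append(("gene_gene", f"{a}|{b}"))

    # intergenic-gene loops with planted dOCR links and DEG targeting
    n_links = round(config.docr_in_anchor_rate * n_ig)
    n_act = round(config.active_link_fraction * n_links)
    act_rate = min(1.0, config.active_docr_target_enrichment * config.docr_link_deg_rate)
    n_act_deg = round(act_rate * n_act)
    n_inact = n_links - 2 * n_act
    n_inact_deg = round(config.docr_link_deg_rate * n_inact)

    activities = ["ear"] * n_act + ["tassel"] * n_act
    activities += ["none"] * (n_links - len(activities))

    # targets: active loops hit their tissue's enriched genes at act_rate,
    # inactive loops at the base rate for each tissue
    deg_pool = {
        t: [g for g, d in sorted(deg_direction.items()) if d == t] for t in TISSUES
    }
    non_deg_pool = [g.id for g in genes if g.id not in deg_direction]
    used_non_deg: set[str] = set()

    def draw(pool: list[str], used: set[str]) -> str:
        avail = [x for x in pool if x not in used]
        if not avail:
            avail = pool
        pick = str(rng.choice(np.array(avail, dtype=object)))
        used.add(pick)
        return pick

    n_none = activities.count("none")
    none_cats = (
        ["ear"] * min(n_inact_deg, n_none)
        + ["tassel"] * min(n_inact_deg, max(0, n_none - n_inact_deg))
    )
    none_cats += ["non"] * (n_none - len(none_cats))
    used_deg: dict[str, set] = {t: set() for t in TISSUES}
    targets: list[str] = []
    seen = {"ear": 0, "tassel": 0, "none": 0}
    for act in activities:
        if act in TISSUES:
            if seen[act] < n_act_deg:
                targets.append(draw(deg_pool[act], used_deg[act]))
            else:
                targets.append(draw(non_deg_pool, used_non_deg))
        else:
            cat = none_cats[seen["none"]]
            if cat in TISSUES:
                targets.append(draw(deg_pool[cat], used_deg[cat]))
            else:
                targets.append(draw(non_deg_pool, used_non_deg))
        seen[act] += 1

    # one dOCR per loop, on the target gene's chromosome; a few inactive
    # dOCRs are reused for a second loop to plant hub dOCRs
    pool_by_chrom = {
        c: [
            str(x)
            for x in rng.permutation(
                np.array(
                    [n for n in distal_names if peak_by_name[n].chrom == c],
                    dtype=object,
                )
            )
        ]
        for c in chroms
    }
    ptr = {c: 0 for c in chroms}
    docr_per_loop: list[str] = []
    for target in targets:
        c = gene_by_id[target].chrom
        docr_per_loop.append(pool_by_chrom[c][ptr[c]])
        ptr[c] += 1
    n_hubs = min(3, n_links // 10)
    none_idx = [i for i, a in enumerate(activities) if a == "none"]
    made = 0
    for x in range(len(none_idx) - 1):
        if made >= n_hubs:
            break
        i, j = none_idx[x], none_idx[x + 1]
        same_chrom = (
            peak_by_name[docr_per_loop[i]].chrom == peak_by_name[docr_per_loop[j]].chrom
        )
        if same_chrom and targets[i] != targets[j] and docr_per_loop[i] != docr_per_loop[j]:
            docr_per_loop[j] = docr_per_loop[i]
            made += 1
    active_docrs: dict[str, str] = {
        name: act
        for name, act in zip(docr_per_loop, activities)
        if act != "none"
    }

    for docr_name, act, target in zip(docr_per_loop, activities, targets):
        docr = peak_by_name[docr_name]
        # anchor pads the dOCR by less than the inter-feature margin, so it
        # contains exactly the dOCRs it was planted with
        anchor = GenomicInterval(docr.chrom, docr.start - 250, docr.end + 250)
        loops.append(Loop(anchor, gene_anchor(target)))
        loop_labels.append(("intergenic_gene", f"{docr_name}>{target}"))
        note("docr_link", f"loop_{len(loops) - 1:04d}", target, docr_name)
    for docr_name, act in sorted(active_docrs.items()):
        note("active_docr", docr_name, act, "linked")

    # dOCR-free intergenic-gene loops
    for _ in range(n_ig - n_links):
        width = int(rng.integers(1500, 2001))
        target = draw(non_deg_pool, used_non_deg)
        anchor = alloc.place(width, chrom=gene_by_id[target].chrom)
        loops.append(Loop(anchor, gene_anchor(target)))
        loop_labels.append(("intergenic_gene", f">{target}"))

    # intergenic-intergenic loops
    for _ in range(n_ii):
        a = alloc.place(int(rng.integers(1000, 1501)))
        b = alloc.place(int(rng.integers(1000, 1501)), chrom=a.chrom)
        loops.append(Loop(a, b))
        loop_labels.append(("intergenic_intergenic", ""))

    for i, (klass, extra) in enumerate(loop_labels):
        note("loop", f"loop_{i:04d}", klass, extra)
    paths["loops"] = out / "loops.bedpe"
    cio.write_loops(loops, paths["loops"])

    # extra (unlinked) tissue-active dOCRs, with differential-peak evidence
    unlinked = [n for n in distal_names if n not in set(docr_per_loop)]
    extra_active = {
        "ear": [str(x) for x in rng.choice(np.array(unlinked, dtype=object), 30, replace=False)],
    }
    rest = [n for n in unlinked if n not in set(extra_active["ear"])]
    extra_active["tassel"] = [
        str(x) for x in rng.choice(np.array(rest, dtype=object), 40, replace=False)
    ]
    all_active = dict(active_docrs)
    for tissue, names in extra_active.items():
        for n in names:
            all_active[n] = tissue
            note("active_docr", n, tissue, "unlinked")
    for i, (name, tissue) in enumerate(sorted(all_active.items())):
        docr = peak_by_name[name]
        iv = docr.interval
        if i % 3 == 0:  # evidence: weaker H3K27me3 in the active tissue
            diff_rows.append((Peak(iv, iv.midpoint), "K27me3", tissue, "depleted"))
        elif i % 3 == 1:  # evidence: more open in the active tissue
            diff_rows.append((Peak(iv, iv.midpoint), "OCR", tissue, "enriched"))
        else:  # both lines of evidence
            diff_rows.append((Peak(iv, iv.midpoint), "OCR", tissue, "enriched"))
            diff_rows.append((Peak(iv, iv.midpoint), "K27me3", tissue, "depleted"))
    paths["diff_peaks"] = out / "diff_peaks.tsv"
    cio.write_differential_peaks(diff_rows, paths["diff_peaks"])

    # --------------------------------------------------- expression panel
    rho = config.looped_pair_pcc
    pair_index = {}
    for pi, (a, b) in enumerate(pair_list):
        pair_index[a] = pi
        pair_index[b] = pi
    n_samples = config.n_tissues_panel
    factors = rng.normal(size=(len(pair_list), n_samples))
    panel = np.zeros((len(genes), n_samples))
    mu_panel = rng.uniform(10.0, 100.0, size=len(genes))
    for i, g in enumerate(genes):
        eps = rng.normal(size=n_samples)
        pi = pair_index.get(g.id)
        x = (
            np.sqrt(rho) * factors[pi] + np.sqrt(1.0 - rho) * eps
            if pi is not None
            else eps
        )
        panel[i] = np.maximum(0.0, mu_panel[i] * (1.0 + 0.25 * x))
    panel_df = pd.DataFrame(
        np.round(panel, 4),
        index=[g.id for g in genes],
        columns=[f"t{j + 1:02d}" for j in range(n_samples)],
    )
    paths["panel"] = out / "panel.tsv"
    panel_df.to_csv(paths["panel"], sep="\t", index_label="gene")

    # ------------------------------------------------ intergenic transcripts
    n_tx = round(config.transcribed_docr_fraction * n_distal)
    tx_docrs = [
        str(x)
        for x in rng.choice(np.array(distal_names, dtype=object), n_tx, replace=False)
    ]
    tx_peaks = []
    for name in tx_docrs:
        iv = peak_by_name[name].interval
        tx_iv = GenomicInterval(iv.chrom, iv.start - 200, iv.end + 200)
        fpkm = float(np.round(rng.lognormal(0.0, 1.0), 4))
        tx_peaks.append(Peak(tx_iv, tx_iv.midpoint, fpkm, name=f"tx_{name}"))
        note("transcribed_docr", name, "transcribed")
    for j in range(20):
        iv = alloc.place(int(rng.integers(400, 801)))
        fpkm = float(np.round(rng.lognormal(0.0, 1.0), 4))
        tx_peaks.append(Peak(iv, iv.midpoint, fpkm, name=f"tx_free_{j:02d}"))
    paths["transcripts"] = out / "transcripts.bed"
    cio.write_peaks(tx_peaks, paths["transcripts"], dialect="bed")

    # ---------------------------------------------------------- TF peaks
    ocr_pool = np.array([p.name for p in ocr_peaks], dtype=object)
    tf_gene_map: dict[str, str] = {}
    for t in range(config.n_tfs):
        tf_name = f"TF_{t + 1}"
        n_in = round(config.tf_in_ocr_rate * config.tf_sites_per_tf)
        sites: list[Peak] = []
        chosen = [str(x) for x in rng.choice(ocr_pool, n_in, replace=True)]
        for j, ocr_name in enumerate(chosen):
            host = peak_by_name[ocr_name]
            width = int(rng.integers(150, 301))
            center = int(
                np.clip(
                    host.summit + int(rng.integers(-100, 101)),
                    host.start + width // 2,
                    host.end - (width - width // 2),
                )
            )
            iv = GenomicInterval(host.chrom, center - width // 2, center - width // 2 + width)
            sites.append(Peak(iv, iv.midpoint, 1.0, name=f"{tf_name}_s{j:03d}"))
        for j in range(config.tf_sites_per_tf - n_in):
            iv = alloc.place(int(rng.integers(150, 301)))
            sites.append(Peak(iv, iv.midpoint, 1.0, name=f"{tf_name}_bg{j:03d}"))
        # the TF's own gene: host gene of its first local binding site
        local_hosts = [
            row["extra"]
            for row in rows
            if row["record_type"] == "ocr"
            and row["label"] == "local"
            and row["record_id"] in set(chosen)
        ]
        if local_hosts:
            tf_gene_map[tf_name] = local_hosts[0]
            note("tf_gene", tf_name, local_hosts[0])
        # replicate 2: 95% of sites, jittered by up to 20 bp
        keep = rng.random(len(sites)) < 0.95
        rep2 = []
        for p, kflag in zip(sites, keep):
            if not kflag:
                continue
            d = int(rng.integers(-20, 21))
            iv = GenomicInterval(p.chrom, max(0, p.start + d), p.end + d)
            rep2.append(Peak(iv, iv.midpoint, 1.0, name=p.name))
        paths[f"tf_{tf_name}_rep1"] = out / f"tf_{tf_name}_rep1.bed"
        paths[f"tf_{tf_name}_rep2"] = out / f"tf_{tf_name}_rep2.bed"
        cio.write_peaks(sites, paths[f"tf_{tf_name}_rep1"], dialect="bed")
        cio.write_peaks(rep2, paths[f"tf_{tf_name}_rep2"], dialect="bed")

    # -------------------------------------------------------------- SNPs
    traits = ["EL", "DTA", "TL", "KRN"]
    n_intergenic = round(config.snp_intergenic_fraction * config.n_snps)
    docr_bp = sum(peak_by_name[n].interval.length for n in distal_names)
    gap_bp = sum(g.length for g in gaps)
    c_null = docr_bp / gap_bp
    n_in_docr = round(min(1.0, config.snp_in_docr_enrichment * c_null) * n_intergenic)
    snps: list[SNPRecord] = []
    docr_sorted = {
        chrom: sorted(
            (peak_by_name[n].interval for n in distal_names if peak_by_name[n].chrom == chrom),
            key=lambda iv: iv.start,
        )
        for chrom in chroms
    }

    def in_any_docr(chrom: str, pos: int) -> bool:
        return any(iv.start <= pos < iv.end for iv in docr_sorted[chrom])

    for j in range(n_in_docr):
        name = str(rng.choice(np.array(distal_names, dtype=object)))
        iv = peak_by_name[name].interval
        pos = int(rng.integers(iv.start, iv.end))
        snps.append(SNPRecord(iv.chrom, pos, f"snp_{j + 1:04d}", traits[j % 4]))
        note("snp", f"snp_{j + 1:04d}", "intergenic", "in_docr")
    j = n_in_docr
    gap_weights = np.array([g.length for g in gaps], dtype=float)
    gap_weights /= gap_weights.sum()
    while j < n_intergenic:
        gap = gaps[int(rng.choice(len(gaps), p=gap_weights))]
        pos = int(rng.integers(gap.start, gap.end))
        if in_any_docr(gap.chrom, pos):
            continue
        j += 1
        snps.append(SNPRecord(gap.chrom, pos, f"snp_{j:04d}", traits[j % 4]))
        note("snp", f"snp_{j:04d}", "intergenic")
    for m in range(config.n_snps - n_intergenic):
        g = genes[int(rng.integers(0, len(genes)))]
        pos = int(
            rng.integers(
                max(0, g.interval.start - _PAD), g.interval.end + _PAD
            )
        )
        sid = f"snp_{n_intergenic + m + 1:04d}"
        snps.append(SNPRecord(g.chrom, pos, sid, traits[m % 4]))
        note("snp", sid, "genic_or_proximal")
    paths["snps"] = out / "snps.tsv"
    cio.write_snps(snps, paths["snps"])

    # -------------------------------------------------------------- PETs
    r = config.intra_inter_ratio
    n_intra = round(config.n_pets * r / (1.0 + r))
    pets: list[PETRecord] = []
    L = config.chrom_length
    for _ in range(n_intra):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        p1 = int(rng.integers(0, L))
        d = int(rng.exponential(150_000)) * (1 if rng.random() < 0.5 else -1)
        p2 = int(np.clip(p1 + d, 0, L - 1))
        pets.append(PETRecord(chrom, p1, chrom, p2))
    for _ in range(config.n_pets - n_intra):
        c1, c2 = (
            str(x) for x in rng.choice(np.array(chroms, dtype=object), 2, replace=False)
        )
        pets.append(
            PETRecord(c1, int(rng.integers(0, L)), c2, int(rng.integers(0, L)))
        )
    paths["pets"] = out / "pets.tsv"
    cio.write_pets(pets, paths["pets"])

    # -------------------------------------------------------- boundaries
    candidates = [
        (chrom, pos)
        for chrom in chroms
        for pos in range(100_000, L - 100_000, 50_000)
    ]
    order = rng.permutation(len(candidates))
    n_cons = round(config.boundary_conserved_fraction * config.n_boundaries)
    n_spec = config.n_boundaries - n_cons
    picked = [candidates[int(i)] for i in order[: n_cons + 2 * n_spec]]
    cons = picked[:n_cons]
    ear_spec = picked[n_cons : n_cons + n_spec]
    tassel_spec = picked[n_cons + n_spec :]
    ear_bounds = sorted(cons + ear_spec)
    tassel_bounds = sorted(
        [(c, p + int(rng.integers(-5000, 5001))) for c, p in cons] + tassel_spec
    )
    for tissue, bounds in (("ear", ear_bounds), ("tassel", tassel_bounds)):
        path = out / f"boundaries_{tissue}.bed"
        paths[f"boundaries_{tissue}"] = path
        with open(path, "w") as fh:
            for chrom, pos in bounds:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
    for chrom, pos in cons:
        note("boundary", f"{chrom}:{pos}", "conserved")

    # ------------------------------------------------------------ tracks
    atac_bumps = [
        (p.chrom, p.summit, p.score, p.interval.length / 3.0) for p in ocr_peaks
    ]
    atac_records = _rasterised_track(atac_bumps, L)
    paths["atac_track"] = out / "atac.bedgraph"
    with open(paths["atac_track"], "w") as fh:
        for chrom, s, e, v in atac_records:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    k4_bumps = []
    for g in genes:
        if "K4" in gene_state[g.id]:
            k4_bumps.append((g.chrom, g.tss, 5.0, 400.0))
    paths["k4_track"] = out / "k4me3.bedgraph"
    with open(paths["k4_track"], "w") as fh:
        for chrom, s, e, v in _rasterised_track(k4_bumps, L, step=25):
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    # CG methylation: high background in 500-bp bins, depleted at OCRs
    paths["meth_track"] = out / "methylation_cg.bedgraph"
    summit_bins: dict[str, set] = {chrom: set() for chrom in chroms}
    for p in ocr_peaks:
        summit_bins[p.chrom].update(
            range(max(0, p.start - 250) // 500, (p.end + 250) // 500 + 1)
        )
    with open(paths["meth_track"], "w") as fh:
        for chrom in chroms:
            for b in range(0, L // 500):
                v = 0.1 if b in summit_bins[chrom] else 0.8
                fh.write(f"{chrom}\t{b * 500}\t{(b + 1) * 500}\t{v}\n")

    manifest = pd.DataFrame(rows)
    paths["manifest"] = out / "manifest.tsv"
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return SimBundle(out, config, paths, manifest)
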