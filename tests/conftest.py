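from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import cistopo as ct
from cistopo import io as cio
from cistopo.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The default synthetic bundle (seed 1), written once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate(SimConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def pipeline(bundle):
    """The full pipeline run on the default bundle, shared across tests."""
    p = SimpleNamespace()
    p.bundle = bundle
    p.manifest = bundle.manifest
    p.genome = cio.read_genome(bundle.path("genome"))
    p.genes = cio.read_genes(bundle.path("genes"))
    p.peaks = cio.read_intervals(bundle.path("ocrs"), dialect="narrowpeak")
    p.classified_ocrs = ct.classify_ocrs(p.peaks, p.genes, genome=p.genome)
    p.loocrs, p.docrs = ct.split_classes(p.classified_ocrs)
    p.loops, p.n_skipped = cio.read_loops(bundle.path("loops"))
    p.classified_loops = ct.classify_loops(p.loops, p.genes, genome=p.genome)
    p.links, p.docr_anchor_fraction, p.hubs = ct.docr_gene_links(
        p.classified_loops, p.docrs
    )
    p.expr = cio.read_expression(bundle.path("expression"))
    p.groups = {s: s.rsplit("_", 1)[0] for s in p.expr.samples}
    p.degs = ct.call_degs(p.expr, p.groups)
    p.panel = cio.read_expression(bundle.path("panel"))
    diff = cio.read_differential_peaks(bundle.path("diff_peaks"))
    p.diff_ocr = [d for d in diff if d[1] == "OCR"]
    p.diff_k27 = [d for d in diff if d[1] == "K27me3"]
    p.active, p.conflicted = ct.call_active_docrs(p.docrs, p.diff_ocr, p.diff_k27)
    idx = {pk.name: i for i, pk in enumerate(p.docrs)}
    p.active_idx = {}
    for a in p.active:
        p.active_idx.setdefault(a.tissue, []).append(idx[a.docr.name])
    p.snps = ct.classify_snps(cio.read_snps(bundle.path("snps")), p.genes)
    p.intergenic_snps = [s for s in p.snps if s.locality == "intergenic"]
    return p


@pytest.fixture()
def toy_genome():
    return ct.Genome({"chr1": 200_000, "chr2": 150_000})


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
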