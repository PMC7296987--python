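# Methods

`cistopo` re-implements, as a tested library, an integrative regulatory-genomics
analysis for a two-tissue study design (maize ear and tassel primordia are the
motivating system): classifying open chromatin regions (OCRs) as local or
distal, linking distal elements to genes through chromatin loops, scoring
overlap enrichments against randomised-shift nulls, relating dynamic chromatin
features and TF binding to differential expression, testing co-expression of
looped gene pairs against a distance-matched null, and connecting intergenic
trait SNPs to candidate target genes via loops.

All coordinates are 0-based half-open; GFF3 input is converted at the parsing
boundary. Chromosome names are passed through verbatim; cross-file mismatches
are reported as errors, never silently renamed.

## Local vs distal OCRs

A gene's *local window* runs from 3 kb upstream of its TSS through its TTS
(strand-aware, clamped to the chromosome). An OCR overlapping >= 1 bp of any
local window is a **LoOCR** and is assigned to *every* such gene; the rest are
**dOCRs**. Any-overlap (rather than summit containment) is the default because
the assignment of differential peaks to adjacent genes uses interval location;
a `by_summit` switch restricts the peak to its summit base. Multi-window peaks
are assigned to all hit genes — a nearest-gene tie-break would silently bias
downstream gene-set counts.

Chromatin-state classes per gene are the transparent combinatorial presence
classes over {open, H3K4me3, H3K9ac, H3K27me3} (16 possible), a deliberate
replacement for HMM-based segmentation: each label is directly auditable
against the peak files.

## Shift-null enrichment

Controls for every overlap claim displace each interval along its own
chromosome: shift magnitude uniform on `[min_shift, max_shift]` (default:
the interval's own length, forcing it off its footprint, up to 1 Mb), sign
uniform, proposals rejected when out of bounds or intersecting a forbidden set
(e.g. all local windows, when the null must stay distal); after 1000 rejection
rounds the interval is placed uniformly on the remaining free space. Proposals
are rejected at chromosome edges rather than reflected, because reflection
distorts the placement distribution near ends. The design generalises the
single shifted control set to N permutations (default 100) with an add-one
empirical p, `p = (1 + #{null >= obs}) / (1 + N)`, which can never be 0 and is
conservative under ties; `n_perm=1` reproduces a single-control design.
Calibration under independent placement is checked by simulation (500
datasets; the fraction of p <= 0.05 must sit in 0.05 +/- 0.02).

## Differential integration

Tissue-enriched genes: fold change of mean FPKM with pseudocount 1
(`(mean_a + 1)/(mean_b + 1)`), thresholds FC > 1.5 and q < 0.01. When the
expression table carries no q-values, q comes from a Welch t-test on
log2(FPKM+1) with Benjamini–Hochberg adjustment (>= 3 replicates per group
required) — a documented stand-in for a count-based differential engine, which
is out of scope along with peak and differential-peak calling.

Differential ATAC/H3K4me3/H3K27me3 peaks (inputs, with feature, tissue and
enriched/depleted labels) accumulate on genes through the same local windows.
Tissue-active dOCRs are dOCRs that overlap a tissue-enriched differential OCR
peak (more open) and/or a tissue-depleted H3K27me3 peak (weaker repression;
the "flanking" reach is a parameter, default 0 bp = direct overlap, since no
distance is canonically defined). dOCRs with evidence in both tissues are
excluded and logged — the tissue-active sets are defined as disjoint.

## Loops

Loops are intrachromosomal anchor pairs (BEDPE), canonically ordered. An
anchor is *genic* when it overlaps a local window (same rule as LoOCRs; a
`genic_definition="body"` switch restricts to gene bodies). Classes:
gene–gene, intergenic–gene, intergenic–intergenic. A **dOCR–gene loop** is an
intergenic–gene loop whose intergenic anchor holds >= 1 dOCR; the headline
statistic is the fraction of intergenic anchors so flagged. Genes are grouped
for expression comparisons with precedence dOCR-looped > other-looped >
no-loop, so multi-membership resolves deterministically.

Whether tissue-active dOCRs preferentially target tissue-enriched genes is
tested per tissue with a one-sided Fisher exact test of the active-link
target table against the all-links background table (the significance test is
not canonically defined for this comparison; Fisher is recorded in the output).

Intergenic SNPs (symmetric +/- 3 kb margin around gene spans, strand-free,
matching an "upstream or downstream" definition) are linked to genes when the
5-kb window centred on the SNP overlaps the intergenic anchor of an
intergenic–gene loop; anchor overlap (not full-span overlap) is the
implemented reading.

## Co-expression of looped pairs

Pearson correlation of each looped gene pair across a multi-tissue panel
(65 samples in the emulated design). The null draws, per real pair, a random
same-chromosome gene pair whose TSS–TSS distance falls in the same log10
distance bin (width 0.1 — "similar distance" needs an operational definition;
the width is a parameter), without replacement within a set, excluding real
looped pairs, falling back to the nearest non-empty bin when one exhausts.
Both sets are randomly split into 1000 batches (reduced to the pair count when
smaller) and batch-mean PCCs are compared by a two-tailed Welch t-test. When
the two sets are the same size the same random partition is applied to both,
so identical inputs give p = 1 exactly.

## TAD boundaries and Hi-C QC

Boundaries are points (bin-interval input is collapsed to midpoints). Two
tissues' sets are matched one-to-one within 10 kb by processing one set in
genomic order and pairing each boundary with the leftmost unmatched partner in
tolerance; for equal-width tolerance windows this greedy rule attains the
maximum matching, so the conserved count is symmetric in the two tissues (an
`any`-within-tolerance mode is also provided). Boundary-resident OCRs are
resized to 200 bp around their summits and split into promoter (1 kb upstream
to 200 bp downstream of a TSS, strand-aware) vs non-promoter classes, ready
for external motif tools.

Hi-C quality: intra/inter-chromosomal PET ratio (infinity flagged when no
inter PETs) and the fraction of fixed-size bins (default 5 kb) whose PET-end
count (2 ends per PET) reaches a threshold. The denominator defaults to bins
with >= 1 observed end; `all_bins` switches to every genomic bin, since the
published denominator convention is ambiguous.

## Synthetic data generator

The generator is a pure function of a `SimConfig` (same config, byte-identical
bundle) and emulates every input format the pipeline reads. Defaults define
the study conditions: 3 chromosomes x 2 Mb; 400 stranded genes on a jittered
grid with 3-kb gene-free pads; 1200 OCRs with 63% planted local (inside the
windows of "open"-state genes) and 37% distal (in intergenic gaps, >= 2 kb from
gap edges); histone-mark peaks realising per-gene combinatorial states (40%
fully active with 10x expression, 15% H3K27me3-only with reduced expression);
a 2-tissue x 3-replicate FPKM table with 15% DEGs at fold change 3 and
log-normal replicate noise sigma = 0.05 (mimicking highly reproducible
replicates; DEGs are planted among genes with base mean >= 1 FPKM, where a
pseudocounted fold change of 3 is detectable); a 65-sample panel in which each
of ~200 disjoint looped gene pairs shares a latent factor with loading
sqrt(0.4), giving pair PCC ~= 0.4; 600 loops at the (0.70, 0.25, 0.05) class
mix with 65% of intergenic–gene anchors holding a dOCR; tissue-active dOCRs
(30% of links per tissue, plus unlinked actives) whose links target that
tissue's DEGs at 3x the 0.25 base rate — the base rate reflects that
dOCR-looped genes are themselves enriched for regulated genes, and at these
loop counts it is what makes a 3-fold enrichment statistically resolvable; a
few dOCRs carry two loops (hub dOCRs); intergenic transcripts covering 12% of
dOCRs with lower FPKM than coding genes; TF binding sites at 90% in-OCR rate
with two jittered replicates; 1000 SNPs, 33% intergenic, placed in dOCRs at
3x the coverage-expected rate; 20,000 PETs at intra/inter ratio 5.36; and 40
TAD boundaries per tissue, 70% conserved within the 10-kb tolerance.

What the generator does **not** emulate: read-level data, genome sequence,
GC/mappability structure, overlapping gene models, peak-calling noise,
spatially structured Hi-C contact decay beyond an exponential intra-chromosome
distance, and assembly differences between datasets. Passing tests therefore
demonstrate correctness of the analysis logic and statistical calibration on
idealised inputs, not robustness to upstream data-processing artefacts.

## Numerical and testing choices

Empirical p-values never reach 0 (add-one); Fisher tests on zero-margin
tables report p = 1 with a warning; zero-variance expression profiles are
dropped from PCC with logged counts; rank correlations on constant input are
reported as undefined (NaN). Interval sorting is total and stable on
(chromosome, start, end). The test suite checks every overlap, assignment,
classification, matching and histogram operation against independent
brute-force oracles on instances of <= 500 records, runs the permutation and
batch-test calibrations at 500 simulated datasets, and recovers all planted
effects on the default bundle (seed 1); `scripts/acceptance.py` re-runs the
whole pipeline at the default sizes above, which keep the complete run in a
few seconds on one CPU.

## Known limitations

Single shifted controls (n_perm = 1) give no significance calibration and are
supported only for design parity. The fallback DEG test is not a count-model
test and will differ from Cufflinks/DESeq-style q-values on real data. The
greedy boundary matching maximises the matched count but does not minimise
total displacement among maximum matchings. TF replicate intersection keeps
replicate-1 coordinates. Loop anchors from real Hi-C are bin-quantised; the
generator's anchors are not.
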