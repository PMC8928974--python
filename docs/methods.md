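# Methods

## Assay model

A reporter screen library contains, per SNP, two constructs whose inserts
are the 55-bp genomic window centered on the variant (27-nt flanks on the
plus strand, the allele at 1-based offset 28), plus exactly one
promoter-only blank construct. Each construct carries a unique barcode;
sub-libraries (cell line × fraction ∈ {DNA, RNA} × replicate) are addressed
by (primer set 1..24, index 1..12), giving a hard capacity of 288
sub-libraries per pooled run.

The estimand is per-construct reporter activity. With barcode counts
normalized to one million per sub-library (CPM), the expression level of
construct *c* in replicate *r* is `ratio = CPM_RNA / CPM_DNA`, and its
activity is that ratio divided by the blank's ratio in the same replicate.
Per-replicate blank calibration removes replicate-level transfection and
recovery efficiency; the blank's activity is identically 1.

## Two-stage nomination

Stage 1 asks whether the two alleles drive expression differently: a
two-tailed two-sample Student's *t*-test with pooled variance
(df = n₁+n₂−2) on the replicate values, threshold *p* < 0.05 (raw, no
multiple-testing correction; Benjamini–Hochberg q-values are reported
alongside for modern use). Degenerate inputs are handled explicitly: zero
pooled variance yields *p* = 1 for equal means and *p* = 0 (flagged) for
unequal means. A Welch variant is available behind a flag.

Stage 2 asks whether the effect is material relative to the blank: the
replicate-mean activity of at least one allele must fall below 0.8 or above
1.2. The mean (rather than any-replicate) convention is chosen for
stability. A SNP is regulatory iff it passes both stages; direction is
"increased" iff fold = mean(risk)/mean(normal) > 1.

**Which values feed the stage-1 test.** Calibrating by the blank divides
both alleles' replicate values by the *same* per-replicate blank ratio.
In an unpaired t-test that shared factor does not cancel: it inflates the
pooled variance estimate while contributing nothing to the mean difference,
making the test conservative (the blank is a single construct, so its ratio
is itself noisy). The default therefore tests the raw RNA/DNA ratios —
which are exactly exchangeable between alleles under the null — and uses
the blank-calibrated activities only where the blank is the point: the
0.8/1.2 band and the reported activity levels. `calibrated_test=True`
switches the test to calibrated activities for users who prefer a single
scale throughout.

SNPs with a construct lacking DNA representation (zero DNA CPM) in more
than one replicate are dropped from testing and flagged, since a one-sided
allele estimate would bias the fold change; a single missing replicate
drops that replicate pair for the SNP.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_snps` | 288 | panel size of the modeled screen |
| `n_replicates` | 3 | independent transfections |
| `read_depth` | 10⁶ | reads per sub-library |
| `dna_dirichlet_concentration` | 5 | plasmid-pool unevenness (proportion CV ≈ 0.4) |
| `replicate_noise_cv` | 0.10 | per-construct lognormal replicate noise; replicates in this assay class are highly concordant |
| `fold_range` | (2.0,) | planted allelic fold |
| `per_base_error_rate` | 0 | sequencing substitutions (set per experiment) |
| `amplicon_split` | (271, 270) | 450-bp cassette halves under 150-bp paired ends |

DNA proportions are drawn once from a symmetric Dirichlet; DNA counts per
sub-library are multinomial at the configured depth. RNA expected
proportions are DNA proportion × true activity × mean-1 lognormal replicate
noise, then multinomial — the simplest model under which the RNA/DNA CPM
ratio is a consistent estimator of activity. Planted regulatory SNPs place
their alleles at `c·√f` and `c/√f` with `c = 1.5/√2`, so a fold-2 SNP has
activities 1.5 and 0.75: discordant alleles with at least one outside the
[0.8, 1.2] band, matching the truth definition the nomination rule mirrors.

Simulated reads carry `[primer(20) | index(8) | barcode(15) | constant
filler]` from the 5' end of the 271-bp first-half amplicon; mate 2 is the
reverse complement of its 3' end (29-bp overlap at 150-bp reads).  The
fixed offsets are an explicit stand-in for the real vector's cassette
architecture, which this package does not claim to reproduce; real data
uses a user-supplied barcode map and, if needed, custom primer/index
sequences. Qualities are constant Q37; the second-half (barcode-free)
amplicon can be emitted behind a flag and is ignored by default counting.
Everything is bit-reproducible under a fixed seed.

What the generator does **not** model: PCR amplification bias and
duplicates, indel sequencing errors, quality-score variation, construct
dropout during cloning, and biological covariance between SNPs. Passing
tests therefore demonstrate correctness of the estimator and calibration of
the test under the stated noise model, not robustness to those artifacts.

## Read processing

Pair merging is a maximum-agreement overlap scan: after
reverse-complementing mate 2, every overlap length from `min_overlap` (20)
to the read length is scored and the one maximizing matching bases wins
(longest on ties), subject to a 10% mismatch-rate cap; disagreements take
the higher-quality base; failure is a tallied rejection, not an error. A
vectorized batch path is used by the pipeline and is tested base-for-base
against the single-pair reference implementation.

Demultiplexing matches the primer window (≤1 mismatch by default) and the
index window (exact by default); ties at equal distance are ambiguous and
unassigned. Barcode counting is exact by default; with `max_barcode_mm=1`
a read within distance 1 of two barcodes is rejected (simulated libraries
guarantee pairwise barcode Hamming distance ≥ 3, so single errors are
unambiguous). Reads with N in the primer/index/barcode windows or with
non-modal length are dropped in cleaning. Per sample,
assigned + unassigned always equals reads processed.

## Clustering

Rows are Z-scored with sample (n−1) SD; constant rows are dropped with a
warning. Similarity is the uncentered Pearson correlation
Σxy/√(Σx²·Σy²); distance 1 − similarity; average linkage by default
(the common choice in this heatmap workflow; complete/single behind a
flag). Scipy's deterministic agglomeration order is kept; outputs include
the reordered matrix and Newick dendrograms. Average linkage on these
distances produces no inversions, asserted on all test matrices.

## Chromatin support and motifs

Peak support uses BED intervals (0-based half-open), a binary-searched
running-max-end index, and "chr"-prefix harmonization. The nomination rule
defaults to `(ATAC | DNase) & (H3K27ac | H3K4me3)` — open chromatin and an
active enhancer/promoter mark — and is a validated boolean expression over
assay names, since published screens rarely formalize this rule and peak
sets differ between labs.

Motif scoring converts a JASPAR PFM to probabilities with a pseudocount of
0.5 per cell and log2 odds against a uniform background. Only windows
covering the SNP base are scored (windows that miss it cannot separate the
alleles and only add ranking noise); the per-allele score is the best hit
over admissible offsets and both strands, and delta = best(risk) −
best(normal) is antisymmetric under allele swap.

## qPCR quantifications

All qPCR formulas are ΔΔCt with amplification efficiency fixed at exactly
2.0 by default (validated primer pairs), overridable per assay, and are
invariant to machine offsets added to all Cts. ChIP/FAIRE enrichment is
E^−[(Ct_IP−Ct_input)_target − (Ct_IP−Ct_input)_control]. Allele-specific
qPCR calibrates the sample's allele ΔCt against heterozygous genomic DNA
(1:1 by definition), with an uncalibrated fallback. The editing (getPCR)
wild-type percentage normalizes a cut-site-spanning amplicon to a nearby
control amplicon, relative to mock cells, clamped to [0, 100] with a
warning. Allele counting at a heterozygous SNP works from alignments (base
at the SNP column) or raw reads (exact 5-nt flanking-context anchor on
either strand); the two-allele counts get a two-sided exact binomial test
against 0.5.

## Problem sizes and tolerances

The validation suite uses the study design at full per-run scale: 200k read
pairs for the FASTQ round trip (bit-exact at zero error; ≥99% of assigned
reads correct at 1% per-base error, measured via the L1 count deviation
bound), and 50 seeds × 300 SNPs at depth 10⁶ for calibration (stage-1 null
rate inside the 99% binomial band around 0.05) and power (two-stage
sensitivity ≥ 0.9 at fold 2, direction accuracy ≥ 95%). Closed-form
checks are exact to 10⁻⁶ relative (t-test) and 10⁻¹² absolute (uncentered
correlation). CPM columns sum to 10⁶ within 10⁻⁶ relative; Z-scored rows
hit mean 0 / SD 1 within 10⁻⁹.

## Known limitations

* The paper-scale screen across nine cell lines is represented by one
  simulated cell line at a time; multi-cell-line tables are supported by
  the data model but not auto-generated.
* The simulated cassette layout is a stand-in, not the real vector.
* No shrinkage/dispersion modeling beyond the procedure described above;
  the raw p < 0.05 rule is kept deliberately faithful to the assay's
  published analysis style, with q-values reported for modern use.
* BED peak calls are the only chromatin evidence consumed; signal-level
  (bigWig) thresholding is out of scope.
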