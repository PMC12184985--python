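# Methods

`cutac` analyzes paired tumor/normal RNAPII occupancy maps produced by
CUTAC-style chromatin profiling: per-sample files of mapped DNA fragments,
each fragment marking engaged (serine-5-phosphorylated) RNA polymerase II.
The package covers the full analysis chain — genome-scaled coverage,
per-element hypertranscription scoring, paired peak calling with the
matched normal as background control, focal-amplification geometry,
the replication-dependent histone-gene prognostic signature, survival
threshold scanning, and whole-arm aneuploidy inference from null cCRE
occupancy — and ships a synthetic-data generator so the entire chain is
testable end to end on a desk-scale genome.

## Coverage model and normalization

Raw depth at a base is the number of fragments spanning it. Each sample's
track is rescaled so that the mean depth over all non-mitochondrial bases
is exactly 1; the mitochondrion carries the same factor but is excluded
from the denominator, because mtDNA content varies systematically between
tumor and normal tissue and would otherwise distort nuclear signal.
Interval signal is the mean normalized depth over the interval's bases,
computed either from per-base arrays (peak calling, dense bin tilings) or
by direct fragment-overlap summation (cCREs, gene spans); the two engines
are algebraically identical and are cross-checked in the test suite.
Before any paired comparison, fragment counts are equalized by
down-sampling the deeper sample without replacement (seeded).

Tumor-minus-normal (T−N) difference tables carry the raw difference of
normalized means; log10((T+N)/2 + 1e-3) is attached for MA-style plotting
only and never enters the statistics. Rank ties break by genomic position.

## Gene spans

A gene's analysis span is the union extent of its transcripts (isoforms
merge), truncated so it does not cross a boundary of another gene's
transcript extent or of a LINE element: offending boundaries left of the
extent midpoint clip the start, those right of it clip the end. Truncation
only shrinks, the result is order-independent and idempotent, and
zero-width spans are permitted (logged).

## Paired peak calling

Signal blocks are maximal runs of strictly positive normalized depth;
each block carries its total (area) and maximum. The enrichment threshold
is selected on block totals: over candidate thresholds t (the pooled
unique totals), the fraction of target blocks and of control blocks with
total ≥ t is compared, and the t maximizing the gap is chosen (`stringent`
takes the largest tied maximizer, `relaxed` the smallest). Retained peaks
are target blocks with total ≥ threshold; in broad mode, retained blocks
closer than `merge_gap` (default 5 kb; benchmarks that bridge cCRE
spacing use 25 kb) are merged with totals summed.

Three numerical safeguards make this selection well behaved on matched
pairs, where target and control are statistically close:

* **Control rescaling.** Control totals are first multiplied by the scale
  that minimizes the integrated CDF distance between the two block-total
  distributions (log-grid search around quantile ratios, two refinement
  passes; snapped to exactly 1 when within 2%, since depth-equalized pairs
  share a quantized singleton-total grid). Per-track mean-1 normalization
  otherwise converts any focal enrichment in one sample into an apparent
  genome-wide offset in the other, which the survival-gap scan would
  mistake for enrichment in the swapped orientation.
* **Control tolerance.** A control block within 1% below a candidate still
  counts as passing it, so residual alignment error cannot promote a
  shared block into apparent enrichment.
* **Minimum separation.** If the best achievable gap does not exceed 0.5%
  of blocks, the target is declared not enriched and the threshold is set
  to the largest observed total, so at most one block passes — the correct
  null behavior for a control-dominated comparison, where the raw argmax
  would sit on sampling noise.

Mitochondrial blocks are excluded from calling: chrM is a single saturated
block with no positional information. A brute-force oracle (naive
base-scan blocks, exhaustive threshold enumeration) reproduces the caller
exactly on random small tracks.

## Amplification geometry

Dense tiling: a sliding window (default 50 kb, step 10 kb) flags windows
whose fraction of bases covered by broad peaks exceeds 0.5; maximal runs
of dense windows are the candidate amplicons. Breakpoints are refined to
the outermost retained peak edge inside the dense region, with sharpness
the ratio of peak-covered fraction 10 kb inside versus outside. Summit
profiles bin tumor and normal depth into 1-kb bins across a 1-Mb window,
smooth the difference with a Gaussian kernel (bandwidth 10 kb), and report
local maxima exceeding median + 3×MAD of the smoothed curve (prominence at
least 3×MAD); each summit is annotated with its width at half height and
the offset to the nearest bin-level tumor peak (the promoter peak).

## Signatures, grading, embedding, integration

The histone signature is the mean gene-span signal over the 64
replication-dependent histone genes (ribosomal-protein genes are the
comparator set). Distance-from-normal grading log10(x+1e-3)-transforms
features, computes the normal-sample centroid, and ranks query samples by
Euclidean distance; agreement with WHO-style grade is summarized by
Spearman correlation. 2-D embeddings use UMAP on log-transformed features
(top 5,000 by variance for bin/cCRE matrices) with a fixed seed; only
neighborhood-level properties are treated as meaningful.

Cross-modality integration treats the shared genes as observations and
samples as variables: both matrices are log-transformed and
gene-standardized, and ridge-regularized CCA (ridge 1e-3 on the
within-modality covariance diagonals, solved via the whitened SVD) yields
canonical sample loadings; samples of both modalities are placed by their
L2-normalized loadings on the first components and each CUTAC sample
reports its k nearest RNA-seq samples (default k=20), through which labels
are transferred by neighbor averaging or voting.

## Survival and aneuploidy

Recurrence-free survival uses Kaplan–Meier curves and the two-sided
log-rank test (lifelines). Biomarker groupings put the top-k patients by
value into the "malignant" group (ties broken by patient id) and the scan
reports log-rank p for every k, uncorrected — the scan is exploratory and
is annotated as such — together with a direction flag (malignant group
must have the lower restricted-mean survival for a p-value to support the
claim).

Arm dosage per sample is the mean signal of an arm's intervals divided by
the median of per-arm means; calls are gain at ≥1.25, loss at ≤0.75
(both exposed), withheld for arms with fewer than 10 intervals. The same
operation applies to RNA-seq gene counts via gene-span positions. Null
occupancy is the fraction of an arm's cCREs with exactly zero signal; per
arm, its Spearman correlation with the histone signature across patients
is reported with a patient-resampling bootstrap SD (default 1,000
replicates) and the asymptotic rank-test p.

## Synthetic data

The miniature genome is a fixed constant (its own build seed, independent
of simulation seeds): three autosomes with p/q arms totalling 27 Mb plus
chrM, 2,500 cCREs in five ENCODE-style categories with category-specific
enrichment weights (PLS 120 … CA-CTCF 40, over background 1), a chr1p
cluster of 64 histone genes whose emission scales with a latent
proliferation rate ρ (normal tissue is fixed at ρ=0.1), 25
ribosomal-protein genes, ~200 further genes with lognormal activities, and
scattered LINEs. Fragments are drawn from this piecewise-constant
intensity by multinomial sampling (fragment length ~ Normal(120, 35),
clipped at 20 bp); tumors multiply cCRE rates by (1 + hyper_factor),
apply per-arm copy ratios and focal amplicon factors
copy_ratio × (1 + gain × triangle(promoter, 50 kb)), and share a
per-tumor lognormal gene program with their matched RNA-seq counts
(Poisson, library 300k), so cross-modality pairing is recoverable.
Mitochondrial fragments are injected to per-role targets (tumor 5%,
normal 15%, mirroring reduced tumor mtDNA).

Cohort defaults model a mostly-benign population: about one patient in six
draws ρ ~ U(0.85, 1), the rest U(0, 0.2); recurrence is exponential with
hazard 0.002·exp(3ρ) per month, censored at 120 months, which yields ≈5 of
30 patients recurring rapidly while benign patients are mostly censored.
WHO-like grades are ρ tertiles. Whole-arm losses are subclonal and graded
— on loss-susceptible arms (alternating arms; stable arms anchor the
dosage reference, and the histone-locus arm is exempt because packing all
64 histone genes onto one miniature arm would otherwise couple dosage
directly into the signature) the lost-cell fraction is
clip(ρ − 0.25 + N(0, 0.1), 0, 1), so dosage falls continuously from 1
toward 0.5; gains are rare (3%) and ρ-independent. All-or-none loss
models cap the attainable score–null-occupancy correlation near 0.3 at
n=30 and cannot reproduce the arm-level sign consistency the analysis is
built to detect; graded subclonality is also what whole-genome sequencing
reports in real tumors.

Two matched-background benchmark pairs isolate the peak caller from
background sampling noise, as spike-in benchmarks should: the tumor shares
the normal's entire fragment pool over the cCRE landscape and adds fresh
fragments only inside the enriched windows — 20 promoter-class cCREs at
10× for the spike-in pair, and a packaged 268-kb, 8-copy amplicon over the
densest cCRE stretch of chr3 for the amplification pair. The amplicon's
designated promoter (6.760 Mb) is the fixed point at which the triangle
center coincides with its own induced smoothed apex given the local cCRE
landscape, computed from the genome alone; its edges abut flanking cCREs,
since an amplicon edge in a signal desert is undetectable in principle by
any fragment-based method.

## Problem sizes

Tests and the acceptance script run the generator at its study scale:
pairs of 1–2 × 10^5 fragments for coverage, peak-calling, amplicon and
signature analyses; 30-patient cohorts at 10^5 fragments per sample for
signature recovery, survival (20 cohort replicates) and integration; and
10^4 fragments per sample for the null-occupancy analysis — null
occupancy is a shallow-coverage statistic, and at 10^5 fragments the
miniature genome's 2,500 cCREs saturate (zero null occupancy everywhere).

## What the synthetic data does and does not show

The generator reproduces the statistical structure the pipeline assumes —
targeted enrichment over a five-category cCRE landscape, depth-equalized
paired comparisons, proliferation-scaled histone emission, graded arm
dosage with its null-occupancy footprint, shared tumor programs across
modalities, and proportional-hazards recurrence. It does not model
sequence content, mappability, duplicate or batch structure, clonal
phylogenies, fragment-size biology, or inter-patient covariate structure;
passing tests demonstrate correctness and statistical behavior of the
implementation under the stated generative model, not clinical
performance on patient data.

## Known limitations

* The miniature genome has 6 autosomal arms; arm-level statistics that
  depend on a large arm panel (e.g. median-of-arms dosage reference under
  heavy aneuploidy) are more fragile than at human scale, which is why
  stable arms are built into the default cohort.
* The threshold-scan p-values are reported uncorrected across k by
  design; they are exploratory.
* Embedding coordinates are contract-free beyond neighborhood structure;
  do not compare them across library versions.
* The peak caller's minimum-separation guard means enrichment confined to
  fewer than ~0.5% of blocks is declared null; detecting a handful of
  enriched sites among tens of thousands of background blocks is below
  the survival-gap statistic's resolution by construction.
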