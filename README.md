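# cutac

Analysis toolkit for paired tumor/normal RNA polymerase II occupancy maps
from CUTAC-style chromatin profiling of FFPE tissue sections. Each sample
is a file of mapped DNA fragments marking engaged (Ser5-phosphorylated)
RNAPII; the package turns matched tumor/normal pairs of such files into:

* **hypertranscription scores** — genome-scaled T−N signal per candidate
  cis-regulatory element (cCRE), ranked, maximized across pairs, and
  broken down by element category;
* **paired peak calls** — sparse-enrichment peak calling in which the
  matched normal replaces the usual background control, plus broad-peak
  merging, swapped-orientation counts and peak/cCRE overlap reports;
* **amplification maps** — densely tiled broad-peak regions, 1-kb binned
  summit profiles over 1-Mb windows with Gaussian smoothing, breakpoint
  localization at dense-region edges, and promoter fold changes;
* **the histone-gene prognostic signature** — mean RNAPII signal over the
  64 replication-dependent histone genes, distance-from-normal grading,
  UMAP embeddings, and ridge-regularized CCA integration with RNA-seq for
  nearest-neighbor label transfer;
* **outcome and aneuploidy analyses** — Kaplan–Meier / log-rank
  separation of top-k biomarker groups across all thresholds, whole-arm
  dosage calls from cCRE (or RNA-seq) signal, and the per-arm Spearman
  correlation between the histone signature and the fraction of an arm's
  cCREs with zero signal ("null occupancy"), with bootstrap SDs.

It is aimed at computational biologists prototyping or validating
RNAPII-based tumor diagnostics. Real patient data is not required: a
first-class synthetic module generates paired fragment sets over a
deterministic 27-Mb miniature genome — with configurable global
hypertranscription, promoter-centered focal amplicons, graded whole-arm
losses tied to a latent proliferation rate, mitochondrial fractions,
recurrence times, and matched RNA-seq counts — so the full pipeline runs
end to end in minutes.

## The model in brief

For sample *s*, per-base depth is the number of fragments spanning the
base, rescaled so the non-mitochondrial genome-wide mean is 1. For an
interval *I* (cCRE, fixed bin, or gene span), the signal is the mean
normalized depth over *I*; hypertranscription of *I* in a depth-equalized
pair is T(I) − N(I). Peaks are contiguous blocks of positive depth whose
total signal exceeds a threshold chosen to maximize the fraction of tumor
blocks minus the fraction of (distribution-aligned) normal blocks
surviving it. The prognostic signature is the mean gene-span signal over
the 64 replication-dependent histone genes; patients in the top-k by
signature form the putative-malignant group for the log-rank threshold
scan. Arm dosage is mean arm signal over the median of per-arm means;
null occupancy of an arm is the fraction of its cCREs with exactly zero
signal, which rises with arm loss. See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
from cutac import simulate, coverage as cov, signatures as sig, outcome as out
from cutac.genome import HISTONE_SET

genome = simulate.miniature_genome()
cfg = simulate.SimulationConfig(genome=genome, n_pairs=30,
                                depth_per_sample=100_000, seed=1)
cohort = simulate.simulate_cohort(cfg)

tumors = [fs for fs in cohort.samples if fs.role == "tumor"]
matrix = cov.build_signal_matrix(tumors, genome, "gene_span")
scores = sig.signature_score(matrix, HISTONE_SET,
                             genome.gene_sets).set_index("sample")["score"]

records = (cohort.metadata[cohort.metadata.role == "tumor"]
           .set_index("sample_id")[["recurrence_months", "event"]])
groups = out.top_k_groups(scores, 5, direction="high")
km = out.km_logrank(records, groups)

print(scores.sort_values(ascending=False).head(5).round(3).to_string())
print(f"log-rank p (top-5 histone vs rest): {km.p_value:.2e}")
```

Output:

```
sample
P19_T    14.793
P29_T    14.090
P08_T    13.914
P07_T    12.745
P26_T    12.202
log-rank p (top-5 histone vs rest): 3.17e-05
```

The five highest histone-signature tumors (scores ≈ 12–15 versus ≈ 6–8
for the rest, in normalized count units) are exactly the simulated
rapidly-proliferating patients (true latent rates 0.87–0.99), and the
Kaplan–Meier split of those five against the other 25 separates
recurrence-free survival at p ≈ 3×10⁻⁵.

A thin CLI covers the shell-facing stages:

```bash
cutac simulate --config cfg.json --out cohort/ --seed 3
cutac peaks --tumor cohort/P01_T.fragments.bed \
            --normal cohort/P01_N.fragments.bed --out peaks.bed
cutac hyper --tumor cohort/P01_T.fragments.bed \
            --normal cohort/P01_N.fragments.bed --k 100 --out top.tsv
```

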