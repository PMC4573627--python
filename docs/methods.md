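# Methods

## Model

`mirtss` treats miRNA promoter identification as one-class transfer: the
chromatin signature of "being a transcription start site" is learned where
TSSs are known (protein-coding genes) and applied where they are not (the
upstream windows of miRNA loci). The model assumes that (i) active promoters
of miRNA primary transcripts carry the same histone-modification profile as
coding-gene promoters, (ii) the profile is locally translation-invariant, so
a classifier trained on TSS-anchored windows scores arbitrary anchored
windows meaningfully, and (iii) the background (non-promoter) score
distribution can be estimated empirically from random genomic positions.

### Coverage and features

Reads are reduced to strand-aware 5' positions and counted in fixed
`bin_size` = 100 bp bins on an absolute genomic grid; counts are normalised
to reads per million per bin (RPM = R·10⁶/N with N the library's mapped-read
count, overridable). The 5'-end counting rule is exact for the point reads
the simulator emits and a close approximation for short reads; a read
contributes to exactly one bin, so Σ RPM · N/10⁶ equals the number of
assigned reads — a conservation law the tests enforce at 10⁻⁶ relative
tolerance. The last, shorter bin of a chromosome keeps its natural span.

Feature vectors are strand-oriented: per mark, `k` bins upstream and `k`
downstream of the anchor with the anchor's own bin as the first downstream
bin, concatenated across marks in a fixed order. Bins beyond a chromosome
edge contribute zero signal rather than dropping the anchor (a flag-free
choice that keeps anchor sets stable; the alternative is noted in the code).
Random negative anchors receive uniformly random strands — features are
oriented, so a convention is unavoidable; negatives are by default sampled
with no exclusion zone around real TSSs, so a realistic fraction of the
negative class actually overlaps promoters and the learning problem is the
harder, honest one.

### Classifier

A scikit-learn pipeline (StandardScaler + RBF-kernel SVC) is tuned by grid
search over C ∈ {0.1, 1, 10, 100} and γ ∈ {10⁻⁴…10⁻¹} with stratified
5-fold cross-validated accuracy on the training half only, ties broken
toward the smallest C then the smallest γ; the winner is refit on the full
training half. Standardisation is fitted on the training half because RBF
kernels are scale-sensitive. Scores are mapped to probabilities by a
Platt-style one-dimensional logistic regression on the training decision
scores; only strict monotonicity of that map is relied upon downstream, so
its (training-set) optimism is immaterial. Evaluation is a stratified random
half/half split: train on one half, ROC/AUC on the other. AUC is computed by
threshold sweep and equals the tie-corrected rank statistic; the test suite
cross-checks it against a brute-force all-pairs concordance oracle.

### Upstream scan and FDR control

Candidate bins tile the `max_upstream` = 10 kbp window ending at the bin
just 5' of the miRNA's 5' end (exactly mirrored for − strand loci, so genome
reflection maps candidate sets onto each other bin for bin). Each candidate
is scored by the classifier. Empirical p-values use the add-one rule
p = (r+1)/(n+1) against ≥ 10,000 decoy scores; Benjamini–Hochberg step-up
q-values are computed across the pooled candidates of all miRNAs, and a
miRNA is called when any of its candidates has q ≤ `fdr` (default 0.1).
Lowering `fdr` can only remove calls.

Two design choices here deserve emphasis:

* **The decoy null must avoid promoters and candidate regions.** In a genome
  with one gene every ~5 kb, 5–10 % of uniformly random positions lie on real
  promoters; with such a contaminated null no candidate can obtain a small
  empirical p-value and the scan loses all power (we measured best q ≈ 0.99
  on simulated data). Decoys are therefore sampled at least
  `decoy_exclusion` = 2,000 bp away from every annotated gene TSS and outside
  every miRNA's scan window — the null is the score distribution of
  non-promoter background, which is the hypothesis actually being tested.
* **Detection and localisation are separate.** FDR control detects *that* a
  window contains a TSS via its best-scoring candidate (ties resolved toward
  the most proximal bin). The *reported* bin is then chosen within ±300 bp of
  the detection bin by a matched filter — the candidate maximising the inner
  product with the mean promoter template (mean positive-anchor features
  minus mean decoy features). The SVM decision surface is nearly flat across
  the top of a broad enrichment peak, and its raw argmax localised only ~75 %
  of planted TSSs to within one bin on simulated data, versus ~90 % for the
  matched filter. Refinement never changes which miRNAs are called, and the
  reported score/q-value remain those of the detection bin.

### Categorisation and distances

A call is `shared_upstream` when the reported bin's midpoint lies within
`shared_tol` = 100 bp of the nearest gene TSS strictly upstream (5'-ward) of
the miRNA, `independent` otherwise, `none` when nothing passes FDR. The
intronic flag is set when the miRNA interval is wholly contained in an
intron (a gap between consecutive exons of one gene record; unspliced gene
records have no introns). Interval midpoints are defined as
(start + end − 1)/2, the centre of the covered bases, which is exactly
invariant under genome reflection.

Printed coordinates follow the conventions of the published tables this
format mirrors: genomic spans are 1-based inclusive, while 100 bp TSS bins
are written as 1-based half-open edge pairs (so printed width equals the bin
size, and the printed gap between a TSS bin and its miRNA is the plain
difference of the facing boundary coordinates). Distances to the miRNA may
be slightly negative when the reported bin overlaps the 5' end.

### Cross-method comparison

Two methods agree on a miRNA when their TSS positions (interval calls are
reduced to midpoints) lie within 100 bp on the same chromosome. For three
call sets, "consistent for all three" requires all three pairwise
agreements — the pairwise rule is not transitive near the tolerance, and a
miRNA with only partial agreement is counted in its largest fully agreeing
subgroup.

## Synthetic data

The simulator emulates the study conditions end to end. The genome is laid
out as shuffled cassettes: 5 kb gene cassettes (one gene of 1.5–3 kb with
2–4 exons, random strand — one gene per ~5 kb, the density of a compact
plant genome) and 14 kb miRNA cassettes, one per miRNA, with the planted
category deciding the local geometry: independent miRNAs get their own TSS
0.3–8 kb upstream inside a signal-clean window; shared miRNAs sit 0.2–1.5 kb
downstream of a dedicated upstream gene and share its TSS; intronic miRNAs
sit inside a 2 kb intron of a host gene and share the host TSS; null miRNAs
get a scan window guaranteed free of planted signal. Default mix: 15 %
independent, 30 % shared, 10 % intronic, 45 % null — the proportions of the
published call partition this package's workflow mirrors.

Reads are single-end 5' points: per mark, Poisson background uniform over
the genome plus, at every planted TSS, Poisson(`peak_amplitude`) reads at
positions drawn from a strand-oriented Gaussian (`peak_offset` = +200 bp
downstream, `peak_sd` = 300 bp), the offset making metagene profiles
visibly downstream-shifted as in real promoter chromatin. The per-library
total matches `library_size` (default 200,000 over the default 11.4 Mb /
2,000-gene genome) in expectation. The nine default marks caricature the
canonical palette: H3K4me3 strongly peaked (amplitude 50), H3K4me2 / H3K9Ac
/ H3K18Ac / H3K27me3 / H3K36me2 moderately peaked (15), H3K9me2 and H3K27me1
flat (0), H3K36me3 broad and gene-body shifted (12, offset +800, sd 600).

What the simulator does **not** model: mappability and sequence content,
nucleosome-scale positioning, replicate/antibody variation in peak shape,
overlapping or nested genes, and chromatin heterogeneity between active and
silent genes (every simulated gene is "on"). Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
stated generative model, not performance on real tissue data.

## Problem sizes used by the checks

Chosen once, as the package's own desk-scale study conditions:

* AUC structure (peaked vs flat marks, combined ≥ 0.9 at every window size):
  default genome (11.4 Mb, 2,000 genes, 9 marks, 2×10⁵ reads/mark), 1,000
  positive + 1,000 negative anchors, reduced grid C ∈ {1, 10},
  γ ∈ {10⁻³, 10⁻²}, 3-fold CV.
* FDR calibration and recovery: 20 replicates of a 1.8 Mb genome with 250
  genes and 36 miRNAs at the default category mix and the default background
  density (30,000 reads/mark); the classifier is trained once on the first
  replicate (3,000 negatives) and reused for scoring, 10,000 decoys per
  scan. Recovery is the fraction of planted independent TSSs whose reported
  bin lies within ±100 bp (one bin) of the bin containing the planted
  position; the realized false-call fraction is calls on signal-free miRNAs
  divided by all calls.

## Numerical and degenerate-input conventions

Bin assignment is floor division on internal 0-based positions; half-open
bins make boundaries unambiguous. Empirical p-values can never be 0 (add-one
rule) and ties count as ≥. BH q-values preserve input order (statsmodels'
step-up, validated in tests against the explicit min-over-suffix formula).
Stratified splitting floors the training side on odd class sizes. A
single-class training set, non-finite features, p-values outside (0, 1], an
empty decoy set, unstranded records passed to strand-dependent operations,
and a genome too small for the requested layout all raise immediately.
Constant decision scores (degenerate calibrations) are jittered by ±10⁻⁹
before fitting the sigmoid so the probability map stays defined.

## Known limitations

* The pooled-candidate BH procedure controls the FDR over candidate bins;
  because each signal-free miRNA contributes ~100 correlated candidates, the
  per-null-miRNA call probability at FDR 0.1 is ~0.15–0.2 even when the
  realized false-call fraction among calls is near nominal. A hierarchical
  (per-window max) null would test one hypothesis per miRNA, but a valid
  window-max null cannot be built from decoy windows in a gene-dense genome,
  where every 10 kb window contains real promoters.
* Localisation precision is limited by the width of the planted enrichment
  (sd 300 bp) relative to the 100 bp grid; the matched filter recovers ~90 %
  of planted TSSs to one bin under defaults, not all.
* Shared-vs-independent categorisation inherits localisation noise: a call
  1–2 bins off a shared promoter can fall outside the 100 bp tolerance and
  be reported independent.
* Reproducing the published per-mark AUC magnitudes and the exact 42/124/132
  partition requires the original ChIP-Seq libraries and annotation releases;
  the package documents that workflow but its tests assert the qualitative
  structure (mark ordering, combined-mark gain, category machinery) on
  synthetic data only.
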