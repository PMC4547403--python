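# Methods

`mirmark` implements an integrated miRNA/mRNA multi-marker discovery
pipeline for diagnosing cancer (motivated by pancreatic ductal
adenocarcinoma, PDAC) from paired expression profiles, together with a
synthetic-cohort generator that makes every stage testable without access
to patient data.

## Model and procedure

**Condition-specific target filtering.** Sequence-based miRNA-target
prediction grossly over-predicts. Because an active miRNA represses its
targets, the pipeline keeps a predicted edge (miRNA m, gene g) only when
the Pearson correlation of their expression across the paired cohort
(cancer and normal samples pooled) satisfies r < −0.3 with p < 0.05, both
strict. The p-value is the two-sided t-test on the simple-regression slope
with n−2 degrees of freedom, which is algebraically identical to the
correlation t-test. Filtering on pooled samples deliberately admits edges
whose anticorrelation is driven by the disease state itself (miRNA up,
target down in tumors); such pairs are exactly the condition-specific
relationships of interest, even when the repression is indirect.

**Class-weighted SVM marker scoring.** Every miRNA and every gene in the
filtered edge set is scored as a single-feature classifier of cancer vs
normal using a linear soft-margin SVM (C = 1) under leave-one-out
cross-validation (LOOCV). The cohort is heavily imbalanced (104 cancer vs
17 normal in the motivating design), so per-class penalty weights
α_cancer = 1, α_normal = n_cancer/n_normal (= 6.117647 for 104/17) equalize
the total penalty mass of the classes and remove the all-cancer degenerate
optimum. Features are z-scored inside each training fold only (no test
leakage). A decision value of exactly 0 is classified as cancer.
Performance is summarized by balanced accuracy BA = (sensitivity +
specificity)/2, by the Mann–Whitney AUC of the pooled LOOCV decision
values (ties counted 1/2), and by a permutation p-value: labels are
permuted, the entire LOOCV is re-run per permutation, and
p = (b+1)/(n_perm+1) with b = #{null BA ≥ observed BA}.

Because Bonferroni correction over m features requires p below 0.05/m, a
per-marker null of N permutations can never be significant unless
N > 20·m. The default is therefore a *pooled* null: each feature of a kind
contributes `n_perm` (default 25) permutation BAs to one shared
kind-level null distribution, so the pool holds m·n_perm values and the
smallest achievable adjusted p is ≈ 1/n_perm regardless of m. A
per-marker mode is available. Permutations refit the SVM from scratch —
reusing decision values would not be a valid permutation test.

A (miRNA, gene) pair is a **multi-marker candidate** when its edge
survived filtering and both endpoints individually exceed BA > 0.8,
AUC > 0.8 and Bonferroni-adjusted p < 0.05 (all strict; adjustment within
feature kind). A joint two-feature SVM mode exists behind a flag but the
endpoint rule is the default, mirroring how per-miRNA and per-gene
performances are reported separately in this literature.

**miRNA activity estimation.** Validation cohorts often lack miRNA
profiling. For each candidate miRNA, one simple linear regression of the
miRNA on each of its filtered target genes is fitted on the paired
training cohort; on an mRNA-only dataset the miRNA's activity is the mean
of the per-target predictions over whichever genes the platform carries.
This mean-of-predictions combination is the default because it degrades
gracefully under gene dropout across platforms; a joint multivariate
least-squares fit is available behind a flag (falling back to the mean on
collinear designs). Note the regression direction: activity estimation
regresses miRNA ON targets (the miRNA is what must be predicted), whereas
the filter tests the gene-on-miRNA slope; the two operations are kept
distinct. Estimated activity is standardized within each dataset before
classification, since intercepts learned on one platform do not transfer;
fold-wise z-scoring inside LOOCV makes the subsequent scoring invariant to
that affine choice. The baseline this scheme is compared against is the
older convention of using the arithmetic mean of the target genes' own BAs
as the miRNA's activity performance; the comparison metric is the mean
squared error between estimated and observed BAs over miRNAs.

**Multi-dataset validation.** A candidate is validated iff (a) its edge
shows r < 0 in the paired validation cohort, (b) both endpoints exceed
BA > 0.7 there (miRNA observed directly), and (c) in at least one
mRNA-only cohort both the gene and the miRNA's estimated activity exceed
BA > 0.7 — all strict, class weights recomputed per dataset from its own
counts. Datasets missing a marker's features count as not-passed for
validation but appear as "unavailable" in reports. Validated markers can
be scored, without thresholding, on cohorts of other cancer types to probe
disease specificity.

**Coregulation report.** From the validated edge set the pipeline counts,
per gene, the distinct miRNAs targeting it; genes with strictly more than
`min_mirnas` (default 6) regulators are tabulated, and the network is
exported as Cytoscape SIF plus a node-attribute table in which gene nodes
whose GO annotation matches a configurable cancer-related term set
(apoptosis, angiogenesis, cell proliferation, blood vessel development,
transcriptional regulation, immune response) are highlighted.

## Synthetic cohorts

The generator plants the causal structure the pipeline assumes: miRNA i
has baseline b_i ~ U(6, 10) (log2 scale); marker miRNAs (half by default)
gain a class shift `de_effect` (default 4.0 = 4·noise_sd) in cancer
samples; each targeted gene follows
g = intercept + slope·miRNA + N(0, noise_sd) with slope
`regulation_strength` < 0; untargeted genes are baseline plus noise. The
default slope is −1.0 so that a planted marker edge carries strong class
signal on the gene side as well: the gene-side separation is
|s|·de/√(1+s²) σ, i.e. 2.83 σ (Bayes-optimal BA ≈ 0.92) at s = −1,
against 1.79 σ (BA ≈ 0.81, marginal against the strict 0.8 cutoff) at
s = −0.5. Analyses of the filter and of activity estimation use s = −0.5
explicitly, a weaker, more realistic repression strength. The default
cohort is 104 cancer / 17 normal, 20 miRNAs with 10 targets each among 200
genes. The edge database contains every planted edge (20% flagged
"validated") plus `fp_edge_rate` decoy edges per true edge drawn from
pairs with no planted relationship. A coregulation preset wires one extra
gene to the first k miRNAs (each contributing slope/k). All randomness
derives from a single seed; identical configs give bit-identical cohorts,
and independent datasets are drawn from the same frozen generative law
(optionally mRNA-only and/or with a constant batch shift on mRNA).

What the generator does **not** emulate: probe-level microarray noise,
saturation, batch structure beyond a constant offset, correlated gene
modules, or miRNAs regulating hundreds of targets. Passing tests
demonstrate correctness of the machinery and qualitative behavior of the
statistics, not clinical performance on real cohorts.

Decoy edges between a marker miRNA and a gene regulated by *another*
marker miRNA are genuinely anticorrelated through the shared disease
factor; the filter and the validation stage intentionally keep such pairs
(they are condition-specific relationships, merely indirect). Recovery
statistics therefore distinguish *pure* (class-null) decoys — never
retained above chance — from confounded ones.

## Numerical choices

* **Exact 1-D SVM solver.** Single-feature linear weighted SVMs are solved
  exactly: for fixed slope w the optimal intercept minimizes a
  piecewise-linear function whose breakpoints are y_i − w·x_i; the
  subgradient of the full objective in w is then monotone and bisection
  (60 iterations over |w| ≤ √(2·ΣC_i)) locates the optimum to machine
  precision. Breakpoints are visited via a two-cursor merge over a
  presorted feature vector, so one LOOCV pass over 121 samples costs
  ~4 ms. The solver is property-tested for coefficient-level agreement
  with libsvm (sklearn `SVC`) and never attains a worse objective value.
  Multi-feature or nonlinear configurations fall back to `SVC` per fold.
* **Quantile normalization** maps each column onto the vector of row-wise
  means of column-sorted values; tied values receive the mean of the
  reference values at the tied positions. The transform is idempotent
  (exactly so on tie-free data).
* **Duplicate probes** in expression tables are collapsed by mean, logged.
* **Degenerate inputs**: zero-variance vectors, single-class cohorts and
  LOOCV folds whose training half contains one class raise typed errors;
  edges with endpoints missing from a matrix are skipped and counted.
* **Tie-breaks**: decision value 0 → cancer; exact class-mean tie →
  regulation "up" with a warning; p-value comparisons use BA ≥ observed
  with a 1e-12 guard against float jitter.

## A LOOCV artifact worth knowing about

With α_normal = n_cancer/n_normal the weighted class masses balance
*exactly*. On a feature with no class signal the SVM then often prefers
the constant classifier — and under LOOCV the constant classifier always
favors the training majority, which is by construction the class the
held-out sample does **not** belong to. Null-feature LOOCV BAs therefore
average ≈ 0.33 (not 0.50) with an atom at BA = 0 whose mass shrinks with
cohort size (≈ 27% at n = 20, ≈ 7% at n = 121). This is a property of the
weighted-SVM-LOOCV combination, reproduced identically by libsvm, not a
solver bug. It is harmless for marker discovery (only high BAs are
selected, and the permutation null carries the same artifact, so p-values
stay calibrated — measured type-I error 0.065 at nominal 0.05, KS
uniformity D = 0.06 over 200 null datasets at the 104/17 design), but
single null BAs must not be read as "chance = 0.5". The calibration study
uses the 104/17 design precisely because smaller cohorts make the BA = 0
atom — and hence the discreteness of permutation p-values — much larger.

## Problem sizes

Simulation-based checks run at the study scale where it matters
(121-sample cohorts; 20 miRNAs × 10 targets; 20 replicates for the MSE
comparison with 40-sample test sets; 200 null datasets × 199 permutations
for calibration) and at reduced scale for quick unit tests. The
acceptance script uses 10 MSE replicates and 100 calibration datasets.

## Known limitations

* The permutation budget (default 25 per feature, pooled) trades
  per-marker resolution for attainable Bonferroni thresholds; p-values
  below ≈ 1/n_perm are not resolvable.
* Multi-marker status is an endpoint conjunction, not a joint model; the
  optional joint 2-feature SVM mode is provided but unvalidated against
  any reference.
* Edge filtering and validation use pooled-sample correlations; per-class
  correlation structure is not examined.
* The generator's linear single-regulator model cannot probe robustness
  to combinatorial regulation beyond the simple coregulation preset.
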