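# Methods

## The resampling statistic

Given an expression matrix (genes × samples) and per-sample follow-up
(time, event), one draw at set size *s* proceeds: sample *s* distinct genes
uniformly without replacement; center each gene row and take the samples'
loadings on the first right singular vector of the centered submatrix (PC1
scores; zero-variance genes are dropped, a fully degenerate draw is redrawn
and counted); split the cohort at the median score; compare the two groups
with the standard two-sample log-rank test. Repeating *b* times yields the
p-value set **P**.

The reference distribution is not the uniform: sparse follow-up and tied
event times distort log-rank p-values even for truly random groups. The
empirical null **R** is therefore built from *b* uniformly random
equal-sized group assignments of the same samples (sizes ⌈n/2⌉/⌊n/2⌋,
mirroring the median split). One **R** serves all set sizes, since it
depends only on survival. The *proportion of significant random sets* is
the fraction of **P** strictly below the 5th percentile of **R**; the
percentile uses numpy's linear interpolation (rank `(n−1)q/100`) and is
recorded in output provenance, because this threshold directly gates the
counts.

The deviation of the proportion p̂ from the nominal 0.05 is tested with a
two-proportion Z statistic, `Z = (p̂ − 0.05)/√(p̂(1−p̂)/b + 0.05·0.95/b)`,
referred to N(0,1) two-sidedly; the sample size in the variance is the
number of resampling draws *b*, the quantity to which the central limit
theorem applies for a proportion of draws. A dataset is labelled positively
(negatively) biased when the two-sided p is below 0.05 and p̂ is above
(below) 0.05. No multiplicity correction is applied across datasets or set
sizes.

Numerical conventions worth stating:

- **Log-rank test.** Implemented as a vectorized batch over many label
  vectors against one survival table (the resampling loop needs thousands of
  evaluations; per-call overhead dominates otherwise). At each distinct
  event time the observed-minus-expected events in group 1 accumulate, with
  the hypergeometric variance including the `(n−d)/(n−1)` tie correction —
  the field-standard choice for day-resolution data; the statistic
  `(ΣO−E)²/ΣV` is referred to chi-square(1). The implementation agrees with
  lifelines to machine precision (tested).
- **Median split.** Samples strictly below the median go low, strictly above
  go high; samples exactly at the median are assigned in input order to the
  currently smaller group (low when equal), so group sizes differ by at most
  one and the split is deterministic. The split is invariant to the sign of
  the PC1 vector.
- **PC1.** Rows are centered but not variance-scaled (scaling is not part of
  the procedure; correlation-like behavior can be obtained by pre-scaling
  the matrix upstream if desired).
- **Strict inequality** (`p < r`) in significance counting; p-values are
  continuous so ties are measure-zero, and strictness makes self-comparison
  well defined.

## Proliferation adjustment

The proliferation score of a sample is the median expression over a
signature gene list; even-length medians are the mean of the middle two
values. The canonical list (genes most correlated with PCNA across many
cohorts) is an external artifact, so the package accepts any gene-list file
and can also derive an in-dataset stand-in: the top `⌈f·M⌉` genes by Pearson
correlation with a user-chosen anchor gene (default f = 0.01, anchor
excluded). Output metadata records which signature was used. Adjustment
replaces each gene by its OLS residual against the score (intercept
included); residuals are orthogonal to the centered score to 1e-8 relative
tolerance and the operation is idempotent. Scores are always computed from
unadjusted expression, never from residuals, preventing circularity.

In the synthetic latent-signature cohorts the anchor is naturally the most
variable gene: under the model `x_g = λ_g z + ε`, marginal variance is
`λ_g² + σ²`, so the top-variance gene is the strongest marker of the latent
program — the simulation analog of a canonical proliferation marker.

## Half-split consistency

Each sample is assigned to one of two halves by an independent fair coin
(splits leaving an empty or event-free half are redrawn with a logged
count). Per split, a fresh batch of random gene sets is evaluated in both
halves with the same PC1/median-split/log-rank machinery; a set is
"significant" in a half when its raw log-rank p falls below α = 0.05 — the
nominal threshold, not the empirical-null one, because halves are compared
directly with each other. Pooling all `n_splits × sets_per_split` sets gives
a 2×2 table (significant in A × significant in B), a sample odds ratio, and
a one-sided Fisher exact p for enrichment of doubly-significant sets.
Defaults are 50 splits × 100 sets. Note the analysis is uninformative at
signal saturation: when essentially every set is significant in every half
the table degenerates and the odds ratio is undefined.

## Graph sub-classification

Distance between samples is 1 − Spearman correlation of their expression
profiles (average ranks for ties). Each sample's k nearest neighbors are
found (ties by ascending index); candidate edges are pairs appearing in
either endpoint's list. An edge (i, j) is weighted by the surprise of the
shared-neighbor overlap: with both neighbor sets restricted to exclude i and
j and a universe of n − 2 other samples, the upper-tail hypergeometric
probability of the observed overlap, transformed to −log10 p and capped at
300. Zero-overlap pairs are kept only when mutually nearest. Communities are
found by Louvain modularity maximization (resolution 1, seeded visit order);
the reported modularity is re-evaluated directly from
`Q = Σ_c (w_c/W − (d_c/2W)²)` rather than taken from the optimizer. Default
k = 30 (the published phenoGraph default), or n/3 for small cohorts.
Partitions are stable across moderate k (15–40 agree essentially perfectly
on well-separated subclasses); very small k (≲10) fragments the graph into
many tiny dense neighborhoods and is not recommended.

Weighting every possible sample pair would give a dense n² graph;
restricting to kNN-union pairs follows the phenoGraph construction and
preserves sparsity. The exact 2×2 layout of the
original weighting is not published; the one-sided hypergeometric
enrichment used here is a reconstruction and is flagged as such in output
metadata.

## Pipeline

`analyze_dataset` runs the size sweep (default sizes 2⁰..2¹⁰, b = 5000 at
full scale; tests and examples use b = 300–1000) on raw and, when a
signature or anchor is configured, adjusted expression. Per-cluster
re-analysis restricts expression and survival to each cluster of at least 10
samples and recomputes the empirical null on the cluster's own survival —
the null depends on group size and follow-up, so inheriting the pooled null
would misestimate the threshold. Size-matched random subsamples are analyzed
identically as the statistical-power control. Label stratification (e.g. by
grade) uses the same machinery with groups under 10 samples skipped. All
figure-shaped outputs are numeric TSVs; the full report round-trips through
JSON with complete provenance (seeds, b, sizes, percentile rule, transform
flags).

## Synthetic cohorts

The generator emulates three mechanisms:

- `null`: expression iid Normal(0, σ²), survival independent of expression —
  the calibration condition.
- `global_signature`: latent `z_i ~ N(0,1)` per sample; a fraction of genes
  (default 0.3) receives `λ_g z_i` with `λ_g ~ N(0, loading_sd²)`; hazard
  `h_i = h₀ exp(β z_i)` (default β = 1). This is the
  "pervasive proliferation-like program" explanation of positive bias.
- `subclasses`: class labels drawn iid from a mixing vector; a fraction of
  genes (default 0.3) is differentially expressed with per-gene random
  high/low patterns over classes (magnitude `de_effect·σ`, default 2σ;
  constant patterns are redrawn so signal is diffuse and no gene is a
  perfect marker); hazard `h_i = h₀ exp(γ_{c_i})`. Equal per-class hazards
  produce negative bias (consistent splits between survival-identical
  groups); unequal hazards produce positive bias that sub-classification
  removes.

Survival is exponential with independent exponential censoring, chosen for
closed-form event fractions `h/(h + c)`; defaults h₀ = 0.01/day and
c = h₀/3 (~25% censored), a follow-up pattern typical of reasonably powered
TCGA cohorts. Default cohort size is 300 samples × 2000 genes — large
enough for stable PC1s and clustering, small enough that full analyses run
in seconds to minutes on one core. Ground truth (latent scores, class
labels, signature/DE gene indices) is stored with the cohort rather than
recomputed, so recovery tests cannot drift.

What the generator does **not** model: count noise (values are Gaussian, not
negative binomial), batch effects, copy-number or mutation structure,
non-proportional hazards, or informative censoring. Passing tests therefore
demonstrate the statistical machinery and the stated mechanisms, not
robustness to every real-data pathology; on real RSEM matrices the log2(x+1)
transform (the reader default) is recommended before PC1 and correlation
steps.

## Known limitations

- With iid class assignment, binomial class-count imbalance (≈ ±√n/2) forces
  the equal-sized median split to flip that many boundary samples, and which
  samples flip varies from draw to draw; in survival-identical subclass
  cohorts this jitters the log-rank p across draws (interquartile ranges
  around 0.2 rather than near zero) even though the significant proportion
  collapses correctly. Exactly balanced cohorts concentrate much more
  tightly.
- The half-split consistency odds ratio is undefined under signal
  saturation (see above).
- The median split is tuned to detect two roughly equal-sized prognostic
  groups; a small subgroup with distinct survival can be missed entirely.
- The two-proportion Z test treats draws as independent; random gene sets
  overlap, so at very large s relative to M the draws are correlated and
  the test is anti-conservative.
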