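# Methods

`notchcall` implements a transcriptome-based caller for NOTCH pathway
activation together with the statistics that typically surround it in a
preclinical γ-secretase-inhibitor study: count normalization and
differential-expression filtering, ranked-list pathway enrichment, and
xenograft efficacy analysis. This note records the models, the defaults
and why they were chosen, and what the synthetic-data generator does and
does not emulate.

## The activation caller

A tumor is scored on a curated signature with an up-set of 21 NOTCH target
genes expected to be elevated when the pathway is active, and a down-set of
four genes (*LXN*, *RAPGEF3*, *TMEM154*, *LGR6*) expected to be suppressed.
The packaged up-set combines directly named NOTCH targets (*HES1*, *HES2*,
*HES5*, *HEY1*, *HEY2*, *HEYL*, *NRARP*, *MYC*, *CDK6*, *CCND1*, *KIT*)
padded to 21 with canonical pathway members (*HES4*, *NOTCH1*, *NOTCH3*,
*DTX1*, *DLL1*, *DLL3*, *JAG1*, *JAG2*, *LFNG*, *SOX9*). The signature
ships as a GMT file (`notchcall/data/notch_signature.gmt`) precisely so it
can be replaced: the membership of the up-set is a curation choice, not an
algorithmic one, and any disjoint up/down pair of gene lists works.

**ssGSEA.** For one sample, genes are ordered by decreasing expression and
the score is the summed difference between the weighted in-set
empirical CDF and the uniform out-of-set CDF,

```
score = Σ_{i=1..N} [ P_in(i) − P_out(i) ],
P_in(i) = Σ_{g∈S, pos(g)≤i} r_g^τ / Σ_{g∈S} r_g^τ,
P_out(i) = |{g∉S, pos(g)≤i}| / (N − |S|),
```

with descending-rank score `r_g = N − pos(g) + 1` and weight exponent
τ = 0.25, the conventional default of the single-sample enrichment family.
Expression ties are broken lexicographically by gene identifier so the
score is bit-reproducible and independent of input row order. If every
gene in the matrix belongs to the set the out-of-set CDF is undefined; the
score is then 0 by convention, with a warning. Across a cohort the scores
are min–max rescaled by default; this is monotone and does not change
calls under the default cohort-median threshold.

**kTSP.** The k-Top-Scoring-Pairs score is the fraction of
(down-gene, up-gene) pairs whose within-sample expression ordering obeys
`down < up`, over the |D|·|U| pairs present in the matrix. Ties count as
non-compliant (strict inequality). The score is a proportion in [0, 1] and
is invariant under any strictly increasing transform of the sample's
expression values — it depends only on ranks, which makes it robust to
normalization choices.

**Decision rule.** A sample is called activated when
`ktsp ≥ 0.5` **and** `ssGSEA ≥ threshold`, where the ssGSEA threshold
defaults to the cohort median (an absolute value may be supplied). The
conjunction with these two thresholds is the package's own choice of how
to combine the two scores; both are configurable, and the thresholds used
are recorded in the output. A cohort-median threshold necessarily labels
about half of an unstructured cohort as "activated" on that axis, so in
screening settings an absolute threshold derived from a reference cohort
is preferable.

**Clustering.** Samples are clustered on the signature genes with
agglomerative hierarchical clustering, Euclidean distance and Ward
linkage. SciPy's `ward` on raw Euclidean distances corresponds to the
Ward.D2 criterion. A flat cut at k = 2 is returned by default.
Cluster-significance testing is out of scope.

## Normalization and differential expression

Size factors are median-of-ratios: the per-sample median of
count/geometric-mean ratios over genes expressed in every sample, with the
median taken on the log scale (geometric interpolation between the two
middle ratios when the reference-gene count is even). This matches the
behavior of the standard count-normalization implementations and is
cross-checked against one of them in the tests. If no gene is expressed in
every sample this is a hard error rather than a silent fallback.

The DE test is intentionally simple and is labeled as such: a
negative-binomial Wald test with variance function `v(m) = m + α·m²`. Per
gene, group means of normalized counts give the log fold-change
`ln(m_t/m_c)`; the delta-method standard error is
`sqrt(v(m_t)/(n_t·m_t²) + v(m_c)/(n_c·m_c²))`; two-sided p-values come
from the normal reference. None of the machinery of a full DE package
(dispersion shrinkage toward a trend, outlier handling, independent
filtering) is reimplemented, because the reproducible content of the
analysis is the three filtering criteria, not the estimator internals.

**Dispersion.** The raw moment estimate
`α̂ = (pooled within-group variance − pooled mean) / pooled mean²` is
nearly unbiased but extremely noisy at the study's 3–5 samples per arm;
plugging it in per gene makes the Wald statistic anti-conservative
(empirical type-I error ≈ 0.09 at nominal 0.05 in our null simulations).
The default `dispersion_mode="pooled"` therefore averages the raw moment
estimates across all genes into a single cohort-level dispersion, which in
the same simulations restores calibration (0.042–0.061 across seeds) while
leaving power at planted 4-fold effects essentially at 1. A
`"per_gene"` mode retains the unpooled estimator (floored at 1e-8) for
cohorts large enough to support it. The pooled default assumes dispersion
is roughly shared across genes — true of the generator and approximately
true of real RNA-seq only after trend-fitting, which is exactly what the
full DE packages add.

**Filters.** A gene passes when (i) its mean normalized expression exceeds
50 reads, (ii) |log2 fold-change| exceeds 1, and (iii) BH-FDR is below
0.05 — all strict inequalities, so a gene at exactly 50 reads or exactly
log2FC = 1 fails. The fold-change uses a pseudocount of 0.5 on the group
means to keep zero means finite without reordering genes. The ">50 reads"
mean is taken over all samples by default (a per-group-minimum flag is
provided, since either reading is defensible).

## Ranked-list enrichment (mHG)

Given a ranked gene list and a set of B member genes, the minimal
hypergeometric statistic scans every prefix cutoff n = 1..N−1 and takes
the smallest hypergeometric tail `HGT(b_n, n) = P(X ≥ b_n)` with
X ~ Hypergeometric(N, B, n); ties in the minimum resolve to the smallest
cutoff. Because the minimum over dependent tails is not a p-value, the
exact p-value is computed by dynamic programming over the lattice of
(successes seen, prefix length) states: under a uniform permutation of the
membership vector, path counts into cells whose tail is ≤ the observed
statistic are zeroed, and the surviving path count over C(N, B) gives the
probability of never reaching the observed extremity. Path counts are
exact Python integers, so the p-value is exact up to one final division,
and tiny p-values survive (the subtraction is done in integer arithmetic).
Tails are evaluated in log space from cumulative log-factorials, stable to
N ≈ 20,000, although the exact DP is practical to roughly N of a few
thousand (it is O(N·B) big-integer operations); the intended universe is
the genes present in the expression matrix. A 1e-12 relative tolerance is
applied when comparing tails to the observed minimum so float round-off
cannot split exact ties.

Set-overlap questions ("k of n downregulated genes fall in a pathway
covering fraction p of the genome") use the exact binomial tail
P(X ≥ k). Multiple gene sets are corrected across sets by
Benjamini–Hochberg.

## Xenograft efficacy

Tumor volume follows the caliper formula `TV = 0.52 · width² · length`
(mm³). Percent tumor growth inhibition is

```
%TGI = 100 · (1 − (T_final − T_baseline) / (C_final − C_baseline)),
```

with group volumes summarized by arithmetic means (a median option
exists); baseline and final days default to the first and last day the two
groups share. Values above 100% indicate regression below the treated
baseline. Animals missing the final measurement are excluded with a
warning rather than interpolated. %TGI is invariant to rescaling all
volumes by a common factor.

Growth rates are per-animal OLS slopes of ln(volume) on study day —
exponential growth appears as a straight line on that scale, and the
generator's multiplicative lognormal noise makes the regression
assumptions hold by construction. Groups are compared by one-way ANOVA on
the slopes followed by Tukey–Cramer pairwise comparisons:
`q_ij = |m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j))` referred to the
studentized range distribution with k groups and N−k degrees of freedom
(SciPy's numerically integrated tail). For two groups this collapses to
`q = √2·|t|`, which the tests verify, and the whole table is cross-checked
against an independent Tukey implementation. Degenerate inputs (zero
within-group variance) are defined, not errors: identical group means give
F = 0 and all adjusted p = 1.

qPCR fold-changes use 2^−ΔΔCt: per (sample, condition), ΔCt is the target
Ct minus the reference-gene Ct (ACTB by convention); ΔΔCt is the mean
treated ΔCt minus the mean control ΔCt.

## The synthetic-data generator

The generator exists so that every stage is testable without any external
download; its defaults encode the study conditions the analysis assumes.

* **Expression cohorts** — negative-binomial counts with variance
  `m + α·m²` (Poisson in the α → 0 limit), per-gene baseline means drawn
  log-uniformly over (20, 2000) reads, a single global dispersion
  α = 0.1 by default (per-gene dispersion behind a flag), and per-sample
  library-size jitter uniform in ±20%. Activated samples have up-set
  means multiplied by 4 and down-set means by 0.25 by default — a strong,
  cleanly separated activation contrast. The null configuration
  (both effects 1) is allowed and makes the two arms exchangeable.
* **Treatment series** — a paired redraw of the same cohort in which the
  drug multiplies up-set means of activated samples by a fold < 1 and
  leaves wild-type samples untouched.
* **Growth curves** — per animal, `V(day) = V0 · exp(rate·day) · ε` with
  lognormal ε (σ = 0.1 by default), V0 uniform in the 150–300 mm³
  randomization window, twice-weekly measurement days over three weeks,
  5 animals per arm, and a default vehicle growth rate of 0.08/day
  (≈ 9-day doubling, a typical rapidly growing xenograft). Width and
  length are back-derived (assuming width = length) so the caliper
  formula reproduces the simulated volume exactly.
* **Ct tables** — target Ct = baseline − log2(true fold) + Gaussian noise,
  reference gene fixed at fold 1.

What the generator deliberately does **not** emulate: gene–gene
correlation structure, per-gene dispersion trends over the mean,
GC/length biases, mouse-read contamination of PDX samples, batch effects,
dropout, or tumor growth plateaus. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated model, not
robustness of the caller to every artifact of real RNA-seq; on real
cohorts the signature content and the ssGSEA threshold are the parameters
to revisit first.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seed and spec produce bitwise-identical outputs, and pipeline outputs
  embed a config hash and seed in a header comment so reruns can be
  diffed byte-for-byte.
* Expression ranking ties → lexicographic by gene id; kTSP ties →
  non-compliant; mHG minimum ties → smallest cutoff.
* All-zero or constant genes in the DE test get z = 0, p = 1 (defined,
  conservative), as does any gene with a zero group mean.
* Hard errors, never silent repairs, for: duplicate identifiers,
  non-numeric or missing expression cells, animals in two groups,
  non-positive caliper dimensions or volumes, missing reference-gene Ct,
  and an all-absent gene set.
* Result tables serialize floats at 6 significant digits; write/read round
  trips are identities at that precision.

## Problem sizes used in the shipped checks

The packaged tests and the acceptance script run, by choice, at the scale
of the study they emulate: cohorts of 10 + 10 samples over 300–1000 genes,
DE calibration on 2000 genes at 5 + 5 samples, mHG exhaustive-enumeration
verification for all list lengths N ≤ 9 (where all C(N, B) orderings can
be enumerated exactly), Tukey familywise calibration over 500–1000
simulated three-arm studies, and growth studies of 5 animals per arm.
These sizes give stable Monte-Carlo estimates while keeping the whole
suite fast.
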