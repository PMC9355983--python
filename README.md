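# notchcall

A NOTCH pathway activation caller for tumor transcriptomes, with the
surrounding statistics of a preclinical γ-secretase-inhibitor study:
count normalization and differential expression, exact ranked-list
enrichment, and xenograft efficacy analysis. Everything runs offline on
synthetic data generated by the package itself, so every result in this
README is reproducible from a seed.

## The scientific problem

Adenoid cystic carcinoma and several other tumor types harbor activating
NOTCH pathway alterations, and NOTCH-activated tumors are the ones
expected to respond to γ-secretase inhibitors. Mutation calling alone
misses pathway activation through non-mutational routes, so the practical
question is: **given an expression profile, is the NOTCH pathway
transcriptionally active in this tumor?** Downstream of that call sit the
standard preclinical questions — which genes does the drug suppress, are
the suppressed genes enriched for NOTCH targets, and does the drug inhibit
tumor growth in xenografts?

## The model in brief

A curated signature (shipped as a GMT file) has an up-set of 21 NOTCH
target genes and a down-set of 4 genes (*LXN*, *RAPGEF3*, *TMEM154*,
*LGR6*). Each sample gets two scores:

* **ssGSEA** — a single-sample running-sum enrichment of the up-set, with
  rank weight exponent τ = 0.25 and lexicographic tie-breaking, rescaled
  to [0, 1] across the cohort;
* **kTSP** — the fraction of (down-gene, up-gene) pairs with
  `down < up` within the sample, a rank-only score invariant to any
  monotone transform of expression.

A sample is called **activated** when `ktsp ≥ 0.5` and its ssGSEA score is
at or above the cohort median (both thresholds configurable). Supporting
machinery: median-of-ratios size factors; a negative-binomial Wald DE test
with pooled moment dispersion and the strict filters mean > 50 reads,
|log2FC| > 1, BH-FDR < 0.05; the minimal-hypergeometric (mHG) ranked-list
statistic with an *exact* big-integer lattice-path p-value; caliper tumor
volume `TV = 0.52·width²·length`, %TGI, ln-volume growth slopes with
ANOVA + Tukey–Cramer; and 2^−ΔΔCt qPCR fold-changes. Full derivations,
defaults and limitations are in [docs/methods.md](docs/methods.md).

## Worked example

`examples/01_activation_calling.py` simulates a cohort of 10 activated and
10 wild-type samples over 500 genes (negative-binomial counts, 4-fold
up-set elevation, 4-fold down-set suppression in activated tumors),
normalizes it, scores it, and compares calls against simulation truth:

```python
from notchcall import (CallerConfig, CohortSpec, call_activation,
                       default_signature, normalize_counts, score_cohort,
                       simulate_expression_cohort)

matrix, metadata, truth = simulate_expression_cohort(
    CohortSpec(n_activated=10, n_wildtype=10, n_genes=500, seed=1))
scores = score_cohort(normalize_counts(matrix), default_signature(),
                      CallerConfig())
calls = call_activation(scores)
```

Output (abridged):

```
sample_id  ssgsea_score  ktsp_score          call
    ACT00         0.931       0.786     activated
    ACT04         1.000       0.798     activated
    ...
     WT03         0.000       0.310 not_activated
     WT09         0.068       0.250 not_activated

label recovery vs simulation truth: 100%
```

The two score distributions separate cleanly (ssGSEA ≥ 0.905 for every
activated sample vs ≤ 0.125 for wild-type; kTSP ≥ 0.75 vs ≤ 0.417), and
the caller recovers all 20 labels.

The other examples continue the story with equally concrete outputs:

* `02_differential_expression.py` — drug-vs-vehicle DE on a treated
  cohort: 21 of 800 genes pass all three filters, 20 of them signature
  up-set genes (top hit *CCND1*, log2FC −2.36, FDR 5.8e-13).
* `03_enrichment.py` — mHG on a 400-gene ranked list: the planted pathway
  scores mhg_stat 2.47e-23 with exact p = 1.03e-22, while an unrelated set
  gets p = 0.09; the exact binomial overlap test gives p = 2.64e-06 for
  60/325 hits at a 10% background rate.
* `04_xenograft_efficacy.py` — a 5+5-animal study where the drug quarters
  the growth rate: %TGI (day 0 → 21) = 92.0%, mean ln-volume slopes
  0.078/day (vehicle) vs 0.018/day (drug), ANOVA F = 220.27,
  p = 4.18e-07.
* `05_qpcr_fold_change.py` — 2^−ΔΔCt recovers planted fold-changes
  (e.g. *HEY1* true 0.25, recovered 0.261).

## Command-line interface

A thin CLI wraps the library for file-to-file runs:

```bash
notchcall simulate --n-activated 10 --n-wildtype 10 --seed 1 --out cohort/
notchcall call --expression cohort/counts.tsv --out results/
notchcall de --expression treated.tsv --metadata meta.tsv --out de.tsv
notchcall efficacy --growth growth.tsv --control vehicle --out results/
notchcall run --config run.yaml        # full pipeline from a YAML config
```

Pipeline outputs carry a provenance header (`# notchcall stage=...
config_hash=... seed=...`); a rerun with the same config and seed is
byte-identical.

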