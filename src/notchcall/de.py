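"""Count normalization and simplified negative-binomial differential expression.

Normalization is median-of-ratios: each sample's size factor is the median,
over genes with a positive geometric mean, of that sample's count divided by
the gene's across-sample geometric mean.

The differential-expression test is a deliberately simple negative-binomial
Wald test: per-gene dispersion is estimated by the method of moments pooled
within groups (no shrinkage, no outlier filtering, no independent
filtering), the Wald statistic is the log fold-change over its delta-method
standard error, and two-sided p-values come from the normal reference.  The
downstream filtering criteria are the reproducible content:

    (i)   average expression > 50 normalized reads,
    (ii)  |log2 fold-change| > 1,
    (iii) FDR < 0.05,

all strict inequalities.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .io_formats import ExpressionKind, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "normalize_counts",
    "log2_fold_change",
    "nb_wald_test",
    "apply_de_filters",
    "de_pipeline",
]

DEFAULT_MEAN_MIN = 50.0
DEFAULT_LFC_MIN = 1.0
DEFAULT_FDR_MAX = 0.05
DISPERSION_FLOOR = 1e-8


def size_factors(raw: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    factor_j = median over reference genes of count_gj / geomean_g, where the
    reference genes are those with a positive geometric mean across samples
    (i.e. nonzero in every sample).
    """
    if raw.kind is not ExpressionKind.raw:
        raise ValueError("size factors are defined on raw counts")
    counts = raw.values
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    ref_ok = np.all(counts > 0, axis=1)
    if not np.any(ref_ok):
        raise ValueError(
            "no gene has nonzero counts in every sample; cannot form the "
            "geometric-mean reference (consider a pseudo-reference fallback)"
        )
    log_geomean = log_counts[ref_ok].mean(axis=1)
    log_ratios = log_counts[ref_ok] - log_geomean[:, None]
    # median taken on the log scale (geometric interpolation between the two
    # middle ratios for an even reference count), the DESeq2 convention
    factors = np.exp(np.median(log_ratios, axis=0))
    if np.any(factors <= 0):
        raise ValueError("computed a non-positive size factor")
    return factors


def normalize_counts(raw: ExpressionMatrix, factors: np.ndarray) -> ExpressionMatrix:
    """Divide each sample column by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (raw.n_samples,):
        raise ValueError("one size factor per sample required")
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    return ExpressionMatrix(
        list(raw.gene_ids),
        list(raw.sample_ids),
        raw.values / factors[None, :],
        ExpressionKind.normalized,
    )


def _split_groups(matrix: ExpressionMatrix, group_labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(list(group_labels))
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    if len(labels) != matrix.n_samples:
        raise ValueError("one group label per sample required")
    control, treated = uniq[0], uniq[1]
    return matrix.values[:, labels == treated], matrix.values[:, labels == control]


def log2_fold_change(
    normalized: ExpressionMatrix, group_labels, pseudocount: float = 0.5
) -> np.ndarray:
    """Per-gene log2((mean_treated + c) / (mean_control + c)).

    The second distinct label in ``group_labels`` is taken as treated.  The
    pseudocount keeps possibly-zero means finite while preserving ordering.
    """
    treated, control = _split_groups(normalized, group_labels)
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    return np.log2(
        (treated.mean(axis=1) + pseudocount) / (control.mean(axis=1) + pseudocount)
    )


def nb_wald_test(
    normalized: ExpressionMatrix, group_labels, dispersion_mode: str = "pooled"
) -> pd.DataFrame:
    """Per-gene Wald test of equal means under a negative-binomial model.

    Dispersion alpha is estimated by the method of moments pooled within
    groups, floored at 1e-8: alpha = (pooled within-group variance - pooled
    mean) / pooled mean^2.  The Wald z statistic is ln(m_t/m_c) over the
    delta-method SE, with var(mean) = (m + alpha m^2)/n per group; two-sided
    p-values use the normal reference.  Degenerate genes (all-zero, or
    constant with no between-group difference signal) get p = 1, z = 0.

    Returns a DataFrame indexed by gene with columns statistic, pvalue.
    """
    if dispersion_mode not in ("pooled", "per_gene"):
        raise ValueError("dispersion_mode must be 'pooled' or 'per_gene'")
    treated, control = _split_groups(normalized, group_labels)
    n_t, n_c = treated.shape[1], control.shape[1]
    if n_t < 3 or n_c < 3:
        warnings.warn(
            "fewer than 3 samples in a group; moment dispersion estimates are noisy",
            stacklevel=2,
        )
    m_t = treated.mean(axis=1)
    m_c = control.mean(axis=1)
    v_t = treated.var(axis=1, ddof=1)
    v_c = control.var(axis=1, ddof=1)

    # pooled within-group moments
    w_t, w_c = n_t - 1, n_c - 1
    pooled_var = (w_t * v_t + w_c * v_c) / (w_t + w_c)
    pooled_mean = (n_t * m_t + n_c * m_c) / (n_t + n_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = (pooled_var - pooled_mean) / pooled_mean**2
    alpha_gene = np.where(np.isfinite(alpha_gene), alpha_gene, DISPERSION_FLOOR)
    alpha_gene = np.maximum(alpha_gene, DISPERSION_FLOOR)
    if dispersion_mode == "pooled":
        # pool the per-gene moment estimates across genes: with only a few
        # samples per group the per-gene estimate is far too noisy for a
        # normal-reference Wald test; the raw moment estimate (pooled_var -
        # pooled_mean)/pooled_mean^2 is nearly unbiased, so its across-gene
        # mean gives a stable cohort-level dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            raw_alpha = (pooled_var - pooled_mean) / pooled_mean**2
        raw_alpha = raw_alpha[np.isfinite(raw_alpha)]
        alpha_pooled = float(raw_alpha.mean()) if raw_alpha.size else DISPERSION_FLOOR
        alpha = np.full_like(alpha_gene, max(alpha_pooled, DISPERSION_FLOOR))
    else:
        alpha = alpha_gene

    ok = (m_t > 0) & (m_c > 0)
    z = np.zeros(normalized.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log(m_t / m_c)
        se = np.sqrt(
            (m_t + alpha * m_t**2) / (n_t * m_t**2)
            + (m_c + alpha * m_c**2) / (n_c * m_c**2)
        )
        z_ok = lfc / se
    z[ok] = np.where(np.isfinite(z_ok[ok]), z_ok[ok], 0.0)
    # constant genes (zero pooled variance, identical means) carry no evidence
    degenerate = ok & (se == 0)
    z[degenerate] = 0.0
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.clip(pvalue, 0.0, 1.0)
    # a zero group mean leaves the log fold-change undefined; such genes keep
    # z = 0, p = 1 (conservative; includes the all-zero case)
    pvalue[~ok] = 1.0
    return pd.DataFrame(
        {"statistic": z, "pvalue": pvalue}, index=normalized.gene_ids
    )


def apply_de_filters(
    results: pd.DataFrame,
    mean_min: float = DEFAULT_MEAN_MIN,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> pd.DataFrame:
    """Set the ``passes`` flag: mean_norm > mean_min AND |log2fc| > lfc_min
    AND fdr < fdr_max (all strict, as printed)."""
    required = {"gene_id", "mean_norm", "log2fc", "fdr"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    out = results.copy()
    out["passes"] = (
        (out["mean_norm"] > mean_min)
        & (out["log2fc"].abs() > lfc_min)
        & (out["fdr"] < fdr_max)
    )
    return out


def de_pipeline(
    raw: ExpressionMatrix,
    group_labels,
    pseudocount: float = 0.5,
    mean_min: float = DEFAULT_MEAN_MIN,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> pd.DataFrame:
    """normalize -> test -> BH-FDR -> filter; returns the full DEResult table."""
    factors = size_factors(raw)
    norm = normalize_counts(raw, factors)
    test = nb_wald_test(norm, group_labels)
    lfc = log2_fold_change(norm, group_labels, pseudocount=pseudocount)
    table = pd.DataFrame(
        {
            "gene_id": norm.gene_ids,
            "mean_norm": norm.values.mean(axis=1),
            "log2fc": lfc,
            "statistic": test["statistic"].to_numpy(),
            "pvalue": test["pvalue"].to_numpy(),
        }
    )
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
    return apply_de_filters(table, mean_min=mean_min, lfc_min=lfc_min, fdr_max=fdr_max)
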