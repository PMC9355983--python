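"""Synthetic cohort, treatment, xenograft-growth and qPCR data generators.

Every generator is deterministic given its seed and emulates the statistical
structure the downstream analysis assumes:

* expression counts follow a negative-binomial model with per-gene baseline
  means and a mean/dispersion parameterization, var = m + alpha * m^2;
* NOTCH-activated samples have signature up-set means multiplied by an
  activation fold and down-set means suppressed;
* drug treatment reduces up-set expression in activated samples only;
* xenograft volumes grow exponentially per animal with multiplicative
  lognormal measurement noise, so ln(volume)-vs-day regression assumptions
  hold by construction;
* qPCR Ct values encode true fold-changes as Ct shifts of -log2(fold) with
  additive Gaussian noise, the reference gene fixed at fold 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CtTable,
    ExpressionKind,
    ExpressionMatrix,
    GeneSignature,
    GrowthTable,
    SampleMetadata,
)

__all__ = [
    "CohortSpec",
    "GrowthSpec",
    "simulate_expression_cohort",
    "simulate_treatment_series",
    "simulate_growth_curves",
    "simulate_ct_table",
]

# Per-sample library-size jitter applied to all genes (uniform fold range).
SIZE_FACTOR_JITTER = (0.8, 1.2)


@dataclass
class CohortSpec:
    """Design of a simulated two-class expression cohort."""

    n_activated: int = 10
    n_wildtype: int = 10
    n_genes: int = 1000
    up_effect: float = 4.0
    down_effect: float = 0.25
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (20.0, 2000.0)
    seed: int = 0
    per_gene_dispersion: bool = False
    size_factor_jitter: tuple[float, float] = SIZE_FACTOR_JITTER

    def __post_init__(self) -> None:
        if self.n_activated < 0 or self.n_wildtype < 0:
            raise ValueError("sample counts must be >= 0")
        # up_effect == 1 / down_effect == 1 are allowed as the null cohort
        if not self.up_effect >= 1:
            raise ValueError("up_effect must be >= 1")
        if not (0 < self.down_effect <= 1):
            raise ValueError("down_effect must be in (0, 1]")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ValueError("base_mean_range must be positive and ordered")


@dataclass
class GrowthSpec:
    """Design of a simulated xenograft growth study.

    ``groups`` is a list of (name, n_animals, daily_growth_rate,
    treatment_rate_multiplier); the realized per-animal rate is
    rate * multiplier.  Initial volumes are drawn uniformly from
    ``v0_range`` (mm^3), mimicking randomization at a target volume window.
    """

    groups: list[tuple[str, int, float, float]] = field(
        default_factory=lambda: [("vehicle", 5, 0.08, 1.0), ("drug", 5, 0.08, 0.25)]
    )
    v0_range: tuple[float, float] = (150.0, 300.0)
    noise_sd: float = 0.1
    days: tuple[int, ...] = (0, 4, 7, 11, 14, 18, 21)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for name, n, _rate, _mult in self.groups:
            if n < 2:
                raise ValueError(f"group {name!r} needs >= 2 animals")
        lo, hi = self.v0_range
        if not (0 < lo <= hi):
            raise ValueError("v0_range must be positive and ordered")
        if len(self.days) == 0:
            raise ValueError("at least one measurement day required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative binomial with var = m + alpha*m^2 (Poisson in the alpha->0 limit)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-12
    if np.any(tiny):
        out[tiny] = rng.poisson(mean[tiny])
    if np.any(~tiny):
        a = alpha[~tiny]
        m = mean[~tiny]
        n_param = 1.0 / a
        p_param = n_param / (n_param + m)
        out[~tiny] = rng.negative_binomial(n_param, p_param)
    return out


def _cohort_means(
    spec: CohortSpec, signature: GeneSignature, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Gene ids, baseline means, per-gene dispersions and activation fold vector."""
    sig_genes = list(signature.up_genes) + list(signature.down_genes)
    if spec.n_genes < len(sig_genes):
        raise ValueError(
            f"n_genes={spec.n_genes} smaller than signature size {len(sig_genes)}"
        )
    n_bg = spec.n_genes - len(sig_genes)
    gene_ids = sig_genes + [f"GENE{i:05d}" for i in range(n_bg)]
    lo, hi = spec.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_genes))
    if spec.per_gene_dispersion:
        alpha = spec.dispersion * np.exp(rng.normal(0.0, 0.5, size=spec.n_genes))
    else:
        alpha = np.full(spec.n_genes, spec.dispersion)
    fold = np.ones(spec.n_genes)
    fold[: len(signature.up_genes)] = spec.up_effect
    fold[len(signature.up_genes) : len(sig_genes)] = spec.down_effect
    return gene_ids, base, alpha, fold


def simulate_expression_cohort(
    spec: CohortSpec, signature: GeneSignature
) -> tuple[ExpressionMatrix, SampleMetadata, pd.Series]:
    """Simulate a raw-count cohort of activated vs wild-type samples.

    Returns the count matrix, sample metadata, and a truth-label Series
    (sample_id -> 'activated'/'wild_type') for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids, base, alpha, fold = _cohort_means(spec, signature, rng)

    n = spec.n_activated + spec.n_wildtype
    sample_ids = [f"ACT{i:02d}" for i in range(spec.n_activated)] + [
        f"WT{i:02d}" for i in range(spec.n_wildtype)
    ]
    labels = ["activated"] * spec.n_activated + ["wild_type"] * spec.n_wildtype
    sf = rng.uniform(*spec.size_factor_jitter, size=n)

    values = np.empty((spec.n_genes, n), dtype=float)
    for j in range(n):
        mean_j = base * (fold if labels[j] == "activated" else 1.0) * sf[j]
        values[:, j] = _nb_draw(rng, mean_j, alpha)

    matrix = ExpressionMatrix(gene_ids, sample_ids, values, ExpressionKind.raw)
    meta = SampleMetadata(
        pd.DataFrame(
            {"sample_id": sample_ids, "group": labels, "treatment": "vehicle"}
        )
    )
    truth = pd.Series(labels, index=sample_ids, name="truth")
    return matrix, meta, truth


def simulate_treatment_series(
    cohort_spec: CohortSpec,
    signature: GeneSignature,
    drug_effect: float,
    seed: int,
) -> ExpressionMatrix:
    """Redraw the cohort under drug treatment.

    Treated activated samples have their up-set means further multiplied by
    ``drug_effect`` (< 1); wild-type samples are statistically unchanged.
    Uses the same per-gene baselines as the untreated cohort (same cohort
    seed) so treated/untreated matrices are paired by design.
    """
    if not drug_effect < 1:
        raise ValueError("drug_effect must be < 1 (a suppressive fold)")
    if drug_effect <= 0:
        raise ValueError("drug_effect must be > 0")
    base_rng = np.random.default_rng(cohort_spec.seed)
    gene_ids, base, alpha, fold = _cohort_means(cohort_spec, signature, base_rng)

    rng = np.random.default_rng(seed)
    n = cohort_spec.n_activated + cohort_spec.n_wildtype
    sample_ids = [f"ACT{i:02d}" for i in range(cohort_spec.n_activated)] + [
        f"WT{i:02d}" for i in range(cohort_spec.n_wildtype)
    ]
    labels = ["activated"] * cohort_spec.n_activated + ["wild_type"] * cohort_spec.n_wildtype
    sf = rng.uniform(*cohort_spec.size_factor_jitter, size=n)

    n_up = len(signature.up_genes)
    drug_fold = np.ones(cohort_spec.n_genes)
    drug_fold[:n_up] = drug_effect

    values = np.empty((cohort_spec.n_genes, n), dtype=float)
    for j in range(n):
        if labels[j] == "activated":
            mean_j = base * fold * drug_fold * sf[j]
        else:
            mean_j = base * sf[j]
        values[:, j] = _nb_draw(rng, mean_j, alpha)
    return ExpressionMatrix(gene_ids, sample_ids, values, ExpressionKind.raw)


def simulate_growth_curves(spec: GrowthSpec) -> GrowthTable:
    """Simulate per-animal exponential tumor growth with lognormal noise.

    V(day) = V0 * exp(rate * day) * noise.  Width and length are back-derived
    assuming width = length so that TV = 0.52 * width^2 * length reproduces
    the noisy volume exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for name, n_animals, rate, mult in spec.groups:
        realized = rate * mult
        for a in range(n_animals):
            animal = f"{name}_{a:02d}"
            v0 = rng.uniform(*spec.v0_range)
            for day in spec.days:
                noise = np.exp(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 1.0
                vol = v0 * np.exp(realized * day) * noise
                # invert TV = 0.52 w^2 l with w = l  ->  w = (V/0.52)^(1/3)
                w = (vol / 0.52) ** (1.0 / 3.0)
                rows.append(
                    {
                        "animal_id": animal,
                        "group": name,
                        "day": int(day),
                        "width": w,
                        "length": w,
                        "volume": vol,
                    }
                )
    return GrowthTable(pd.DataFrame(rows))


def simulate_ct_table(
    n_samples: int,
    genes: list[str],
    true_fold_changes: dict[str, float],
    noise_sd: float,
    seed: int,
    reference_gene: str = "ACTB",
    baseline_ct: float = 24.0,
    reference_ct: float = 18.0,
) -> CtTable:
    """Simulate a qPCR Ct table encoding known treated-vs-control folds.

    Target Ct under treatment is baseline - log2(fold) + noise; the reference
    gene's fold is fixed at 1 in both conditions.
    """
    for g, f in true_fold_changes.items():
        if not f > 0:
            raise ValueError(f"fold change for {g!r} must be > 0")
    missing = set(genes) - set(true_fold_changes)
    if missing:
        raise ValueError(f"no fold change given for genes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        sid = f"S{i:02d}"
        for cond in ("control", "treated"):
            rows.append(
                {
                    "sample_id": sid,
                    "condition": cond,
                    "gene": reference_gene,
                    "ct": reference_ct + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0),
                    "is_reference": True,
                }
            )
            for g in genes:
                shift = -np.log2(true_fold_changes[g]) if cond == "treated" else 0.0
                ct = baseline_ct + shift + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    {
                        "sample_id": sid,
                        "condition": cond,
                        "gene": g,
                        "ct": ct,
                        "is_reference": False,
                    }
                )
    return CtTable(pd.DataFrame(rows))
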