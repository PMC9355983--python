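"""NOTCH pathway activation scoring and calling.

Two rank-based scores are computed per sample and combined into a binary
call:

* **ssGSEA** — a single-sample running-sum enrichment score for the up-set.
  Genes are ordered by decreasing expression (ties broken lexicographically
  by gene id for bit-reproducibility); walking down the ranking, the score
  accumulates the difference between the rank-weighted in-set CDF
  (weights r^tau, r the descending rank score) and the uniform out-of-set
  CDF.  Higher scores mean the up-set concentrates at the top of the
  sample's expression profile.

* **kTSP** — the fraction of (down, up) signature gene pairs whose
  within-sample ordering complies with the expected rule down < up.  The
  score is a proportion in [0, 1], invariant under any strictly increasing
  transform of the expression column; ties count as non-compliant.

A sample is called *activated* when both scores clear their thresholds
(kTSP >= 0.5 and ssGSEA >= the cohort median by default).  Samples are also
clustered on the signature genes by Ward.D2 agglomeration on Euclidean
distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "ssgsea_score",
    "ktsp_score",
    "score_cohort",
    "call_activation",
    "signature_cluster",
]


@dataclass
class CallerConfig:
    """Tunable caller parameters.

    tau is the ssGSEA rank-weight exponent (0.25, the conventional default
    of the single-sample enrichment family); ssgsea_threshold of None means
    "cohort median" (data-dependent); ktsp ties are non-compliant.
    """

    tau: float = 0.25
    normalize_scores: bool = True
    ktsp_threshold: float = 0.5
    ssgsea_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0 <= self.ktsp_threshold <= 1):
            raise ValueError("ktsp_threshold must be in [0, 1]")


def _descending_order(values: pd.Series) -> list[str]:
    """Gene ids ordered by decreasing expression, ties lexicographic."""
    df = pd.DataFrame({"v": values.to_numpy(), "g": values.index})
    df = df.sort_values(["v", "g"], ascending=[False, True], kind="mergesort")
    return df["g"].tolist()


def ssgsea_score(
    expression: pd.Series, gene_set, tau: float = 0.25
) -> float:
    """Single-sample enrichment score of ``gene_set`` in one expression column.

    With genes at descending-rank positions 1..N and rank scores
    r = N - position + 1, the score is sum_i [P_in(i) - P_out(i)] where
    P_in weights in-set genes by r^tau and P_out is the uniform CDF of
    out-of-set genes.  If every gene is in the set the out-of-set CDF is
    undefined and the score is 0 by convention (warned).
    """
    genes = list(gene_set.genes) if hasattr(gene_set, "genes") else list(gene_set)
    if len(expression) < 2:
        raise ValueError("need at least 2 genes in the expression column")
    present = [g for g in genes if g in expression.index]
    if not present:
        missing = sorted(set(genes))
        raise ValueError(f"gene set entirely absent from matrix: {missing}")
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} gene-set genes absent from matrix; "
            "scoring on the intersection",
            stacklevel=2,
        )
    order = _descending_order(expression)
    N = len(order)
    present_set = set(present)
    in_set = np.array([g in present_set for g in order])
    if in_set.all():
        warnings.warn("every gene is in the set; score defined as 0", stacklevel=2)
        return 0.0
    r = np.arange(N, 0, -1, dtype=float)  # N, N-1, ..., 1
    w = np.where(in_set, r**tau, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_set) / (N - in_set.sum())
    return float(np.sum(p_in - p_out))


def ktsp_score(expression: pd.Series, signature: GeneSignature) -> float:
    """Fraction of (down, up) pairs with x_down < x_up (strict; ties fail)."""
    up = [g for g in signature.up_genes if g in expression.index]
    down = [g for g in signature.down_genes if g in expression.index]
    if not up or not down:
        raise ValueError(
            "signature needs at least one up gene and one down gene present "
            f"(found {len(up)} up, {len(down)} down)"
        )
    x_up = expression[up].to_numpy()[None, :]
    x_down = expression[down].to_numpy()[:, None]
    return float(np.mean(x_down < x_up))


def score_cohort(
    matrix: ExpressionMatrix, signature: GeneSignature, config: CallerConfig | None = None
) -> pd.DataFrame:
    """ssGSEA and kTSP scores for every sample in the cohort.

    With ``normalize_scores`` the ssGSEA column is min-max rescaled across
    the cohort (purely monotone; calls are unaffected under the default
    cohort-median threshold).
    """
    config = config or CallerConfig()
    rows = []
    for sid in matrix.sample_ids:
        col = matrix.column(sid)
        rows.append(
            {
                "sample_id": sid,
                "ssgsea_score": ssgsea_score(col, signature.up_genes, tau=config.tau),
                "ktsp_score": ktsp_score(col, signature),
            }
        )
    scores = pd.DataFrame(rows)
    if config.normalize_scores and len(scores) > 1:
        lo, hi = scores["ssgsea_score"].min(), scores["ssgsea_score"].max()
        if hi > lo:
            scores["ssgsea_score"] = (scores["ssgsea_score"] - lo) / (hi - lo)
    return scores


def call_activation(
    scores: pd.DataFrame, config: CallerConfig | None = None
) -> pd.DataFrame:
    """Binary activation calls from the two-score table.

    call = activated  iff  ktsp_score >= ktsp_threshold AND
    ssgsea_score >= ssgsea_threshold (cohort median when unset).  The output
    doubles as the two-axis table behind the caller plot (kTSP on x,
    ssGSEA on y).
    """
    config = config or CallerConfig()
    for col in ("sample_id", "ssgsea_score", "ktsp_score"):
        if col not in scores.columns:
            raise ValueError(f"scores table missing column {col!r}")
    if scores[["ssgsea_score", "ktsp_score"]].isna().any().any():
        bad = scores.loc[scores[["ssgsea_score", "ktsp_score"]].isna().any(axis=1)]
        raise ValueError(f"missing score for sample(s): {bad['sample_id'].tolist()}")
    ss_thresh = (
        float(np.median(scores["ssgsea_score"]))
        if config.ssgsea_threshold is None
        else config.ssgsea_threshold
    )
    out = scores.copy()
    activated = (out["ktsp_score"] >= config.ktsp_threshold) & (
        out["ssgsea_score"] >= ss_thresh
    )
    out["call"] = np.where(activated, "activated", "not_activated")
    out.attrs["ktsp_threshold"] = config.ktsp_threshold
    out.attrs["ssgsea_threshold"] = ss_thresh
    logger.info(
        "activation calls: %d/%d activated (ktsp>=%.3g, ssgsea>=%.3g)",
        activated.sum(), len(out), config.ktsp_threshold, ss_thresh,
    )
    return out


def signature_cluster(
    matrix: ExpressionMatrix, signature: GeneSignature, k: int = 2
) -> tuple[np.ndarray, pd.Series]:
    """Ward.D2 hierarchical clustering of samples on signature genes.

    Distances are Euclidean over the signature-gene expression vectors;
    scipy's 'ward' linkage on raw Euclidean distances is the Ward.D2
    criterion.  Returns the linkage matrix and flat labels at the k cut.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    sig_genes = list(signature.up_genes) + list(signature.down_genes)
    sub = matrix.subset_genes(sig_genes)
    if sub.n_genes == 0:
        raise ValueError("no signature genes present in matrix")
    X = sub.values.T  # samples x genes
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=matrix.sample_ids, name="cluster")
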