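"""Xenograft efficacy statistics and qPCR relative quantification.

Tumor volume follows the caliper formula TV = width^2 x length x 0.52
(mm^3).  Percent tumor growth inhibition compares treated and control
group-mean volume changes from baseline to a final day:

    %TGI = 100 * (1 - (T_final - T_baseline) / (C_final - C_baseline))

values above 100% indicate regression below the treated baseline.  Growth
rates are per-animal ordinary-least-squares slopes of ln(volume) on study
day; treatment groups are compared by one-way ANOVA on the slopes followed
by Tukey–Cramer pairwise comparisons (studentized-range reference with the
unequal-n adjustment).  qPCR fold-changes use the 2^-ddCt method with a
designated reference gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CtTable, GrowthTable

logger = logging.getLogger(__name__)

__all__ = [
    "TGIResult",
    "tumor_volume",
    "ensure_volumes",
    "percent_tgi",
    "growth_slopes",
    "anova_tukey",
    "ddct_fold_change",
]

TV_COEFFICIENT = 0.52


@dataclass
class TGIResult:
    treated_group: str
    control_group: str
    baseline_day: int
    final_day: int
    baseline_mean_t: float
    final_mean_t: float
    baseline_mean_c: float
    final_mean_c: float
    tgi_percent: float


def tumor_volume(width_mm, length_mm):
    """Caliper volume TV = 0.52 * width^2 * length (mm^3)."""
    width_mm = np.asarray(width_mm, dtype=float)
    length_mm = np.asarray(length_mm, dtype=float)
    if np.any(width_mm <= 0) or np.any(length_mm <= 0):
        raise ValueError("width and length must be positive")
    out = TV_COEFFICIENT * width_mm**2 * length_mm
    return float(out) if out.ndim == 0 else out


def ensure_volumes(growth: GrowthTable) -> pd.DataFrame:
    """Return the growth table with a volume column, computing it if absent."""
    t = growth.table.copy()
    if "volume" not in t.columns or t["volume"].isna().any():
        t["volume"] = tumor_volume(t["width"].to_numpy(), t["length"].to_numpy())
    return t


def percent_tgi(
    growth: GrowthTable,
    treated_group: str,
    control_group: str,
    baseline_day: int | None = None,
    final_day: int | None = None,
    summary: str = "mean",
) -> TGIResult:
    """Percent tumor growth inhibition of treated vs control group.

    Group volumes are summarized with the arithmetic mean by default (a
    median option is provided).  Baseline defaults to the first day both
    groups share, final to the last shared day.  Animals missing the final
    measurement are excluded with a warning.
    """
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    t = ensure_volumes(growth)
    sub = {g: t[t["group"] == g] for g in (treated_group, control_group)}
    for g, df in sub.items():
        if len(df) == 0:
            raise ValueError(f"group {g!r} not found in growth table")
    common_days = sorted(
        set(sub[treated_group]["day"]) & set(sub[control_group]["day"])
    )
    if not common_days:
        raise ValueError("treated and control groups share no measurement days")
    baseline_day = int(common_days[0]) if baseline_day is None else int(baseline_day)
    final_day = int(common_days[-1]) if final_day is None else int(final_day)

    def summarize(df: pd.DataFrame, day: int) -> float:
        at_day = df[df["day"] == day]
        if len(at_day) == 0:
            raise ValueError(
                f"group {df['group'].iloc[0]!r} has no measurements on day {day}"
            )
        absent = set(df["animal_id"]) - set(at_day["animal_id"])
        if absent:
            logger.warning(
                "day %d: animals %s missing a measurement; excluded",
                day, sorted(absent),
            )
        vals = at_day["volume"].to_numpy()
        return float(np.mean(vals) if summary == "mean" else np.median(vals))

    bt = summarize(sub[treated_group], baseline_day)
    ft = summarize(sub[treated_group], final_day)
    bc = summarize(sub[control_group], baseline_day)
    fc = summarize(sub[control_group], final_day)
    delta_c = fc - bc
    if delta_c == 0:
        raise ValueError("control group volume change is zero; %TGI undefined")
    tgi = 100.0 * (1.0 - (ft - bt) / delta_c)
    return TGIResult(
        treated_group, control_group, baseline_day, final_day, bt, ft, bc, fc, tgi
    )


def growth_slopes(growth: GrowthTable) -> pd.DataFrame:
    """Per-animal OLS slope of ln(volume) on day.

    Returns a DataFrame with animal_id, group, slope (per day on the ln
    scale), intercept, r_squared and n_points.
    """
    t = ensure_volumes(growth)
    if (t["volume"] <= 0).any():
        bad = t.loc[t["volume"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive volume for animal {bad['animal_id']!r} "
            f"day {bad['day']} (ln undefined)"
        )
    rows = []
    for animal, df in t.groupby("animal_id", sort=False):
        days = df["day"].to_numpy(dtype=float)
        lnv = np.log(df["volume"].to_numpy(dtype=float))
        if len(np.unique(days)) < 2:
            raise ValueError(f"animal {animal!r} has < 2 distinct days")
        fit = stats.linregress(days, lnv)
        rows.append(
            {
                "animal_id": animal,
                "group": df["group"].iloc[0],
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r_squared": float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0,
                "n_points": int(len(days)),
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(slopes: pd.DataFrame) -> dict:
    """One-way ANOVA on per-animal slopes plus Tukey–Cramer pairwise table.

    Pairwise comparisons use the studentized-range distribution with the
    harmonic unequal-n adjustment: q_ij = |m_i - m_j| /
    sqrt(MSE/2 * (1/n_i + 1/n_j)), referred to q(k, N-k).  Returns a dict
    with anova_F, anova_p and a pairwise DataFrame.
    """
    groups = list(pd.unique(slopes["group"]))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: slopes.loc[slopes["group"] == g, "slope"].to_numpy() for g in groups}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has < 2 animals")
    F, p = stats.f_oneway(*arrays.values())
    k = len(groups)
    n_total = sum(len(a) for a in arrays.values())
    df_resid = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_resid
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            ai, aj = arrays[gi], arrays[gj]
            diff = ai.mean() - aj.mean()
            if mse == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / len(ai) + 1.0 / len(aj)))
                q = abs(diff) / se
            adj_p = float(stats.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group_i": gi,
                    "group_j": gj,
                    "mean_diff": float(diff),
                    "q": float(q),
                    "adjusted_p": min(max(adj_p, 0.0), 1.0),
                }
            )
    if mse == 0 or not np.isfinite(F):
        # degenerate within-group variance: define F from the group means
        means_equal = len({float(a.mean()) for a in arrays.values()}) == 1
        F, p = (0.0, 1.0) if means_equal else (np.inf, 0.0)
    return {
        "groups": groups,
        "anova_F": float(F),
        "anova_p": float(p),
        "pairwise": pd.DataFrame(rows),
    }


def ddct_fold_change(ct: CtTable) -> pd.DataFrame:
    """Per-gene 2^-ddCt fold change, treated vs control.

    dCt = Ct_target - Ct_reference per (sample, condition); ddCt is the mean
    treated dCt minus the mean control dCt; fold = 2^-ddCt.
    """
    t = ct.table
    ref = t[t["is_reference"]].set_index(["sample_id", "condition"])["ct"]
    targets = t[~t["is_reference"]].copy()
    keys = list(zip(targets["sample_id"], targets["condition"]))
    missing = [k for k in keys if k not in ref.index]
    if missing:
        raise ValueError(f"missing reference Ct for (sample, condition): {missing[0]}")
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[keys].to_numpy()
    rows = []
    for gene, df in targets.groupby("gene", sort=True):
        mean_t = df.loc[df["condition"] == "treated", "dct"].mean()
        mean_c = df.loc[df["condition"] == "control", "dct"].mean()
        if np.isnan(mean_t) or np.isnan(mean_c):
            raise ValueError(f"gene {gene!r} lacks measurements in one condition")
        ddct = mean_t - mean_c
        rows.append({"gene": gene, "ddct": float(ddct), "fold_change": float(2.0**-ddct)})
    return pd.DataFrame(rows)
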