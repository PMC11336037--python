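"""Per-region linear age trends on anchored volumes.

For each region, v'' is regressed on age by OLS within an analysis group.
The slope ``beta`` is the cross-sectional annual rate of change in percent
of anchor-age volume per year; a companion regression on within-group
z-scores of both variables yields the standardized coefficient ``beta_s``,
which in simple regression equals the Pearson correlation of v'' with age.

Effect sizes are classified on |beta_s| with the conventional cutpoints
(negligible < 0.10 <= small < 0.30 <= medium < 0.50 <= large), and
per-region significance uses a Bonferroni-corrected threshold
alpha = 0.05 / 148 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import AnchoredVolumes, anchor_normalize
from .regions import N_REGIONS, RegionRegistry, RegionWeights

EFFECT_CUTPOINTS = (0.10, 0.30, 0.50)
EFFECT_LABELS = ("negligible", "small", "medium", "large")


class TrendError(ValueError):
    pass


def classify_effect(beta_s: float) -> str:
    """Effect-size class from a standardized coefficient.

    Boundaries are closed on the left: |beta_s| in [0.10, 0.30) is small,
    [0.30, 0.50) medium, >= 0.50 large.
    """
    if not np.isfinite(beta_s):
        raise TrendError(f"cannot classify non-finite standardized coefficient {beta_s!r}")
    mag = abs(float(beta_s))
    for cut, label in zip(EFFECT_CUTPOINTS, EFFECT_LABELS[:-1]):
        if mag < cut:
            return label
    return EFFECT_LABELS[-1]


def fit_region_trends(
    anchored: AnchoredVolumes,
    alpha: float = 0.05,
    n_comparisons: int = N_REGIONS,
) -> pd.DataFrame:
    """OLS trend of v'' on age for every region of one group.

    Returns one row per region with ``beta`` (%/year), ``beta_se``,
    ``p`` (two-sided, t distribution with n-2 df), ``beta_s`` (slope after
    z-scoring both v'' and age within the group; NaN for zero-variance
    regions, which are flagged ``degenerate``), ``effect_class`` and
    ``significant`` (Bonferroni, p < alpha / n_comparisons).
    """
    a = anchored.ages.to_numpy(dtype=float)
    n = len(a)
    if n < 3:
        raise TrendError("trend fitting needs at least 3 subjects")
    if np.ptp(a) == 0:
        raise TrendError("degenerate design: constant age")
    V = anchored.vpp.to_numpy(dtype=float)

    a_c = a - a.mean()
    ss_a = a_c @ a_c
    V_c = V - V.mean(axis=0)
    beta = a_c @ V_c / ss_a
    resid = V_c - np.outer(a_c, beta)
    dof = n - 2
    sigma2 = (resid**2).sum(axis=0) / dof
    beta_se = np.sqrt(sigma2 / ss_a)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(beta_se > 0, beta / np.where(beta_se > 0, beta_se, 1.0), np.inf)
        t_stat = np.where((beta == 0) & (beta_se == 0), 0.0, t_stat)
    p = 2.0 * stats.t.sf(np.abs(t_stat), dof)

    sd_v = V.std(axis=0, ddof=0)
    degenerate = sd_v == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_s = np.where(degenerate, np.nan, beta * a.std(ddof=0) / np.where(degenerate, 1.0, sd_v))

    thresh = alpha / n_comparisons
    out = pd.DataFrame(
        {
            "region": anchored.region_names,
            "group": anchored.group,
            "beta": beta,
            "beta_se": beta_se,
            "p": p,
            "beta_s": beta_s,
            "degenerate": degenerate,
            "significant": p < thresh,
        }
    )
    out["effect_class"] = [
        classify_effect(b) if np.isfinite(b) else "undefined" for b in out["beta_s"]
    ]
    return out


def fit_aggregate_trend(
    cohort_group: pd.DataFrame,
    columns: Iterable[str],
    a0="auto",
    label: str = "aggregate",
) -> pd.Series:
    """Trend of a summed (tissue-level) volume, e.g. total cortical GM.

    Sums the given volume columns per subject, applies both normalization
    stages to the sum, and fits the same OLS trend; returns the single
    result row.
    """
    cols = list(columns)
    summed = cohort_group[cols].sum(axis=1).to_frame(label)
    icv = cohort_group["icv"].to_numpy(dtype=float)
    vprime = summed.div(icv, axis=0)
    anchored = anchor_normalize(vprime, cohort_group["age"], a0=a0, group=label)
    fit = fit_region_trends(anchored, n_comparisons=1)
    return fit.iloc[0]


@dataclass(frozen=True)
class DirectionSummary:
    """Counts and cortical-weight fractions of trend signs for one group."""

    group: str
    n_negative: int
    n_positive: int
    n_zero: int
    frac_cortex_negative: float
    frac_cortex_positive: float
    per_hemisphere: dict

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "n_negative": self.n_negative,
            "n_positive": self.n_positive,
            "n_zero": self.n_zero,
            "frac_cortex_negative": self.frac_cortex_negative,
            "frac_cortex_positive": self.frac_cortex_positive,
            "per_hemisphere": self.per_hemisphere,
        }


def summarize_directions(
    trends: pd.DataFrame,
    weights: RegionWeights,
    registry: RegionRegistry,
) -> DirectionSummary:
    """Directional summary: how many structures, and how much cortex, trend
    negative vs positive with age."""
    missing = [n for n in registry.names if n not in set(trends["region"])]
    if missing:
        raise TrendError(f"trend table is missing regions: {missing}")
    t = trends.set_index("region").loc[registry.names]
    beta = t["beta"].to_numpy(dtype=float)
    w = weights.array
    neg, pos = beta < 0, beta > 0
    per_hemi = {}
    for hemi in ("left", "right"):
        mask = registry.hemispheres == hemi
        per_hemi[hemi] = {
            "n_negative": int((neg & mask).sum()),
            "n_positive": int((pos & mask).sum()),
        }
    return DirectionSummary(
        group=str(t["group"].iloc[0]),
        n_negative=int(neg.sum()),
        n_positive=int(pos.sum()),
        n_zero=int((~neg & ~pos).sum()),
        frac_cortex_negative=float(w[neg].sum()),
        frac_cortex_positive=float(w[pos].sum()),
        per_hemisphere=per_hemi,
    )
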