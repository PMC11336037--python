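"""Between-population comparison of age trends and the weighted statistic kappa.

For each region, the bootstrap slope draws of the study group and its
matched reference are compared with Welch's unequal-variance t-test (the
sample size on each side is the number of bootstrap realizations B).  A
ternary indicator m(r) records the outcome under a Bonferroni-corrected
threshold:

    m(r) = +1  if the study slope is significantly more negative (study
               cortex shrinks faster),
           -1  if significantly less negative,
            0  otherwise.

The cortical summary is kappa = 100 * sum_r m(r) * w_r with w_r the
region's fraction of total cortical GM volume, so kappa > 0 means the study
population's cortex declines faster with age on average, and kappa is
bounded by [-100, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import BootstrapResult
from .regions import N_REGIONS, RegionRegistry, RegionWeights


class ComparisonError(ValueError):
    pass


def welch_t(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's two-sample t-statistic from summary statistics.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p-value; accepts scalars or aligned arrays.  The
    p-value is cross-checked against scipy's implementation in the test
    suite rather than delegated, because scipy does not expose df.
    """
    sd1 = np.asarray(sd1, dtype=float)
    sd2 = np.asarray(sd2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ComparisonError("Welch test needs n >= 2 per sample")
    if np.any((sd1 == 0) & (sd2 == 0)):
        raise ComparisonError("Welch test undefined: both variances are zero")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (np.asarray(mean1, dtype=float) - np.asarray(mean2, dtype=float)) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def welch_t_from_draws(x: np.ndarray, y: np.ndarray):
    """Draws-level Welch test; must agree with :func:`welch_t` on the
    draws' moments (ddof=1)."""
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_regions(
    boot: BootstrapResult,
    alpha_family: float = 0.05,
    n_comparisons: int = N_REGIONS,
) -> pd.DataFrame:
    """Welch comparison of study vs reference slope draws for every region.

    Returns one row per region with the bootstrap moments, the Welch
    ``t``/``df``/``p`` at n1 = n2 = B, and the indicator ``m``.
    """
    alpha = alpha_family / n_comparisons
    t, df, p = welch_t(
        boot.mu_study, boot.sigma_study, boot.B,
        boot.mu_reference, boot.sigma_reference, boot.B,
    )
    sig = p < alpha
    m = np.where(sig & (boot.mu_study < boot.mu_reference), 1,
                 np.where(sig & (boot.mu_study > boot.mu_reference), -1, 0))
    return pd.DataFrame(
        {
            "region": boot.region_names,
            "beta_study": boot.mu_study,
            "sd_study": boot.sigma_study,
            "beta_ref": boot.mu_reference,
            "sd_ref": boot.sigma_reference,
            "t": t,
            "df": df,
            "p": p,
            "m": m.astype(int),
            "alpha_used": alpha,
        }
    )


@dataclass(frozen=True)
class KappaSummary:
    """The weighted cortical statistic and its directional decomposition."""

    kappa: float  # percent, in [-100, 100]
    frac_faster_study: float  # weight where m = +1
    frac_faster_reference: float  # weight where m = -1
    frac_no_difference: float
    per_hemisphere: Optional[dict] = None

    def as_dict(self) -> dict:
        d = {
            "kappa": self.kappa,
            "frac_faster_study": self.frac_faster_study,
            "frac_faster_reference": self.frac_faster_reference,
            "frac_no_difference": self.frac_no_difference,
        }
        if self.per_hemisphere is not None:
            d["per_hemisphere"] = self.per_hemisphere
        return d


def kappa(
    comparisons: pd.DataFrame,
    weights: RegionWeights,
    registry: Optional[RegionRegistry] = None,
) -> KappaSummary:
    """kappa = 100 * sum_r m(r) w_r, with directional weight fractions.

    When a registry is supplied, per-hemisphere figures are reported in two
    variants: ``renormalized`` (weights rescaled to sum to 1 within the
    hemisphere, so each hemisphere's kappa spans [-100, 100]) and ``raw``
    (hemisphere contribution to the whole-cortex kappa).
    """
    w_all = weights.values
    missing = [r for r in comparisons["region"] if r not in w_all.index]
    if missing:
        raise ComparisonError(f"no weight for regions: {missing}")
    c = comparisons.set_index("region")
    w = w_all.loc[c.index].to_numpy(dtype=float)
    if abs(w_all.sum() - 1.0) > 1e-9:
        raise ComparisonError("region weights must sum to 1")
    m = c["m"].to_numpy(dtype=int)
    f_plus = float(w[m == 1].sum())
    f_minus = float(w[m == -1].sum())
    f_zero = float(w[m == 0].sum())
    k = 100.0 * float(m @ w)

    per_hemi = None
    if registry is not None:
        per_hemi = {}
        hemi_of = {e.name: e.hemisphere for e in registry.entries}
        hemis = np.array([hemi_of[r] for r in c.index])
        for hemi in ("left", "right"):
            mask = hemis == hemi
            raw = 100.0 * float(m[mask] @ w[mask])
            wsum = w[mask].sum()
            per_hemi[hemi] = {
                "raw": raw,
                "renormalized": raw / wsum if wsum > 0 else np.nan,
            }
    return KappaSummary(
        kappa=k,
        frac_faster_study=f_plus,
        frac_faster_reference=f_minus,
        frac_no_difference=f_zero,
        per_hemisphere=per_hemi,
    )


def laterality_summary(
    trends: pd.DataFrame,
    registry: RegionRegistry,
    comparisons: Optional[pd.DataFrame] = None,
    weights: Optional[RegionWeights] = None,
) -> dict:
    """Per-hemisphere counts of negative/positive-trend structures (of 74)
    and, when a comparison table and weights are given, per-hemisphere
    kappa (renormalized within hemisphere, raw variant alongside)."""
    hemi_of = {e.name: e.hemisphere for e in registry.entries}
    t = trends.set_index("region")
    out: dict = {}
    for hemi in ("left", "right"):
        names = [n for n in t.index if hemi_of.get(n) == hemi]
        beta = t.loc[names, "beta"].to_numpy(dtype=float)
        out[hemi] = {
            "n_structures": len(names),
            "n_negative": int((beta < 0).sum()),
            "n_positive": int((beta > 0).sum()),
        }
    if comparisons is not None and weights is not None:
        ks = kappa(comparisons, weights, registry)
        out["kappa_per_hemisphere"] = ks.per_hemisphere
    return out
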