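"""Single-level mediation of the age-volume relationship (product of
coefficients).

Three OLS regressions on one complete-case sample:

    volume ~ age              -> beta_a        (total effect)
    volume ~ age + mediator   -> beta_a_prime  (direct effect),
                                 beta_t_prime  (mediator effect on volume)
    mediator ~ age            -> beta_b        (age effect on the mediator)

The indirect (mediated) effect is the product beta_b * beta_t_prime, and
the OLS identity

    beta_a = beta_a_prime + beta_b * beta_t_prime

holds exactly on any complete-case sample — it is the primary correctness
oracle for this module.  Inference on the product uses a nonparametric
bootstrap (rows resampled with replacement, 1000 iterations by default):
a percentile confidence interval and sign-flip p-value, plus a normal
approximation that converts the product over its bootstrap standard error
to a z-statistic (reported one- and two-sided).

Inputs are expected already standardized (z-scored within population and
sex); :func:`standardize` is provided for that step, and
:func:`combined_positive_volume` builds the volume of interest used in the
pipeline — the summed volume of structures with positive age trends and
standardized effect sizes above 0.10 within the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


class MediationError(ValueError):
    pass


def standardize(x: pd.Series | np.ndarray) -> np.ndarray:
    """z-score with the sample mean and (population) standard deviation."""
    a = np.asarray(x, dtype=float)
    sd = a.std(ddof=0)
    if sd == 0:
        raise MediationError("cannot standardize a constant variable")
    return (a - a.mean()) / sd


@dataclass(frozen=True)
class MediationResult:
    beta_a: float  # total effect of age on volume
    beta_a_prime: float  # direct effect, adjusting for the mediator
    beta_t_prime: float  # mediator effect on volume, adjusting for age
    beta_b: float  # age effect on the mediator
    indirect: float  # beta_b * beta_t_prime
    boot_ci: tuple[float, float]
    p_percentile: float  # two-sided sign-flip bootstrap p
    p_z_two_sided: float  # product / bootstrap SE against the normal
    p_z_one_sided: float
    boot_se: float
    n_boot: int
    n_obs: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "beta_a": self.beta_a,
            "beta_a_prime": self.beta_a_prime,
            "beta_t_prime": self.beta_t_prime,
            "beta_b": self.beta_b,
            "indirect": self.indirect,
            "boot_ci": list(self.boot_ci),
            "p_percentile": self.p_percentile,
            "p_z_two_sided": self.p_z_two_sided,
            "p_z_one_sided": self.p_z_one_sided,
            "boot_se": self.boot_se,
            "n_boot": self.n_boot,
            "n_obs": self.n_obs,
            "seed": self.seed,
        }


def _fit_paths(age: np.ndarray, mediator: np.ndarray, volume: np.ndarray):
    """The three OLS fits; returns (beta_a, beta_a_prime, beta_t_prime, beta_b)."""
    X1 = np.column_stack([np.ones_like(age), age])
    X2 = np.column_stack([np.ones_like(age), age, mediator])
    beta_a = np.linalg.lstsq(X1, volume, rcond=None)[0][1]
    coef2 = np.linalg.lstsq(X2, volume, rcond=None)[0]
    beta_b = np.linalg.lstsq(X1, mediator, rcond=None)[0][1]
    return beta_a, coef2[1], coef2[2], beta_b


def mediate(
    age,
    mediator,
    volume,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Product-of-coefficients mediation with bootstrap inference.

    Missing values in any variable drop the row (complete-case analysis);
    a warning is logged when more than half of the rows are lost.
    """
    age = np.asarray(age, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if not (len(age) == len(mediator) == len(volume)):
        raise MediationError("age, mediator and volume must have equal length")
    keep = np.isfinite(age) & np.isfinite(mediator) & np.isfinite(volume)
    n_drop = int((~keep).sum())
    if n_drop > 0.5 * len(age):
        logger.warning(
            "mediation drops %d of %d rows as incomplete (> 50%% missingness)",
            n_drop, len(age),
        )
    age, mediator, volume = age[keep], mediator[keep], volume[keep]
    n = len(age)
    if n < 10:
        raise MediationError(f"mediation needs >= 10 complete cases, got {n}")
    if np.ptp(mediator) == 0:
        raise MediationError("mediation undefined: mediator is constant")

    beta_a, beta_a_prime, beta_t_prime, beta_b = _fit_paths(age, mediator, volume)
    indirect = beta_b * beta_t_prime

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    prods = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        _, _, tprime_k, b_k = _fit_paths(age[idx], mediator[idx], volume[idx])
        prods[k] = b_k * tprime_k
    lo, hi = np.percentile(prods, [2.5, 97.5])
    p_pct = 2.0 * min((prods <= 0).mean(), (prods >= 0).mean())
    p_pct = min(1.0, max(p_pct, 1.0 / n_boot))
    se = prods.std(ddof=1)
    if se > 0:
        z = indirect / se
        p_two = 2.0 * stats.norm.sf(abs(z))
        p_one = stats.norm.sf(abs(z))
    else:
        p_two = p_one = 0.0 if indirect != 0 else 1.0
    return MediationResult(
        beta_a=float(beta_a),
        beta_a_prime=float(beta_a_prime),
        beta_t_prime=float(beta_t_prime),
        beta_b=float(beta_b),
        indirect=float(indirect),
        boot_ci=(float(lo), float(hi)),
        p_percentile=float(p_pct),
        p_z_two_sided=float(p_two),
        p_z_one_sided=float(p_one),
        boot_se=float(se),
        n_boot=int(n_boot),
        n_obs=int(n),
        seed=int(seed),
    )


def ols_summary(age, mediator, volume) -> pd.DataFrame:
    """Detailed statsmodels fits of the three regressions (coefficients,
    standard errors and p-values) for reporting."""
    age = np.asarray(age, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    volume = np.asarray(volume, dtype=float)
    X1 = sm.add_constant(age)
    X2 = sm.add_constant(np.column_stack([age, mediator]))
    rows = []
    fits = {
        "volume~age": (sm.OLS(volume, X1).fit(), ["const", "age"]),
        "volume~age+mediator": (sm.OLS(volume, X2).fit(), ["const", "age", "mediator"]),
        "mediator~age": (sm.OLS(mediator, X1).fit(), ["const", "age"]),
    }
    for model, (fit, names) in fits.items():
        for name, b, se, p in zip(names, fit.params, fit.bse, fit.pvalues):
            rows.append({"model": model, "term": name, "coef": b, "se": se, "p": p})
    return pd.DataFrame(rows)


def combined_positive_volume(
    cohort_group: pd.DataFrame,
    trends: pd.DataFrame,
    effect_threshold: float = 0.10,
) -> Optional[pd.Series]:
    """Summed volume of structures with positive trends and |beta_s| above
    the threshold within the group; None when no structure qualifies."""
    sel = trends[(trends["beta"] > 0) & (trends["beta_s"].abs() > effect_threshold)]
    if sel.empty:
        return None
    cols = [r for r in sel["region"] if r in cohort_group.columns]
    if not cols:
        return None
    return cohort_group[cols].sum(axis=1)
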