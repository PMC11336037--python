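"""Matched-subsample bootstrap for per-region trend slopes.

Each of B realizations draws a subsample of ``m_sub`` subjects from the
study group (without replacement by default — a subsample, not a classical
resample, since the study groups are several times larger than ``m_sub``)
and an age-matched subsample of the same size from the reference pool of
the same sex.  Per-region OLS slopes of v'' on age are recorded for both
subsamples at every realization; the draw vectors then yield mu(beta),
sigma(beta), percentile confidence intervals, and the inputs of the
between-population comparison.

Matching draws, for each sampled study subject, one not-yet-used reference
subject with the same integer age; when the pool for an age is exhausted
the nearest available age is used (ties split at random) and the fallback
is counted, never silent.  When the reference pool allows it, the reference
subsample therefore reproduces the study subsample's integer-age histogram
exactly.

RNG scheme: realization k uses the k-th child of ``SeedSequence(seed)``, so
realizations are order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .normalization import AnchoredVolumes

logger = logging.getLogger(__name__)


class BootstrapError(ValueError):
    pass


def _slopes(V: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Per-column OLS slopes of V on a (closed form)."""
    a_c = a - a.mean()
    return a_c @ (V - V.mean(axis=0)) / (a_c @ a_c)


@dataclass(frozen=True)
class BootstrapResult:
    """Per-realization slope draws for a study group and its matched
    reference, over all regions."""

    group: str
    reference: str
    region_names: tuple[str, ...]
    B: int
    m_sub: int
    seed: int
    betas_study: np.ndarray  # (B, R), %/year
    betas_reference: np.ndarray  # (B, R)
    n_fallback: int = 0
    replace: bool = False
    matched: bool = True

    @property
    def mu_study(self) -> np.ndarray:
        return self.betas_study.mean(axis=0)

    @property
    def sigma_study(self) -> np.ndarray:
        return self.betas_study.std(axis=0, ddof=1)

    @property
    def mu_reference(self) -> np.ndarray:
        return self.betas_reference.mean(axis=0)

    @property
    def sigma_reference(self) -> np.ndarray:
        return self.betas_reference.std(axis=0, ddof=1)

    def ci(self, level: float = 0.95, which: str = "study") -> np.ndarray:
        """Percentile interval per region, shape (2, R)."""
        draws = self.betas_study if which == "study" else self.betas_reference
        lo = 100 * (1 - level) / 2
        return np.percentile(draws, [lo, 100 - lo], axis=0)

    def summary(self) -> pd.DataFrame:
        ci_s = self.ci(which="study")
        ci_r = self.ci(which="reference")
        return pd.DataFrame(
            {
                "region": self.region_names,
                "mu_study": self.mu_study,
                "sigma_study": self.sigma_study,
                "ci_lo_study": ci_s[0],
                "ci_hi_study": ci_s[1],
                "mu_reference": self.mu_reference,
                "sigma_reference": self.sigma_reference,
                "ci_lo_reference": ci_r[0],
                "ci_hi_reference": ci_r[1],
            }
        )

    def draws_frame(self) -> pd.DataFrame:
        """Long-format draws (region, realization, beta_study, beta_reference)."""
        B, R = self.betas_study.shape
        return pd.DataFrame(
            {
                "region": np.repeat(self.region_names, B),
                "realization": np.tile(np.arange(B), R),
                "beta_study": self.betas_study.T.ravel(),
                "beta_reference": self.betas_reference.T.ravel(),
            }
        )


def _match_reference(
    rng: np.random.Generator,
    study_ages_int: np.ndarray,
    ref_ages_int: np.ndarray,
    pools_by_age: dict[int, np.ndarray],
) -> tuple[np.ndarray, int]:
    """Indices into the reference pool matching the study integer-age
    histogram as closely as the pool allows; returns (indices, n_fallback)."""
    need = {}
    for age in study_ages_int:
        need[age] = need.get(age, 0) + 1

    remaining: dict[int, list[int]] = {}
    chosen: list[int] = []
    deficit: list[int] = []  # ages still needing a subject
    for age, idx in pools_by_age.items():
        perm = rng.permutation(idx)
        k = need.get(age, 0)
        take = min(k, len(perm))
        chosen.extend(perm[:take].tolist())
        remaining[age] = perm[take:].tolist()
        if k > take:
            deficit.extend([age] * (k - take))
    for age in need:
        if age not in pools_by_age:
            deficit.extend([age] * need[age])

    n_fallback = len(deficit)
    for age in deficit:
        avail = [a for a, lst in remaining.items() if lst]
        if not avail:
            raise BootstrapError("reference pool exhausted during matching")
        dists = np.abs(np.array(avail) - age)
        nearest = [a for a, d in zip(avail, dists) if d == dists.min()]
        pick_age = nearest[rng.integers(len(nearest))] if len(nearest) > 1 else nearest[0]
        chosen.append(remaining[pick_age].pop())
    return np.array(chosen), n_fallback


def bootstrap_group_betas(
    anchored_study: AnchoredVolumes,
    anchored_reference: AnchoredVolumes,
    B: int = 1000,
    m_sub: int = 100,
    seed: int = 0,
    replace: bool = False,
    match: bool = True,
) -> BootstrapResult:
    """Draw B matched subsample pairs and record per-region trend slopes.

    ``anchored_study`` and ``anchored_reference`` must already be restricted
    to the same sex (groups are population x sex throughout); matching is on
    integer age.  ``replace=True`` switches to with-replacement resampling,
    in which case ``m_sub`` may equal or exceed the group size (classical
    bootstrap); ``match=False`` draws the reference subsample uniformly.
    """
    names = anchored_study.region_names
    if list(anchored_reference.region_names) != list(names):
        raise BootstrapError("study and reference anchored tables cover different regions")
    V_s = anchored_study.vpp.to_numpy(dtype=float)
    V_r = anchored_reference.vpp.to_numpy(dtype=float)
    a_s = anchored_study.ages.to_numpy(dtype=float)
    a_r = anchored_reference.ages.to_numpy(dtype=float)
    n_s, n_r = len(a_s), len(a_r)
    if not replace and n_s < m_sub:
        raise BootstrapError(f"study group ({n_s}) smaller than subsample size ({m_sub})")
    if not replace and n_r < m_sub:
        raise BootstrapError(f"reference group ({n_r}) smaller than subsample size ({m_sub})")

    ref_ages_int = np.round(a_r).astype(int)
    pools_by_age = {
        int(age): np.flatnonzero(ref_ages_int == age) for age in np.unique(ref_ages_int)
    }

    children = np.random.SeedSequence(int(seed)).spawn(B)
    bs = np.empty((B, len(names)))
    br = np.empty((B, len(names)))
    total_fallback = 0
    for k in range(B):
        rng = np.random.default_rng(children[k])
        idx_s = rng.choice(n_s, size=m_sub, replace=replace)
        if match:
            study_ages_int = np.round(a_s[idx_s]).astype(int)
            idx_r, nf = _match_reference(rng, study_ages_int, ref_ages_int, pools_by_age)
            total_fallback += nf
        else:
            idx_r = rng.choice(n_r, size=m_sub, replace=replace)
        bs[k] = _slopes(V_s[idx_s], a_s[idx_s])
        br[k] = _slopes(V_r[idx_r], a_r[idx_r])
    if total_fallback:
        logger.info(
            "age matching used nearest-age fallback %d time(s) across %d realizations "
            "(%s vs %s)", total_fallback, B, anchored_study.group, anchored_reference.group,
        )
    return BootstrapResult(
        group=anchored_study.group,
        reference=anchored_reference.group,
        region_names=tuple(names),
        B=B,
        m_sub=m_sub,
        seed=int(seed),
        betas_study=bs,
        betas_reference=br,
        n_fallback=total_fallback,
        replace=replace,
        matched=match,
    )


def test_beta_nonzero(
    result: BootstrapResult,
    alpha: float = 0.05,
    which: str = "study",
    bonferroni_n: Optional[int] = None,
) -> pd.DataFrame:
    """Per-region test of H0: beta = 0 from the bootstrap draws.

    Rejects when the two-sided percentile interval at level ``alpha``
    (optionally Bonferroni-divided by ``bonferroni_n``) excludes zero.
    """
    if result.B < 100:
        raise BootstrapError("beta tests need at least 100 realizations")
    level = alpha / (bonferroni_n or 1)
    ci = result.ci(level=1 - level, which=which)
    reject = (ci[0] > 0) | (ci[1] < 0)
    return pd.DataFrame(
        {
            "region": result.region_names,
            "ci_lo": ci[0],
            "ci_hi": ci[1],
            "reject": reject,
            "alpha_used": level,
        }
    )
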