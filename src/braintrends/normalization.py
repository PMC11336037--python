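"""Two-stage volumetric normalization.

Stage 1 divides each regional volume by the subject's intracranial volume
(ICV), removing head-size differences: ``v'_ir = v_ir / ICV_i``.

Stage 2 anchors each region to its regression-predicted value at the
sample's youngest age a0.  An ordinary least-squares line ``v' = beta_r *
age + c_r`` is fit per region within the group; each v' is then expressed
as a percent of the predicted anchor value:

    v''_ir = 100 * v'_ir / (beta_r * a0 + c_r)

so a subsequent slope of v'' on age reads directly as percent of
anchor-age volume per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .regions import RegionRegistry

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class AnchoredVolumes:
    """Doubly normalized volumes for one analysis group.

    ``vpp`` holds v'' (subjects x regions, percent of predicted anchor-age
    volume); ``fits`` holds one row per region with the anchor regression
    (columns ``region``, ``beta_r``, ``c_r``, ``a0``, ``anchor_pred``).
    Regions whose predicted anchor volume is not positive are excluded from
    ``vpp`` and listed in ``excluded``.
    """

    group: str
    a0: float
    ages: pd.Series
    vpp: pd.DataFrame
    fits: pd.DataFrame
    excluded: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return len(self.vpp)

    @property
    def region_names(self) -> list[str]:
        return list(self.vpp.columns)


def icv_normalize(cohort: pd.DataFrame, registry: RegionRegistry) -> pd.DataFrame:
    """Divide every regional volume by the subject's ICV (stage 1)."""
    icv = cohort["icv"].to_numpy(dtype=float)
    bad = ~(icv > 0)
    if bad.any():
        offenders = cohort.loc[bad, "subject_id"].tolist()
        raise NormalizationError(f"non-positive ICV for subjects: {offenders}")
    vols = cohort[registry.names].to_numpy(dtype=float)
    vprime = vols / icv[:, None]
    return pd.DataFrame(vprime, index=cohort.index, columns=registry.names)


def anchor_normalize(
    vprime: pd.DataFrame,
    ages: pd.Series,
    a0: Union[float, str] = "auto",
    group: str = "",
) -> AnchoredVolumes:
    """Express v' as percent of the regression-predicted anchor-age value
    (stage 2).

    ``a0="auto"`` resolves to the minimum observed age, the sample's
    youngest age.
    """
    a = np.asarray(ages, dtype=float)
    if len(a) < 3:
        raise NormalizationError("anchoring needs at least 3 subjects")
    if np.ptp(a) == 0:
        raise NormalizationError("degenerate design: all subjects share the same age")
    anchor_age = float(np.min(a)) if isinstance(a0, str) and a0 == "auto" else float(a0)

    V = vprime.to_numpy(dtype=float)
    a_c = a - a.mean()
    betas = a_c @ (V - V.mean(axis=0)) / (a_c @ a_c)
    intercepts = V.mean(axis=0) - betas * a.mean()
    anchor_pred = betas * anchor_age + intercepts

    usable = anchor_pred > 0
    excluded = tuple(np.asarray(vprime.columns)[~usable])
    if excluded:
        logger.warning(
            "anchor prediction <= 0 for %d region(s); excluded: %s",
            len(excluded), list(excluded),
        )
    vpp = 100.0 * V[:, usable] / anchor_pred[None, usable]
    fits = pd.DataFrame(
        {
            "region": vprime.columns,
            "beta_r": betas,
            "c_r": intercepts,
            "a0": anchor_age,
            "anchor_pred": anchor_pred,
            "usable": usable,
        }
    )
    return AnchoredVolumes(
        group=group,
        a0=anchor_age,
        ages=pd.Series(a, index=vprime.index, name="age"),
        vpp=pd.DataFrame(vpp, index=vprime.index, columns=vprime.columns[usable]),
        fits=fits,
        excluded=excluded,
    )


def anchor_by_group(
    cohort: pd.DataFrame,
    registry: RegionRegistry,
    a0: Union[float, str] = "auto",
    anchor_grouping: str = "population_sex",
) -> dict[tuple[str, str], AnchoredVolumes]:
    """Run both normalization stages within each population x sex group.

    Anchoring is done within each group (``anchor_grouping="population_sex"``,
    the default, mirroring the within-group standardization used downstream);
    ``"pooled"`` fits one anchor line on the full table instead.
    """
    out: dict[tuple[str, str], AnchoredVolumes] = {}
    if anchor_grouping == "pooled":
        vprime_all = icv_normalize(cohort, registry)
        pooled = anchor_normalize(vprime_all, cohort["age"], a0=a0, group="pooled")
        for (pop, sex), idx in cohort.groupby(["population", "sex"]).groups.items():
            out[(pop, sex)] = AnchoredVolumes(
                group=f"{pop}/{sex}",
                a0=pooled.a0,
                ages=pooled.ages.loc[idx],
                vpp=pooled.vpp.loc[idx],
                fits=pooled.fits,
                excluded=pooled.excluded,
            )
        return out
    if anchor_grouping != "population_sex":
        raise NormalizationError(f"unknown anchor_grouping {anchor_grouping!r}")
    for (pop, sex), sub in cohort.groupby(["population", "sex"]):
        vprime = icv_normalize(sub, registry)
        out[(pop, sex)] = anchor_normalize(
            vprime, sub["age"], a0=a0, group=f"{pop}/{sex}"
        )
    return out
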