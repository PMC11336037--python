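"""CT-vs-MRI agreement metrics for regional volumetry.

CT-derived regional volumes are validated against MRI (the gold standard)
on a small paired sample.  Two quantities are computed:

* the per-region average difference Delta v_r between CT and MRI volumes
  (in mm^3, or in percent of the MRI volume);
* a weighted scalar summary varpi of the absolute discrepancies.

Two varpi conventions are provided.  The ``weighted_percent`` default is a
cortical-weight-weighted mean of per-region absolute percent differences,

    varpi = sum_r w_r * |Delta v_r^percent|,   w_r fractions summing to 1,

which reads directly as "CT differs from MRI by varpi percent of the MRI
volume on average".  The ``verbatim`` mode is the alternative
(1/R) * sum_r w_r |Delta v_r| form with w_r expressed in percent and the
deltas in mm^3; it is retained for fidelity but is brain-size dependent and
does not carry the percent-of-MRI interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import N_REGIONS, RegionWeights


class ValidationError(ValueError):
    pass


def region_deltas(pairs: pd.DataFrame, percent: bool = True) -> pd.Series:
    """Average CT - MRI difference per region.

    ``pairs`` is long-format with columns ``subject_id``, ``region``,
    ``v_ct``, ``v_mri``.  Every (subject, region) must appear exactly once
    with both modalities present.  In percent mode each difference is
    expressed as 100 * (CT - MRI) / MRI before averaging.
    """
    required = {"subject_id", "region", "v_ct", "v_mri"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValidationError(f"pairs table missing columns: {sorted(missing)}")
    dupes = pairs.duplicated(subset=["subject_id", "region"])
    if dupes.any():
        raise ValidationError(
            f"duplicate (subject, region) rows: "
            f"{pairs.loc[dupes, ['subject_id', 'region']].values.tolist()[:5]}"
        )
    bad = pairs[["v_ct", "v_mri"]].isna().any(axis=1)
    if bad.any():
        raise ValidationError(
            f"unpaired rows (missing modality): "
            f"{pairs.loc[bad, ['subject_id', 'region']].values.tolist()[:5]}"
        )
    if percent:
        diff = 100.0 * (pairs["v_ct"] - pairs["v_mri"]) / pairs["v_mri"]
    else:
        diff = pairs["v_ct"] - pairs["v_mri"]
    out = diff.groupby(pairs["region"]).mean()
    out.name = "delta"
    return out


def varpi(deltas: pd.Series, weights: RegionWeights, mode: str = "weighted_percent") -> float:
    """Weighted summary of absolute CT/MRI discrepancies (see module docs)."""
    w = weights.values
    missing = [r for r in deltas.index if r not in w.index]
    if missing:
        raise ValidationError(f"no weight for regions: {missing}")
    if len(deltas) != len(w):
        raise ValidationError(
            f"deltas cover {len(deltas)} regions but weights cover {len(w)}"
        )
    aligned = w.loc[deltas.index].to_numpy(dtype=float)
    abs_d = np.abs(deltas.to_numpy(dtype=float))
    if mode == "weighted_percent":
        return float(aligned @ abs_d)
    if mode == "verbatim":
        return float((100.0 * aligned) @ abs_d / len(deltas))
    raise ValidationError(f"unknown varpi mode {mode!r}")


@dataclass(frozen=True)
class ValidationResult:
    deltas_mm3: pd.Series
    deltas_percent: pd.Series
    varpi_weighted_percent: float
    varpi_verbatim: float

    def as_dict(self) -> dict:
        return {
            "varpi_weighted_percent": self.varpi_weighted_percent,
            "varpi_verbatim_mm3": self.varpi_verbatim,
            "deltas_percent": self.deltas_percent.to_dict(),
        }


def validate_ct_mri(pairs: pd.DataFrame, weights: RegionWeights) -> ValidationResult:
    """Full agreement report: per-region deltas in both units and both
    varpi conventions."""
    d_mm3 = region_deltas(pairs, percent=False)
    d_pct = region_deltas(pairs, percent=True)
    return ValidationResult(
        deltas_mm3=d_mm3,
        deltas_percent=d_pct,
        varpi_weighted_percent=varpi(d_pct, weights, "weighted_percent"),
        varpi_verbatim=varpi(d_mm3, weights, "verbatim"),
    )
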