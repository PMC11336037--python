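"""Readers/writers for cohort, validation and configuration files.

All tables are plain CSV/TSV with documented headers; percentages are
stored as fractions internally and rendered as percent only in reports.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .regions import RegionRegistry, load_region_registry

REQUIRED_COHORT_COLUMNS = ("subject_id", "population", "sex", "age", "icv")
OPTIONAL_COHORT_COLUMNS = ("stick_score", "moderate_minutes", "mediated_volume")


class ParseError(ValueError):
    pass


def read_cohort(path, registry: Optional[RegionRegistry] = None) -> pd.DataFrame:
    """Read and validate a subject-level cohort CSV.

    The file must carry the required demographic columns and one volume
    column per registry region name; unknown extra columns are preserved
    untouched.
    """
    registry = registry or load_region_registry()
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    missing_regions = [r for r in registry.names if r not in df.columns]
    if missing_regions:
        raise ParseError(
            f"{path}: missing {len(missing_regions)} region column(s), "
            f"first few: {missing_regions[:5]}"
        )
    for col in ("age", "icv", *registry.names):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = vals
    if not df["subject_id"].is_unique:
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()[:5]
        raise ParseError(f"{path}: duplicate subject_id values {dupes}")
    if (df["icv"] <= 0).any():
        offenders = df.loc[df["icv"] <= 0, "subject_id"].tolist()[:5]
        raise ParseError(f"{path}: non-positive ICV for subjects {offenders}")
    if (df[list(registry.names)] < 0).any().any():
        raise ParseError(f"{path}: negative regional volume")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_validation_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "region", "v_ct", "v_mri"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if (df[["v_ct", "v_mri"]] <= 0).any().any():
        raise ParseError(f"{path}: non-positive volume in validation pairs")
    return df


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return data


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
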