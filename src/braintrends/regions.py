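"""Registry of the 148 Destrieux cortical structures and cortical volume weights.

The Destrieux parcellation divides each cortical hemisphere into 74 gyral and
sulcal gray-matter structures (148 in total).  Every analysis in this package
is indexed by these structures, so the registry is the single source of truth
for region identity, ordering, hemisphere membership and left/right pairing.

Region ids are 1-based: the left hemisphere occupies ids 1..74 (pair ids
1..74 in the bundled label order) and the right hemisphere ids 75..148, so a
left/right homologous pair shares its ``pair_id``.  All files and reports use
the verbatim label text (``lh_``/``rh_`` prefixed FreeSurfer a2009s codes) to
avoid ordering drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_REGIONS = 148
N_PER_HEMISPHERE = 74
HEMISPHERES = ("left", "right")
_PREFIX = {"left": "lh", "right": "rh"}

#: FreeSurfer a2009s structure codes, one per homologous left/right pair,
#: in the conventional aparc.a2009s table order.
DESTRIEUX_BASE_LABELS: tuple[str, ...] = (
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
)

assert len(DESTRIEUX_BASE_LABELS) == N_PER_HEMISPHERE


class RegistryError(ValueError):
    """Raised when a region registry source violates the 148-structure scheme."""


@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    hemisphere: str
    pair_id: int


@dataclass(frozen=True)
class RegionRegistry:
    """Ordered collection of the 148 cortical structures.

    Invariants (checked on construction): exactly 148 entries, 74 per
    hemisphere, unique names, each pair_id appearing exactly once per
    hemisphere.
    """

    entries: tuple[Region, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != N_REGIONS:
            raise RegistryError(
                f"registry must contain {N_REGIONS} structures, got {len(self.entries)}"
            )
        names = [e.name for e in self.entries]
        if len(set(names)) != N_REGIONS:
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RegistryError(f"duplicate region labels: {dupes}")
        for hemi in HEMISPHERES:
            n = sum(e.hemisphere == hemi for e in self.entries)
            if n != N_PER_HEMISPHERE:
                raise RegistryError(
                    f"expected {N_PER_HEMISPHERE} {hemi}-hemisphere structures, got {n}"
                )
        seen = set()
        for e in self.entries:
            key = (e.hemisphere, e.pair_id)
            if key in seen:
                raise RegistryError(f"duplicate (hemisphere, pair_id) for {e.name!r}")
            seen.add(key)
        pair_hemis: dict[int, set[str]] = {}
        for e in self.entries:
            pair_hemis.setdefault(e.pair_id, set()).add(e.hemisphere)
        for e in self.entries:
            if len(pair_hemis[e.pair_id]) != 2:
                raise RegistryError(f"structure {e.name!r} has no homologue in the other hemisphere")

    # -- accessors -------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def region_ids(self) -> np.ndarray:
        return np.array([e.region_id for e in self.entries])

    @property
    def hemispheres(self) -> np.ndarray:
        return np.array([e.hemisphere for e in self.entries])

    @property
    def pair_ids(self) -> np.ndarray:
        return np.array([e.pair_id for e in self.entries])

    def hemisphere_names(self, hemisphere: str) -> list[str]:
        return [e.name for e in self.entries if e.hemisphere == hemisphere]

    def by_name(self, name: str) -> Region:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [e.region_id for e in self.entries],
                "name": self.names,
                "hemisphere": [e.hemisphere for e in self.entries],
                "pair_id": [e.pair_id for e in self.entries],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _split_label(label: str) -> tuple[str, str]:
    """Return (hemisphere, base_code) for a prefixed label."""
    for hemi, pfx in _PREFIX.items():
        if label.startswith(pfx + "_"):
            return hemi, label[len(pfx) + 1 :]
    if label.startswith("L "):
        return "left", label[2:]
    if label.startswith("R "):
        return "right", label[2:]
    raise RegistryError(f"label {label!r} carries no hemisphere marker (lh_/rh_ or 'L '/'R ')")


def default_region_labels() -> list[str]:
    """The bundled label list: lh block (ids 1..74) then rh block (75..148)."""
    return [f"{_PREFIX[h]}_{code}" for h in HEMISPHERES for code in DESTRIEUX_BASE_LABELS]


def load_region_registry(source: Optional[pd.DataFrame | Sequence[str]] = None) -> RegionRegistry:
    """Build the region registry, from the bundled labels or a user table.

    Parameters
    ----------
    source
        Optional table of 148 labels.  Either a sequence of prefixed label
        strings or a DataFrame with a ``name`` column.  Labels must carry a
        hemisphere marker; each left structure must have a right homologue.
        Ordering of the source is irrelevant: the registry is normalized to
        the canonical region-id order (bundled order when the base codes are
        the bundled ones, alphabetical base-code order otherwise).
    """
    if source is None:
        labels = default_region_labels()
    elif isinstance(source, pd.DataFrame):
        if "name" not in source.columns:
            raise RegistryError("registry source table must have a 'name' column")
        labels = [str(x) for x in source["name"]]
    else:
        labels = [str(x) for x in source]

    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise RegistryError(f"duplicate region labels: {dupes}")
    if len(labels) != N_REGIONS:
        raise RegistryError(f"expected {N_REGIONS} labels, got {len(labels)}")

    parsed = [_split_label(l) for l in labels]
    by_hemi: dict[str, set[str]] = {"left": set(), "right": set()}
    for hemi, code in parsed:
        by_hemi[hemi].add(code)
    unpaired_left = sorted(by_hemi["left"] - by_hemi["right"])
    unpaired_right = sorted(by_hemi["right"] - by_hemi["left"])
    if unpaired_left or unpaired_right:
        offender = (unpaired_left + unpaired_right)[0]
        raise RegistryError(
            f"structure {offender!r} has no homologue in the other hemisphere "
            f"(unpaired left: {unpaired_left}, unpaired right: {unpaired_right})"
        )

    base_codes = by_hemi["left"]
    if base_codes == set(DESTRIEUX_BASE_LABELS):
        ordered_codes = list(DESTRIEUX_BASE_LABELS)
    else:
        ordered_codes = sorted(base_codes)

    # Preserve the verbatim label text from the source for each (hemi, code).
    label_of = {(h, c): lbl for lbl, (h, c) in zip(labels, parsed)}
    entries = []
    rid = 0
    for hemi in HEMISPHERES:
        for pair_id, code in enumerate(ordered_codes, start=1):
            rid += 1
            entries.append(Region(rid, label_of[(hemi, code)], hemi, pair_id))
    return RegionRegistry(tuple(entries))


@dataclass(frozen=True)
class RegionWeights:
    """Per-region fractions of total cortical GM volume (sum to 1).

    Stored as fractions; rendered as percent only in reports.
    """

    values: pd.Series  # index: region name, in registry order

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("region weights must be non-negative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"region weights must sum to 1 (got {v.sum()!r})")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_percent(self) -> pd.Series:
        return self.values * 100.0

    def subset(self, names: Iterable[str]) -> pd.Series:
        """Raw (unrenormalized) weights for a subset of regions."""
        return self.values.loc[list(names)]


def compute_region_weights(
    cohort: pd.DataFrame,
    registry: RegionRegistry,
    population: Optional[str] = None,
    sex: Optional[str] = None,
) -> RegionWeights:
    """Cortical-share weights w_r for a population/sex group.

    w_r = (group mean volume of region r) / (group mean total cortical GM
    volume); the total is the sum over the 148 structures, so the weights
    sum to 1 by construction.
    """
    sel = pd.Series(True, index=cohort.index)
    if population is not None:
        sel &= cohort["population"] == population
    if sex is not None:
        sel &= cohort["sex"] == sex
    group = cohort.loc[sel, registry.names]
    if group.empty:
        raise ValueError(f"empty group for population={population!r}, sex={sex!r}")
    vals = group.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative regional volume in weight computation")
    means = vals.mean(axis=0)
    weights = means / means.sum()
    return RegionWeights(pd.Series(weights, index=registry.names, name="weight"))
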