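"""ROI sampling plan enumeration, vascular-adjacency validation, and
clinical stratification of the cohort.

The sampling design is a full factorial per case: 5 stains x 4 Brodmann
areas x {grey, white} matter x {vascular-adjacent, non-adjacent} x 3
replicate 500x500 um fields = 240 ROIs per case (4,800 for a 20-case
cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from neuroihc.cohort import domains_from_str
from neuroihc.constants import (
    ADJACENCIES,
    ECAS_DOMAINS,
    MATTERS,
    MIN_VESSEL_DIAMETER_UM,
    NVA_CLEARANCE_UM,
    REGIONS,
    ROI_SIZE_UM,
    STAINS,
    SURVIVAL_CUTOFF_MONTHS,
)

PLAN_COLUMNS = ["roi_id", "case_id", "stain", "region", "matter", "adjacency", "replicate"]


@dataclass(frozen=True)
class ROISpec:
    """One sampled 500x500 um field."""

    roi_id: str
    case_id: str
    stain: str
    region: str
    matter: str
    adjacency: str
    replicate: int
    size_um: tuple = (ROI_SIZE_UM, ROI_SIZE_UM)


def _check_unique(name: str, levels: Sequence[str]) -> None:
    if len(set(levels)) != len(levels):
        raise ValueError(f"duplicate levels in {name}: {levels!r}")
    if not levels:
        raise ValueError(f"{name} must be nonempty")


def enumerate_plan(
    cohort: pd.DataFrame,
    stains: Sequence[str] = STAINS,
    regions: Sequence[str] = REGIONS,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Enumerate the full-factorial ROI plan for a cohort sheet."""
    for name, levels in (("stains", stains), ("regions", regions)):
        _check_unique(name, list(levels))
    rows = []
    for case_id in cohort["case_id"]:
        for stain in stains:
            for region in regions:
                for matter in MATTERS:
                    for adjacency in ADJACENCIES:
                        for rep in range(1, n_replicates + 1):
                            rid = f"{case_id}|{stain}|{region}|{matter}|{adjacency}|r{rep}"
                            rows.append((rid, case_id, stain, region, matter, adjacency, rep))
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def specs_from_plan(plan: pd.DataFrame) -> list[ROISpec]:
    return [
        ROISpec(r.roi_id, r.case_id, r.stain, r.region, r.matter, r.adjacency, int(r.replicate))
        for r in plan.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# vascular adjacency


def _dist_point_to_roi_um(x: float, y: float, size_um: tuple[float, float]) -> float:
    """Euclidean distance from a point to the ROI rectangle (0 if inside)."""
    dx = max(0.0 - x, 0.0, x - size_um[0])
    dy = max(0.0 - y, 0.0, y - size_um[1])
    return float(np.hypot(dx, dy))


def validate_adjacency(
    vessels: Iterable[tuple[float, float, float]] | None,
    *,
    roi_size_um: tuple[float, float] = (ROI_SIZE_UM, ROI_SIZE_UM),
    min_clearance_um: float = NVA_CLEARANCE_UM,
    min_vessel_diameter_um: float = MIN_VESSEL_DIAMETER_UM,
    central_box_frac: float = 0.2,
) -> str:
    """Classify an ROI as vascular-adjacent (VA), non-adjacent (NVA), or invalid.

    ``vessels`` is the vessel annotation for the field, a sequence of
    (x_um, y_um, lumen_diameter_um) in ROI coordinates (points may lie
    outside the ROI).  A vessel qualifies if its lumen diameter is at
    least ``min_vessel_diameter_um`` ("larger than a small capillary").

    VA: a qualifying vessel lies within the central tolerance box (the
    central ``central_box_frac`` of each side) — the ROI is centred on it.
    NVA: no qualifying vessel within ``min_clearance_um`` of the ROI.
    Anything else (an off-centre qualifying vessel too close to the field)
    is ``invalid`` and should be resampled.
    """
    if vessels is None:
        raise ValueError("vessel annotation is required (pass an empty list for none)")
    qualifying = [(x, y, d) for x, y, d in vessels if d >= min_vessel_diameter_um]
    cx, cy = roi_size_um[0] / 2.0, roi_size_um[1] / 2.0
    half_box = (central_box_frac * roi_size_um[0] / 2.0, central_box_frac * roi_size_um[1] / 2.0)
    for x, y, _ in qualifying:
        if abs(x - cx) <= half_box[0] and abs(y - cy) <= half_box[1]:
            return "VA"
    if all(
        _dist_point_to_roi_um(x, y, roi_size_um) >= min_clearance_um for x, y, _ in qualifying
    ):
        return "NVA"
    return "invalid"


# ---------------------------------------------------------------------------
# clinical stratification


@dataclass
class ClinicalGroups:
    """Case-ID groupings used in the clinicopathological analyses."""

    domain: str
    impaired: list = field(default_factory=list)
    unimpaired: list = field(default_factory=list)
    no_ecas: list = field(default_factory=list)
    long_survivors: list = field(default_factory=list)
    short_survivors: list = field(default_factory=list)
    controls: list = field(default_factory=list)

    def testable(self, min_n: int = 3) -> dict:
        """Which groups may enter statistical comparisons (n >= min_n)."""
        return {
            name: len(group) >= min_n
            for name, group in (
                ("impaired", self.impaired),
                ("unimpaired", self.unimpaired),
                ("long_survivors", self.long_survivors),
                ("short_survivors", self.short_survivors),
                ("controls", self.controls),
            )
        }


def stratify_cases(
    cohort: pd.DataFrame,
    domain: str,
    survival_cutoff_months: int = SURVIVAL_CUTOFF_MONTHS,
) -> ClinicalGroups:
    """Partition disease cases by ECAS-domain impairment and by survival.

    Disease cases with ECAS data split into domain-impaired vs unimpaired
    (a multi-domain FTD case counts as impaired in each constituent
    domain; impairment confined to other domains counts as unimpaired
    here).  Cases without ECAS are excluded from the domain groups but
    retained for the survival split (duration > cutoff = long survivor).
    """
    if domain not in ECAS_DOMAINS:
        raise ValueError(f"unknown ECAS domain {domain!r}; valid: {ECAS_DOMAINS}")
    groups = ClinicalGroups(domain=domain)
    for row in cohort.itertuples(index=False):
        if row.group == "control":
            groups.controls.append(row.case_id)
            continue
        if row.ecas_available:
            if domain in domains_from_str(row.ecas_domains_impaired):
                groups.impaired.append(row.case_id)
            else:
                groups.unimpaired.append(row.case_id)
        else:
            groups.no_ecas.append(row.case_id)
        if pd.notna(row.duration_months):
            if row.duration_months > survival_cutoff_months:
                groups.long_survivors.append(row.case_id)
            else:
                groups.short_survivors.append(row.case_id)
    return groups
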