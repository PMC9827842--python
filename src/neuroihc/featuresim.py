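"""Detection-level synthetic feature sampler.

Draws superpixel and cell feature records directly from the same
effect/noise model the image renderer uses (case-level intercepts +
per-ROI multiplicative noise on a latent stain burden), without rasterising
images.  This is the workhorse for classifier and statistics experiments
where thousands of ROIs are needed; the pixel-level renderer ties the same
model to the actual quantification code on a smaller grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from neuroihc.constants import ROI_SIZE_UM, stage_seed
from neuroihc.effects import EffectConfig, StainEffect
from neuroihc.render import _class_probs

#: Band of mean DAB OD per intensity class (matches the 0.2/0.4/0.6
#: thresholds; class 3 capped at 0.9).
CLASS_OD_BANDS = {0: (0.01, 0.2), 1: (0.2, 0.4), 2: (0.4, 0.6), 3: (0.6, 0.9)}

DEFAULT_SUPERPIXELS_PER_ROI = 24
DEFAULT_CELLS_PER_ROI = 10

#: Marginal sd of superpixel mean DAB OD under control baselines; the
#: unit for detection-level ``od_shift_sigma`` effects.
MARGINAL_OD_SD = 0.10


def latent_positive_fraction(
    config: EffectConfig, stain: str, case_id: str, group: str, rng: np.random.Generator
) -> float:
    """One ROI's latent positive-area fraction under the effect model."""
    base = config.baseline(stain)
    delta = config.effect(stain).positive_density_delta if group == "disease" else 0.0
    u = config.case_intercept(case_id, stain)
    e = rng.normal(0.0, config.roi_sd) if config.roi_sd else 0.0
    return float(np.clip((base.positive_fraction + delta + u) * (1.0 + e), 0.0, 0.85))


def burden_sigma(config: EffectConfig, stain: str) -> float:
    """Sd of the latent positive fraction across ROIs of one group.

    Combines the case-level intercept sd with the per-ROI multiplicative
    noise at the control baseline; used to express planted effects in
    sigma units.
    """
    base = config.baseline(stain).positive_fraction
    return float(np.hypot(config.case_sd, config.roi_sd * base))


def sigma_effect(config: EffectConfig, stain: str, n_sigma: float = 2.0) -> StainEffect:
    """A pure positive-density effect of ``n_sigma`` latent sd for one stain."""
    return StainEffect(positive_density_delta=n_sigma * burden_sigma(config, stain))


def sample_detections(
    plan: pd.DataFrame,
    cohort: pd.DataFrame,
    config: EffectConfig,
    seed: int,
    *,
    n_superpixels_per_roi: int = DEFAULT_SUPERPIXELS_PER_ROI,
    n_cells_per_roi: int = DEFAULT_CELLS_PER_ROI,
    cell_stains: tuple = ("FUS",),
    superpixel_area_um2: float = 400.0,
) -> pd.DataFrame:
    """Sample per-detection feature records for every ROI in the plan.

    Returns a tidy frame with the plan metadata plus superpixel features
    (mean DAB OD, intensity class, area, perimeter, circularity, centroid,
    distance-to-vessel for VA fields) and, for ``cell_stains``, cell
    records (nucleus area, compartment ODs, N/C ratio).
    """
    group_of = dict(zip(cohort["case_id"], cohort["group"]))
    rng = np.random.default_rng(stage_seed(seed, "featuresim"))
    rows: list[dict] = []
    for roi in plan.itertuples(index=False):
        group = group_of[roi.case_id]
        base = config.baseline(roi.stain)
        eff = config.effect(roi.stain) if group == "disease" else StainEffect()
        meta = {
            "roi_id": roi.roi_id,
            "case_id": roi.case_id,
            "stain": roi.stain,
            "region": roi.region,
            "matter": roi.matter,
            "adjacency": roi.adjacency,
            "label": group,
        }
        f = latent_positive_fraction(config, roi.stain, roi.case_id, group, rng)
        probs = _class_probs(base.mean_class + eff.intensity_class_shift)
        circ_mu = float(np.clip(base.circularity + eff.circularity_delta, 0.1, 0.95))
        prox_mu = max(10.0, base.vessel_proximity_mean_um + eff.vessel_proximity_delta_um)
        n_pos = rng.binomial(n_superpixels_per_roi, f)
        classes = np.concatenate(
            [
                rng.choice([1, 2, 3], size=n_pos, p=probs),
                np.zeros(n_superpixels_per_roi - n_pos, dtype=int),
            ]
        )
        od_shift = eff.od_shift_sigma * MARGINAL_OD_SD
        for klass in classes:
            lo, hi = CLASS_OD_BANDS[int(klass)]
            area = rng.lognormal(np.log(superpixel_area_um2), 0.25)
            circ = float(np.clip(rng.normal(circ_mu, 0.08), 0.1, 1.0))
            od = rng.uniform(lo, hi)
            if od_shift:
                od = float(np.clip(od + od_shift, 0.0, 1.2))
                klass = int(np.digitize(od, [0.2, 0.4, 0.6]))
            rows.append(
                meta
                | {
                    "detection_type": "superpixel",
                    "mean_dab_od": od,
                    "intensity_class": int(klass),
                    "area_um2": area,
                    "perimeter_um": float(np.sqrt(4 * np.pi * area / circ)),
                    "circularity": circ,
                    "centroid_x_um": rng.uniform(0, ROI_SIZE_UM),
                    "centroid_y_um": rng.uniform(0, ROI_SIZE_UM),
                    "dist_to_vessel_um": (
                        15.0 + rng.exponential(prox_mu) if roi.adjacency == "VA" else np.nan
                    ),
                    "nucleus_area_um2": np.nan,
                    "nuclear_mean_od": np.nan,
                    "cytoplasmic_mean_od": np.nan,
                    "nc_ratio": np.nan,
                }
            )
        if roi.stain in cell_stains:
            nc_glia = base.nc_ratio + (eff.glial_nc_ratio_delta if group == "disease" else 0.0)
            for _ in range(n_cells_per_roi):
                is_neuron = rng.random() < 0.25
                nuc_area = rng.normal(95.0, 15.0) if is_neuron else rng.normal(28.0, 5.0)
                nuc_od = max(0.05, rng.normal(0.32, 0.05))
                nc = (base.nc_ratio if is_neuron else nc_glia) * max(
                    0.2, 1.0 + rng.normal(0.0, 0.08)
                )
                rows.append(
                    meta
                    | {
                        "detection_type": "cell",
                        "mean_dab_od": np.nan,
                        "intensity_class": 0,
                        "area_um2": np.nan,
                        "perimeter_um": np.nan,
                        "circularity": np.nan,
                        "centroid_x_um": rng.uniform(0, ROI_SIZE_UM),
                        "centroid_y_um": rng.uniform(0, ROI_SIZE_UM),
                        "dist_to_vessel_um": np.nan,
                        "nucleus_area_um2": max(5.0, nuc_area),
                        "nuclear_mean_od": nuc_od,
                        "cytoplasmic_mean_od": nuc_od / nc,
                        "nc_ratio": nc,
                    }
                )
    return pd.DataFrame(rows)


def informative_noise_detections(
    n_rois: int,
    n_noise_features: int,
    shift: float,
    seed: int,
    *,
    rows_per_roi: int = 10,
) -> pd.DataFrame:
    """Detection table with one informative feature among pure noise.

    Half the ROIs are labelled disease with ``signal`` shifted by
    ``shift`` (in units of its sd = 1); all other features are N(0, 1)
    noise for both groups.  Used for leave-one-out feature-importance
    checks with a known answer.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_rois):
        label = "disease" if i % 2 == 0 else "control"
        case = f"{'ALS' if label == 'disease' else 'CTL'}-{i // 2:02d}"
        mu = shift if label == "disease" else 0.0
        for _ in range(rows_per_roi):
            rec = {
                "roi_id": f"roi-{i:03d}",
                "case_id": case,
                "stain": "Iba1",
                "region": "BA4",
                "matter": "GM",
                "adjacency": "VA",
                "label": label,
                "signal": rng.normal(mu, 1.0),
            }
            for j in range(n_noise_features):
                rec[f"noise_{j}"] = rng.normal(0.0, 1.0)
            recs.append(rec)
    return pd.DataFrame(recs)
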