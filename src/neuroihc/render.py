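"""Brightfield IHC ROI renderer with known ground truth.

Each 500x500 um field is composed in optical-density space: a
haematoxylin channel of elliptical nuclei (two nuclear-area modes for
neuron-like vs glia-like cells) plus a DAB channel whose texture depends
on the stain — ramified/amoeboid blobs (microglial markers), fibrillar
strands (astrocyte marker), sparse puncta (pTDP-43 aggregates), or
nuclear + cytoplasmic cell staining (FUS).  Vascular-adjacent fields get
a centred vessel (lumen + wall annulus).  The two OD fields are mixed
through the haematoxylin/DAB stain vectors and inverted through
Beer-Lambert (I = I0 * 10^-OD) into an 8-bit RGB image; Gaussian noise is
added on OD.  The planted stain content is returned alongside the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw

from neuroihc.constants import ROI_SIZE_UM
from neuroihc.effects import EffectConfig, StainBaseline
from neuroihc.sampling import ROISpec
from neuroihc.stain_quant import HD_VECTORS

#: DAB OD painted for intensity classes 1+/2+/3+ (centres of the
#: conventional 0.2/0.4/0.6 threshold bands).
CLASS_OD = {1: 0.30, 2: 0.50, 3: 0.70}

DEFAULT_UM_PER_PX = 0.5
NUCLEI_PER_MM2 = 3200.0
NEURON_FRACTION_GM = 0.25
NEURON_FRACTION_WM = 0.05


@dataclass
class GroundTruth:
    """Planted content of one rendered ROI."""

    roi_id: str
    positive_fraction: float
    mean_intensity_class: float
    n_objects: int
    n_nuclei: int
    n_neurons: int
    n_glia: int
    vessel_mask: np.ndarray
    vessels: list  # [(x_um, y_um, lumen_diameter_um)]
    nc_ratio_target: float = np.nan
    cells: pd.DataFrame | None = None
    dab_mask: np.ndarray | None = field(default=None, repr=False)


def _class_probs(mean_class: float) -> np.ndarray:
    """Discretised-normal class distribution over {1,2,3} with given centre."""
    m = float(np.clip(mean_class, 1.0, 3.0))
    k = np.array([1.0, 2.0, 3.0])
    p = np.exp(-0.5 * ((k - m) / 0.7) ** 2)
    return p / p.sum()


def _paint_disks(dab, class_map, centers, r_px, od, klass):
    h, w = dab.shape
    for cy, cx in centers:
        rr, cc = draw.disk((cy, cx), max(1.0, r_px), shape=(h, w))
        np.maximum.at(dab, (rr, cc), od)
        np.maximum.at(class_map, (rr, cc), klass)


def _paint_object(dab, class_map, rng, cy, cx, r_px, steps, od, klass):
    """One stained object: union of disks along a random walk."""
    centers = [(cy, cx)]
    y, x = float(cy), float(cx)
    ang = rng.uniform(0, 2 * np.pi)
    for _ in range(max(0, steps - 1)):
        ang += rng.normal(0.0, 0.9)
        step = r_px * rng.uniform(0.8, 1.6)
        y += step * np.sin(ang)
        x += step * np.cos(ang)
        centers.append((y, x))
    _paint_disks(dab, class_map, centers, r_px, od, klass)


def render_roi(
    spec: ROISpec,
    config: EffectConfig,
    seed: int,
    *,
    group: str = "control",
    um_per_px: float = DEFAULT_UM_PER_PX,
    i0: float = 255.0,
):
    """Render one brightfield ROI and its ground truth.

    ``group`` ("disease" or "control") selects whether the planted
    disease deltas from ``config`` apply.  Identical arguments produce
    byte-identical images.
    """
    base: StainBaseline = config.baseline(spec.stain)
    eff = config.effect(spec.stain) if group == "disease" else None
    rng = np.random.default_rng(seed)
    side = int(round(ROI_SIZE_UM / um_per_px))
    px_area_mm2 = (ROI_SIZE_UM / 1000.0) ** 2

    hema = np.zeros((side, side), dtype=float)
    dab = np.zeros((side, side), dtype=float)
    class_map = np.zeros((side, side), dtype=np.int8)

    # ---- vessel (VA only): centred lumen + wall annulus ----
    vessel_mask = np.zeros((side, side), dtype=bool)
    vessels: list[tuple[float, float, float]] = []
    lumen_xy = None
    if spec.adjacency == "VA":
        lumen_r_um = rng.uniform(8.0, 20.0)
        jitter = 0.8 * (0.2 * ROI_SIZE_UM / 2.0) - lumen_r_um  # stay inside central box
        jitter = max(jitter, 0.0)
        cx_um = ROI_SIZE_UM / 2 + rng.uniform(-jitter, jitter)
        cy_um = ROI_SIZE_UM / 2 + rng.uniform(-jitter, jitter)
        lumen_xy = (cy_um / um_per_px, cx_um / um_per_px)
        lumen_r_px = lumen_r_um / um_per_px
        wall_px = 4.0 / um_per_px
        rr, cc = draw.disk(lumen_xy, lumen_r_px + wall_px, shape=(side, side))
        vessel_mask[rr, cc] = True
        hema[rr, cc] = 0.45  # wall
        rr, cc = draw.disk(lumen_xy, lumen_r_px, shape=(side, side))
        hema[rr, cc] = 0.0  # open lumen
        vessels.append((cx_um, cy_um, 2 * lumen_r_um))

    # ---- nuclei (haematoxylin) ----
    neuron_frac = NEURON_FRACTION_GM if spec.matter == "GM" else NEURON_FRACTION_WM
    n_nuclei = int(rng.poisson(NUCLEI_PER_MM2 * px_area_mm2))
    nuc_rows = []
    for i in range(n_nuclei):
        cy = rng.uniform(0, side)
        cx = rng.uniform(0, side)
        if vessel_mask[int(cy) % side, int(cx) % side]:
            continue  # keep the vessel open
        is_neuron = rng.random() < neuron_frac
        r_um = rng.normal(5.5, 0.7) if is_neuron else rng.normal(3.0, 0.4)
        r_px = max(1.5, r_um / um_per_px)
        ry, rx = r_px * rng.uniform(0.85, 1.15), r_px * rng.uniform(0.85, 1.15)
        rr, cc = draw.ellipse(cy, cx, ry, rx, shape=(side, side), rotation=rng.uniform(0, np.pi))
        np.maximum.at(hema, (rr, cc), rng.normal(0.55, 0.06))
        nuc_rows.append(
            {
                "cell_id": i + 1,
                "x_px": cx,
                "y_px": cy,
                "r_px": float(np.sqrt(ry * rx)),
                "cell_type": "neuron" if is_neuron else "glia",
            }
        )
    nuclei = pd.DataFrame(nuc_rows)

    # ---- latent burden: baseline + disease delta + case intercept,
    # times per-ROI multiplicative noise ----
    delta_pf = eff.positive_density_delta if eff else 0.0
    u_case = config.case_intercept(spec.case_id, spec.stain)
    e_roi = rng.normal(0.0, config.roi_sd) if config.roi_sd else 0.0
    target_f = float(np.clip((base.positive_fraction + delta_pf + u_case) * (1.0 + e_roi), 0.0, 0.85))
    mean_class = base.mean_class + (eff.intensity_class_shift if eff else 0.0)
    probs = _class_probs(mean_class)

    nc_target = np.nan
    cells_df = None
    n_objects = 0

    if base.texture == "cellular":
        # nuclear + cytoplasmic compartment staining on every cell
        nc_base = base.nc_ratio
        nc_glia = nc_base + (eff.glial_nc_ratio_delta if eff else 0.0)
        nc_target = nc_glia
        ring_px = 3.0 / um_per_px
        cell_rows = []
        for row in nuclei.itertuples(index=False):
            nuc_od = max(0.05, rng.normal(0.32, 0.04))
            nc = nc_glia if row.cell_type == "glia" else nc_base
            nc *= max(0.2, 1.0 + rng.normal(0.0, 0.05))
            cyto_od = nuc_od / nc
            rr, cc = draw.disk((row.y_px, row.x_px), row.r_px + ring_px, shape=(side, side))
            np.maximum.at(dab, (rr, cc), cyto_od)
            np.maximum.at(class_map, (rr, cc), 1)
            rr, cc = draw.disk((row.y_px, row.x_px), row.r_px, shape=(side, side))
            np.maximum.at(dab, (rr, cc), nuc_od)
            np.maximum.at(class_map, (rr, cc), 2)
            cell_rows.append(
                {
                    "cell_id": row.cell_id,
                    "cell_type": row.cell_type,
                    "nuclear_od": nuc_od,
                    "cytoplasmic_od": cyto_od,
                    "nc_ratio": nuc_od / cyto_od,
                }
            )
        cells_df = pd.DataFrame(cell_rows)
        n_objects = len(cells_df)
    elif target_f > 0:
        # paint stained objects until the planted area fraction is reached
        total_px = side * side
        steps = base.elongation_steps
        if eff and eff.circularity_delta < 0:
            steps += int(round(-eff.circularity_delta * 25))
        prox_mean = base.vessel_proximity_mean_um + (
            eff.vessel_proximity_delta_um if eff else 0.0
        )
        prox_mean = max(10.0, prox_mean)
        max_objects = 30_000
        while (class_map > 0).mean() < target_f and n_objects < max_objects:
            r_um = rng.uniform(*base.blob_radius_um)
            r_px = r_um / um_per_px
            if lumen_xy is not None:
                d_px = (rng.exponential(prox_mean)) / um_per_px
                ang = rng.uniform(0, 2 * np.pi)
                cy = lumen_xy[0] + d_px * np.sin(ang)
                cx = lumen_xy[1] + d_px * np.cos(ang)
                if not (0 <= cy < side and 0 <= cx < side):
                    continue
            else:
                cy, cx = rng.uniform(0, side), rng.uniform(0, side)
            klass = int(rng.choice([1, 2, 3], p=probs))
            od = CLASS_OD[klass] + rng.normal(0.0, 0.02)
            _paint_object(dab, class_map, rng, cy, cx, r_px, steps, od, klass)
            n_objects += 1
        del total_px

    dab_mask = class_map > 0
    # planted DAB is never painted into the open lumen
    if lumen_xy is not None:
        lum_rr, lum_cc = draw.disk(lumen_xy, (vessels[0][2] / 2) / um_per_px, shape=(side, side))
        dab[lum_rr, lum_cc] = 0.0
        class_map[lum_rr, lum_cc] = 0
        dab_mask = class_map > 0

    positive_fraction = float(dab_mask.mean())
    mean_cls = float(class_map[dab_mask].mean()) if dab_mask.any() else 0.0

    # ---- Beer-Lambert composition ----
    od_rgb = hema[..., None] * HD_VECTORS[0] + dab[..., None] * HD_VECTORS[1]
    if config.od_noise_sd:
        od_rgb = od_rgb + rng.normal(0.0, config.od_noise_sd, od_rgb.shape)
    od_rgb = np.clip(od_rgb, 0.0, None)
    img = np.clip(np.round(i0 * np.power(10.0, -od_rgb)), 0, 255).astype(np.uint8)

    n_neurons = int((nuclei["cell_type"] == "neuron").sum()) if len(nuclei) else 0
    truth = GroundTruth(
        roi_id=spec.roi_id,
        positive_fraction=positive_fraction,
        mean_intensity_class=mean_cls,
        n_objects=n_objects,
        n_nuclei=len(nuclei),
        n_neurons=n_neurons,
        n_glia=len(nuclei) - n_neurons,
        vessel_mask=vessel_mask,
        vessels=vessels,
        nc_ratio_target=nc_target,
        cells=cells_df,
        dab_mask=dab_mask,
    )
    return img, truth
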