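"""Superpixel-level DAB quantification of brightfield IHC ROIs.

Pipeline per ROI: RGB -> optical density (Beer-Lambert), colour
deconvolution into haematoxylin + DAB densities, SLIC superpixel
segmentation of the DAB channel, per-superpixel intensity class (0, 1+,
2+, 3+), morphology and spatial features, and a digital Allred score
summarising the distribution of superpixel stain intensities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from skimage.segmentation import slic

# Published haematoxylin / eosin / DAB unit optical-density vectors
# (Ruifrok-Johnston colour-deconvolution convention), rows normalised.
STAIN_VECTORS = {
    "hematoxylin": np.array([0.650, 0.704, 0.286]),
    "eosin": np.array([0.072, 0.990, 0.105]),
    "dab": np.array([0.268, 0.570, 0.776]),
}


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: Default 2-stain basis for DAB-developed, haematoxylin-counterstained IHC.
HD_VECTORS = np.vstack([unit(STAIN_VECTORS["hematoxylin"]), unit(STAIN_VECTORS["dab"])])

#: DAB mean-OD thresholds separating intensity classes 0 / 1+ / 2+ / 3+.
DEFAULT_INTENSITY_THRESHOLDS = (0.2, 0.4, 0.6)

#: Intensity floor added before the log to avoid -inf at intensity 0.
OD_EPS = 1.0 / 255.0


def rgb_to_od(image: np.ndarray, i0=255.0) -> np.ndarray:
    """Convert an 8-bit RGB image to per-channel optical density.

    OD_c = -log10((I_c + eps) / I0_c), clipped at 0 so a white pixel
    (I = I0) has zero OD in all channels.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3); got shape {image.shape}")
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), (3,))
    if np.any(i0 <= 0):
        raise ValueError("I0 must be > 0 in every channel")
    od = -np.log10((image.astype(float) + OD_EPS) / i0)
    return np.clip(od, 0.0, None)


class DegenerateStainsError(ValueError):
    """Stain vectors are collinear (unmixing is ill-posed)."""


def deconvolve(od: np.ndarray, stain_vectors: np.ndarray = HD_VECTORS):
    """Least-squares colour deconvolution of an OD image.

    Parameters
    ----------
    od : (H, W, 3) optical-density image.
    stain_vectors : (n, 3) array of 2-3 unit stain OD vectors.

    Returns
    -------
    densities : (H, W, n) per-stain density images, clipped at 0.
    residual : (H, W) Euclidean norm of the unexplained OD (for a 2-stain
        basis this is the third, residual component).
    """
    vectors = np.atleast_2d(np.asarray(stain_vectors, dtype=float))
    n = vectors.shape[0]
    if vectors.shape[1] != 3 or not 2 <= n <= 3:
        raise ValueError("stain_vectors must be (2-3, 3)")
    if np.linalg.matrix_rank(vectors, tol=1e-8) < n:
        raise DegenerateStainsError("stain vectors are collinear / linearly dependent")
    flat = od.reshape(-1, 3)
    dens = flat @ np.linalg.pinv(vectors)
    resid = flat - dens @ vectors
    dens = np.clip(dens, 0.0, None)
    return (
        dens.reshape(od.shape[:-1] + (n,)),
        np.linalg.norm(resid, axis=1).reshape(od.shape[:-1]),
    )


def separate_hd(image: np.ndarray, i0=255.0):
    """RGB ROI -> (haematoxylin density, DAB density) convenience wrapper."""
    dens, _ = deconvolve(rgb_to_od(image, i0), HD_VECTORS)
    return dens[..., 0], dens[..., 1]


def segment_superpixels(
    density: np.ndarray,
    target_area_um2: float,
    um_per_px: float,
    *,
    compactness: float = 0.2,
    sigma: float = 1.5,
    seed: int | None = None,
) -> np.ndarray:
    """SLIC superpixel segmentation of a single-channel density image.

    ``target_area_um2`` sets the requested mean superpixel area; labels
    start at 1 and partition the image.  The image is Gaussian-smoothed
    (``sigma``, px) before clustering so superpixel boundaries adhere to
    stained-object edges rather than pixel noise.  SLIC is deterministic,
    so ``seed`` is accepted for interface stability but not consumed.
    """
    del seed
    if target_area_um2 <= 0:
        raise ValueError("target_area_um2 must be > 0")
    density = np.asarray(density, dtype=float)
    roi_area_um2 = density.size * um_per_px**2
    n_segments = int(round(roi_area_um2 / target_area_um2))
    if n_segments < 2:
        warnings.warn("target superpixel area >= ROI area; returning a single label")
        return np.ones(density.shape, dtype=int)
    return slic(
        density,
        n_segments=n_segments,
        compactness=compactness,
        sigma=sigma,
        channel_axis=None,
        start_label=1,
        enforce_connectivity=True,
    )


def classify_intensity(mean_dab_od, thresholds=DEFAULT_INTENSITY_THRESHOLDS):
    """Bin mean DAB OD into intensity class 0 (negative) or 1+/2+/3+.

    Half-open convention: class k for OD in [t_k, t_{k+1}).
    """
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (3,) or not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be a strictly ascending triple")
    out = np.digitize(mean_dab_od, t)
    if np.isscalar(mean_dab_od):
        return int(out)
    return out


def superpixel_features(
    labels: np.ndarray,
    dab_density: np.ndarray,
    vessel_mask: np.ndarray | None,
    um_per_px: float,
    *,
    roi_id: str = "roi",
    thresholds=DEFAULT_INTENSITY_THRESHOLDS,
) -> pd.DataFrame:
    """Extract one feature record per superpixel.

    Features: mean DAB OD and intensity class (staining), area and
    perimeter in um (morphology), circularity 4*pi*A/P^2 (shape, clipped
    at 1 against rasterisation overshoot), centroid in um from the ROI
    top-left (x right, y down), and centroid distance to the nearest
    vessel pixel (absent when no vessel mask is supplied).
    """
    labels = np.asarray(labels)
    if labels.shape != np.asarray(dab_density).shape:
        raise ValueError("labels and dab_density must share a shape")
    if vessel_mask is not None and np.asarray(vessel_mask).any():
        dist_px = ndi.distance_transform_edt(~np.asarray(vessel_mask, dtype=bool))
    else:
        dist_px = None
    rows = []
    for rp in measure.regionprops(labels, intensity_image=dab_density):
        area_px = rp.area
        perim_px = max(rp.perimeter, 1.0)
        circ = min(1.0, 4.0 * math.pi * area_px / perim_px**2)
        cy, cx = rp.centroid  # row, col
        if dist_px is not None:
            d = float(dist_px[int(round(cy)), int(round(cx))]) * um_per_px
        else:
            d = np.nan
        mean_od = float(rp.intensity_mean)
        rows.append(
            {
                "roi_id": roi_id,
                "label": int(rp.label),
                "mean_dab_od": mean_od,
                "intensity_class": classify_intensity(mean_od, thresholds),
                "area_um2": area_px * um_per_px**2,
                "perimeter_um": perim_px * um_per_px,
                "circularity": circ,
                "centroid_x_um": cx * um_per_px,
                "centroid_y_um": cy * um_per_px,
                "dist_to_vessel_um": d,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# digital Allred score


@dataclass(frozen=True)
class AllredScore:
    proportion_score: int  # 0-5
    intensity_score: int  # 0-3
    total: int  # 0-8


#: Standard clinical Allred proportion-score bins on the positive fraction.
ALLRED_PROPORTION_EDGES = (0.0, 0.01, 0.1, 1.0 / 3.0, 2.0 / 3.0)


def allred_proportion_score(f: float) -> int:
    """Positive fraction -> Allred proportion score 0-5 (standard bins)."""
    if not 0 <= f <= 1:
        raise ValueError("positive fraction must be in [0, 1]")
    if f == 0:
        return 0
    return int(np.searchsorted(np.asarray(ALLRED_PROPORTION_EDGES[1:]), f, side="left")) + 1


def digital_allred(records: pd.DataFrame) -> AllredScore:
    """Digital Allred score of one ROI from its superpixel records.

    Proportion score bins the fraction of superpixels with class >= 1;
    intensity score is the mean class among positive superpixels rounded
    half-up to 1-3 (0 when none are positive); total is their sum.
    """
    if len(records) == 0:
        raise ValueError("digital_allred needs at least one superpixel record")
    classes = records["intensity_class"].to_numpy()
    positive = classes >= 1
    f = positive.mean()
    p = allred_proportion_score(float(f))
    if positive.any():
        i = int(np.clip(math.floor(classes[positive].mean() + 0.5), 1, 3))
    else:
        i = 0
    return AllredScore(p, i, p + i)


def count_detections(
    superpixels: pd.DataFrame, cells: pd.DataFrame | None = None
) -> dict:
    """Per-ROI detection counts: superpixels by intensity class, cells by type."""
    counts = {
        "n_superpixels": int(len(superpixels)),
        "n_positive_superpixels": int((superpixels["intensity_class"] >= 1).sum())
        if len(superpixels)
        else 0,
    }
    for k in range(4):
        counts[f"n_class_{k}"] = (
            int((superpixels["intensity_class"] == k).sum()) if len(superpixels) else 0
        )
    if cells is not None:
        counts["n_cells"] = int(len(cells))
        for t in ("neuron", "glia"):
            counts[f"n_{t}"] = (
                int((cells["cell_type"] == t).sum()) if len(cells) else 0
            )
    return counts


def positive_area_fraction(records: pd.DataFrame) -> float:
    """Area-weighted fraction of the ROI covered by positive superpixels."""
    if len(records) == 0:
        return 0.0
    pos = records["intensity_class"] >= 1
    return float(records.loc[pos, "area_um2"].sum() / records["area_um2"].sum())
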